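"""Turn a differential-expression table into a reversion-ready disease signature.

Strict |LFC|/padj filtering with an adaptive cutoff targeting 100-200 genes, orthology
mapping onto the reference universe, then the top 100 genes per direction by fold
change.
"""

from sigrev import (SimulationConfig, adaptive_lfc_cutoff, build_signature,
                    filter_de, map_orthologs, simulate_bundle)
from sigrev.signatures import DEFAULT_GRID

bundle = simulate_bundle(SimulationConfig(seed=7))
table = bundle.de_tables["precystic"]

cutoff, n_pass = adaptive_lfc_cutoff(table, padj_cutoff=0.05, grid=DEFAULT_GRID)
print(f"adaptive LFC cutoff: {cutoff} ({n_pass} genes pass; target window 100-200)")

filtered = filter_de(table, cutoff, 0.05)
mapped = map_orthologs(filtered, bundle.orthology, bundle.reference.universe)
print(f"{len(filtered)} significant mouse genes -> {len(mapped)} mapped human genes")

sig = build_signature(mapped, n_per_side=100, dataset_id="precystic",
                      lfc_cutoff=cutoff, padj_cutoff=0.05)
print(f"signature: {len(sig.up)} up / {len(sig.down)} down genes")
print(f"strongest upregulated:   {list(sig.up[:3])}")
print(f"strongest downregulated: {list(sig.down[:3])}")
# These ordered lists are the query for connectivity scoring: compounds whose
# perturbation response pushes the up genes down and the down genes up are the
# candidate signature reversers.
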