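"""Score a disease signature against the drug-perturbation reference.

Each reference signature gets a bi-directional weighted KS connectivity score (WTCS in
[-1, 1]; -1 = perfect reverser), normalized to NCS within cell-line groups.  Results
are restricted to kidney-derived cell lines and to negative NCS (inverse direction).
"""

from sigrev import SimulationConfig, query_reference, simulate_bundle
from examples_common import build_signature_from_bundle

bundle = simulate_bundle(SimulationConfig(seed=7))
sig = build_signature_from_bundle(bundle)

results = query_reference(sig, bundle.reference,
                          bundle.reference.kidney_cell_lines(), direction="inverse")
print(f"{len(results)} (compound, cell line) signatures with negative NCS "
      f"in kidney lines, of {bundle.reference.n_signatures} total")
print(results.head(7)[["rank", "pert_id", "cell_line", "wtcs", "ncs"]]
      .to_string(index=False))

planted = set(bundle.truth["reversers"])
top5 = set(results.head(5)["pert_id"])
print(f"planted reversers recovered in top 5: {len(planted & top5)}/{len(planted)}")
# WTCS = -1 means every query-up gene ranks below every query-down gene in that
# compound's response; the most negative NCS ranks are the strongest reversion
# candidates.
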