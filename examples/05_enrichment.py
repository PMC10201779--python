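"""Hypergeometric enrichment: ORA on signature genes and DSEA on drug targets.

ORA asks which gene sets over-represent the signature's upregulated genes against the
measured-gene background (strict term sizes > 5 and < 1000, Bonferroni).  DSEA pools
the unique targets of the prioritized drug set and tests them against the same kind of
collection (sizes > 10 and < 500, Benjamini-Hochberg).
"""

from sigrev import SimulationConfig, dsea_hyperG, ora, run_cascade, simulate_bundle
from examples_common import build_signature_from_bundle, up_gene_sets_from_bundle

bundle = simulate_bundle(SimulationConfig(seed=7))
sig = build_signature_from_bundle(bundle)

cascade = run_cascade(sig, bundle.reference, bundle.annotations, bundle.fda,
                      up_gene_sets_from_bundle(bundle),
                      cell_lines=bundle.reference.kidney_cell_lines(),
                      cystic_ids=("cystic_a", "cystic_b"))

fea = ora(sig.up, bundle.gene_sets, bundle.reference.universe,
          size_bounds=(5, 1000), method="bonferroni", alpha=0.05)
print(f"ORA: {len(fea)} terms enriched in the {len(sig.up)} upregulated signature genes")
if len(fea):
    print(fea.head(3)[["term_id", "term_size", "overlap", "p_adj", "recall_term"]]
          .to_string(index=False))

targets = dict(zip(cascade.candidates["pert_id"], cascade.candidates["targets"]))
dsea, edges = dsea_hyperG(targets, bundle.annotations, bundle.gene_sets,
                          size_bounds=(10, 500), method="bh", alpha=0.05)
print(f"DSEA: {len(dsea)} terms enriched in the pooled targets of "
      f"{len(targets)} prioritized drugs; {len(edges)} drug-target-term edges")
# A significant DSEA term means the prioritized drugs' targets concentrate in that
# gene set beyond chance, pointing at a shared mechanism.
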