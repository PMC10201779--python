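"""Prioritize reversion candidates: launched -> FDA-approved -> cystic drug targets.

The cascade collapses connectivity results to one record per compound, keeps launched
drugs, matches ingredient names against an FDA registry, and finally retains drugs
whose annotated targets are upregulated in both cystic-stage datasets.
"""

from sigrev import SimulationConfig, run_cascade, simulate_bundle
from examples_common import build_signature_from_bundle, up_gene_sets_from_bundle

bundle = simulate_bundle(SimulationConfig(seed=7))
sig = build_signature_from_bundle(bundle)

cascade = run_cascade(sig, bundle.reference, bundle.annotations, bundle.fda,
                      up_gene_sets_from_bundle(bundle),
                      cell_lines=bundle.reference.kidney_cell_lines(),
                      cystic_ids=("cystic_a", "cystic_b"))

for stage, count in cascade.stage_counts.items():
    print(f"  {stage:22s}: {count}")
print(f"unique cystic-upregulated target genes: {cascade.unique_target_count}")
print(f"final candidates: {sorted(cascade.candidates['pert_id'])[:8]} ...")

planted = set(bundle.truth["forced_approved_reversers"])
final = set(cascade.candidates["pert_id"])
print(f"planted approved reversers surviving the cascade: "
      f"{len(planted & final)}/{len(planted)}")
# Each stage count is a strict subset of the previous one; the final set holds drugs
# predicted to reverse the early-disease signature while targeting genes that are
# still upregulated at the later cystic stage.
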