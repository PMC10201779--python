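"""Generate a synthetic three-dataset kidney-disease study with planted ground truth.

The bundle contains one pre-cystic and two cystic differential-expression tables, a
mouse-to-human orthology map, a drug-perturbation reference with planted signature
reversers, drug annotations, an FDA ingredient registry, gene sets, and the
acute-kidney-injury consensus panel.  Everything is determined by the seed.
"""

from sigrev import SimulationConfig, simulate_bundle

config = SimulationConfig(seed=7)
bundle = simulate_bundle(config)

print(f"mouse genes: {config.n_genes_mouse}, human reference genes: {config.n_genes_human}")
for ds, table in bundle.de_tables.items():
    n_sig = ((table["padj"] < 0.05) & (table["lfc"].abs() > 2.0)).sum()
    print(f"  {ds:10s}: {len(table)} genes, {n_sig} significant at |LFC|>2, padj<0.05")
print(f"reference: {bundle.reference.n_signatures} signatures "
      f"({config.n_compounds} compounds x {config.n_cell_lines} cell lines), "
      f"kidney lines = {bundle.reference.kidney_cell_lines()}")
print(f"planted reversers: {bundle.truth['reversers']}")
print(f"planted mimics:    {bundle.truth['mimics']}")
# The reversers' kidney-line score vectors anti-rank the planted pre-cystic program,
# so a downstream reversion query should surface exactly these compounds first.
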