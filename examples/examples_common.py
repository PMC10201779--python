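"""Shared helpers for the example scripts."""

from sigrev import adaptive_lfc_cutoff, build_signature, filter_de, map_orthologs
from sigrev.signatures import DEFAULT_GRID


def build_signature_from_bundle(bundle, padj=0.05, n_per_side=100):
    table = bundle.de_tables["precystic"]
    cutoff, _ = adaptive_lfc_cutoff(table, padj, grid=DEFAULT_GRID)
    mapped = map_orthologs(filter_de(table, cutoff, padj), bundle.orthology,
                           bundle.reference.universe)
    return build_signature(mapped, n_per_side, dataset_id="precystic",
                           lfc_cutoff=cutoff, padj_cutoff=padj)


def up_gene_sets_from_bundle(bundle, padj=0.05, cut_precystic=1.1, cut_cystic=2.0):
    out = {}
    for ds, table in bundle.de_tables.items():
        cut = cut_precystic if ds == "precystic" else cut_cystic
        de = filter_de(table, cut, padj)
        de = de[de["lfc"] > 0]
        out[ds] = set(map_orthologs(de, bundle.orthology,
                                    bundle.reference.universe)["gene_id"])
    return out
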