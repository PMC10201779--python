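"""Candidate collapse and the launched/FDA/target-overlap prioritization cascade."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_precystic_signature, pipeline_up_gene_sets
from sigrev import (collapse_to_drugs, filter_fda, filter_launched,
                    normalize_ingredient, prioritize_cystic, run_cascade,
                    target_overlap)
from sigrev.errors import ParameterError


def results(rows):
    return pd.DataFrame(rows, columns=["pert_id", "cell_line", "ncs"])


def test_collapse_takes_most_negative_ncs():
    res = results([("d1", "HA1E", -1.2), ("d1", "NKDBA", -0.4), ("d2", "HA1E", -0.2)])
    out = collapse_to_drugs(res)
    assert out.iloc[0]["pert_id"] == "d1"
    assert out.iloc[0]["best_ncs"] == pytest.approx(-1.2)
    assert out.iloc[0]["cell_lines"] == "HA1E,NKDBA"


def test_collapse_tie_orders_lexicographically():
    res = results([("dB", "X", -0.5), ("dA", "X", -0.5)])
    out = collapse_to_drugs(res)
    assert out["pert_id"].tolist() == ["dA", "dB"]


def test_collapse_counts_distinct_compounds(small_bundle):
    from sigrev import query_reference

    sig = build_precystic_signature(small_bundle)
    res = query_reference(sig, small_bundle.reference,
                          small_bundle.reference.kidney_cell_lines())
    out = collapse_to_drugs(res)
    assert len(out) == res["pert_id"].nunique()


ANN = pd.DataFrame({
    "pert_id": ["d1", "d2", "d3"],
    "name": ["Alpha", "Beta", "Gamma"],
    "clinical_phase": ["Launched", "Phase 3", "Launched"],
    "moa": ["x", "y", "z"],
    "targets": [frozenset({"A", "B"}), frozenset(), frozenset({"C"})],
    "indication": ["i", "j", "k"],
})


def test_filter_launched_keeps_launched_drops_others_and_unannotated():
    cands = pd.DataFrame({"pert_id": ["d1", "d2", "d9"],
                          "best_ncs": [-1.0, -0.9, -0.8],
                          "cell_lines": ["X", "X", "X"]})
    out = filter_launched(cands, ANN)
    assert out["pert_id"].tolist() == ["d1"]   # d2 is Phase 3, d9 unannotated


@pytest.mark.parametrize(
    "name,registry_row,kept",
    [
        ("Bromocriptine", ("bromocriptine", "prescription"), True),
        ("Alpha", ("  ALPHA ", "tentative approval"), True),
        ("Alpha", ("alpha", "discontinued"), False),
        ("Gamma", ("delta", "prescription"), False),
    ],
)
def test_filter_fda_normalized_ingredient_match(name, registry_row, kept):
    cands = pd.DataFrame({"pert_id": ["d1"], "name": [name]})
    registry = pd.DataFrame([registry_row], columns=["ingredient", "marketing_status"])
    assert (len(filter_fda(cands, registry)) == 1) is kept


def test_normalize_ingredient_collapses_case_and_whitespace():
    assert normalize_ingredient("  Foo   Bar ") == "foo bar"


def _overlap_fixture():
    """3 drugs x 4 genes constructed so each dataset summary is 2 genes / 2 drugs."""
    cands = pd.DataFrame({
        "pert_id": ["d1", "d2", "d3"],
        "name": ["D1", "D2", "D3"],
        "targets": [frozenset({"A", "B"}), frozenset({"B", "D"}), frozenset()],
    })
    up_sets = {"c1": {"B", "C"}, "c2": {"A", "D"}}
    return cands, up_sets


def test_target_overlap_intersection_and_summary():
    cands, up_sets = _overlap_fixture()
    out, summary = target_overlap(cands, up_sets)
    assert out["overlap_c1"].tolist() == [frozenset({"B"}), frozenset({"B"}), frozenset()]
    assert out["overlap_c2"].tolist() == [frozenset({"A"}), frozenset({"D"}), frozenset()]
    assert summary == {"c1": {"unique_genes": 1, "drugs": 2},
                       "c2": {"unique_genes": 2, "drugs": 2}}


def test_prioritize_cystic_requires_overlap_in_each_dataset():
    cands, up_sets = _overlap_fixture()
    out, _ = target_overlap(cands, up_sets)
    pri, edges, n_unique = prioritize_cystic(out, ("c1", "c2"))
    # d1 overlaps B in c1 and A in c2 (different genes is fine); d3 has no targets
    assert pri["pert_id"].tolist() == ["d1", "d2"]
    assert set(map(tuple, edges[["pert_id", "target"]].to_numpy())) == {
        ("d1", "A"), ("d1", "B"), ("d2", "B"), ("d2", "D")}
    assert n_unique == 3  # shared target B counted once


def test_prioritize_cystic_excludes_single_dataset_overlap():
    cands = pd.DataFrame({"pert_id": ["d1"], "name": ["D1"],
                          "targets": [frozenset({"B"})]})
    out, _ = target_overlap(cands, {"c1": {"B"}, "c2": {"Z"}})
    pri, edges, n = prioritize_cystic(out, ("c1", "c2"))
    assert len(pri) == 0 and len(edges) == 0 and n == 0


def test_prioritize_cystic_requires_two_ids():
    cands, up_sets = _overlap_fixture()
    out, _ = target_overlap(cands, up_sets)
    with pytest.raises(ParameterError):
        prioritize_cystic(out, ("c1",))


def _cascade(bundle, registry=None):
    sig = build_precystic_signature(bundle)
    return run_cascade(
        sig, bundle.reference, bundle.annotations,
        bundle.fda if registry is None else registry,
        pipeline_up_gene_sets(bundle),
        cell_lines=bundle.reference.kidney_cell_lines(),
        cystic_ids=("cystic_a", "cystic_b"))


def test_cascade_monotone_and_nonempty(small_bundle):
    casc = _cascade(small_bundle)
    c = casc.stage_counts
    assert (c["negative_ncs_drugs"] >= c["launched"] >= c["fda_approved"]
            >= c["targets_both_cystic"])
    assert c["targets_both_cystic"] > 0
    stages = casc.stages
    assert set(stages["launched"]["pert_id"]) <= set(stages["collapsed"]["pert_id"])
    assert set(stages["fda"]["pert_id"]) <= set(stages["launched"]["pert_id"])
    assert set(casc.candidates["pert_id"]) <= set(stages["fda"]["pert_id"])


def test_cascade_unique_target_count_matches_edge_union(small_bundle):
    casc = _cascade(small_bundle)
    assert casc.unique_target_count == casc.edges["target"].nunique()


def test_cascade_empty_registry_empties_only_late_stages(small_bundle):
    empty = pd.DataFrame(columns=["ingredient", "marketing_status"])
    full = _cascade(small_bundle)
    gutted = _cascade(small_bundle, registry=empty)
    assert gutted.stage_counts["fda_approved"] == 0
    assert gutted.stage_counts["targets_both_cystic"] == 0
    for stage in ("negative_ncs_drugs", "launched"):
        assert gutted.stage_counts[stage] == full.stage_counts[stage]


def test_cascade_input_row_order_invariance(small_bundle):
    rng = np.random.default_rng(9)
    casc = _cascade(small_bundle)
    shuffled = small_bundle.annotations.sample(frac=1.0, random_state=5).reset_index(drop=True)
    shuffled_fda = small_bundle.fda.sample(frac=1.0, random_state=6).reset_index(drop=True)
    sig = build_precystic_signature(small_bundle)
    casc2 = run_cascade(sig, small_bundle.reference, shuffled, shuffled_fda,
                        pipeline_up_gene_sets(small_bundle),
                        cell_lines=small_bundle.reference.kidney_cell_lines(),
                        cystic_ids=("cystic_a", "cystic_b"))
    assert casc.stage_counts == casc2.stage_counts
    assert casc.candidates["pert_id"].tolist() == casc2.candidates["pert_id"].tolist()
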