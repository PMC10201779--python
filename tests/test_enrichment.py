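"""Hypergeometric tail, multiple-testing adjustment, ORA, and drug-set enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sigrev import GeneSet, adjust, dsea_hyperG, hypergeom_upper, ora
from sigrev.errors import ParameterError, QueryError

from _oracles import bh_stepup, enum_hypergeom_upper


def test_hypergeom_closed_forms():
    assert hypergeom_upper(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-12)
    assert hypergeom_upper(0, 5, 5, 20) == pytest.approx(1.0)
    # single-term sanity: drawing the full 10-gene term from a 100-gene universe
    assert hypergeom_upper(10, 10, 10, 100) == pytest.approx(1 / comb(100, 10), rel=1e-9)


def test_hypergeom_rejects_impossible_overlap():
    with pytest.raises(ParameterError):
        hypergeom_upper(6, 5, 5, 20)
    with pytest.raises(ParameterError):
        hypergeom_upper(1, 25, 5, 20)


def test_hypergeom_matches_enumeration_small_universes():
    """Spot-check upper-tail values against literal enumeration of all draws."""
    for N in (5, 7, 9):
        for K in range(1, N):
            for n in range(1, N):
                for k in range(0, min(K, n) + 1):
                    assert hypergeom_upper(k, K, n, N) == pytest.approx(
                        enum_hypergeom_upper(k, K, n, N), abs=1e-12)


def test_adjust_hand_computed_values():
    assert adjust([0.01, 0.4], method="bonferroni").tolist() == pytest.approx([0.02, 0.8])
    assert adjust([0.01, 0.02, 0.03], method="bh").tolist() == pytest.approx(
        [0.03, 0.03, 0.03])
    assert adjust([0.2], method="bh").tolist() == pytest.approx([0.2])
    assert adjust([], method="bh").size == 0


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.integers(0, 10_000))
def test_bh_matches_stepup_oracle_and_is_permutation_invariant(pvals, seed):
    got = adjust(pvals, method="bh")
    assert got.tolist() == pytest.approx(bh_stepup(pvals), abs=1e-12)
    perm = np.random.default_rng(seed).permutation(len(pvals))
    permuted = adjust([pvals[i] for i in perm], method="bh")
    assert [permuted[list(perm).index(i)] for i in range(len(pvals))] == pytest.approx(
        got.tolist(), abs=1e-12)


def _collection():
    return [
        GeneSet("T_hit", "query-matching term", frozenset(f"g{i}" for i in range(10))),
        GeneSet("T_small", "boundary-size term", frozenset(f"g{i}" for i in range(5))),
        GeneSet("T_other", "unrelated term", frozenset(f"x{i}" for i in range(20))),
    ]


def test_ora_strict_size_bounds_exclude_boundary_term():
    universe = [f"g{i}" for i in range(50)] + [f"x{i}" for i in range(50)]
    res = ora([f"g{i}" for i in range(10)], _collection(), universe,
              size_bounds=(5, 1000), method="bonferroni", alpha=1.1)
    assert "T_small" not in set(res["term_id"])  # size 5 fails the strict > 5 bound
    assert {"T_hit", "T_other"} == set(res["term_id"])


def test_ora_full_term_query_minimal_p():
    universe = [f"g{i}" for i in range(10)] + [f"u{i}" for i in range(90)]
    res = ora([f"g{i}" for i in range(10)], _collection(), universe,
              size_bounds=(5, 1000), alpha=0.05)
    assert res.iloc[0]["term_id"] == "T_hit"
    assert res.iloc[0]["p"] == pytest.approx(1 / comb(100, 10), rel=1e-9)
    assert res.iloc[0]["overlap"] == 10
    assert res.iloc[0]["recall_query"] == pytest.approx(1.0)
    assert res.iloc[0]["recall_term"] == pytest.approx(1.0)


def test_ora_disjoint_query_returns_empty():
    universe = [f"g{i}" for i in range(10)] + [f"x{i}" for i in range(20)] + ["q1", "q2"]
    res = ora(["q1", "q2"], _collection(), universe, alpha=0.05)
    assert len(res) == 0


def test_ora_universe_restriction_affects_term_size():
    """Term members outside the measured background do not count toward term size."""
    universe = [f"g{i}" for i in range(7)] + ["u1", "u2"]
    res = ora([f"g{i}" for i in range(3)],
              [GeneSet("T_hit", "d", frozenset(f"g{i}" for i in range(10)))],
              universe, size_bounds=(5, 1000), alpha=1.1)
    assert res.iloc[0]["term_size"] == 7


def test_ora_parameter_errors():
    with pytest.raises(ParameterError):
        ora([], _collection(), ["g1"])
    with pytest.raises(ParameterError):
        ora(["g1"], _collection(), [])


def test_dsea_duplicate_target_sets_collapse():
    """Two drugs with identical targets give the same result as one drug."""
    ann = pd.DataFrame({
        "pert_id": ["d1", "d2", "d3"],
        "targets": [frozenset({"g1", "g2"}), frozenset({"g1", "g2"}),
                    frozenset({f"x{i}" for i in range(30)})],
    })
    coll = [GeneSet("T", "t", frozenset({"g1", "g2"} | {f"x{i}" for i in range(15)}))]
    one, _ = dsea_hyperG({"d1": {"g1", "g2"}}, ann, coll, size_bounds=(2, 500), alpha=1.1)
    two, _ = dsea_hyperG({"d1": {"g1", "g2"}, "d2": {"g1", "g2"}}, ann, coll,
                         size_bounds=(2, 500), alpha=1.1)
    pd.testing.assert_frame_equal(one, two)


def test_dsea_tiling_fixture_ranks_target_term_first():
    """16 drugs tiling one 20-gene term in a 200-gene target universe."""
    term_genes = [f"t{i:02d}" for i in range(20)]
    filler = [f"f{i:03d}" for i in range(180)]
    drugs = {f"d{i:02d}": {term_genes[(2 * i) % 20], term_genes[(2 * i + 1) % 20]}
             for i in range(16)}
    ann_rows = [{"pert_id": d, "targets": frozenset(t)} for d, t in drugs.items()]
    ann_rows.append({"pert_id": "bg", "targets": frozenset(filler)})
    ann = pd.DataFrame(ann_rows)
    rng = np.random.default_rng(4)
    coll = [GeneSet("T_target", "tiled", frozenset(term_genes))]
    for i in range(5):
        members = rng.choice(filler, size=30, replace=False)
        coll.append(GeneSet(f"T_bg{i}", "noise", frozenset(members)))
    res, edges = dsea_hyperG(drugs, ann, coll, size_bounds=(10, 500), alpha=0.05)
    assert res.iloc[0]["term_id"] == "T_target"
    # every drug contributes its in-term targets to the network edges
    assert set(edges["pert_id"]) == set(drugs)
    assert set(edges["target"]) <= set(term_genes)


def test_dsea_zero_target_drug_is_an_error():
    ann = pd.DataFrame({"pert_id": ["d1"], "targets": [frozenset()]})
    with pytest.raises(QueryError):
        dsea_hyperG({"d1": set()}, ann, _collection())
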