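"""Weighted KS enrichment score, WTCS combination, and NCS normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sigrev import (GeneSignature, ReferenceSet, ncs_normalize, query_reference,
                    score_signatures, weighted_es, wtcs)
from sigrev.errors import DomainError, ParameterError, QueryError

from _oracles import brute_es

GENES5 = ["g1", "g2", "g3", "g4", "g5"]
SCORES5 = [5.0, 4.0, 3.0, 2.0, 1.0]


@pytest.mark.parametrize(
    "query,expected",
    [({"g1"}, 1.0), ({"g5"}, -1.0), ({"g1", "g3"}, 2.0 / 3.0)],
)
def test_weighted_es_small_rankings(query, expected):
    """Queries at the top, bottom, and mixed positions of a 5-gene ranking."""
    assert weighted_es(GENES5, SCORES5, query) == pytest.approx(expected, abs=1e-15)


def test_weighted_es_extremum_tie_returns_positive():
    """A perfectly symmetric running sum resolves to the positive extremum."""
    es = weighted_es(["g1", "g2", "g3", "g4"], [2.0, 1.0, -1.0, -2.0], {"g1", "g4"})
    assert es == pytest.approx(0.5)


def test_weighted_es_tie_break_is_lexicographic():
    """Equal scores rank by gene id, so renaming a tied gene can move the hit."""
    es_a = weighted_es(["a", "b", "c"], [1.0, 1.0, 0.0], {"a"})
    es_b = weighted_es(["z", "b", "c"], [1.0, 1.0, 0.0], {"z"})
    assert es_a == pytest.approx(1.0)   # "a" sorts before tied "b"
    assert es_b < es_a                   # "z" sorts after "b"


@pytest.mark.parametrize(
    "universe,scores,query,err",
    [
        (GENES5, SCORES5, set(), QueryError),
        (GENES5, SCORES5, {"nope"}, QueryError),
        (GENES5, SCORES5, set(GENES5), QueryError),
        (GENES5, [1.0] * 5, {"g1"}, ParameterError),
    ],
)
def test_weighted_es_rejects_degenerate_inputs(universe, scores, query, err):
    with pytest.raises(err):
        weighted_es(universe, scores, query)


def test_weighted_es_matches_brute_force_exhaustively():
    """Every non-trivial query subset of random universes up to size 6 matches the
    literal running-sum definition exactly."""
    rng = np.random.default_rng(42)
    for n in range(2, 7):
        genes = [f"g{i}" for i in range(n)]
        scores = list(rng.normal(size=n))
        for r in range(1, n):
            for query in itertools.combinations(genes, r):
                assert weighted_es(genes, scores, set(query)) == brute_es(
                    genes, scores, set(query))


@given(st.integers(0, 2**31 - 1))
def test_weighted_es_antisymmetry(seed):
    """Negating tie-free scores reverses the ranking and negates the ES.

    Generic (normal) scores keep the running-sum extrema untied; the property is
    exact away from the measure-zero |max| = |min| tie where the positive-extremum
    rule applies instead.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    genes = [f"g{i:03d}" for i in range(n)]
    scores = rng.normal(size=n)
    k = int(rng.integers(1, n))
    query = set(rng.choice(genes, size=k, replace=False))
    es = weighted_es(genes, scores, query)
    es_neg = weighted_es(genes, -scores, query)
    assert -1.0 <= es <= 1.0
    assert es_neg == pytest.approx(-es, abs=1e-12)


@pytest.mark.parametrize(
    "eu,ed,expected",
    [
        (1.0, -1.0, 1.0),
        (-1.0, 1.0, -1.0),
        (-0.6, 0.4, -0.5),
        (0.5, 0.3, 0.0),
        (-0.5, -0.3, 0.0),
        (0.0, 0.0, 0.0),
        (0.0, 0.4, -0.2),  # zero counts as opposite to either sign
    ],
)
def test_wtcs_combination_rules(eu, ed, expected):
    assert wtcs(eu, ed) == pytest.approx(expected)


def test_wtcs_rejects_out_of_range():
    with pytest.raises(DomainError):
        wtcs(1.2, 0.0)


def test_ncs_normalize_worked_group():
    """mu+ = 0.75 and mu- = 0.6 rescale the five-score group as expected."""
    df = pd.DataFrame({
        "pert_id": list("abcde"), "cell_line": ["X"] * 5,
        "es_up": 0.0, "es_down": 0.0,
        "wtcs": [0.5, 1.0, -0.3, -0.9, 0.0], "ncs": np.nan,
    })
    out = ncs_normalize(df)
    assert out["ncs"].tolist() == pytest.approx(
        [2 / 3, 4 / 3, -0.5, -1.5, 0.0])


def test_ncs_single_positive_score_normalizes_to_one():
    df = pd.DataFrame({"pert_id": ["a"], "cell_line": ["X"], "es_up": [0.4],
                       "es_down": [-0.1], "wtcs": [0.4], "ncs": [np.nan]})
    assert ncs_normalize(df)["ncs"].iloc[0] == pytest.approx(1.0)


def test_ncs_group_means_are_unit_by_construction():
    """Within any cell-line group the positive NCS mean is 1 and negative mean -1."""
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "pert_id": [f"d{i}" for i in range(60)],
        "cell_line": rng.choice(["X", "Y", "Z"], size=60),
        "es_up": 0.0, "es_down": 0.0,
        "wtcs": rng.uniform(-1, 1, size=60), "ncs": np.nan,
    })
    out = ncs_normalize(df)
    for _, grp in out.groupby("cell_line"):
        pos, neg = grp[grp.ncs > 0], grp[grp.ncs < 0]
        if len(pos):
            assert pos["ncs"].mean() == pytest.approx(1.0, abs=1e-12)
        if len(neg):
            assert neg["ncs"].mean() == pytest.approx(-1.0, abs=1e-12)


def _toy_reference():
    """4-gene universe, 3 signatures: a perfect reverser and mimic in the kidney
    line and noise in a non-kidney line."""
    genes = ["h1", "h2", "h3", "h4"]
    data = pd.DataFrame(
        {
            "rev__KID": [-1.0, -0.9, 0.9, 1.0],
            "mim__KID": [1.0, 0.9, -0.9, -1.0],
            "rev__OTH": [0.1, -0.2, 0.3, -0.1],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return ReferenceSet(data=data, cell_line_tags={"KID": "kidney", "OTH": "other"})


def test_query_reference_reverser_first_mimic_excluded():
    sig = GeneSignature(up=("h1", "h2"), down=("h3", "h4"))
    ref = _toy_reference()
    res = query_reference(sig, ref, ["KID"])
    assert res.iloc[0]["pert_id"] == "rev"
    assert res.iloc[0]["wtcs"] == pytest.approx(-1.0)
    assert "mim" not in set(res["pert_id"])          # mimic has wtcs = +1
    assert res["rank"].tolist() == list(range(1, len(res) + 1))


def test_query_reference_cell_line_restriction():
    """A compound scoring only in a non-kidney line is absent from kidney results."""
    sig = GeneSignature(up=("h1", "h2"), down=("h3", "h4"))
    ref = _toy_reference()
    kid = query_reference(sig, ref, ["KID"])
    assert set(kid["cell_line"]) == {"KID"}
    both = query_reference(sig, ref, ["KID", "OTH"], direction="all")
    assert set(both["cell_line"]) == {"KID", "OTH"}


def test_query_reference_parameter_errors():
    sig = GeneSignature(up=("h1",), down=())
    ref = _toy_reference()
    with pytest.raises(ParameterError):
        query_reference(sig, ref, [])
    with pytest.raises(ParameterError):
        query_reference(sig, ref, ["MISSING"])
    with pytest.raises(QueryError):
        query_reference(GeneSignature(up=(), down=()), ref, ["KID"])


def test_score_signatures_range_on_random_reference():
    rng = np.random.default_rng(5)
    genes = [f"h{i:02d}" for i in range(30)]
    data = pd.DataFrame(rng.normal(size=(30, 8)),
                        index=pd.Index(genes, name="gene_id"),
                        columns=[f"d{j}__X" for j in range(8)])
    ref = ReferenceSet(data=data, cell_line_tags={"X": "kidney"})
    sig = GeneSignature(up=tuple(genes[:5]), down=tuple(genes[5:10]))
    res = score_signatures(sig, ref)
    for col in ("es_up", "es_down", "wtcs"):
        assert res[col].between(-1, 1).all()
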