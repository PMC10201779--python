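"""Hypergeometric over-representation machinery.

Two front-ends share one engine: :func:`ora` tests a gene list against a gene-set
collection (functional enrichment with a measured-gene background), and
:func:`dsea_hyperG` tests the pooled unique targets of a drug set against the same kind
of collection (drug-set enrichment), additionally reporting the drug-target edges
inside each significant term.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, QueryError
from .types import GeneSet

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term_id", "description", "term_size", "overlap",
    "p", "p_adj", "precision", "recall_query", "recall_term",
]

_ADJUST_METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    ``X`` counts the overlap when drawing ``n`` query genes without replacement from a
    universe of ``N`` genes of which ``K`` belong to the term.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ParameterError(f"invalid sizes K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ParameterError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust(pvals: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni or Benjamini-Hochberg step-up.

    Input order is preserved; values are capped at 1 and BH monotonicity is enforced.
    """
    if method not in _ADJUST_METHODS:
        raise ParameterError(f"method must be one of {sorted(_ADJUST_METHODS)}")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def ora(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
    size_bounds: tuple[int, int] = (5, 1000),
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term of ``collection``.

    Term members are first restricted to ``universe`` (the measured-gene background);
    terms whose restricted size is not strictly inside ``size_bounds`` are not tested.
    The adjustment spans tested terms only, and only terms with ``p_adj < alpha`` are
    returned, sorted by (p_adj, term_id).
    """
    uni = set(universe)
    if not uni:
        raise ParameterError("universe is empty")
    qall = set(query)
    if not qall:
        raise ParameterError("query is empty")
    q = qall & uni
    if len(q) < len(qall):
        logger.warning("dropped %d query genes outside the universe", len(qall) - len(q))
    if not q:
        raise ParameterError("no query genes remain inside the universe")
    lo, hi = size_bounds
    rows = []
    for gs in collection:
        members = gs.members & uni
        if not (lo < len(members) < hi):
            continue
        k = len(members & q)
        p = hypergeom_upper(k, len(members), len(q), len(uni))
        rows.append((gs.term_id, gs.description, len(members), k, p))
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows, columns=["term_id", "description", "term_size", "overlap", "p"])
    df["p_adj"] = adjust(df["p"].to_numpy(), method=method)
    df["precision"] = df["overlap"] / len(q)
    df["recall_query"] = df["overlap"] / len(q)
    df["recall_term"] = df["overlap"] / df["term_size"]
    df = df[df["p_adj"] < alpha]
    return df.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(drop=True)


def dsea_hyperG(
    drug_targets: Mapping[str, frozenset[str] | set[str]],
    annotations: pd.DataFrame,
    collection: Sequence[GeneSet],
    size_bounds: tuple[int, int] = (10, 500),
    method: str = "bh",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug-set enrichment: hypergeometric test on the drug set's pooled unique targets.

    ``drug_targets`` maps each prioritized drug to its annotated target genes
    (duplicate targets across drugs collapse into one query gene).  The background is
    the union of all target genes in the full annotation table.  Returns the
    enrichment table plus drug->target edges restricted to each significant term.
    """
    if not drug_targets:
        raise ParameterError("no drugs supplied")
    untargeted = sorted(d for d, t in drug_targets.items() if not t)
    if untargeted:
        raise QueryError(f"drugs without annotated targets: {untargeted}")
    if "targets" not in annotations.columns:
        raise ParameterError("annotation table lacks a 'targets' column")
    universe: set[str] = set()
    for t in annotations["targets"]:
        universe |= set(t)
    query: set[str] = set()
    for t in drug_targets.values():
        query |= set(t)
    results = ora(query, collection, universe, size_bounds, method, alpha)
    edges = []
    sig_terms = {
        row.term_id: set(gs.members)
        for gs in collection for row in results.itertuples()
        if gs.term_id == row.term_id
    }
    for term_id, members in sig_terms.items():
        for drug in sorted(drug_targets):
            for target in sorted(set(drug_targets[drug]) & members & query):
                edges.append((term_id, drug, target))
    edges_df = pd.DataFrame(edges, columns=["term_id", "pert_id", "target"])
    return results, edges_df
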