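"""Bi-directional weighted Kolmogorov-Smirnov connectivity scoring.

A disease signature (ordered up/down gene lists) is compared against every reference
perturbation signature.  For each direction a weighted KS enrichment score (ES) asks
whether the query genes sit at an extreme of the reference ranking; the two directional
scores combine into the weighted connectivity score (WTCS, in [-1, 1], 0 = null), which
is then normalized within cell-line groups to the normalized connectivity score (NCS).
Compounds whose expression response *reverses* the disease signature have negative
WTCS/NCS.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, QueryError
from .types import GeneSignature, ReferenceSet

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["pert_id", "cell_line", "es_up", "es_down", "wtcs", "ncs"]


def _es_core(sorted_scores: np.ndarray, hit: np.ndarray, weight_exponent: float) -> float:
    """Running-sum extremum for a query over an already rank-ordered score vector.

    ``sorted_scores`` must be in descending rank order (ties already broken); ``hit``
    marks query membership per position.  Hits advance the sum by |score|^p normalized
    over all hits, misses retreat it by 1/(N-t).  Returns the extremum with the larger
    absolute value; on an exact tie the positive extremum is returned.
    """
    n = sorted_scores.shape[0]
    t = int(hit.sum())
    w = np.abs(sorted_scores) ** weight_exponent
    denom = float(w[hit].sum())
    if denom > 0.0:
        hit_inc = w / denom
    else:
        # all query genes scored exactly zero: fall back to unweighted increments
        hit_inc = np.full(n, 1.0 / t)
    inc = np.where(hit, hit_inc, -1.0 / (n - t))
    running = np.cumsum(inc)
    mx = float(running.max())
    mn = float(running.min())
    es = mx if abs(mx) >= abs(mn) else mn
    # the exact extremum lies in [-1, 1]; cumsum rounding can overshoot by ~1e-13
    return min(1.0, max(-1.0, es))


def _rank_order(gene_ids: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Indices ordering genes by descending score, ties broken lexicographically by id."""
    lex = np.argsort(gene_ids)
    order = np.argsort(-scores[lex], kind="stable")
    return lex[order]


def weighted_es(
    universe: Sequence[str],
    scores: Sequence[float],
    query: Iterable[str],
    weight_exponent: float = 1.0,
) -> float:
    """Weighted KS enrichment score of ``query`` in the ranked reference ``scores``.

    Parameters
    ----------
    universe, scores
        Parallel gene ids and differential-expression scores (one per gene).
    query
        Non-empty proper subset of ``universe``.
    weight_exponent
        Exponent ``p`` on |score| in the hit increments (GSEA-style; 1 by default).

    Returns
    -------
    float in [-1, 1]; positive when the query concentrates at the top of the ranking,
    negative at the bottom.
    """
    genes = np.asarray(list(universe), dtype=object)
    s = np.asarray(scores, dtype=float)
    if genes.shape[0] != s.shape[0]:
        raise ParameterError("universe and scores must have equal length")
    if not np.isfinite(s).all():
        raise ParameterError("scores must be finite")
    qset = set(query)
    if not qset:
        raise QueryError("query gene set is empty")
    missing = qset - set(genes.tolist())
    if missing:
        raise QueryError(f"query genes absent from universe: {sorted(missing)[:5]}")
    if len(qset) == genes.shape[0]:
        raise QueryError("query equals the whole universe (degenerate)")
    if np.all(s == s[0]):
        raise ParameterError("all reference scores are equal; ranking is undefined")
    order = _rank_order(genes.astype(str), s)
    hit = np.fromiter((g in qset for g in genes[order]), dtype=bool, count=len(genes))
    return _es_core(s[order], hit, weight_exponent)


def wtcs(es_up: float, es_down: float) -> float:
    """Combine directional enrichment scores into the weighted connectivity score.

    Returns ``(es_up - es_down) / 2`` when the two scores disagree in sign (zero counts
    as opposite to either sign) and 0 when both share a strict sign — the null case.
    """
    for v in (es_up, es_down):
        if not -1.0 <= v <= 1.0:
            raise DomainError(f"enrichment score {v} outside [-1, 1]")
    if (es_up > 0 and es_down > 0) or (es_up < 0 and es_down < 0):
        return 0.0
    return (es_up - es_down) / 2.0


def score_signatures(
    sig: GeneSignature, ref: ReferenceSet, weight_exponent: float = 1.0
) -> pd.DataFrame:
    """ES_up/ES_down/WTCS for ``sig`` against every signature in ``ref``.

    An empty query side contributes a neutral ES of 0 so single-sided signatures still
    score.  The returned frame carries an ``ncs`` column of NaN to be filled by
    :func:`ncs_normalize`.
    """
    if not sig.up and not sig.down:
        raise QueryError("signature is empty on both sides")
    genes = np.asarray(ref.universe, dtype=object)
    uni = set(genes.tolist())
    for side, members in (("up", sig.up), ("down", sig.down)):
        extra = set(members) - uni
        if extra:
            raise QueryError(f"signature {side} genes missing from reference universe: "
                             f"{sorted(extra)[:5]}")
    lex = np.argsort(genes.astype(str))
    matrix = ref.data.to_numpy()[lex]
    genes_lex = genes[lex]
    up_mask = np.isin(genes_lex, list(sig.up))
    down_mask = np.isin(genes_lex, list(sig.down))
    rows = []
    for j, sig_id in enumerate(ref.data.columns):
        s = matrix[:, j]
        order = np.argsort(-s, kind="stable")
        eu = _es_core(s[order], up_mask[order], weight_exponent) if sig.up else 0.0
        ed = _es_core(s[order], down_mask[order], weight_exponent) if sig.down else 0.0
        pert, cell = ReferenceSet.split_id(sig_id)
        rows.append((pert, cell, eu, ed, wtcs(eu, ed), np.nan))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def ncs_normalize(
    results: pd.DataFrame, group_keys: Sequence[str] = ("cell_line",)
) -> pd.DataFrame:
    """Fill the ``ncs`` column by scaling WTCS within each group.

    Within a group, positive scores divide by the group mean of positive WTCS and
    negative scores by the mean magnitude of negative WTCS, so each side's mean |NCS|
    is 1 and signs are preserved; zero WTCS stays zero.  A group missing one sign
    entirely is logged (its present-side scores normalize as usual).
    """
    out = results.copy()
    ncs = np.zeros(len(out))
    w = out["wtcs"].to_numpy()
    for key, idx in out.groupby(list(group_keys)).indices.items():
        gw = w[idx]
        pos = gw > 0
        neg = gw < 0
        if not pos.any() or not neg.any():
            logger.warning("NCS group %s lacks %s WTCS values; one-sided normalization",
                           key, "positive" if not pos.any() else "negative")
        if pos.any():
            ncs[idx[pos]] = gw[pos] / gw[pos].mean()
        if neg.any():
            ncs[idx[neg]] = gw[neg] / (-gw[neg]).mean()
    out["ncs"] = ncs
    return out


def query_reference(
    sig: GeneSignature,
    ref: ReferenceSet,
    cell_line_filter: Iterable[str],
    direction: str = "inverse",
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Score ``sig`` against ``ref`` and return the ranked candidate table.

    NCS is normalized over *all* reference signatures first; only then are results
    restricted to ``cell_line_filter``.  ``direction="inverse"`` keeps strictly
    negative NCS (signature reversers), ``"similar"`` keeps positive (mimics), and
    ``"all"`` keeps everything.  Rows are sorted ascending by NCS with pert_id as the
    deterministic tie-break, and numbered in a ``rank`` column.
    """
    cells = set(cell_line_filter)
    if not cells:
        raise ParameterError("cell_line_filter is empty")
    known = set(ref.cell_lines)
    if not cells <= known:
        raise ParameterError(f"unknown cell lines requested: {sorted(cells - known)}")
    if direction not in {"inverse", "similar", "all"}:
        raise ParameterError(f"direction must be inverse/similar/all, got {direction!r}")
    res = ncs_normalize(score_signatures(sig, ref, weight_exponent))
    res = res[res["cell_line"].isin(cells)]
    if direction == "inverse":
        res = res[res["ncs"] < 0]
    elif direction == "similar":
        res = res[res["ncs"] > 0]
    res = res.sort_values(["ncs", "pert_id"], kind="mergesort").reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    logger.info("query_reference: %d/%d signatures kept (cells=%s, direction=%s)",
                len(res), ref.n_signatures, sorted(cells), direction)
    return res
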