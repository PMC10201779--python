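"""Consensus-signature concordance assessment across differential-expression tables.

Quantifies how strongly a direction-labelled consensus panel (here, genes consistently
moved 24h after acute kidney injury) is recapitulated in each disease dataset: the
consensus genes passing relaxed significance thresholds are extracted, and the fraction
whose fold-change sign matches the consensus direction is reported together with the
mean direction-signed log2 fold change.  An LFC matrix across datasets backs heatmap
inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .signatures import _check_de
from .types import ConsensusSignature


def aki_subset(
    table: pd.DataFrame,
    consensus: ConsensusSignature,
    lfc_min: float = 0.15,
    padj_max: float = 0.1,
) -> pd.DataFrame:
    """Consensus genes passing |lfc| > lfc_min and padj < padj_max (both strict).

    Returns the matching DE rows with a ``direction`` column holding the consensus
    label (``up``/``down``) of each gene.
    """
    if lfc_min <= 0 or padj_max <= 0:
        raise ParameterError("thresholds must be positive")
    _check_de(table)
    sub = table[table["gene_id"].isin(consensus.genes)]
    sub = sub[sub["padj"].notna() & (sub["padj"] < padj_max) & (sub["lfc"].abs() > lfc_min)]
    direction = np.where(sub["gene_id"].isin(consensus.up), "up", "down")
    out = sub.copy()
    out["direction"] = direction
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-dataset concordance of a consensus signature.

    ``frac_concordant`` is the fraction of assessed genes whose lfc sign matches the
    consensus direction; ``mean_signed_lfc`` is the mean of lfc multiplied by the
    consensus direction (+1 up, -1 down).  Both are NaN when nothing is assessed.
    """

    dataset: str
    n_assessed: int
    frac_concordant: float
    mean_signed_lfc: float


def concordance_score(subset: pd.DataFrame, dataset: str = "dataset") -> ConcordanceReport:
    """Summarize a labelled consensus subset (output of :func:`aki_subset`)."""
    if "direction" not in subset.columns:
        raise ParameterError("subset must carry a 'direction' column (use aki_subset)")
    n = len(subset)
    if n == 0:
        return ConcordanceReport(dataset, 0, float("nan"), float("nan"))
    sign = np.where(subset["direction"].to_numpy() == "up", 1.0, -1.0)
    signed = subset["lfc"].to_numpy() * sign
    return ConcordanceReport(
        dataset=dataset,
        n_assessed=n,
        frac_concordant=float((signed > 0).mean()),
        mean_signed_lfc=float(signed.mean()),
    )


def lfc_matrix(
    tables: Mapping[str, pd.DataFrame],
    consensus: ConsensusSignature,
    lfc_min: float = 0.15,
    padj_max: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x datasets matrix of lfc values for consensus genes assessed anywhere.

    A gene appears if it passes the thresholds in at least one dataset; cells where it
    does not pass in a particular dataset are NaN.  The companion series annotates each
    row with its consensus direction.
    """
    assessed: dict[str, dict[str, float]] = {}
    for ds, table in tables.items():
        sub = aki_subset(table, consensus, lfc_min, padj_max)
        assessed[ds] = dict(zip(sub["gene_id"], sub["lfc"]))
    genes = sorted({g for vals in assessed.values() for g in vals})
    mat = pd.DataFrame(
        {ds: [assessed[ds].get(g, np.nan) for g in genes] for ds in tables},
        index=pd.Index(genes, name="gene_id"),
    )
    directions = pd.Series(
        ["up" if g in consensus.up else "down" for g in genes],
        index=mat.index, name="direction",
    )
    return mat, directions
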