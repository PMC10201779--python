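"""Disease-signature construction from differential-expression tables.

The reversion query is built in four steps: strict LFC/padj threshold filtering, an
adaptive LFC cutoff that targets a 100-200 gene signature (the size previously found
optimal for signature reversion), orthology mapping from the mouse assay namespace onto
the human reference gene universe, and top-N selection per direction by log2 fold
change.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SignatureSizeError
from .types import GeneSignature

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "lfc", "padj"]

#: default adaptive grid: mirrors relaxing a cutoff of 2.0 stepwise down to 1.0
DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(2.0, 0.95, -0.1), 2))


def _check_de(table: pd.DataFrame) -> None:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"DE table missing columns: {missing}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParameterError(f"DE table has duplicate gene id {dup!r}")


def filter_de(table: pd.DataFrame, lfc_cutoff: float, padj_cutoff: float) -> pd.DataFrame:
    """Rows with |lfc| strictly above ``lfc_cutoff`` and padj strictly below ``padj_cutoff``.

    Boundary rows are excluded (strict inequalities) and rows with missing padj are
    treated as not significant, matching how independent filtering in DE tools reports
    untestable genes.  The input frame is not modified.
    """
    if lfc_cutoff <= 0:
        raise ParameterError(f"lfc_cutoff must be positive, got {lfc_cutoff}")
    if not 0 < padj_cutoff <= 1:
        raise ParameterError(f"padj_cutoff must be in (0, 1], got {padj_cutoff}")
    _check_de(table)
    mask = (
        table["padj"].notna()
        & (table["padj"] < padj_cutoff)
        & (table["lfc"].abs() > lfc_cutoff)
    )
    return table.loc[mask].reset_index(drop=True)


class AdaptiveCutoff(NamedTuple):
    cutoff: float
    n_genes: int


def adaptive_lfc_cutoff(
    table: pd.DataFrame,
    padj_cutoff: float = 0.05,
    target_range: tuple[int, int] = (100, 200),
    grid: Sequence[float] = DEFAULT_GRID,
) -> AdaptiveCutoff:
    """Choose an LFC cutoff whose filtered gene count lands in ``target_range``.

    Returns the *largest* grid cutoff giving a count inside [min, max] (inclusive); if
    no cutoff lands in range, the one minimizing the distance of its count to the
    nearest bound wins, with ties resolved toward the larger (more stringent) cutoff.
    """
    if len(table) == 0:
        raise SignatureSizeError("empty DE table: no genes to size a signature from")
    grid = list(grid)
    if not grid:
        raise ParameterError("cutoff grid is empty")
    if any(c <= 0 for c in grid) or any(a <= b for a, b in zip(grid, grid[1:])):
        raise ParameterError("cutoff grid must be strictly descending and positive")
    lo, hi = target_range
    counts = [len(filter_de(table, c, padj_cutoff)) for c in grid]
    for c, n in zip(grid, counts):
        if lo <= n <= hi:
            logger.info("adaptive cutoff %.3g -> %d genes (in range)", c, n)
            return AdaptiveCutoff(float(c), n)
    # no cutoff in range: nearest-count fallback; grid order breaks ties toward larger
    def dist(n: int) -> int:
        return lo - n if n < lo else n - hi
    best = min(range(len(grid)), key=lambda i: dist(counts[i]))
    logger.info("adaptive cutoff %.3g -> %d genes (nearest to [%d, %d])",
                grid[best], counts[best], lo, hi)
    return AdaptiveCutoff(float(grid[best]), counts[best])


def map_orthologs(
    table: pd.DataFrame, orthology: pd.DataFrame, universe: Iterable[str]
) -> pd.DataFrame:
    """Project a mouse-namespace DE table onto the human reference universe.

    Mouse genes with anything other than exactly one ortholog are dropped (ambiguity
    cannot be resolved deterministically from a DE table alone), as are genes whose
    ortholog is absent from ``universe``.  When several mouse genes map onto the same
    human gene, the row with the larger |lfc| survives (ties: smaller padj, then
    lexicographic source id).  The result is a DE table in the human namespace with a
    ``source_gene`` provenance column.
    """
    uni = set(universe)
    if not uni:
        raise ParameterError("reference gene universe is empty")
    _check_de(table)
    if {"source_gene", "target_gene"} - set(orthology.columns):
        raise ParameterError("orthology map needs source_gene/target_gene columns")
    if orthology.duplicated(["source_gene", "target_gene"]).any():
        raise ParameterError("orthology map contains duplicate (source, target) pairs")
    n_targets = orthology.groupby("source_gene")["target_gene"].nunique()
    unique_sources = set(n_targets[n_targets == 1].index)
    omap = orthology[orthology["source_gene"].isin(unique_sources)]
    omap = omap[omap["target_gene"].isin(uni)]
    merged = table.merge(omap, left_on="gene_id", right_on="source_gene", how="inner")
    merged = merged.assign(_abs=merged["lfc"].abs())
    merged = merged.sort_values(
        ["target_gene", "_abs", "padj", "gene_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("target_gene", keep="first")
    out = pd.DataFrame({
        "gene_id": merged["target_gene"].to_numpy(),
        "lfc": merged["lfc"].to_numpy(),
        "padj": merged["padj"].to_numpy(),
        "source_gene": merged["gene_id"].to_numpy(),
    })
    out = out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    logger.info("orthology mapping kept %d/%d genes", len(out), len(table))
    return out


def build_signature(
    mapped: pd.DataFrame,
    n_per_side: int = 100,
    dataset_id: str = "dataset",
    lfc_cutoff: float | None = None,
    padj_cutoff: float | None = None,
) -> GeneSignature:
    """Top-``n_per_side`` up- and downregulated genes of a filtered, mapped DE table.

    Up genes are those with positive lfc ordered descending, down genes negative lfc
    ordered ascending; ties in lfc break by smaller padj then lexicographic gene id.
    Sides with fewer than ``n_per_side`` genes take all available.
    """
    if n_per_side <= 0:
        raise ParameterError("n_per_side must be positive")
    _check_de(mapped)
    up_rows = mapped[mapped["lfc"] > 0].sort_values(
        ["lfc", "padj", "gene_id"], ascending=[False, True, True], kind="mergesort"
    )
    down_rows = mapped[mapped["lfc"] < 0].sort_values(
        ["lfc", "padj", "gene_id"], ascending=[True, True, True], kind="mergesort"
    )
    up = tuple(up_rows["gene_id"].head(n_per_side))
    down = tuple(down_rows["gene_id"].head(n_per_side))
    if not up and not down:
        raise SignatureSizeError("no genes on either side after filtering")
    return GeneSignature(
        up=up,
        down=down,
        provenance={
            "dataset": dataset_id,
            "lfc_cutoff": lfc_cutoff,
            "padj_cutoff": padj_cutoff,
            "n_per_side": n_per_side,
        },
    )
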