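"""Candidate-prioritization cascade for signature-reversion hits.

Connectivity results (negative NCS in allowed cell lines) collapse to one record per
compound, then pass through successive filters: clinical status ("Launched"), presence
of the ingredient in an FDA active-ingredient registry, and finally intersection of the
compound's annotated targets with the genes upregulated in independent disease-stage
datasets — keeping only drugs whose targets are upregulated in *both* cystic-stage
datasets.  Each stage strictly narrows the previous one, mirroring a
candidates -> launched -> FDA-approved -> target-supported funnel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .connectivity import query_reference
from .errors import ParameterError
from .types import GeneSignature, ReferenceSet

logger = logging.getLogger(__name__)

CLINICAL_PHASES = ("Launched", "Phase 3", "Phase 2", "Phase 1", "Preclinical", "Unknown")
FDA_STATUSES = frozenset({"prescription", "over-the-counter", "tentative approval"})

ANNOTATION_COLUMNS = ["pert_id", "name", "clinical_phase", "moa", "targets", "indication"]

_WS = re.compile(r"\s+")


def normalize_ingredient(name: str) -> str:
    """Case-fold, trim and collapse internal whitespace of an ingredient string."""
    return _WS.sub(" ", str(name).strip()).casefold()


def collapse_to_drugs(results: pd.DataFrame) -> pd.DataFrame:
    """One record per compound: most-negative NCS and the contributing cell lines.

    ``results`` is the (already cell-line- and direction-filtered) connectivity table.
    Output rows are ordered by (best_ncs, pert_id).
    """
    needed = {"pert_id", "cell_line", "ncs"}
    if needed - set(results.columns):
        raise ParameterError(f"results table needs columns {sorted(needed)}")
    if len(results) == 0:
        return pd.DataFrame(columns=["pert_id", "best_ncs", "cell_lines"])
    grouped = results.groupby("pert_id", sort=True)
    out = pd.DataFrame({
        "pert_id": list(grouped.groups),
        "best_ncs": grouped["ncs"].min().to_numpy(),
        "cell_lines": [
            ",".join(sorted(set(g["cell_line"]))) for _, g in grouped
        ],
    })
    return out.sort_values(["best_ncs", "pert_id"], kind="mergesort").reset_index(drop=True)


def filter_launched(cands: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Keep candidates annotated with clinical phase "Launched".

    Candidates without any annotation row are dropped (their status is unknowable) and
    the dropped count is logged.
    """
    if set(ANNOTATION_COLUMNS) - set(annotations.columns):
        raise ParameterError(f"annotation table needs columns {ANNOTATION_COLUMNS}")
    merged = cands.merge(annotations, on="pert_id", how="left")
    unannotated = merged["clinical_phase"].isna()
    if unannotated.any():
        logger.warning("dropping %d candidates without drug annotations", unannotated.sum())
    out = merged[merged["clinical_phase"] == "Launched"].reset_index(drop=True)
    logger.info("launched filter: %d -> %d candidates", len(cands), len(out))
    return out


def filter_fda(cands: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Keep candidates whose ingredient name appears in the FDA registry.

    Matching is by normalized name (case-fold/trim/whitespace-collapse) against
    registry rows with any accepted marketing status, regardless of dosage form.
    """
    if {"ingredient", "marketing_status"} - set(registry.columns):
        raise ParameterError("registry needs ingredient/marketing_status columns")
    ok = registry[registry["marketing_status"].isin(FDA_STATUSES)]
    approved = {normalize_ingredient(i) for i in ok["ingredient"]}
    keep = cands["name"].map(normalize_ingredient).isin(approved)
    out = cands[keep].reset_index(drop=True)
    logger.info("FDA registry filter: %d -> %d candidates", len(cands), len(out))
    return out


def target_overlap(
    cands: pd.DataFrame, up_gene_sets: Mapping[str, set[str] | frozenset[str]]
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Intersect each drug's targets with the upregulated genes of each dataset.

    Adds one ``overlap_<dataset>`` column of frozensets per dataset and returns a
    summary of, per dataset, how many unique upregulated genes are matched by any drug
    and how many drugs have a non-empty overlap.
    """
    if "targets" not in cands.columns:
        raise ParameterError("candidates must carry a 'targets' column (merge annotations first)")
    out = cands.copy()
    summary: dict[str, dict[str, int]] = {}
    for ds, up_genes in up_gene_sets.items():
        up = set(up_genes)
        overlaps = [frozenset(set(t) & up) for t in out["targets"]]
        out[f"overlap_{ds}"] = overlaps
        matched: set[str] = set().union(*overlaps) if overlaps else set()
        summary[ds] = {
            "unique_genes": len(matched),
            "drugs": sum(1 for o in overlaps if o),
        }
    return out, summary


def prioritize_cystic(
    cands: pd.DataFrame, cystic_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Keep drugs with upregulated targets in *each* of the two cystic datasets.

    The overlapping gene need not be the same in both datasets.  Returns the
    prioritized candidates, the drug->target edge list over the union of cystic
    overlaps, and the number of unique target genes in that union.
    """
    if len(cystic_ids) != 2:
        raise ParameterError(f"exactly two cystic dataset ids required, got {list(cystic_ids)}")
    cols = [f"overlap_{ds}" for ds in cystic_ids]
    for c in cols:
        if c not in cands.columns:
            raise ParameterError(f"candidates lack column {c!r}; run target_overlap first")
    keep = cands[cols[0]].astype(bool) & cands[cols[1]].astype(bool)
    pri = cands[keep].reset_index(drop=True)
    edges = []
    for row in pri.itertuples():
        union = set(getattr(row, cols[0])) | set(getattr(row, cols[1]))
        for gene in sorted(union):
            edges.append((row.pert_id, row.name, gene))
    edges_df = pd.DataFrame(edges, columns=["pert_id", "name", "target"])
    n_unique = edges_df["target"].nunique() if len(edges_df) else 0
    logger.info("cystic-target prioritization: %d -> %d drugs (%d unique targets)",
                len(cands), len(pri), n_unique)
    return pri, edges_df, n_unique


@dataclass
class CascadeResult:
    """Everything the prioritization cascade produces."""

    connectivity: pd.DataFrame
    candidates: pd.DataFrame          # final prioritized drugs
    edges: pd.DataFrame               # drug -> cystic-upregulated-target edge list
    stage_counts: dict[str, int] = field(default_factory=dict)
    overlap_summary: dict[str, dict[str, int]] = field(default_factory=dict)
    unique_target_count: int = 0
    stages: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_cascade(
    sig: GeneSignature,
    ref: ReferenceSet,
    annotations: pd.DataFrame,
    registry: pd.DataFrame,
    up_gene_sets: Mapping[str, set[str] | frozenset[str]],
    cell_lines: Sequence[str],
    cystic_ids: Sequence[str],
    weight_exponent: float = 1.0,
) -> CascadeResult:
    """Full funnel: reversion query -> collapse -> launched -> FDA -> cystic targets."""
    if len(cystic_ids) != 2:
        raise ParameterError("exactly two cystic dataset ids required")
    for ds in cystic_ids:
        if ds not in up_gene_sets:
            raise ParameterError(f"no upregulated gene set supplied for dataset {ds!r}")
    results = query_reference(sig, ref, cell_lines, direction="inverse",
                              weight_exponent=weight_exponent)
    drugs = collapse_to_drugs(results)
    launched = filter_launched(drugs, annotations)
    fda = filter_fda(launched, registry)
    with_overlap, summary = target_overlap(fda, up_gene_sets)
    final, edges, n_unique = prioritize_cystic(with_overlap, cystic_ids)
    counts = {
        "connectivity_rows": len(results),
        "negative_ncs_drugs": len(drugs),
        "launched": len(launched),
        "fda_approved": len(fda),
        "targets_both_cystic": len(final),
    }
    logger.info("cascade counts: %s", counts)
    return CascadeResult(
        connectivity=results,
        candidates=final,
        edges=edges,
        stage_counts=counts,
        overlap_summary=summary,
        unique_target_count=n_unique,
        stages={"collapsed": drugs, "launched": launched, "fda": fda,
                "overlap": with_overlap},
    )
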