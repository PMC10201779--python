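"""Core in-memory containers shared across pipeline stages.

Differential-expression tables travel as plain :class:`pandas.DataFrame` objects with
columns ``gene_id``, ``lfc`` (log2 fold change) and ``padj`` (adjusted p-value); the
richer objects below wrap everything that carries structural invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError

#: separator between perturbagen and cell line in reference-signature column ids
SIG_ID_SEP = "__"


@dataclass(frozen=True)
class GeneSignature:
    """Ordered, disjoint up/down gene lists used as a reversion query.

    ``up`` is ordered by descending log2 fold change, ``down`` by ascending, so the
    strongest genes of each direction come first.  ``provenance`` records the dataset
    and the cutoffs the signature was built with.
    """

    up: tuple[str, ...]
    down: tuple[str, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ParameterError("signature up/down lists must be disjoint")
        if len(set(self.up)) != len(self.up) or len(set(self.down)) != len(self.down):
            raise ParameterError("signature gene lists must not contain duplicates")

    @property
    def n_genes(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class ReferenceSet:
    """A drug-perturbation reference: one score vector per (compound, cell line).

    ``data`` holds genes on the rows (the common gene universe) and signatures on the
    columns, with column ids formatted ``<pert_id>__<cell_line>``. ``cell_line_tags``
    maps each cell line to ``"kidney"`` or ``"other"``.
    """

    data: pd.DataFrame
    cell_line_tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ParameterError("reference gene universe contains duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ParameterError("reference contains duplicate signature ids")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ParameterError("reference scores must be finite")
        for col in self.data.columns:
            if SIG_ID_SEP not in col:
                raise ParameterError(
                    f"signature id {col!r} is not formatted '<pert>{SIG_ID_SEP}<cell>'"
                )

    @property
    def universe(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def n_signatures(self) -> int:
        return self.data.shape[1]

    @staticmethod
    def split_id(sig_id: str) -> tuple[str, str]:
        pert, _, cell = sig_id.partition(SIG_ID_SEP)
        return pert, cell

    @property
    def pert_ids(self) -> list[str]:
        return sorted({self.split_id(c)[0] for c in self.data.columns})

    @property
    def cell_lines(self) -> list[str]:
        return sorted({self.split_id(c)[1] for c in self.data.columns})

    def kidney_cell_lines(self) -> list[str]:
        return sorted(c for c, t in self.cell_line_tags.items() if t == "kidney")


@dataclass(frozen=True)
class GeneSet:
    """One term of a gene-set collection (a single GMT line)."""

    term_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError(f"gene set {self.term_id!r} has no members")


@dataclass(frozen=True)
class ConsensusSignature:
    """Direction-labelled consensus gene lists (e.g. a 24h acute-kidney-injury panel)."""

    up: frozenset[str]
    down: frozenset[str]
    label: str = "consensus"

    def __post_init__(self) -> None:
        if not self.up or not self.down:
            raise ParameterError("consensus signature needs non-empty up and down sets")
        if self.up & self.down:
            raise ParameterError("consensus up/down sets must be disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down
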