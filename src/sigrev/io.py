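"""Readers and writers for every on-disk format the pipeline touches.

All tabular inputs are TSV with documented headers; the perturbation reference uses the
text GCT dialect (version ``#1.2``) with signature columns named
``<pert_id>__<cell_line>``, and gene sets / signatures use GMT.  Floats are written
with Python's shortest round-trip repr so write(read(x)) is byte-stable and lossless.
Malformed rows raise :class:`~sigrev.errors.ParseError` naming the offending line.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .types import ConsensusSignature, GeneSet, GeneSignature, ReferenceSet

# ---------------------------------------------------------------------- helpers

def _fmt(value: object) -> str:
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        return repr(float(value))
    return str(value)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _to_float(df: pd.DataFrame, col: str, path: Path, allow_na: bool = False) -> np.ndarray:
    raw = df[col].to_numpy()
    out = np.empty(len(raw))
    for i, v in enumerate(raw):
        if allow_na and v in ("NA", ""):
            out[i] = np.nan
            continue
        try:
            out[i] = float(v)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric {col!r} value {v!r} at line {i + 2}"
            ) from None
    return out


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------- DE tables (TSV)

def read_de_table(path: str | Path) -> pd.DataFrame:
    """TSV with header ``gene_id  lfc  padj``; padj may be ``NA``."""
    path = Path(path)
    df = _read_tsv(path, ["gene_id", "lfc", "padj"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        line = int(np.where(df["gene_id"] == dup)[0][1]) + 2
        raise ParseError(f"{path}: duplicate gene id {dup!r} at line {line}")
    return pd.DataFrame({
        "gene_id": df["gene_id"].astype(str),
        "lfc": _to_float(df, "lfc", path),
        "padj": _to_float(df, "padj", path, allow_na=True),
    })


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    lines = ["gene_id\tlfc\tpadj"]
    for row in table.itertuples(index=False):
        lines.append(f"{row.gene_id}\t{_fmt(row.lfc)}\t{_fmt(row.padj)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- orthology

def read_orthology(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_tsv(path, ["source_gene", "target_gene"])
    if df.duplicated(["source_gene", "target_gene"]).any():
        raise ParseError(f"{path}: duplicate (source, target) pair")
    return df.astype(str)


def write_orthology(omap: pd.DataFrame, path: str | Path) -> None:
    lines = ["source_gene\ttarget_gene"]
    for row in omap.itertuples(index=False):
        lines.append(f"{row.source_gene}\t{row.target_gene}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------- annotations

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Drug annotation TSV; ``targets`` is a pipe-separated gene list (may be empty)."""
    path = Path(path)
    df = _read_tsv(path, ["pert_id", "name", "clinical_phase", "moa", "targets",
                          "indication"])
    if df["pert_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate pert_id")
    df = df.astype(str)
    df["targets"] = [
        frozenset(t.split("|")) if t else frozenset() for t in df["targets"]
    ]
    return df


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    lines = ["pert_id\tname\tclinical_phase\tmoa\ttargets\tindication"]
    for row in annotations.itertuples(index=False):
        targets = "|".join(sorted(row.targets))
        lines.append(f"{row.pert_id}\t{row.name}\t{row.clinical_phase}\t{row.moa}\t"
                     f"{targets}\t{row.indication}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- FDA registry

def read_fda(path: str | Path) -> pd.DataFrame:
    return _read_tsv(Path(path), ["ingredient", "marketing_status"]).astype(str)


def write_fda(registry: pd.DataFrame, path: str | Path) -> None:
    lines = ["ingredient\tmarketing_status"]
    for row in registry.itertuples(index=False):
        lines.append(f"{row.ingredient}\t{row.marketing_status}")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------ consensus lists

def read_consensus(path: str | Path, label: str = "consensus") -> ConsensusSignature:
    path = Path(path)
    df = _read_tsv(path, ["gene_id", "direction"])
    up, down = set(), set()
    for i, (gene, direction) in enumerate(zip(df["gene_id"], df["direction"])):
        if direction == "up":
            up.add(gene)
        elif direction == "down":
            down.add(gene)
        else:
            raise ParseError(f"{path}: direction must be up/down, got {direction!r} "
                             f"at line {i + 2}")
    return ConsensusSignature(up=frozenset(up), down=frozenset(down), label=label)


def write_consensus(consensus: ConsensusSignature, path: str | Path) -> None:
    lines = ["gene_id\tdirection"]
    for gene in sorted(consensus.up):
        lines.append(f"{gene}\tup")
    for gene in sorted(consensus.down):
        lines.append(f"{gene}\tdown")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: GMT line {i + 1} has fewer than 3 fields")
        term, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in seen:
            raise ParseError(f"{path}: duplicate term id {term!r} at line {i + 1}")
        seen.add(term)
        sets.append(GeneSet(term_id=term, description=desc, members=frozenset(members)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.term_id, gs.description, *sorted(gs.members)])
        for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_signature_gmt(sig: GeneSignature, path: str | Path) -> None:
    """Serialize a disease signature as a two-line GMT (<dataset>_UP / <dataset>_DOWN).

    Gene order inside each line preserves the signature's LFC ordering.
    """
    ds = str(sig.provenance.get("dataset", "signature"))
    lines = [
        "\t".join([f"{ds}_UP", "upregulated signature genes", *sig.up]),
        "\t".join([f"{ds}_DOWN", "downregulated signature genes", *sig.down]),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_signature_gmt(path: str | Path) -> GeneSignature:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) != 2:
        raise ParseError(f"{path}: signature GMT must have exactly two lines")
    up_parts, down_parts = lines[0].split("\t"), lines[1].split("\t")
    if not up_parts[0].endswith("_UP") or not down_parts[0].endswith("_DOWN"):
        raise ParseError(f"{path}: expected <dataset>_UP then <dataset>_DOWN terms")
    ds = up_parts[0][: -len("_UP")]
    return GeneSignature(up=tuple(g for g in up_parts[2:] if g),
                         down=tuple(g for g in down_parts[2:] if g),
                         provenance={"dataset": ds})


# ------------------------------------------------------------------------- GCT

def read_gct(path: str | Path) -> pd.DataFrame:
    """Text GCT (#1.2): rows = genes, columns = signature ids."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise ParseError(f"{path}: not a text GCT file (missing '#1.2' header)")
    try:
        nr, nc = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise ParseError(f"{path}: malformed GCT dimension line") from None
    header = lines[2].split("\t")
    if header[:2] != ["Name", "Description"]:
        raise ParseError(f"{path}: GCT column header must start with Name, Description")
    cols = header[2:]
    if len(cols) != nc:
        raise ParseError(f"{path}: header has {len(cols)} columns, expected {nc}")
    body = lines[3:]
    if len(body) != nr:
        raise ParseError(f"{path}: {len(body)} data rows, expected {nr}")
    genes, values = [], np.empty((nr, nc))
    for i, line in enumerate(body):
        parts = line.split("\t")
        if len(parts) != nc + 2:
            raise ParseError(f"{path}: row at line {i + 4} has {len(parts)} fields")
        genes.append(parts[0])
        try:
            values[i] = [float(v) for v in parts[2:]]
        except ValueError:
            raise ParseError(f"{path}: non-numeric value at line {i + 4}") from None
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene ids in GCT")
    return df


def write_gct(data: pd.DataFrame, path: str | Path) -> None:
    nr, nc = data.shape
    lines = ["#1.2", f"{nr}\t{nc}", "\t".join(["Name", "Description", *map(str, data.columns)])]
    values = data.to_numpy()
    for i, gene in enumerate(data.index):
        lines.append("\t".join([str(gene), "na", *(_fmt(v) for v in values[i])]))
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------- cell-line tags + reference

def read_cell_line_tags(path: str | Path) -> dict[str, str]:
    df = _read_tsv(Path(path), ["cell_line", "tag"])
    bad = set(df["tag"]) - {"kidney", "other"}
    if bad:
        raise ParseError(f"{path}: tags must be kidney/other, got {sorted(bad)}")
    return dict(zip(df["cell_line"], df["tag"]))


def write_cell_line_tags(tags: dict[str, str], path: str | Path) -> None:
    lines = ["cell_line\ttag"]
    for cell in sorted(tags):
        lines.append(f"{cell}\t{tags[cell]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference(gct_path: str | Path, tags_path: str | Path) -> ReferenceSet:
    return ReferenceSet(data=read_gct(gct_path),
                        cell_line_tags=read_cell_line_tags(tags_path))


def write_reference(ref: ReferenceSet, gct_path: str | Path,
                    tags_path: str | Path) -> None:
    write_gct(ref.data, gct_path)
    write_cell_line_tags(dict(ref.cell_line_tags), tags_path)
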