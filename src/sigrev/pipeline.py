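"""End-to-end run configuration, manifest, and the `run_all` driver.

The driver chains signature construction (pre-cystic dataset), reversion querying of
the perturbation reference, the prioritization cascade, functional and drug-set
enrichment, and consensus-signature concordance, writing every stage's table plus a
manifest (config echo, input hashes, stage counts) into the output directory.  Two
runs over identical inputs produce identical outputs and identical manifests up to the
timestamp field.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .concordance import aki_subset, concordance_score, lfc_matrix
from .enrichment import dsea_hyperG, ora
from .errors import ConfigError, SigrevError
from .prioritization import CascadeResult, run_cascade
from .signatures import (DEFAULT_GRID, adaptive_lfc_cutoff, build_signature,
                         filter_de, map_orthologs)

logger = logging.getLogger(__name__)

DATASET_KEYS = ("precystic", "cystic_a", "cystic_b")


@dataclass
class RunConfig:
    """Paths and stage parameters of a full pipeline run."""

    # input paths
    de_precystic: str = ""
    de_cystic_a: str = ""
    de_cystic_b: str = ""
    orthology: str = ""
    reference_gct: str = ""
    cell_line_tags: str = ""
    annotations: str = ""
    fda: str = ""
    gene_sets: str = ""
    aki_consensus: str = ""
    out_dir: str = "sigrev_out"
    # signature stage
    signature_lfc: str | float = "auto"
    signature_padj: float = 0.05
    n_per_side: int = 100
    # connectivity stage
    weight_exponent: float = 1.0
    cell_lines: tuple[str, ...] = ()          # empty -> all kidney-tagged lines
    direction: str = "inverse"
    # prioritization stage
    cystic_ids: tuple[str, str] = ("cystic_a", "cystic_b")
    up_lfc_precystic: float = 1.1
    up_lfc_cystic: float = 2.0
    # enrichment stage
    fea_method: str = "bonferroni"
    fea_size_min: int = 5
    fea_size_max: int = 1000
    fea_alpha: float = 0.05
    dsea_method: str = "bh"
    dsea_size_min: int = 10
    dsea_size_max: int = 500
    dsea_alpha: float = 0.05
    # concordance stage
    aki_lfc_min: float = 0.15
    aki_padj_max: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config file, rejecting unknown keys outright."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("cell_lines", "cystic_ids"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.direction not in {"inverse", "similar", "all"}:
            raise ConfigError(f"direction must be inverse/similar/all, got {self.direction!r}")
        if not 0 < self.signature_padj <= 1:
            raise ConfigError("signature_padj must be in (0, 1]")
        if isinstance(self.signature_lfc, str) and self.signature_lfc != "auto":
            raise ConfigError("signature_lfc must be 'auto' or a positive number")
        if len(self.cystic_ids) != 2:
            raise ConfigError("cystic_ids must name exactly two datasets")
        for key in ("de_precystic", "de_cystic_a", "de_cystic_b", "orthology",
                    "reference_gct", "cell_line_tags", "annotations", "fda",
                    "gene_sets", "aki_consensus"):
            if not getattr(self, key):
                raise ConfigError(f"missing input path: {key}")

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        d["cystic_ids"] = list(self.cystic_ids)
        return d


@dataclass
class RunManifest:
    """Reproducibility record of a completed run."""

    config: dict
    input_hashes: dict[str, str]
    stage_counts: dict[str, int]
    overlap_summary: dict[str, dict[str, int]] = field(default_factory=dict)
    concordance: dict[str, dict] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))

    def comparable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("timestamp")
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise any failure naming the stage."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, SigrevError):
                raise SigrevError(f"stage '{name}' failed: {exc}") from exc
            if isinstance(exc, SigrevError) and "stage '" not in str(exc):
                raise SigrevError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


def _write_results_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, frozenset)).any():
            out[col] = out[col].map(lambda v: "|".join(sorted(v)))
    out.to_csv(path, sep="\t", index=False)


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage in order and write all outputs plus the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_paths = {
        key: getattr(config, key)
        for key in ("de_precystic", "de_cystic_a", "de_cystic_b", "orthology",
                    "reference_gct", "cell_line_tags", "annotations", "fda",
                    "gene_sets", "aki_consensus")
    }
    hashes = {k: sio.sha256_file(v) for k, v in input_paths.items()}

    with _stage("load"):
        tables = {
            "precystic": sio.read_de_table(config.de_precystic),
            "cystic_a": sio.read_de_table(config.de_cystic_a),
            "cystic_b": sio.read_de_table(config.de_cystic_b),
        }
        orthology = sio.read_orthology(config.orthology)
        reference = sio.read_reference(config.reference_gct, config.cell_line_tags)
        annotations = sio.read_annotations(config.annotations)
        registry = sio.read_fda(config.fda)
        gene_sets = sio.read_gmt(config.gene_sets)
        consensus = sio.read_consensus(config.aki_consensus, label="AKI-24h")

    with _stage("signature"):
        table = tables["precystic"]
        if config.signature_lfc == "auto":
            cutoff, n_at_cutoff = adaptive_lfc_cutoff(
                table, config.signature_padj, grid=DEFAULT_GRID)
        else:
            cutoff, n_at_cutoff = float(config.signature_lfc), -1
        filtered = filter_de(table, cutoff, config.signature_padj)
        mapped = map_orthologs(filtered, orthology, reference.universe)
        sig = build_signature(mapped, config.n_per_side, dataset_id="precystic",
                              lfc_cutoff=cutoff, padj_cutoff=config.signature_padj)
        sio.write_signature_gmt(sig, out / "signature.gmt")

    with _stage("cascade"):
        cells = tuple(config.cell_lines) or tuple(reference.kidney_cell_lines())
        up_gene_sets = {}
        for ds in DATASET_KEYS:
            up_cut = (config.up_lfc_precystic if ds == "precystic"
                      else config.up_lfc_cystic)
            de_up = filter_de(tables[ds], up_cut, config.signature_padj)
            de_up = de_up[de_up["lfc"] > 0]
            mapped_up = map_orthologs(de_up, orthology, reference.universe)
            up_gene_sets[ds] = set(mapped_up["gene_id"])
        cascade: CascadeResult = run_cascade(
            sig, reference, annotations, registry, up_gene_sets,
            cell_lines=cells, cystic_ids=config.cystic_ids,
            weight_exponent=config.weight_exponent)
        cascade.connectivity.to_csv(out / "connectivity.tsv", sep="\t", index=False)
        _write_results_tsv(cascade.candidates, out / "candidates.tsv")
        cascade.edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        counts_df = pd.DataFrame(
            {"stage": list(cascade.stage_counts), "count": list(cascade.stage_counts.values())})
        counts_df.to_csv(out / "stage_counts.tsv", sep="\t", index=False)

    with _stage("enrichment"):
        bounds = (config.fea_size_min, config.fea_size_max)
        for side, genes in (("up", sig.up), ("down", sig.down)):
            if genes:
                fea = ora(genes, gene_sets, reference.universe, bounds,
                          config.fea_method, config.fea_alpha)
            else:
                fea = pd.DataFrame()
            fea.to_csv(out / f"fea_{side}.tsv", sep="\t", index=False)
        targets = dict(zip(cascade.candidates["pert_id"],
                           cascade.candidates["targets"]))
        if targets and all(targets.values()):
            dsea, dsea_edges = dsea_hyperG(
                targets, annotations, gene_sets,
                (config.dsea_size_min, config.dsea_size_max),
                config.dsea_method, config.dsea_alpha)
        else:
            logger.warning("no prioritized drugs with targets; skipping drug-set enrichment")
            dsea, dsea_edges = pd.DataFrame(), pd.DataFrame()
        dsea.to_csv(out / "dsea.tsv", sep="\t", index=False)
        dsea_edges.to_csv(out / "dsea_edges.tsv", sep="\t", index=False)

    with _stage("concordance"):
        reports = {}
        for ds in DATASET_KEYS:
            sub = aki_subset(tables[ds], consensus, config.aki_lfc_min,
                             config.aki_padj_max)
            reports[ds] = dataclasses.asdict(concordance_score(sub, dataset=ds))
        pd.DataFrame(reports.values()).to_csv(out / "concordance.tsv", sep="\t",
                                              index=False)
        mat, directions = lfc_matrix(tables, consensus, config.aki_lfc_min,
                                     config.aki_padj_max)
        mat.assign(direction=directions).to_csv(out / "lfc_matrix.tsv", sep="\t")

    manifest = RunManifest(
        config=config.asdict(),
        input_hashes=hashes,
        stage_counts=dict(cascade.stage_counts),
        overlap_summary=cascade.overlap_summary,
        concordance=reports,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return manifest
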