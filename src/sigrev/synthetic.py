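"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of a three-dataset kidney-disease study: one
pre-cystic differential-expression table with its own perturbed gene program, two
cystic tables sharing a strong common program plus an acute-kidney-injury (AKI)
contamination program (absent from the pre-cystic table), a mouse-to-human orthology
map with unmappable and ambiguous genes, a drug-perturbation reference with planted
signature reversers and mimics across kidney-tagged and other cell lines, drug
annotations, an FDA active-ingredient registry, gene-set collections, and the AKI
consensus lists.  Everything is a deterministic function of the configuration seed,
and the planted memberships are returned as an explicit truth record so downstream
recovery can be asserted exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as sio
from .enrichment import adjust
from .errors import ParameterError, SizingError
from .types import ConsensusSignature, GeneSet, ReferenceSet

DATASET_IDS = ("precystic", "cystic_a", "cystic_b")

DEFAULT_PROGRAM_SIZES: dict[str, int] = {
    # pre-cystic program sized so the derived signature lands inside the
    # 100-200 gene window after orthology mapping
    "precystic_up": 80,
    "precystic_down": 80,
    "cystic_up": 150,
    "cystic_down": 150,
    # consensus AKI panel sizes: 157 genes consistently up, 88 down at 24h post-injury
    "aki_up": 157,
    "aki_down": 88,
}

DEFAULT_PHASE_PROPORTIONS: dict[str, float] = {
    "Launched": 0.35,
    "Phase 3": 0.10,
    "Phase 2": 0.15,
    "Phase 1": 0.15,
    "Preclinical": 0.20,
    "Unknown": 0.05,
}

_CELL_LINE_POOL = ("A375", "MCF7", "PC3", "VCAP", "HT29", "HEPG2", "A549", "HCC515")

_MOA_VOCAB = (
    "dopamine receptor antagonist", "dopamine receptor agonist",
    "HMGCR inhibitor", "tubulin polymerization inhibitor",
    "topoisomerase inhibitor", "sodium channel blocker",
    "calcium channel blocker", "serotonin receptor antagonist",
    "PPAR receptor agonist", "acetylcholine receptor agonist",
    "glucocorticoid receptor agonist", "tyrosine kinase inhibitor",
)

_INDICATION_VOCAB = (
    "hypertension", "depression", "schizophrenia", "oncology",
    "hypercholesterolemia", "infectious disease", "smoking cessation",
    "inflammation", "diabetes", "unknown",
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; identical configs yield identical bundles."""

    seed: int = 7
    n_genes_mouse: int = 2200
    n_genes_human: int = 2000
    frac_unmappable: float = 0.10
    frac_many_to_one: float = 0.02
    frac_one_to_many: float = 0.01
    program_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PROGRAM_SIZES))
    effect_size_mean: float = 4.0
    effect_size_sd: float = 0.5
    null_lfc_sd: float = 0.3
    n_compounds: int = 500
    n_cell_lines: int = 2
    kidney_cell_lines: tuple[str, ...] = ("HA1E",)
    n_planted_reversers: int = 5
    n_planted_mimics: int = 3
    reverser_strength: float = 1.0
    phase_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_PROPORTIONS))
    target_overlap_bias: float = 0.9
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (10, 80)
    n_forced_approved_reversers: int = 3

    def cell_lines(self) -> tuple[str, ...]:
        names = list(self.kidney_cell_lines)
        for c in _CELL_LINE_POOL:
            if len(names) >= self.n_cell_lines:
                break
            if c not in names:
                names.append(c)
        i = 0
        while len(names) < self.n_cell_lines:
            names.append(f"CL{i:02d}")
            i += 1
        return tuple(names[: self.n_cell_lines])

    def validate(self) -> None:
        for name in ("frac_unmappable", "frac_many_to_one", "frac_one_to_many",
                     "reverser_strength", "target_overlap_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        for name in ("n_genes_mouse", "n_genes_human", "n_compounds", "n_cell_lines",
                     "n_gene_sets"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        missing = set(DEFAULT_PROGRAM_SIZES) - set(self.program_sizes)
        if missing:
            raise ParameterError(f"program_sizes missing entries: {sorted(missing)}")
        if any(v <= 0 for v in self.program_sizes.values()):
            raise ParameterError("program sizes must be positive")
        total = sum(self.program_sizes.values())
        if total > self.n_genes_mouse:
            raise SizingError(
                f"program genes ({total}) exceed mouse gene universe ({self.n_genes_mouse})")
        n_mappable = round((1 - self.frac_unmappable) * self.n_genes_mouse)
        if n_mappable > self.n_genes_human:
            raise SizingError(
                f"{n_mappable} mappable mouse genes exceed human universe "
                f"({self.n_genes_human})")
        if len(self.kidney_cell_lines) > self.n_cell_lines:
            raise ParameterError("more kidney cell lines than total cell lines")
        if self.n_planted_reversers + self.n_planted_mimics > self.n_compounds:
            raise ParameterError("planted compounds exceed n_compounds")
        if self.n_forced_approved_reversers > self.n_planted_reversers:
            raise ParameterError("cannot force-approve more reversers than planted")
        if abs(sum(self.phase_proportions.values()) - 1.0) > 1e-9:
            raise ParameterError("phase_proportions must sum to 1")
        lo, hi = self.gene_set_size_range
        if not 0 < lo <= hi <= self.n_genes_human:
            raise ParameterError("gene_set_size_range out of bounds")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticBundle:
    """All generated inputs plus the ground-truth record."""

    config: SimulationConfig
    de_tables: dict[str, pd.DataFrame]
    orthology: pd.DataFrame
    reference: ReferenceSet
    annotations: pd.DataFrame
    fda: pd.DataFrame
    gene_sets: list[GeneSet]
    aki: ConsensusSignature
    truth: dict


# ----------------------------------------------------------------- DE simulation

def simulate_de_table(
    config: SimulationConfig,
    dataset_profile: str,
    rng: np.random.Generator,
    programs: Mapping[str, list[str]] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One differential-expression table for a ``precystic`` or ``cystic`` profile.

    Null genes draw LFC ~ Normal(0, null_lfc_sd) with exactly uniform raw p-values
    (the p implied by z = lfc / null_lfc_sd); planted genes draw
    LFC ~ Normal(±effect_size_mean, effect_size_sd) with per-gene standard errors, and
    adjusted p-values come from Benjamini-Hochberg within the table.
    """
    if dataset_profile not in {"precystic", "cystic"}:
        raise ParameterError(f"unknown dataset profile {dataset_profile!r}")
    if programs is None or gene_ids is None:
        gene_ids = _mouse_genes(config)
        programs = _assign_programs(config, gene_ids, _stream(config.seed, 0))
    n = len(gene_ids)
    lfc = rng.normal(0.0, config.null_lfc_sd, size=n)
    se = np.full(n, config.null_lfc_sd)
    index = {g: i for i, g in enumerate(gene_ids)}
    if dataset_profile == "precystic":
        active = (("precystic_up", 1.0), ("precystic_down", -1.0))
    else:
        active = (("cystic_up", 1.0), ("cystic_down", -1.0),
                  ("aki_up", 1.0), ("aki_down", -1.0))
    for name, sign in active:
        idx = np.array([index[g] for g in programs[name]])
        lfc[idx] = sign * rng.normal(config.effect_size_mean, config.effect_size_sd,
                                     size=len(idx))
        # SE fixed per planted gene: realistic joint (LFC, padj) without a count model
        se[idx] = rng.uniform(0.2, 0.4, size=len(idx))
    pvals = 2.0 * stats.norm.sf(np.abs(lfc) / se)
    padj = adjust(pvals, method="bh")
    return pd.DataFrame({"gene_id": list(gene_ids), "lfc": lfc, "padj": padj})


def _stream(seed: int, k: int) -> np.random.Generator:
    """Independent deterministic generator for sub-component ``k`` of a simulation."""
    return np.random.default_rng(np.random.SeedSequence([seed, k]))


def _mouse_genes(config: SimulationConfig) -> list[str]:
    return [f"mgene{i:05d}" for i in range(config.n_genes_mouse)]


def _human_genes(config: SimulationConfig) -> list[str]:
    return [f"hgene{i:05d}" for i in range(config.n_genes_human)]


def _assign_programs(
    config: SimulationConfig, gene_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Draw pairwise-disjoint program gene sets from the mouse universe."""
    names = list(DEFAULT_PROGRAM_SIZES)  # fixed order for determinism
    total = sum(config.program_sizes[n] for n in names)
    picked = rng.choice(len(gene_ids), size=total, replace=False)
    programs: dict[str, list[str]] = {}
    start = 0
    for name in names:
        size = config.program_sizes[name]
        programs[name] = sorted(gene_ids[i] for i in picked[start:start + size])
        start += size
    return programs


# -------------------------------------------------------------------- orthology

def _simulate_orthology(
    config: SimulationConfig,
    mouse: Sequence[str],
    human: Sequence[str],
    program_genes: set[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_m = len(mouse)
    n_mappable = round((1 - config.frac_unmappable) * n_m)
    mapped_idx = rng.choice(n_m, size=n_mappable, replace=False)
    target_idx = rng.choice(len(human), size=n_mappable, replace=False)
    pairs = [(mouse[m], human[h]) for m, h in zip(mapped_idx, target_idx)]
    mapped_set = {mouse[m] for m in mapped_idx}
    null_unmapped = [g for g in mouse if g not in mapped_set and g not in program_genes]
    null_mapped = [(s, t) for s, t in pairs if s not in program_genes]
    # many-to-one: a second mouse gene pointing at an already-used human target
    k = min(round(config.frac_many_to_one * n_m), len(null_unmapped), len(null_mapped))
    if k:
        extra_sources = rng.choice(len(null_unmapped), size=k, replace=False)
        share_with = rng.choice(len(null_mapped), size=k, replace=False)
        for s_i, t_i in zip(extra_sources, share_with):
            pairs.append((null_unmapped[s_i], null_mapped[t_i][1]))
    # one-to-many: give a few null mouse genes a second human target (ambiguous)
    j = min(round(config.frac_one_to_many * n_m), len(null_mapped))
    if j:
        ambiguous = rng.choice(len(null_mapped), size=j, replace=False)
        second = rng.choice(len(human), size=j, replace=True)
        for a_i, h_i in zip(ambiguous, second):
            src, first_target = null_mapped[a_i]
            alt = human[h_i] if human[h_i] != first_target else human[(h_i + 1) % len(human)]
            pairs.append((src, alt))
    df = pd.DataFrame(sorted(set(pairs)), columns=["source_gene", "target_gene"])
    return df


def _human_image(orthology: pd.DataFrame, genes: Sequence[str]) -> list[str]:
    """Unambiguous human orthologs of ``genes``, preserving input order, deduplicated."""
    counts = orthology.groupby("source_gene")["target_gene"].nunique()
    unique = set(counts[counts == 1].index)
    lookup = dict(zip(orthology["source_gene"], orthology["target_gene"]))
    image, seen = [], set()
    for g in genes:
        if g in unique:
            h = lookup[g]
            if h not in seen:
                seen.add(h)
                image.append(h)
    return image


# -------------------------------------------------------------------- reference

def _anti_profile(
    up_ordered: Sequence[str], down_ordered: Sequence[str],
    human: Sequence[str], rng: np.random.Generator,
) -> np.ndarray:
    """A perfect anti-signature score vector: query-up genes at the bottom of the
    ranking (scores in [-1, -0.5]), query-down genes at the top ([+0.5, +1]), with
    background genes strictly in between."""
    index = {g: i for i, g in enumerate(human)}
    scores = rng.uniform(-0.45, 0.45, size=len(human))
    n_up = len(up_ordered)
    for i, g in enumerate(up_ordered):
        scores[index[g]] = -(1.0 - 0.5 * i / max(n_up, 1))
    n_down = len(down_ordered)
    for i, g in enumerate(down_ordered):
        scores[index[g]] = 1.0 - 0.5 * i / max(n_down, 1)
    return scores


def _simulate_reference(
    config: SimulationConfig,
    human: Sequence[str],
    compounds: Sequence[str],
    reversers: Sequence[str],
    mimics: Sequence[str],
    anti_up: Sequence[str],
    anti_down: Sequence[str],
    rng: np.random.Generator,
) -> ReferenceSet:
    cells = config.cell_lines()
    kidney = set(config.kidney_cell_lines)
    cols = [f"{pert}__{cell}" for pert in compounds for cell in cells]
    matrix = rng.standard_normal((len(human), len(cols)))
    col_index = {c: i for i, c in enumerate(cols)}
    s = config.reverser_strength
    for pert in list(reversers) + list(mimics):
        for cell in cells:
            if cell not in kidney:
                continue  # planted behavior is kidney-specific
            base = _anti_profile(anti_up, anti_down, human, rng)
            if pert in set(mimics):
                base = -base
            noise = rng.standard_normal(len(human))
            matrix[:, col_index[f"{pert}__{cell}"]] = s * base + (1 - s) * noise
    tags = {c: ("kidney" if c in kidney else "other") for c in cells}
    data = pd.DataFrame(matrix, index=pd.Index(list(human), name="gene_id"),
                        columns=cols)
    return ReferenceSet(data=data, cell_line_tags=tags)


# ------------------------------------------------------------------ annotations

def _simulate_annotations(
    config: SimulationConfig,
    compounds: Sequence[str],
    reversers: Sequence[str],
    human: Sequence[str],
    cystic_up_human: Sequence[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    phases = list(config.phase_proportions)
    probs = np.array([config.phase_proportions[p] for p in phases])
    phase_draw = rng.choice(len(phases), size=len(compounds), p=probs)
    reverser_set = set(reversers)
    forced = set(list(reversers)[: config.n_forced_approved_reversers])
    rows = []
    for i, pert in enumerate(compounds):
        phase = phases[phase_draw[i]]
        if pert in reverser_set:
            phase = "Launched"
        n_targets = int(rng.integers(3, 9)) if pert in reverser_set else int(rng.integers(0, 9))
        targets: set[str] = set()
        while len(targets) < n_targets:
            if pert in reverser_set and rng.random() < config.target_overlap_bias:
                targets.add(cystic_up_human[int(rng.integers(0, len(cystic_up_human)))])
            else:
                targets.add(human[int(rng.integers(0, len(human)))])
        if pert in forced:
            # guarantee a deterministic non-empty final cascade stage
            pool = list(cystic_up_human)
            targets.add(pool[0])
            targets.add(pool[1 % len(pool)])
        rows.append({
            "pert_id": pert,
            "name": pert.capitalize(),
            "clinical_phase": phase,
            "moa": _MOA_VOCAB[int(rng.integers(0, len(_MOA_VOCAB)))],
            "targets": frozenset(targets),
            "indication": _INDICATION_VOCAB[int(rng.integers(0, len(_INDICATION_VOCAB)))],
        })
    annotations = pd.DataFrame(rows, columns=["pert_id", "name", "clinical_phase",
                                              "moa", "targets", "indication"])
    statuses = sorted({"prescription", "over-the-counter", "tentative approval"})
    fda_rows = []
    for row in annotations.itertuples(index=False):
        if row.clinical_phase != "Launched":
            continue
        if row.pert_id not in forced and rng.random() >= 0.7:
            continue
        variant = int(rng.integers(0, 3))
        name = [row.name.lower(), row.name.upper(), f"  {row.name} "][variant]
        fda_rows.append({"ingredient": name,
                         "marketing_status": statuses[int(rng.integers(0, 3))]})
    for i in range(20):  # decoy ingredients absent from the annotation table
        fda_rows.append({"ingredient": f"compound-x{i:03d}",
                         "marketing_status": statuses[int(rng.integers(0, 3))]})
    fda = pd.DataFrame(fda_rows, columns=["ingredient", "marketing_status"])
    fda = fda.sort_values(["ingredient", "marketing_status"],
                          kind="mergesort").reset_index(drop=True)
    return annotations, fda


def _simulate_gene_sets(
    config: SimulationConfig,
    human: Sequence[str],
    cystic_up_human: Sequence[str],
    precystic_up_human: Sequence[str],
    rng: np.random.Generator,
) -> list[GeneSet]:
    """Random gene sets plus a few planted ones concentrated in the disease programs
    (cystic-up for drug-set enrichment, pre-cystic-up for signature enrichment)."""
    lo, hi = config.gene_set_size_range
    sets = []
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        bias_pool: Sequence[str] = ()
        if i < 2 and cystic_up_human:
            bias_pool = cystic_up_human
        elif i < 4 and precystic_up_human:
            bias_pool = precystic_up_human
        if bias_pool:
            size = hi  # planted terms sit at the top of the size range so they
            # cover enough of their program to be detectable
            n_prog = min(int(size * 0.7), len(bias_pool))
            prog = rng.choice(len(bias_pool), size=n_prog, replace=False)
            rest = rng.choice(len(human), size=size, replace=False)
            members = {bias_pool[j] for j in prog}
            members |= {human[j] for j in rest[: size - len(members)]}
        else:
            members = {human[j] for j in rng.choice(len(human), size=size, replace=False)}
        sets.append(GeneSet(term_id=f"GS{i:04d}",
                            description=f"synthetic gene set {i}",
                            members=frozenset(members)))
    return sets


# ----------------------------------------------------------------------- bundle

def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate every pipeline input with known ground truth, fully seed-determined."""
    config.validate()
    rng_prog, rng_orth, rng_pre, rng_ca, rng_cb, rng_ref, rng_ann, rng_gs = (
        _stream(config.seed, k) for k in range(8))

    mouse = _mouse_genes(config)
    human = _human_genes(config)
    programs = _assign_programs(config, mouse, rng_prog)
    program_genes = {g for genes in programs.values() for g in genes}
    orthology = _simulate_orthology(config, mouse, human, program_genes, rng_orth)

    de_tables = {
        "precystic": simulate_de_table(config, "precystic", rng_pre, programs, mouse),
        "cystic_a": simulate_de_table(config, "cystic", rng_ca, programs, mouse),
        "cystic_b": simulate_de_table(config, "cystic", rng_cb, programs, mouse),
    }

    # planted pre-cystic signature in the human namespace, ordered by effect size
    pre = de_tables["precystic"].set_index("gene_id")
    up_sorted = sorted(programs["precystic_up"],
                       key=lambda g: (-pre.loc[g, "lfc"], g))
    down_sorted = sorted(programs["precystic_down"],
                         key=lambda g: (pre.loc[g, "lfc"], g))
    anti_up = _human_image(orthology, up_sorted)
    anti_down = _human_image(orthology, down_sorted)
    programs_human = {name: sorted(_human_image(orthology, genes))
                      for name, genes in programs.items()}

    compounds = [f"drug-{i:04d}" for i in range(config.n_compounds)]
    n_planted = config.n_planted_reversers + config.n_planted_mimics
    planted_idx = rng_ref.choice(config.n_compounds, size=n_planted, replace=False)
    reversers = [compounds[i] for i in planted_idx[: config.n_planted_reversers]]
    mimics = [compounds[i] for i in planted_idx[config.n_planted_reversers:]]

    reference = _simulate_reference(config, human, compounds, reversers, mimics,
                                    anti_up, anti_down, rng_ref)
    annotations, fda = _simulate_annotations(
        config, compounds, reversers, human, programs_human["cystic_up"], rng_ann)
    # the drug-set-enrichment universe is the annotated-target pool, so the planted
    # cystic terms are drawn from the drugged portion of the cystic-up program
    annotated_targets: set[str] = set()
    for t in annotations["targets"]:
        annotated_targets |= set(t)
    cystic_drugged = [g for g in programs_human["cystic_up"] if g in annotated_targets]
    gene_sets = _simulate_gene_sets(config, human, cystic_drugged,
                                    programs_human["precystic_up"], rng_gs)
    aki = ConsensusSignature(up=frozenset(programs["aki_up"]),
                             down=frozenset(programs["aki_down"]), label="AKI-24h")

    truth = {
        "programs_mouse": {k: list(v) for k, v in programs.items()},
        "programs_human": programs_human,
        "anti_up_order": anti_up,
        "anti_down_order": anti_down,
        "reversers": reversers,
        "mimics": mimics,
        "forced_approved_reversers": reversers[: config.n_forced_approved_reversers],
    }
    return SyntheticBundle(config=config, de_tables=de_tables, orthology=orthology,
                           reference=reference, annotations=annotations, fda=fda,
                           gene_sets=gene_sets, aki=aki, truth=truth)


# ------------------------------------------------------------------- round trip

BUNDLE_FILES = {
    "precystic": "de_precystic.tsv",
    "cystic_a": "de_cystic_a.tsv",
    "cystic_b": "de_cystic_b.tsv",
}


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Serialize a bundle to a directory of plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds, fname in BUNDLE_FILES.items():
        sio.write_de_table(bundle.de_tables[ds], out / fname)
    sio.write_orthology(bundle.orthology, out / "orthology.tsv")
    sio.write_reference(bundle.reference, out / "reference.gct",
                        out / "cell_line_tags.tsv")
    sio.write_annotations(bundle.annotations, out / "annotations.tsv")
    sio.write_fda(bundle.fda, out / "fda.tsv")
    sio.write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    sio.write_consensus(bundle.aki, out / "aki_consensus.tsv")
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    cfg = dataclasses.asdict(bundle.config)
    cfg["program_sizes"] = dict(cfg["program_sizes"])
    cfg["phase_proportions"] = dict(cfg["phase_proportions"])
    (out / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))


def read_bundle(in_dir: str | Path) -> SyntheticBundle:
    """Reload a bundle written by :func:`write_bundle`."""
    p = Path(in_dir)
    cfg = json.loads((p / "config.json").read_text())
    for key in ("kidney_cell_lines", "gene_set_size_range"):
        cfg[key] = tuple(cfg[key])
    config = SimulationConfig(**cfg)
    de_tables = {ds: sio.read_de_table(p / fname) for ds, fname in BUNDLE_FILES.items()}
    return SyntheticBundle(
        config=config,
        de_tables=de_tables,
        orthology=sio.read_orthology(p / "orthology.tsv"),
        reference=sio.read_reference(p / "reference.gct", p / "cell_line_tags.tsv"),
        annotations=sio.read_annotations(p / "annotations.tsv"),
        fda=sio.read_fda(p / "fda.tsv"),
        gene_sets=sio.read_gmt(p / "gene_sets.gmt"),
        aki=sio.read_consensus(p / "aki_consensus.tsv", label="AKI-24h"),
        truth=json.loads((p / "truth.json").read_text()),
    )
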