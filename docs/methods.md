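# Methods

## Problem setting

Autosomal dominant polycystic kidney disease progresses from a pre-cystic stage, where
transcriptomic changes reflect driving mechanisms (cell cycle, proliferation), to a
cystic stage dominated by secondary inflammation and injury response. Signature
reversion asks which compounds in a drug-perturbation compendium produce an expression
response *opposite* to the disease signature. This package implements that search and
the prioritization that follows, building the reversion query from pre-cystic data
(least confounded) and validating candidate drug targets against upregulation in two
independent cystic-stage datasets.

## Disease-signature construction

A differential-expression (DE) table (gene, log2 fold change, BH-adjusted p) is
filtered with *strict* inequalities |LFC| > c and padj < 0.05; boundary rows are
excluded and missing padj counts as not significant. The cutoff c is chosen
adaptively from a descending grid (2.0, 1.9, …, 1.0): the largest cutoff whose pass
count falls in [100, 200] wins, because signatures of 100–200 genes have been found
optimal for reversion queries; if no cutoff lands in range, the one whose count is
nearest the window wins, ties toward the stricter cutoff. Mouse genes are mapped to
the human reference universe through an orthology table: one-to-many mouse genes are
dropped (their target is not identifiable from a DE table), many-to-one collisions are
resolved by larger |LFC|, then smaller padj, then lexicographic id — determinism is
prioritized over any unstated convention. The signature is the top 100 genes per
direction by LFC (ties again by padj, then id), taking all available when a side has
fewer.

## Connectivity scoring

For query set Q against a reference score vector, genes are ranked by descending score
with lexicographic gene-id tie-breaks. The running sum gains |s|^p/Σ_hits|s|^p at hits
and loses 1/(N−t) at misses; the enrichment score (ES) is the extremum of larger
magnitude, returning the positive extremum on an exact tie (the tie rule also means
the ES of a negated score vector is the exact negation of the original *except* at
such measure-zero ties). The weight exponent p defaults to 1 (the GSEA convention)
and is exposed in the API. ES of an empty query side is defined as 0, so single-sided
signatures degrade gracefully.

WTCS = (ES_up − ES_down)/2 when the two directional scores disagree in sign (zero
counts as opposite to either); same-strict-sign pairs score 0 (null). NCS divides
positive WTCS by the group mean of positive WTCS and negative WTCS by the mean
magnitude of negative WTCS, grouping by cell line; each present side therefore has
mean |NCS| = 1 within its group, signs are preserved, and a group missing one sign
normalizes one-sidedly with a logged warning. NCS is computed over *all* reference
signatures before any cell-line restriction, matching how a compendium-wide
normalization behaves. Candidate tables keep strictly negative NCS in the allowed
(kidney-tagged) cell lines, sorted ascending with pert-id tie-breaks.

Numerical notes: the running-sum extremum is clamped to [−1, 1] (cumulative float
rounding can overshoot by ~1e−13 on long vectors); score ties in the reference
ranking break lexicographically for reproducibility.

## Prioritization cascade

Connectivity rows collapse to one record per compound (most-negative NCS, contributing
cell lines). Stages then apply, each a strict subset of the last:

1. **Launched** — keep compounds annotated at clinical phase "Launched";
   unannotated compounds are dropped with a logged count.
2. **FDA registry** — keep compounds whose ingredient name, normalized by
   case-folding/trimming/whitespace-collapse, appears in the registry with status
   prescription, over-the-counter, or tentative approval, regardless of dosage form.
   Salt/ester-suffix handling is deliberately out of the default path (no matching
   rule is defined by the sources); exact normalized match keeps behavior auditable.
3. **Cystic-target support** — intersect each drug's annotated targets with the
   upregulated DE genes of each dataset (cutoffs 1.1 pre-cystic / 2.0 cystic, mapped
   to the human universe) and keep drugs with a non-empty overlap in *each* of the two
   cystic datasets. The overlapping gene need not be the same in both: a drug whose
   target A is up in one cystic dataset and target B in the other still qualifies,
   which matches how drug-target evidence is pooled across stages. The edge list is
   drug × (union of its cystic overlaps) and the unique-target count is the size of
   the union of edge genes.

Mechanism-of-action and indication annotations are carried and summarized but never
used as filters.

## Enrichment

One hypergeometric engine backs both front-ends: p = P[X ≥ k] for X ~
Hypergeometric(N, K, n) via the stable survival function. Term members are restricted
to the background universe before the size filter, which is *strict* (size > lo and
size < hi). Functional enrichment uses bounds (5, 1000), Bonferroni, α = 0.05, with
the measured-gene universe as background. Drug-set enrichment pools the unique
targets of the prioritized drugs as the query, uses the union of all annotated targets
as the background (configurable; the original tooling's choice is not recoverable),
bounds (10, 500) and Benjamini–Hochberg, and reports drug→target edges inside each
significant term. The result table carries `precision` and `recall_query` (both
overlap/|query| — the source material defines recall this way, conflating the usual
precision/recall pair) alongside `recall_term` = overlap/term-size, so either ranking
convention is available. Multiple-testing adjustment delegates to
statsmodels' `multipletests`.

## AKI concordance

The consensus injury panel (157 up, 88 down genes at 24 h post-injury) is subset from
each DE table at relaxed strict thresholds |LFC| > 0.15, padj < 0.1. The concordance
fraction (share of assessed genes whose LFC sign matches the consensus direction) and
the direction-signed mean LFC are this package's own quantification of what the
source figures show qualitatively; an empty subset reports NaN rather than a
fabricated value, and genes missing from a table are excluded rather than zero-filled.
The LFC matrix includes genes passing thresholds in at least one dataset, with
failing cells missing-coded.

## Synthetic study generator

The generator emulates the statistical structure of the three-dataset design rather
than any real dataset gene-for-gene:

- **Universes.** 2,200 mouse genes, 2,000 human reference genes by default — a
  scaled-down transcriptome keeping every pipeline stage non-trivial at interactive
  runtimes (a full bundle simulates in ~0.3 s).
- **Programs.** Pairwise-disjoint gene programs: pre-cystic up/down (80 + 80, sized so
  the derived signature lands inside the 100–200 window after orthology mapping, like
  the real pre-cystic signature of 130 genes), cystic up/down (150 + 150, shared by
  both cystic tables — mirroring the ~92% overlap reported between the two cystic
  datasets), and injury up/down (157 + 88, the consensus panel sizes). Injury genes
  are perturbed only in cystic tables; in the pre-cystic table they are null.
- **DE tables.** Null genes draw LFC ~ N(0, 0.3) with exactly uniform raw p-values
  (p implied by z = LFC/0.3); planted genes draw LFC ~ N(±4, 0.5) with per-gene
  standard errors U(0.2, 0.4), giving a realistic joint (LFC, padj) distribution
  without re-implementing a count model; BH runs within each table. The 4-log2 mean
  effect makes >95% of planted genes pass the cystic thresholds, so planted programs
  dominate significant sets.
- **Orthology.** 90% of mouse genes map 1:1 to distinct human genes; ~2% extra
  many-to-one pairs and ~1% one-to-many (ambiguous) sources are added among null
  genes only, exercising the mapper's resolution and drop rules without disturbing
  planted programs.
- **Reference.** 500 compounds × 2 cell lines (HA1E tagged kidney, A375 other);
  null signatures are standard normal per gene. A planted reverser's kidney-line
  vector places the query-up genes in [−1, −0.5] (ordered by rank percentile), the
  query-down genes in [+0.5, +1], and background genes in (−0.45, 0.45), mixed with
  standard-normal noise at weight (1 − strength): strength 1 gives a perfect
  anti-signature (WTCS exactly −1), and strength continuously controls difficulty.
  Mimics are the negated profile. Planted behavior is kidney-line-specific, so
  cell-line restriction is exercised.
- **Annotations / registry.** Clinical phases are sampled from configured proportions
  (35% launched); planted reversers are forced Launched, and a configurable number of
  them are guaranteed registry entries with at least two cystic-program targets, so
  the full cascade always ends non-empty and deterministic. Registry entries mangle
  case/whitespace to exercise ingredient normalization, and decoy ingredients are
  present. Reverser targets are drawn from the cystic-up program with probability 0.9
  (`target_overlap_bias`); other compounds draw targets uniformly.
- **Gene sets.** Random sets of 10–80 genes; four planted sets sit at the top of the
  size range and draw 70% of members from the cystic-up drugged targets (detectable by
  drug-set enrichment) or the pre-cystic-up program (detectable by signature
  enrichment).
- **Determinism.** Every sub-component uses its own generator derived from
  SeedSequence([seed, k]); identical configurations give byte-identical serialized
  bundles.

What the generator does **not** emulate: read-level noise and count overdispersion,
correlated co-expression structure, batch effects, realistic orthology complexity
(paralog families), compound dose/time series, or any real dataset's gene
identities. Passing tests therefore demonstrate that the *rules* of the pipeline are
implemented correctly and that planted signal of stated strength is recovered — not
that the pipeline's biological conclusions transfer to any particular real dataset.

## Test-design choices

- The enrichment-score implementation is checked against a literal pure-Python
  running-sum oracle: exhaustively for every query subset of universes up to size 8,
  and at 1e−12 tolerance for 1,000 random (universe 500, query 50) instances (the
  vectorized path uses pairwise summation above numpy's block size, so exact equality
  is only guaranteed for small universes).
- Cascade stage counts are recomputed by an independent recount implementation
  (csv + sorted + the brute-force ES) over the serialized bundle files.
- The concordance discrimination check uses a dedicated dense configuration
  (1,250 mouse genes with 330 + 330 planted pre-cystic genes): with a realistically
  sparse universe, almost no null injury-panel gene reaches padj < 0.1 in the
  pre-cystic table, leaving the chance-level concordance fraction estimated from ~0–3
  genes, where it ties 1.0 with non-trivial probability. The dense design raises the
  BH threshold so that ~14 null panel genes are assessed on average
  (P[all concordant by chance] ≈ e⁻⁷ per seed), making the cystic > pre-cystic
  comparison decisive. This sizing comes from the power analysis above, fixed before
  the check was first run.
- Multi-seed checks use seeds 0–9 (recovery, concordance) and 0–4 (recount), fixed a
  priori; hypothesis-based property tests run derandomized.

## Known limitations

- Reference-ranking tie-breaks, the ES sign-tie rule, and the weight exponent are
  documented package conventions; other implementations of the same statistic may
  differ bit-for-bit on tied or borderline inputs.
- The drug-set-enrichment background is the annotated-target union by default; with
  genome-wide backgrounds p-values would be smaller.
- Ingredient matching is exact after normalization; salts, esters, and brand
  synonyms require an explicit mapping table upstream.
- The pipeline consumes finished DE tables; expression modeling, LFC shrinkage, and
  ortholog inference are upstream concerns.
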