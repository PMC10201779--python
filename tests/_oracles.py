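"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the definitions with plain Python
(csv/itertools/sorted), sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import csv
from itertools import combinations
from math import comb
from pathlib import Path


def brute_es(universe, scores, query, weight_exponent=1.0):
    """Literal running-sum enrichment score: sort, walk, track the extremum."""
    pairs = sorted(zip(universe, scores), key=lambda t: (-t[1], t[0]))
    n = len(pairs)
    t = len(query)
    denom = sum(abs(s) ** weight_exponent for g, s in pairs if g in query)
    running = 0.0
    values = []
    for g, s in pairs:
        if g in query:
            running += (abs(s) ** weight_exponent / denom) if denom > 0 else 1.0 / t
        else:
            running -= 1.0 / (n - t)
        values.append(running)
    mx, mn = max(values), min(values)
    es = mx if abs(mx) >= abs(mn) else mn
    return min(1.0, max(-1.0, es))


def brute_wtcs_sign(universe, scores, up, down):
    """Sign of the bi-directional connectivity score via the brute ES."""
    eu = brute_es(universe, scores, up)
    ed = brute_es(universe, scores, down)
    if (eu > 0 and ed > 0) or (eu < 0 and ed < 0):
        return 0.0
    return (eu - ed) / 2.0


def enum_hypergeom_upper(k, K, n, N):
    """P[overlap >= k] by enumerating every draw of n items from N (first K marked)."""
    hits = sum(1 for draw in combinations(range(N), n)
               if sum(1 for x in draw if x < K) >= k)
    return hits / comb(N, n)


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up with monotonicity, by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


# ------------------------------------------------------------- cascade recount

def _read_tsv_rows(path):
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _normalize(name):
    return " ".join(str(name).split()).casefold()


def recount_cascade(bundle_dir, padj=0.05, n_per_side=100,
                    up_cut_precystic=1.1, up_cut_cystic=2.0,
                    cystic_ids=("cystic_a", "cystic_b")):
    """Recompute every cascade stage count from the bundle files alone.

    Uses csv + sorted + brute ES only; mirrors the documented rules (adaptive cutoff,
    unambiguous orthology with |lfc| duplicate resolution, top-N signature, negative
    connectivity in kidney lines, launched -> FDA -> both-cystic target overlap).
    """
    bundle_dir = Path(bundle_dir)

    # reference GCT, parsed by hand
    lines = (bundle_dir / "reference.gct").read_text().splitlines()
    assert lines[0] == "#1.2"
    cols = lines[2].split("\t")[2:]
    genes, matrix = [], []
    for line in lines[3:]:
        parts = line.split("\t")
        genes.append(parts[0])
        matrix.append([float(v) for v in parts[2:]])
    universe = set(genes)
    tags = {r["cell_line"]: r["tag"]
            for r in _read_tsv_rows(bundle_dir / "cell_line_tags.tsv")}
    kidney = {c for c, t in tags.items() if t == "kidney"}

    # orthology: unique-target sources only
    n_targets, first_target = {}, {}
    for r in _read_tsv_rows(bundle_dir / "orthology.tsv"):
        s, t = r["source_gene"], r["target_gene"]
        n_targets.setdefault(s, set()).add(t)
        first_target[s] = t
    unique_map = {s: next(iter(ts)) for s, ts in n_targets.items()
                  if len(ts) == 1 and next(iter(ts)) in universe}

    def read_de(name):
        rows = []
        for r in _read_tsv_rows(bundle_dir / f"de_{name}.tsv"):
            padj_v = None if r["padj"] in ("NA", "") else float(r["padj"])
            rows.append((r["gene_id"], float(r["lfc"]), padj_v))
        return rows

    # adaptive cutoff + mapped top-N signature for the pre-cystic table
    pre = read_de("precystic")

    def n_pass(cut):
        return sum(1 for _, l, p in pre if p is not None and p < padj and abs(l) > cut)

    grid = [round(2.0 - 0.1 * i, 2) for i in range(11)]
    cutoff = None
    for c in grid:
        if 100 <= n_pass(c) <= 200:
            cutoff = c
            break
    if cutoff is None:
        def dist(c):
            n = n_pass(c)
            return (100 - n) if n < 100 else max(0, n - 200)
        cutoff = min(grid, key=lambda c: (dist(c), -c))

    passed = [(g, l, p) for g, l, p in pre
              if p is not None and p < padj and abs(l) > cutoff]
    candidates_by_target = {}
    for g, l, p in passed:
        if g in unique_map:
            candidates_by_target.setdefault(unique_map[g], []).append((g, l, p))
    mapped = []
    for h, cands in candidates_by_target.items():
        # larger |lfc| wins; ties break by smaller padj, then lexicographic source id
        g, l, p = min(cands, key=lambda r: (-abs(r[1]), r[2], r[0]))
        mapped.append((h, l, p))
    ups = sorted([r for r in mapped if r[1] > 0], key=lambda r: (-r[1], r[2], r[0]))
    downs = sorted([r for r in mapped if r[1] < 0], key=lambda r: (r[1], r[2], r[0]))
    up_query = {r[0] for r in ups[:n_per_side]}
    down_query = {r[0] for r in downs[:n_per_side]}

    # stage 1: compounds with a negative connectivity score in a kidney line
    stage1 = set()
    n_rows = 0
    for j, col in enumerate(cols):
        pert, _, cell = col.partition("__")
        if cell not in kidney:
            continue
        scores = [matrix[i][j] for i in range(len(genes))]
        w = brute_wtcs_sign(genes, scores, up_query, down_query)
        if w < 0:
            stage1.add(pert)
            n_rows += 1

    ann = {r["pert_id"]: r for r in _read_tsv_rows(bundle_dir / "annotations.tsv")}
    launched = {p for p in stage1
                if p in ann and ann[p]["clinical_phase"] == "Launched"}

    ok_status = {"prescription", "over-the-counter", "tentative approval"}
    registry = {_normalize(r["ingredient"])
                for r in _read_tsv_rows(bundle_dir / "fda.tsv")
                if r["marketing_status"] in ok_status}
    fda = {p for p in launched if _normalize(ann[p]["name"]) in registry}

    up_sets = {}
    for ds in ("precystic",) + tuple(cystic_ids):
        cut = up_cut_precystic if ds == "precystic" else up_cut_cystic
        up_sets[ds] = {unique_map[g] for g, l, p in read_de(ds)
                       if p is not None and p < padj and l > cut and g in unique_map}

    final = set()
    for p in fda:
        targets = set(ann[p]["targets"].split("|")) if ann[p]["targets"] else set()
        if all(targets & up_sets[ds] for ds in cystic_ids):
            final.add(p)

    return {
        "connectivity_rows": n_rows,
        "negative_ncs_drugs": len(stage1),
        "launched": len(launched),
        "fda_approved": len(fda),
        "targets_both_cystic": len(final),
    }
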