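"""Independent naive reference implementations used only by the tests.

Everything here is written the slow, obvious way — character loops,
dictionary counting, exhaustive enumeration — deliberately sharing no code
with the package so the two routes check each other.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in s.upper()[::-1])


def base_counts(seq: str) -> Counter:
    return Counter(seq.upper())


def gc_pct(seq: str) -> float:
    c = base_counts(seq)
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    return 100.0 * (c["G"] + c["C"]) / denom if denom else 0.0


def gc_skew(seq: str) -> float:
    c = base_counts(seq)
    return (c["G"] - c["C"]) / (c["G"] + c["C"]) if c["G"] + c["C"] else 0.0


def at_skew(seq: str) -> float:
    c = base_counts(seq)
    return (c["A"] - c["T"]) / (c["A"] + c["T"]) if c["A"] + c["T"] else 0.0


def n_pct(seq: str) -> float:
    return 100.0 * seq.upper().count("N") / len(seq) if seq else 0.0


def eff_len(seq: str) -> int:
    return sum(1 for c in seq.upper() if c in "ACGT")


def count_substring(seq: str, sub: str) -> int:
    """Overlapping occurrences by explicit position-by-position scan."""
    s, m = seq.upper(), sub.upper()
    return sum(1 for i in range(len(s) - len(m) + 1) if s[i : i + len(m)] == m)


def cpg_pct(seq: str) -> float:
    e = eff_len(seq)
    return 100.0 * count_substring(seq, "CG") / (e - 1) if e >= 2 else 0.0


def stop_freq(seq: str) -> float:
    e = eff_len(seq)
    if e < 3 or len(seq) < 3:
        return 0.0
    hits = sum(count_substring(seq, s) for s in ("TAA", "TAG", "TGA"))
    return hits / (e - 2)


def motif_freq(seq: str, motif: str, rc: bool) -> float:
    e = eff_len(seq)
    if e == 0:
        return 0.0
    hits = count_substring(seq, motif)
    if rc and revcomp(motif) != motif.upper():
        hits += count_substring(seq, revcomp(motif))
    return 100.0 * hits / e


def kmer_profile_dict(seqs, k: int) -> dict:
    counts: Counter = Counter()
    for seq in seqs:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" not in km:
                counts[km] += 1
    total = sum(counts.values())
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    if total == 0:
        return {km: 1.0 / 4**k for km in kmers}
    return {km: counts[km] / total for km in kmers}


def kmer_deviation(seq: str, k: int, genome_profile: dict) -> float:
    win = kmer_profile_dict([seq], k)
    s = seq.upper()
    n_valid = sum(
        1 for i in range(len(s) - k + 1) if "N" not in s[i : i + k]
    )
    if n_valid == 0:
        return 0.0
    return math.sqrt(
        sum((win[km] - genome_profile[km]) ** 2 for km in genome_profile)
    )


def tandem_fraction(seq: str, max_unit: int = 12) -> float:
    """Brute force over every unit length and start position.

    A region [i, j) is a perfect tandem run of unit u if j-i >= 2u and
    seq[p] == seq[p-u] for all p in [i+u, j); maximal such regions for all
    u in 1..max_unit are merged by per-base marking.
    """
    s = seq.upper()
    n = len(s)
    covered = [False] * n
    for u in range(1, max_unit + 1):
        i = 0
        while i + 2 * u <= n:
            if s[i] != "N" and all(
                s[p] == s[p - u] and s[p] != "N" for p in range(i + u, i + 2 * u)
            ):
                j = i + 2 * u
                while j < n and s[j] == s[j - u] and s[j] != "N":
                    j += 1
                for p in range(i, j):
                    covered[p] = True
                i = j - 2 * u + 1
            else:
                i += 1
    return sum(covered) / n if n else 0.0


def gene_window_means(genes, grid_df):
    """Quadratic-scan per-window gene stats.

    ``genes``: list of dicts with scaffold/start/end/type/exons.
    ``grid_df``: DataFrame with scaffold/start/end rows in window order.
    Returns dict of lists keyed like the package's gene tracks.
    """
    n = len(grid_df)
    out = {
        "mRNA_annotations": [0.0] * n,
        "tRNA_annotations": [0.0] * n,
        "rRNA_annotations": [0.0] * n,
        "pseudogene_annotations": [0.0] * n,
        "gene_length": [0.0] * n,
        "exon_count": [0.0] * n,
        "gene_average_exon_length": [0.0] * n,
        "gene_average_intron_length": [0.0] * n,
    }
    per_window_genes = [[] for _ in range(n)]
    for g in genes:
        for wi, row in enumerate(grid_df.itertuples(index=False)):
            if row.scaffold == g["scaffold"] and g["start"] < row.end and g["end"] > row.start:
                per_window_genes[wi].append(g)
    for wi, gl in enumerate(per_window_genes):
        if not gl:
            continue
        for g in gl:
            out[f"{g['type']}_annotations"][wi] += 1
        out["gene_length"][wi] = float(np.mean([g["end"] - g["start"] for g in gl]))
        out["exon_count"][wi] = float(np.mean([len(g["exons"]) for g in gl]))
        out["gene_average_exon_length"][wi] = float(
            np.mean([np.mean([e - s for s, e in g["exons"]]) for g in gl])
        )
        def intron_mean(g):
            ex = sorted(g["exons"])
            gaps = [b[0] - a[1] for a, b in zip(ex, ex[1:])]
            return float(np.mean(gaps)) if gaps else 0.0
        out["gene_average_intron_length"][wi] = float(
            np.mean([intron_mean(g) for g in gl])
        )
    return out


def rebin_per_base(intervals, grid_df, mode="mean"):
    """Per-base array expansion oracle for bedgraph re-binning."""
    values = []
    scaff_arrays = {}
    lengths = {}
    for row in grid_df.itertuples(index=False):
        lengths[row.scaffold] = max(lengths.get(row.scaffold, 0), row.end)
    for scaf, L in lengths.items():
        scaff_arrays[scaf] = np.zeros(L)
    frac = {scaf: np.zeros(L) for scaf, L in lengths.items()}
    for scaf, s, e, v in intervals:
        if scaf not in scaff_arrays:
            continue
        s2, e2 = max(0, s), min(lengths[scaf], e)
        scaff_arrays[scaf][s2:e2] += v if mode == "mean" else v / (e - s)
    for row in grid_df.itertuples(index=False):
        arr = scaff_arrays[row.scaffold][row.start : row.end]
        values.append(arr.mean() if mode == "mean" else arr.sum())
    return np.array(values)


# ---------------------------------------------------------------------------
# statistics oracles


def ks_one_sided_stats(x, y):
    """(d_plus, d_minus) by explicit ECDF comparison over pooled values.

    d_plus is large when x values sit above y (ECDF of x below ECDF of y).
    """
    x, y = np.sort(x), np.sort(y)
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / len(x)
    fy = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(fy - fx)), float(np.max(fx - fy))


def ks_exact_p_enumeration(x, y, direction: str):
    """Exact one-sided p by enumerating all splits of the pooled sample."""
    x, y = list(x), list(y)
    n = len(x)
    pooled = x + y
    if direction == "plus":
        observed = ks_one_sided_stats(x, y)[0]
    else:
        observed = ks_one_sided_stats(x, y)[1]
    hits = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n):
        cx = [pooled[i] for i in comb]
        cy = [pooled[i] for i in idx if i not in set(comb)]
        dp, dm = ks_one_sided_stats(cx, cy)
        stat = dp if direction == "plus" else dm
        if stat >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def fisher_exact_p(table):
    """Two-sided Fisher p by hypergeometric enumeration over the margins."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(a_):
        return (
            math.comb(row1, a_)
            * math.comb(row2, col1 - a_)
            / math.comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for a_ in range(max(0, col1 - row2), min(col1, row1) + 1):
        p = prob(a_)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def silhouette(points, labels):
    """Textbook silhouette: mean over samples of (b-a)/max(a,b)."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    scores = []
    for i in range(len(points)):
        same = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = min(
            np.mean(
                [np.linalg.norm(points[i] - points[j])
                 for j in range(len(points)) if labels[j] == k]
            )
            for k in set(labels) if k != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def adjusted_rand(labels_a, labels_b):
    """Closed-form ARI from the contingency table."""
    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    table = np.zeros((len(a_vals), len(b_vals)), dtype=int)
    for la, lb in zip(labels_a, labels_b):
        table[a_vals.index(la), b_vals.index(lb)] += 1
    n = table.sum()
    sum_comb = sum(math.comb(int(v), 2) for v in table.ravel())
    sum_a = sum(math.comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(math.comb(int(v), 2) for v in table.sum(axis=0))
    expected = sum_a * sum_b / math.comb(int(n), 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)
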