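"""Statistical characterisation of window clusters.

Each cluster is compared feature-by-feature against the rest of the
genomic windows with two one-sided two-sample Kolmogorov–Smirnov tests,
giving a D+ ("values higher than the rest") and a D− ("lower") statistic
per (cluster, feature). A feature is called *higher* (icon "∧") when only
the D+ p-value clears the significance level, *lower* ("∨") when only D−
does, and *dispersed* ("−") when both do — the cluster's values then
straddle the rest. The default level α = 1e-20 reflects the very large
sample sizes genomic windows provide.

Junctions between adjacent windows on the same scaffold are tested for
enrichment of each unordered cluster-label pair with Fisher's exact test
against the expectation under random label placement, with
Benjamini–Hochberg correction across pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import FeatureMatrix
from .windows import WindowGrid

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-20

ICONS = {"higher": "∧", "lower": "∨", "dispersed": "−", "none": ""}


def ks_one_sided(cluster_values, rest_values, method: str = "asymp"):
    """One-sided two-sample KS statistics in both directions.

    Returns (d_plus, p_plus, d_minus, p_minus) where d_plus measures the
    cluster's values lying *above* the rest and d_minus below. ``method``
    is passed to scipy (``"exact"`` enumerates for small samples).
    """
    up = sps.ks_2samp(cluster_values, rest_values, alternative="less", method=method)
    dn = sps.ks_2samp(cluster_values, rest_values, alternative="greater", method=method)
    return float(up.statistic), float(up.pvalue), float(dn.statistic), float(dn.pvalue)


def _call(p_plus: float, p_minus: float, alpha: float) -> str:
    hi = p_plus <= alpha
    lo = p_minus <= alpha
    if hi and lo:
        return "dispersed"
    if hi:
        return "higher"
    if lo:
        return "lower"
    return "none"


def characterise(
    matrix: FeatureMatrix, labels: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Per (cluster, feature) KS characterisation against the rest.

    Unclassified windows (label −1) never form a cluster row but are part
    of every cluster's "rest" sample. Clusters with fewer than 2 windows
    get call="none" rows and a warning. Uses asymptotic p-values.
    """
    labels = np.asarray(labels)
    if len(labels) != len(matrix.grid):
        raise ValueError("labels length does not match the window grid")
    clusters = sorted(int(c) for c in np.unique(labels) if c >= 0)
    if len(clusters) < 2:
        log.warning("characterise called with %d cluster(s)", len(clusters))
    raw = matrix.raw
    scaled = matrix.scaled
    rows = []
    for k in clusters:
        in_k = labels == k
        degenerate = in_k.sum() < 2
        if degenerate:
            log.warning("cluster %d has <2 windows; no KS calls made", k)
        for feat in matrix.feature_names:
            x = raw[feat].to_numpy()[in_k]
            y = raw[feat].to_numpy()[~in_k]
            if degenerate or len(y) < 1:
                rows.append((k, feat, np.nan, np.nan, np.nan, np.nan, "none",
                             float(scaled[feat].to_numpy()[in_k].mean())))
                continue
            dp, pp, dm, pm = ks_one_sided(x, y, method="asymp")
            rows.append(
                (k, feat, dp, pp, dm, pm, _call(pp, pm, alpha),
                 float(scaled[feat].to_numpy()[in_k].mean()))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "feature", "d_plus", "p_plus", "d_minus", "p_minus",
            "call", "mean_scaled",
        ],
    )


def heatmap_table(ks_results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(mean scaled values, significance icons) as cluster × feature tables."""
    means = ks_results.pivot(index="cluster", columns="feature", values="mean_scaled")
    icons = ks_results.pivot(index="cluster", columns="feature", values="call")
    icons = icons.map(lambda c: ICONS.get(c, ""))
    order = [f for f in ks_results["feature"].unique()]
    return means[order], icons[order]


# ---------------------------------------------------------------------------
# junctions


def junction_enrichment(labels: np.ndarray, grid: WindowGrid) -> pd.DataFrame:
    """Fisher enrichment of adjacent-window label pairs within scaffolds.

    Junctions are unordered pairs of consecutive windows' labels (self
    pairs included, scaffold boundaries excluded; unclassified windows
    participate as label −1). Each pair's observed junction count is
    compared with its expectation under the marginal label frequencies via
    Fisher's exact test, BH-corrected across pairs.
    """
    labels = np.asarray(labels)
    same_scaffold = grid.scaffold[1:] == grid.scaffold[:-1]
    a = labels[:-1][same_scaffold]
    b = labels[1:][same_scaffold]
    total = len(a)
    if total == 0:
        return pd.DataFrame(
            columns=["cluster_a", "cluster_b", "observed", "expected",
                     "odds_ratio", "p", "q"]
        )
    pairs = np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    observed = {(int(i), int(j)): int(c) for (i, j), c in zip(uniq, counts)}
    present = np.unique(labels)
    freq = {int(k): float((labels == k).mean()) for k in present}
    rows = []
    for i, j in itertools.combinations_with_replacement(sorted(freq), 2):
        p_ij = freq[i] ** 2 if i == j else 2 * freq[i] * freq[j]
        o = observed.get((i, j), 0)
        e = total * p_ij
        e_int = int(round(e))
        table = [[o, total - o], [e_int, total - e_int]]
        odds, p = sps.fisher_exact(table)
        rows.append((i, j, o, e, odds, p))
    df = pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "observed", "expected",
                       "odds_ratio", "p"]
    )
    df["q"] = sps.false_discovery_control(df["p"], method="bh")
    return df


# ---------------------------------------------------------------------------
# overlaps and subtelomeres


def overlap_clusters(
    intervals: pd.DataFrame, labels: np.ndarray, grid: WindowGrid
) -> pd.DataFrame:
    """Count annotated intervals overlapping each cluster.

    ``intervals`` needs columns scaffold/start/end (0-based half-open; an
    optional ``id`` column is carried through). An interval overlaps
    cluster k iff it overlaps at least one window labelled k, so one
    interval may count for several clusters.
    """
    labels = np.asarray(labels)
    rows = []
    ids = intervals["id"] if "id" in intervals.columns else intervals.index.astype(str)
    for (scaf, start, end), iid in zip(
        intervals[["scaffold", "start", "end"]].itertuples(index=False), ids
    ):
        idx = grid.overlapping_windows(str(scaf), int(start), int(end))
        for k in np.unique(labels[idx]):
            rows.append((str(iid), int(k)))
    hits = pd.DataFrame(rows, columns=["id", "cluster"])
    out = (
        hits.groupby("cluster")
        .agg(n_features=("id", "nunique"))
        .reset_index()
        .sort_values("cluster")
        .reset_index(drop=True)
    )
    return out


def split_subtelomeric(grid: WindowGrid, distance: int = 200_000) -> np.ndarray:
    """Boolean mask: True for windows within ``distance`` of a scaffold end.

    A window is subtelomeric iff it starts within ``distance`` of the
    scaffold's 5' end or ends within ``distance`` of its 3' end; scaffolds
    shorter than twice the distance are entirely subtelomeric.
    """
    names = grid.scaffold_names()
    lengths = np.array([grid.scaffold_lengths[str(s)] for s in names])
    return (grid.start < distance) | (grid.end > lengths - distance)


# ---------------------------------------------------------------------------
# BED output


def write_cluster_bed(
    labels: np.ndarray, grid: WindowGrid, path, merge_runs: bool = False,
    header_comments=(),
) -> None:
    """Per-window cluster labels as BED (name column ``cluster_<k>``;
    unclassified windows are ``unclassified``). With ``merge_runs``,
    consecutive same-label windows on a scaffold collapse to one record."""
    labels = np.asarray(labels)
    rows = []
    names = grid.scaffold_names()
    for i in range(len(grid)):
        name = "unclassified" if labels[i] < 0 else f"cluster_{labels[i]}"
        rows.append([str(names[i]), int(grid.start[i]), int(grid.end[i]), name])
    if merge_runs:
        merged = [rows[0]]
        for r in rows[1:]:
            last = merged[-1]
            if r[0] == last[0] and r[3] == last[3] and r[1] == last[2]:
                last[2] = r[2]
            else:
                merged.append(r)
        rows = merged
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
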