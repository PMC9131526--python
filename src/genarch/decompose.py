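"""Genome decomposition model: UMAP embedding + HDBSCAN clustering of
windowed features, parameter sweeps, and a Results object that carries the
labels, quality metrics, statistical characterisation and plots.

The model is built from a :class:`~genarch.matrix.FeatureMatrix` (or
directly from a FASTA); ``fit`` embeds the min-max-scaled windows in two
dimensions with UMAP (n_neighbours controls how local the manifold
approximation is) and clusters the embedding with HDBSCAN
(min_cluster_size sets the smallest allowed cluster; windows in no dense
region are labelled −1, "unclassified"). ``sweep`` explores a parameter
grid and scores every combination with the silhouette, Davies–Bouldin and
Calinski–Harabasz indices plus the unclassified percentage, the criteria
used to pick a final parameter pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from . import stats as _stats
from .matrix import FeatureMatrix, merge_tracks
from .windows import load_fasta, partition_windows

log = logging.getLogger(__name__)

DEFAULT_N_VALUES = (5, 10, 15, 20)
DEFAULT_C_VALUES = (50, 100, 200, 500)
DEFAULT_SEED = 42


@dataclass(frozen=True)
class ClusteringParams:
    """UMAP/HDBSCAN parameters for one decomposition run."""

    n_neighbours: int = 5
    min_cluster_size: int = 50
    min_dist: float = 0.1
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_neighbours < 2:
            raise ValueError("n_neighbours must be >= 2")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


class GenomeDecomposition:
    """Decompose a genome's windows into architectural clusters.

    Parameters
    ----------
    matrix:
        Windows × features table; clustering operates on its min-max-scaled
        view.

    Examples
    --------
    >>> model = GenomeDecomposition.from_fasta("assembly.fa")  # doctest: +SKIP
    >>> res = model.fit(n_neighbours=5, min_cluster_size=50)   # doctest: +SKIP
    >>> print(res.summary())                                   # doctest: +SKIP
    """

    def __init__(self, matrix: FeatureMatrix):
        self.matrix = matrix
        self._embedding_cache: dict[tuple, np.ndarray] = {}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_fasta(
        cls,
        fasta_path,
        gff3_path=None,
        track_paths: Sequence = (),
        window_size: int = 5000,
        seq_config=None,
        include=None,
        exclude=None,
    ) -> "GenomeDecomposition":
        """Build the model straight from an assembly (plus optional
        annotation and external bedgraph tracks)."""
        from .annot import gene_density_tracks, load_gff3, rebin_bedgraph
        from .seqfeats import extract_seq_features

        records = load_fasta(fasta_path)
        grid = partition_windows(records, window_size)
        tracks = extract_seq_features(records, grid, seq_config)
        if gff3_path is not None:
            models = load_gff3(gff3_path, {r.id: r.length for r in records})
            tracks += gene_density_tracks(models, grid)
        for p in track_paths:
            tracks.append(rebin_bedgraph(p, grid))
        matrix = merge_tracks(tracks, grid)
        if include is not None or exclude is not None:
            matrix = matrix.select(include=include, exclude=exclude)
        return cls(matrix)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenomeDecomposition":
        """Build from a DataFrame with scaffold/start/end + feature columns."""
        from .matrix import _grid_from_intervals

        grid = _grid_from_intervals(df)
        raw = df.drop(columns=["scaffold", "start", "end"]).reset_index(drop=True)
        return cls(FeatureMatrix(grid, raw))

    # -- embedding / clustering --------------------------------------------

    def embed(self, params: ClusteringParams) -> np.ndarray:
        """2-D UMAP embedding of the scaled windows (seed-deterministic)."""
        import umap

        n_windows = len(self.matrix.grid)
        if n_windows < params.n_neighbours + 1:
            raise ValueError(
                f"{n_windows} windows is too few for n_neighbours="
                f"{params.n_neighbours}; use a smaller n"
            )
        key = (params.n_neighbours, params.min_dist, params.seed)
        if key not in self._embedding_cache:
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", module="umap")
                warnings.filterwarnings("ignore", module="sklearn")
                reducer = umap.UMAP(
                    n_neighbors=params.n_neighbours,
                    min_dist=params.min_dist,
                    n_components=2,
                    random_state=params.seed,
                )
                emb = reducer.fit_transform(self.matrix.scaled.to_numpy())
            self._embedding_cache[key] = np.asarray(emb, dtype=float)
        return self._embedding_cache[key]

    @staticmethod
    def cluster(embedding: np.ndarray, params: ClusteringParams) -> np.ndarray:
        """HDBSCAN labels on embedding coordinates; −1 = unclassified."""
        if not np.all(np.isfinite(embedding)):
            raise ValueError("embedding contains non-finite coordinates")
        if np.ptp(embedding, axis=0).max() == 0.0:
            # degenerate: every point identical; one cluster, no noise
            return np.zeros(len(embedding), dtype=int)
        model = HDBSCAN(min_cluster_size=params.min_cluster_size, copy=True)
        return model.fit_predict(embedding)

    def fit(
        self,
        n_neighbours: int = 5,
        min_cluster_size: int = 50,
        min_dist: float = 0.1,
        seed: int = DEFAULT_SEED,
    ) -> "DecompositionResults":
        """Embed, cluster and score one parameter combination."""
        params = ClusteringParams(n_neighbours, min_cluster_size, min_dist, seed)
        embedding = self.embed(params)
        labels = self.cluster(embedding, params)
        metrics = clustering_metrics(embedding, labels)
        return DecompositionResults(self, params, embedding, labels, metrics)

    # -- parameter sweep ----------------------------------------------------

    def sweep(
        self,
        n_values: Sequence[int] = DEFAULT_N_VALUES,
        c_values: Sequence[int] = DEFAULT_C_VALUES,
        min_dist: float = 0.1,
        seed: int = DEFAULT_SEED,
    ) -> pd.DataFrame:
        """Metrics for every (n_neighbours, min_cluster_size) combination.

        The embedding is computed once per n value and reused across c.
        Rows with fewer than 2 clusters carry silhouette = NaN.
        """
        if not len(n_values) or not len(c_values):
            raise ValueError("n_values and c_values must be non-empty")
        rows = []
        for n in n_values:
            params_n = ClusteringParams(n, 2, min_dist, seed)
            embedding = self.embed(params_n)
            for c in c_values:
                params = ClusteringParams(n, c, min_dist, seed)
                labels = self.cluster(embedding, params)
                m = clustering_metrics(embedding, labels)
                rows.append({"n_neighbours": n, "min_cluster_size": c, **m})
        return pd.DataFrame(rows)

    @staticmethod
    def select_params(
        sweep_table: pd.DataFrame,
        min_dist: float = 0.1,
        seed: int = DEFAULT_SEED,
    ) -> ClusteringParams:
        """Advisory parameter choice from a sweep table.

        Keeps rows with >= 2 clusters, then ranks by lowest unclassified
        percentage, highest silhouette, most clusters; ties break toward
        smaller n then smaller c. The final run should still be an explicit
        human choice.
        """
        valid = sweep_table[sweep_table["n_clusters"] >= 2].copy()
        if valid.empty:
            raise ValueError("no sweep row produced >= 2 clusters")
        valid["_sil"] = valid["silhouette"].fillna(-2.0)
        valid = valid.sort_values(
            by=["pct_unclassified", "_sil", "n_clusters",
                "n_neighbours", "min_cluster_size"],
            ascending=[True, False, False, True, True],
            kind="mergesort",
        )
        top = valid.iloc[0]
        return ClusteringParams(
            int(top["n_neighbours"]), int(top["min_cluster_size"]), min_dist, seed
        )


def clustering_metrics(embedding: np.ndarray, labels: np.ndarray) -> dict:
    """Quality scores for one clustering, on embedding coordinates and
    classified windows only; NaN scores when fewer than 2 clusters."""
    labels = np.asarray(labels)
    classified = labels >= 0
    n_clusters = int(len(np.unique(labels[classified]))) if classified.any() else 0
    pct_unclassified = 100.0 * float((~classified).sum()) / len(labels)
    sil = db = ch = float("nan")
    if n_clusters >= 2 and classified.sum() > n_clusters:
        pts = embedding[classified]
        labs = labels[classified]
        sil = float(silhouette_score(pts, labs))
        db = float(davies_bouldin_score(pts, labs))
        ch = float(calinski_harabasz_score(pts, labs))
    return {
        "n_clusters": n_clusters,
        "pct_unclassified": pct_unclassified,
        "silhouette": sil,
        "davies_bouldin": db,
        "calinski_harabasz": ch,
    }


@dataclass
class DecompositionResults:
    """Fitted decomposition: embedding, labels, metrics and diagnostics."""

    model: GenomeDecomposition
    params: ClusteringParams
    embedding: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    metrics: dict = field(default_factory=dict)

    @property
    def grid(self):
        return self.model.matrix.grid

    @property
    def n_clusters(self) -> int:
        return self.metrics["n_clusters"]

    @property
    def pct_unclassified(self) -> float:
        return self.metrics["pct_unclassified"]

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    # -- statistics ---------------------------------------------------------

    def characterise(self, alpha: float = _stats.DEFAULT_ALPHA) -> pd.DataFrame:
        """KS D+/D− characterisation of every cluster × feature."""
        return _stats.characterise(self.model.matrix, self.labels, alpha)

    def heatmap_table(self, alpha: float = _stats.DEFAULT_ALPHA):
        return _stats.heatmap_table(self.characterise(alpha))

    def junction_enrichment(self) -> pd.DataFrame:
        return _stats.junction_enrichment(self.labels, self.grid)

    def subtelomeric_mask(self, distance: int = 200_000) -> np.ndarray:
        return _stats.split_subtelomeric(self.grid, distance)

    def to_bed(self, path, merge_runs: bool = False, header_comments=()) -> None:
        _stats.write_cluster_bed(
            self.labels, self.grid, path, merge_runs, header_comments
        )

    # -- presentation -------------------------------------------------------

    def summary(self, alpha: float = _stats.DEFAULT_ALPHA) -> str:
        """Human-readable run summary with per-cluster signatures."""
        p = self.params
        lines = [
            "Genome decomposition results",
            "=" * 60,
            f"windows:            {len(self.grid)}"
            f"  (window size {self.grid.window_size} bp)",
            f"features:           {len(self.model.matrix.feature_names)}",
            f"n_neighbours (n):   {p.n_neighbours}",
            f"min_cluster_size:   {p.min_cluster_size}",
            f"seed:               {p.seed}",
            f"clusters:           {self.n_clusters}",
            f"unclassified:       {self.pct_unclassified:.2f}%",
            f"silhouette:         {self.metrics['silhouette']:.4f}",
            f"davies_bouldin:     {self.metrics['davies_bouldin']:.4f}",
            f"calinski_harabasz:  {self.metrics['calinski_harabasz']:.1f}",
            "-" * 60,
        ]
        if self.n_clusters >= 2:
            ks = self.characterise(alpha)
            sizes = self.cluster_sizes()
            for k in sorted(c for c in sizes.index if c >= 0):
                sub = ks[(ks["cluster"] == k) & (ks["call"] != "none")]
                hi = sub[sub["call"] == "higher"]["feature"].tolist()
                lo = sub[sub["call"] == "lower"]["feature"].tolist()
                lines.append(
                    f"cluster {k}: {sizes[k]} windows"
                    f" ({100 * sizes[k] / len(self.labels):.1f}%)"
                )
                if hi:
                    lines.append(f"  high: {', '.join(hi)}")
                if lo:
                    lines.append(f"  low:  {', '.join(lo)}")
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------

    def plot_embedding(self, path=None, ax=None):
        """UMAP scatter coloured by cluster (grey = unclassified)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(6, 5))
        else:
            fig = ax.figure
        for k in sorted(np.unique(self.labels)):
            pts = self.embedding[self.labels == k]
            kwargs = (
                {"color": "0.7", "label": "unclassified"}
                if k < 0
                else {"label": f"cluster {k}"}
            )
            ax.scatter(pts[:, 0], pts[:, 1], s=6, **kwargs)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        ax.legend(markerscale=2, fontsize=8)
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax

    def plot_chromosomes(self, path=None, ax=None):
        """Clusters painted along each scaffold as coloured bars."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            fig, ax = plt.subplots(figsize=(8, 0.5 * len(self.grid.scaffold_ids) + 1))
        else:
            fig = ax.figure
        uniq = sorted(np.unique(self.labels))
        colors = {
            k: ("0.8" if k < 0 else plt.get_cmap("tab10")(i % 10))
            for i, k in enumerate(uniq)
        }
        names = self.grid.scaffold_names()
        for row, sid in enumerate(self.grid.scaffold_ids):
            sel = names == sid
            for s, e, lab in zip(
                self.grid.start[sel], self.grid.end[sel], self.labels[sel]
            ):
                ax.barh(row, e - s, left=s, height=0.6, color=colors[lab])
        ax.set_yticks(range(len(self.grid.scaffold_ids)))
        ax.set_yticklabels(self.grid.scaffold_ids, fontsize=8)
        ax.set_xlabel("position (bp)")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax

    def plot_heatmap(self, path=None, alpha: float = _stats.DEFAULT_ALPHA, ax=None):
        """Cluster × feature heatmap of mean scaled values with KS icons."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        means, icons = self.heatmap_table(alpha)
        if ax is None:
            fig, ax = plt.subplots(
                figsize=(0.5 * means.shape[1] + 2, 0.5 * means.shape[0] + 2)
            )
        else:
            fig = ax.figure
        im = ax.imshow(means.to_numpy(), cmap="coolwarm", aspect="auto")
        for i in range(means.shape[0]):
            for j in range(means.shape[1]):
                icon = icons.iloc[i, j]
                if icon:
                    ax.text(j, i, icon, ha="center", va="center", fontsize=8)
        ax.set_xticks(range(means.shape[1]))
        ax.set_xticklabels(means.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(means.shape[0]))
        ax.set_yticklabels([f"cluster {k}" for k in means.index], fontsize=8)
        fig.colorbar(im, ax=ax, label="mean scaled value")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax
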