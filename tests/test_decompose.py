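"""Embedding, clustering, sweeps and the model/results interface."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

import genarch as ga
from genarch.decompose import clustering_metrics
from genarch.matrix import FeatureMatrix
from genarch.seqfeats import FeatureTrack

import oracles


def two_block_matrix(n_per=60, seed=3):
    """Two well-separated feature blocks on a toy grid."""
    rng = np.random.default_rng(seed)
    grid = ga.partition_windows(
        [ga.SequenceRecord("c", "A" * (2 * n_per * 1000))], 1000
    )
    a = rng.normal(0.1, 0.02, size=(n_per, 3))
    b = rng.normal(0.9, 0.02, size=(n_per, 3))
    raw = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2", "f3"])
    return FeatureMatrix(grid, raw)


class TestEmbed:
    def test_deterministic_for_fixed_seed(self):
        m = two_block_matrix()
        e1 = ga.GenomeDecomposition(m).embed(ga.ClusteringParams(seed=42))
        e2 = ga.GenomeDecomposition(m).embed(ga.ClusteringParams(seed=42))
        assert np.array_equal(e1, e2)

    def test_separates_two_blocks(self):
        m = two_block_matrix()
        model = ga.GenomeDecomposition(m)
        emb = model.embed(ga.ClusteringParams(n_neighbours=10, seed=1))
        a, b = emb[:60], emb[60:]
        centroid_dist = np.linalg.norm(a.mean(0) - b.mean(0))
        spread = max(a.std(0).max(), b.std(0).max())
        assert centroid_dist > 3 * spread

    def test_too_few_windows_raises(self):
        grid = ga.partition_windows([ga.SequenceRecord("c", "A" * 3000)], 1000)
        m = FeatureMatrix(grid, pd.DataFrame({"f": [0.0, 0.5, 1.0]}))
        with pytest.raises(ValueError, match="smaller n"):
            ga.GenomeDecomposition(m).embed(ga.ClusteringParams(n_neighbours=15))


class TestCluster:
    def test_two_tight_clouds(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.05, (100, 2)), rng.normal(5, 0.05, (100, 2))]
        )
        labels = ga.GenomeDecomposition.cluster(
            pts, ga.ClusteringParams(min_cluster_size=50)
        )
        assert len(np.unique(labels)) == 2
        assert (labels >= 0).all()
        for k in np.unique(labels):
            assert (labels == k).sum() >= 50

    def test_uniform_cloud_mostly_noise(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1, size=(300, 2))
        labels = ga.GenomeDecomposition.cluster(
            pts, ga.ClusteringParams(min_cluster_size=140)
        )
        assert (labels == -1).mean() > 0.5

    def test_identical_points_single_cluster(self):
        pts = np.zeros((80, 2))
        labels = ga.GenomeDecomposition.cluster(
            pts, ga.ClusteringParams(min_cluster_size=10)
        )
        assert len(np.unique(labels)) == 1 and labels[0] >= 0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ga.ClusteringParams(n_neighbours=1)
        with pytest.raises(ValueError):
            ga.ClusteringParams(min_cluster_size=1)


class TestMetrics:
    def test_metrics_match_reference_formulas_on_toy_points(self):
        pts = np.array(
            [[0.0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1], [0.05, 0.05],
             [3.0, 3], [3.1, 3], [3, 3.1], [3.1, 3.1], [3.05, 3.05]]
        )
        labels = np.array([0] * 5 + [1] * 5)
        m = clustering_metrics(pts, labels)
        assert m["n_clusters"] == 2
        assert m["silhouette"] == pytest.approx(oracles.silhouette(pts, labels), rel=1e-9)
        assert m["davies_bouldin"] == pytest.approx(davies_bouldin_score(pts, labels))
        assert m["calinski_harabasz"] == pytest.approx(
            calinski_harabasz_score(pts, labels)
        )

    def test_unclassified_excluded_from_scores(self):
        pts = np.array([[0.0, 0], [0.1, 0], [5.0, 5], [5.1, 5], [99.0, 99]])
        labels = np.array([0, 0, 1, 1, -1])
        with_noise = clustering_metrics(pts, labels)
        without = clustering_metrics(pts[:4], labels[:4])
        assert with_noise["silhouette"] == pytest.approx(without["silhouette"])
        assert with_noise["pct_unclassified"] == pytest.approx(20.0)

    def test_permutation_invariance(self, rng):
        pts = rng.normal(size=(60, 2))
        labels = rng.integers(-1, 3, size=60)
        base = clustering_metrics(pts, labels)
        perm = rng.permutation(60)
        other = clustering_metrics(pts[perm], labels[perm])
        for key in ("silhouette", "davies_bouldin", "calinski_harabasz",
                    "pct_unclassified", "n_clusters"):
            assert base[key] == pytest.approx(other[key], nan_ok=True)

    def test_single_cluster_gives_nan_sentinel(self):
        pts = np.zeros((10, 2))
        m = clustering_metrics(pts, np.zeros(10, int))
        assert m["n_clusters"] == 1 and np.isnan(m["silhouette"])


class TestSweepAndSelection:
    def test_default_grid_shape(self):
        m = two_block_matrix()
        table = ga.GenomeDecomposition(m).sweep(
            n_values=(5, 10), c_values=(20, 40), seed=9
        )
        assert len(table) == 4
        assert set(table.columns) >= {
            "n_neighbours", "min_cluster_size", "n_clusters", "pct_unclassified",
            "silhouette", "davies_bouldin", "calinski_harabasz",
        }

    def test_sweep_finds_two_blocks(self):
        m = two_block_matrix()
        table = ga.GenomeDecomposition(m).sweep(
            n_values=(5, 10), c_values=(20, 40), seed=9
        )
        good = table[(table.n_clusters == 2) & (table.pct_unclassified < 5)]
        assert len(good) > 0

    def test_select_prefers_low_unclassified_over_silhouette(self):
        table = pd.DataFrame(
            {
                "n_neighbours": [5, 10],
                "min_cluster_size": [50, 50],
                "n_clusters": [3, 2],
                "pct_unclassified": [0.0, 10.0],
                "silhouette": [0.28, 0.50],
            }
        )
        p = ga.GenomeDecomposition.select_params(table)
        assert (p.n_neighbours, p.min_cluster_size) == (5, 50)

    def test_select_matches_bruteforce_ranking(self, rng):
        rows = []
        for n in (5, 10, 15):
            for c in (50, 100):
                rows.append(
                    {
                        "n_neighbours": n,
                        "min_cluster_size": c,
                        "n_clusters": int(rng.integers(0, 5)),
                        "pct_unclassified": float(rng.choice([0, 2.5, 10, 40])),
                        "silhouette": float(rng.uniform(-0.2, 0.9)),
                    }
                )
        table = pd.DataFrame(rows)
        valid = [r for r in rows if r["n_clusters"] >= 2]
        if not valid:
            with pytest.raises(ValueError):
                ga.GenomeDecomposition.select_params(table)
            return
        best = sorted(
            valid,
            key=lambda r: (
                r["pct_unclassified"], -r["silhouette"], -r["n_clusters"],
                r["n_neighbours"], r["min_cluster_size"],
            ),
        )[0]
        p = ga.GenomeDecomposition.select_params(table)
        assert (p.n_neighbours, p.min_cluster_size) == (
            best["n_neighbours"], best["min_cluster_size"]
        )

    def test_single_valid_row_selected(self):
        table = pd.DataFrame(
            {
                "n_neighbours": [5],
                "min_cluster_size": [50],
                "n_clusters": [2],
                "pct_unclassified": [1.0],
                "silhouette": [0.4],
            }
        )
        p = ga.GenomeDecomposition.select_params(table)
        assert (p.n_neighbours, p.min_cluster_size) == (5, 50)

    def test_no_valid_rows_raises(self):
        table = pd.DataFrame(
            {
                "n_neighbours": [5],
                "min_cluster_size": [50],
                "n_clusters": [0],
                "pct_unclassified": [100.0],
                "silhouette": [np.nan],
            }
        )
        with pytest.raises(ValueError):
            ga.GenomeDecomposition.select_params(table)


class TestResults:
    def test_fit_summary_and_outputs(self, tmp_path):
        m = two_block_matrix()
        res = ga.GenomeDecomposition(m).fit(
            n_neighbours=10, min_cluster_size=20, seed=4
        )
        assert res.n_clusters == 2
        text = res.summary(alpha=1e-3)
        assert "clusters:" in text and "cluster 0" in text
        res.to_bed(tmp_path / "c.bed")
        rows = open(tmp_path / "c.bed").read().splitlines()
        assert len(rows) == len(m.grid)

    def test_full_run_repeatable(self):
        m = two_block_matrix()
        r1 = ga.GenomeDecomposition(m).fit(10, 20, seed=4)
        r2 = ga.GenomeDecomposition(m).fit(10, 20, seed=4)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.embedding, r2.embedding)
        assert r1.metrics == r2.metrics

    def test_plots_written(self, tmp_path):
        m = two_block_matrix()
        res = ga.GenomeDecomposition(m).fit(10, 20, seed=4)
        for name, fn in (
            ("emb.png", res.plot_embedding),
            ("chrom.png", res.plot_chromosomes),
        ):
            fn(tmp_path / name)
            assert (tmp_path / name).stat().st_size > 0
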