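"""Cluster characterisation statistics against exhaustive oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import genarch as ga
from genarch.matrix import FeatureMatrix
from genarch.seqfeats import FeatureTrack
from genarch.stats import ks_one_sided

import oracles


def grid_of(n_windows, w=1000, scaffolds=1):
    recs = [
        ga.SequenceRecord(f"c{i}", "A" * (n_windows * w)) for i in range(scaffolds)
    ]
    return ga.partition_windows(recs, w)


class TestKsOneSided:
    def test_disjoint_supports(self):
        dp, pp, dm, pm = ks_one_sided([10, 11, 12], [1, 2, 3])
        assert dp == 1.0
        assert pp < 0.2 < pm

    def test_identical_distributions(self):
        x = list(range(50))
        dp, pp, dm, pm = ks_one_sided(x, x)
        assert dp == 0.0 and dm == 0.0
        assert pp == pytest.approx(1.0) and pm == pytest.approx(1.0)

    def test_statistics_match_ecdf_oracle(self, rng):
        for _ in range(30):
            x = rng.normal(size=int(rng.integers(4, 20)))
            y = rng.normal(loc=rng.uniform(-1, 1), size=int(rng.integers(4, 20)))
            dp, _, dm, _ = ks_one_sided(x, y)
            odp, odm = oracles.ks_one_sided_stats(x, y)
            assert dp == pytest.approx(odp, abs=1e-12)
            assert dm == pytest.approx(odm, abs=1e-12)

    def test_exact_p_matches_enumeration(self, rng):
        """One-sided D and exact p agree with full enumeration of all
        assignments of the pooled sample, on <=10-point samples."""
        for _ in range(8):
            n, m = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            pooled = rng.permutation(np.arange(1.0, n + m + 1))  # distinct values
            x, y = pooled[:n], pooled[n:]
            dp, pp, dm, pm = ks_one_sided(x, y, method="exact")
            assert pp == pytest.approx(
                oracles.ks_exact_p_enumeration(x, y, "plus"), abs=1e-9
            )
            assert pm == pytest.approx(
                oracles.ks_exact_p_enumeration(x, y, "minus"), abs=1e-9
            )

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=40) + 0.5
        base = ks_one_sided(x, y)
        warped = ks_one_sided(np.exp(x), np.exp(y))
        assert base[0] == pytest.approx(warped[0])
        assert base[2] == pytest.approx(warped[2])


class TestCharacterise:
    def make_matrix(self, columns):
        n = len(next(iter(columns.values())))
        grid = grid_of(n)
        return FeatureMatrix(grid, pd.DataFrame(columns))

    def test_higher_call_on_disjoint_clusters(self):
        vals = np.r_[np.zeros(30), np.ones(30)]
        m = self.make_matrix({"f": vals})
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        res = ga.characterise(m, labels, alpha=1e-6)
        row = res[(res.cluster == 1) & (res.feature == "f")].iloc[0]
        assert row.d_plus == 1.0 and row.call == "higher"
        row0 = res[(res.cluster == 0) & (res.feature == "f")].iloc[0]
        assert row0.call == "lower"

    def test_identical_distribution_no_call(self, rng):
        vals = np.tile(rng.normal(size=40), 2)
        m = self.make_matrix({"f": vals})
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        res = ga.characterise(m, labels, alpha=1e-20)
        assert set(res.call) == {"none"}

    def test_unclassified_in_rest_not_as_cluster(self):
        vals = np.r_[np.zeros(20), np.ones(20), np.full(5, 0.5)]
        labels = np.r_[np.zeros(20, int), np.ones(20, int), np.full(5, -1, int)]
        m = self.make_matrix({"f": vals})
        res = ga.characterise(m, labels, alpha=1e-3)
        assert set(res.cluster) == {0, 1}

    def test_tiny_cluster_warns_and_calls_none(self, caplog):
        vals = np.arange(41.0)
        labels = np.r_[np.zeros(40, int), np.array([1])]
        m = self.make_matrix({"f": vals})
        res = ga.characterise(m, labels)
        assert res[res.cluster == 1].iloc[0].call == "none"

    def test_heatmap_round_trip(self, tmp_path):
        vals = np.r_[np.zeros(30), np.ones(30)]
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        m = self.make_matrix({"f": vals, "g": vals[::-1].copy()})
        res = ga.characterise(m, labels, alpha=1e-6)
        means, icons = ga.heatmap_table(res)
        assert means.shape == (2, 2) and icons.shape == (2, 2)
        assert icons.loc[1, "f"] == "∧" and icons.loc[0, "f"] == "∨"
        p = tmp_path / "h.tsv"
        means.to_csv(p, sep="\t")
        back = pd.read_csv(p, sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), means.to_numpy())


class TestJunctions:
    def test_direct_count_aabb(self):
        grid = grid_of(4)
        table = ga.junction_enrichment(np.array([0, 0, 1, 1]), grid)
        obs = {(r.cluster_a, r.cluster_b): r.observed for r in table.itertuples()}
        assert obs[(0, 0)] == 1 and obs[(0, 1)] == 1 and obs[(1, 1)] == 1

    def test_observed_total_conservation(self, rng):
        grid = ga.partition_windows(
            [ga.SequenceRecord("a", "A" * 37_000), ga.SequenceRecord("b", "A" * 12_000)],
            1000,
        )
        labels = rng.integers(-1, 3, size=len(grid))
        table = ga.junction_enrichment(labels, grid)
        expected_total = (37 - 1) + (12 - 1)
        assert table.observed.sum() == expected_total

    def test_alternating_labels_enriched(self):
        grid = grid_of(200)
        labels = np.tile([0, 1], 100)
        table = ga.junction_enrichment(labels, grid)
        row = table[(table.cluster_a == 0) & (table.cluster_b == 1)].iloc[0]
        assert row.observed == 199
        assert row.q < 1e-10
        assert (table.q >= table.p - 1e-15).all()

    def test_fisher_p_matches_hypergeometric_oracle(self):
        grid = grid_of(20)
        labels = np.array([0] * 10 + [1] * 10)
        table = ga.junction_enrichment(labels, grid)
        for r in table.itertuples():
            e = int(round(r.expected))
            total = 19
            oracle_p = oracles.fisher_exact_p([[r.observed, total - r.observed],
                                               [e, total - e]])
            assert r.p == pytest.approx(oracle_p, rel=1e-9)

    def test_random_labels_rarely_significant(self):
        grid = grid_of(300)
        n_sig = 0
        n_pairs = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = rng.integers(0, 3, size=300)
            table = ga.junction_enrichment(labels, grid)
            n_sig += int((table.p < 0.05).sum())
            n_pairs += len(table)
        assert n_sig / n_pairs <= 0.05

    def test_bh_monotone(self, rng):
        grid = grid_of(100)
        labels = rng.integers(0, 4, size=100)
        table = ga.junction_enrichment(labels, grid).sort_values("p")
        assert (np.diff(table.q.to_numpy()) >= -1e-15).all()


class TestOverlapAndSubtelomeres:
    def test_gene_single_and_spanning(self):
        grid = grid_of(4)
        labels = np.array([0, 0, 1, 1])
        intervals = pd.DataFrame(
            {
                "scaffold": ["c0", "c0"],
                "start": [100, 1900],
                "end": [300, 2100],
                "id": ["inside", "spanning"],
            }
        )
        out = ga.overlap_clusters(intervals, labels, grid)
        counts = dict(zip(out.cluster, out.n_features))
        assert counts[0] == 2 and counts[1] == 1

    def test_overlap_matches_bruteforce(self, rng):
        grid = grid_of(30)
        labels = rng.integers(-1, 3, size=30)
        intervals = pd.DataFrame(
            {
                "scaffold": "c0",
                "start": (s := rng.integers(0, 29_000, size=40)),
                "end": s + rng.integers(10, 3000, size=40),
                "id": [f"g{i}" for i in range(40)],
            }
        )
        out = ga.overlap_clusters(intervals, labels, grid)
        got = dict(zip(out.cluster, out.n_features))
        want = {}
        for _, row in intervals.iterrows():
            hit = set()
            for wi in range(len(grid)):
                ws, we = grid.start[wi], min(grid.end[wi], 30_000)
                if row.start < we and row.end > ws:
                    hit.add(int(labels[wi]))
            for k in hit:
                want[k] = want.get(k, 0) + 1
        assert got == want

    def test_subtelomeric_windows_1mb(self):
        grid = ga.partition_windows([ga.SequenceRecord("c", "A" * 1_000_000)], 5000)
        mask = ga.split_subtelomeric(grid, 200_000)
        assert mask[:40].all() and mask[-40:].all()
        assert not mask[40:-40].any()
        assert mask.sum() == 80

    def test_short_scaffold_fully_subtelomeric(self):
        grid = ga.partition_windows([ga.SequenceRecord("c", "A" * 300_000)], 5000)
        assert ga.split_subtelomeric(grid, 200_000).all()


class TestClusterBed:
    def test_covers_every_window_once(self, tmp_path, rng):
        grid = grid_of(10)
        labels = rng.integers(-1, 2, size=10)
        p = tmp_path / "c.bed"
        ga.write_cluster_bed(labels, grid, p)
        rows = [l.split("\t") for l in open(p).read().splitlines() if not l.startswith("#")]
        assert len(rows) == 10
        assert [int(r[1]) for r in rows] == [i * 1000 for i in range(10)]

    def test_merge_runs(self, tmp_path):
        grid = grid_of(4)
        ga.write_cluster_bed(np.array([0, 0, 1, 1]), grid, tmp_path / "c.bed",
                             merge_runs=True)
        rows = open(tmp_path / "c.bed").read().splitlines()
        assert rows == ["c0\t0\t2000\tcluster_0", "c0\t2000\t4000\tcluster_1"]
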