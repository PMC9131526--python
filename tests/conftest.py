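import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

warnings.filterwarnings("ignore", module="umap")
warnings.filterwarnings("ignore", message=".*n_jobs.*")

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = np.array(list("ACGT"))


def random_seq(rng, n, at=0.5):
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_sequences():
    """200 seeded random sequences of 1-5 kb with varying AT content."""
    rng = np.random.default_rng(7)
    seqs = []
    for _ in range(200):
        n = int(rng.integers(1000, 5001))
        at = float(rng.uniform(0.3, 0.8))
        seqs.append(random_seq(rng, n, at))
    return seqs


@pytest.fixture(scope="session")
def parasite_genome():
    """The parasite-like preset genome, shared across tests."""
    import genarch as ga

    return ga.simulate_genome(ga.parasite_preset(), seed=0)


@pytest.fixture(scope="session")
def parasite_matrix(parasite_genome):
    import genarch as ga

    grid = ga.partition_windows(parasite_genome.records, 5000)
    tracks = ga.extract_seq_features(parasite_genome.records, grid)
    return ga.merge_tracks(tracks, grid)


@pytest.fixture()
def small_genome():
    """A 3 x 200 kb genome with the same planted architecture, for fast
    end-to-end tests."""
    import genarch as ga

    def tare(n):
        return ga.SegmentSpec(
            "tare", n, gc=0.55, motif_arrays=[ga.MotifArray("TTTAGGG", 60)]
        )

    def multi(n):
        return ga.SegmentSpec(
            "multigene", n, gc=0.30, tandem_duplication=(5000, n // 5000)
        )

    def core(n):
        return ga.SegmentSpec("core", n, gc=0.19, gene_density=4.0)

    plans = [
        [tare(20_000), multi(40_000), core(120_000), tare(20_000)]
        for _ in range(3)
    ]
    return ga.simulate_genome(plans, seed=11)
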