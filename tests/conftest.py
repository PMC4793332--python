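import numpy as np
import pytest

from domainlen import (
    GenomicInterval,
    IntervalTrack,
    ModelConfig,
    build_feature_matrix,
    fit_length_model,
)
from domainlen.simulate import SimulationConfig, simulate_all

#: The planted benchmark used across the suite: 2000 domains with log-normal
#: lengths (log10 mean 3.2, sd 0.4), 6 informative tracks with sigmoid link
#: slopes alternating +2/-2 and fraction noise sd 0.05, 14 decoys, seed 7.
BENCHMARK = dict(
    n_domains=2000,
    length_log10_mean=3.2,
    length_log10_sd=0.4,
    n_informative=6,
    n_decoy=14,
    noise_sd=0.05,
    seed=7,
)


@pytest.fixture(scope="session")
def benchmark_data():
    cfg = SimulationConfig(**BENCHMARK)
    domains, tracks, anchors, truth = simulate_all(cfg)
    return cfg, domains, tracks, anchors, truth


@pytest.fixture(scope="session")
def benchmark_matrix(benchmark_data):
    _, domains, tracks, _, _ = benchmark_data
    return build_feature_matrix(domains, tracks)


@pytest.fixture(scope="session")
def benchmark_model(benchmark_matrix):
    return fit_length_model(benchmark_matrix, ModelConfig(seed=7))


def random_track(rng: np.random.Generator, label: str, n: int, span: int = 2000,
                 chrom: str = "chr1") -> IntervalTrack:
    """Random small-coordinate instances, mutual overlaps allowed."""
    starts = rng.integers(0, span - 1, n)
    lengths = rng.integers(1, span // 4, n)
    return IntervalTrack(
        label=label,
        intervals=[GenomicInterval(chrom, int(s), int(min(s + l, span)))
                   for s, l in zip(starts, lengths) if min(s + l, span) > s],
    )
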