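import numpy as np
import pytest

from mireader.fixtures import make_benchmark, make_planted_library
from mireader.pipeline import PipelineConfig, train_from_patterns

#: documented seed and iteration count of the shipped benchmark runs
BENCHMARK_SEED = 1
BENCHMARK_K = 30


@pytest.fixture(scope="session")
def benchmark():
    """The standard synthetic benchmark: 500+500 train, 500+500 test."""
    return make_benchmark(seed=BENCHMARK_SEED, n_per_class=500)


@pytest.fixture(scope="session")
def bench_config():
    return PipelineConfig(K=BENCHMARK_K)


@pytest.fixture(scope="session")
def trained(benchmark, bench_config):
    """Profiles and per-cluster MultiBoost models trained on the benchmark."""
    return train_from_patterns(
        benchmark.train.patterns, benchmark.train.labels, bench_config
    )


@pytest.fixture(scope="session")
def planted_library():
    return make_planted_library(seed=BENCHMARK_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, length):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))
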