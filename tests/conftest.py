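import numpy as np
import pytest

from splicehmm.benchmark import make_benchmark, run_benchmark


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """20 kb balanced random genome shared by unit tests."""
    from splicehmm.simulate import make_genome

    return make_genome(20_000, gc=0.5, seed=99)


@pytest.fixture(scope="session")
def bench():
    """Standard 1 Mb / 100-transcript benchmark runs at 1x, 5x and 10x.

    All runs share seed 7 (and hence genome and truth table); computed once
    per session because the sensitivity, FPR and ROC checks all read from it.
    """
    out = {}
    for cov in (1, 5, 10):
        result, data = run_benchmark(seed=7, coverage=cov)
        out[cov] = (result, data)
    return out
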