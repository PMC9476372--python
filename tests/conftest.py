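import numpy as np
import pytest
from hypothesis import settings

from tmsid.spectra_io import Peak, Spectrum
from tmsid.synthetic_data import GeneratorConfig, make_benchmark
from tmsid.workflow import RunConfig, run_train

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def spec_from_pairs(pairs, **meta):
    """Build a Spectrum from (mz, intensity) pairs (duplicate m/z merged
    by intensity sum, as the MSP reader does)."""
    merged = {}
    for m, i in pairs:
        merged[m] = merged.get(m, 0.0) + i
    return Spectrum(peaks=[Peak(m, i) for m, i in sorted(merged.items())], **meta)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study shared by integration tests."""
    return make_benchmark(GeneratorConfig(n_train=60, n_test=10, master_seed=3))


@pytest.fixture(scope="session")
def trained_small(small_bundle):
    return run_train(RunConfig(master_seed=3), small_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
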