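import numpy as np
import pytest

from armsign import features, synth


@pytest.fixture(scope="session")
def small_dataset():
    """10 signs x 5 reps at moderate noise, featurized once per session."""
    ds = synth.synthesize_dataset(10, 5, noise_level=0.25, seed=7)
    features.extract_feature_table(ds)
    return ds


@pytest.fixture(scope="session")
def bench_dataset():
    """The full 80-sign x 10-rep synthetic benchmark, featurized once.

    Shared by the acceptance tests (parameter recovery, split protocol) to
    keep the suite inside its runtime budget.
    """
    ds = synth.synthesize_dataset(80, 10, noise_level=0.25, seed=1)
    features.extract_feature_table(ds)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
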