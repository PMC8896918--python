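import numpy as np
import pytest

from epiwave.data_io import Signal
from epiwave.features import build_feature_table
from epiwave.synthetic import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def fast_spec():
    """Short segments keep the unit-test pipeline quick; 5-level DWT still valid."""
    return SynthSpec(n_segments_per_class=30, segment_length=512, seed=7)


@pytest.fixture(scope="session")
def fast_dataset(fast_spec):
    return generate_dataset(fast_spec)


@pytest.fixture(scope="session")
def fast_table(fast_dataset):
    return build_feature_table(fast_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture()
def random_signal(rng):
    return Signal(samples=rng.standard_normal(1024), fs=173.61, source_id="rand")
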