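import numpy as np
import pytest

from fgcn import Montage, SynthSpec, make_subject


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    """A fast 8-channel, 2-subject study used across the suite."""
    return SynthSpec(
        n_channels=8,
        n_subjects=2,
        trials_per_class=5,
        fs=128.0,
        duration=4.0,
        n_edges_per_class=4,
    )


@pytest.fixture(scope="session")
def subject_data(small_spec):
    return make_subject(small_spec, 0)


@pytest.fixture(scope="session")
def small_montage() -> Montage:
    return Montage.synthetic(8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
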