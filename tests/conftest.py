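import numpy as np
import pytest

from boldvar import synthgen
from boldvar.signalprep import VoxelTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Tiny cohort for fast unit tests (not the spec'd 20x300 preset)."""
    return synthgen.SynthConfig(
        n_subjects=10, n_voxels=80, n_effect_voxels=20, n_timepoints=120, seed=42
    )


@pytest.fixture
def small_cohort(small_config):
    return synthgen.simulate_cohort(small_config)


@pytest.fixture
def random_series(rng):
    def make(n_voxels=5, n_timepoints=200, tr=2.5):
        return VoxelTimeSeries(
            values=rng.standard_normal((n_voxels, n_timepoints)),
            tr_seconds=tr,
        )

    return make
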