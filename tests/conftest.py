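import warnings

import numpy as np
import pytest

from emoeeg import SynthConfig, process_cohort
from emoeeg.layout import small_layout
from emoeeg.synth import generate_cohort

warnings.filterwarnings("ignore", message="no reference channels")


@pytest.fixture(scope="session")
def quick_config():
    """Four-channel, short-segment cohort for fast unit tests."""
    return SynthConfig(n_subjects=6, fs=250.0, film_duration_s=12.0,
                       baseline_duration_s=8.0, layout=small_layout(), seed=42)


@pytest.fixture(scope="session")
def quick_cohort(quick_config):
    return generate_cohort(quick_config)


@pytest.fixture(scope="session")
def full_layout_powers():
    """Band-power table on the full 31-channel layout (reduced durations)."""
    cfg = SynthConfig(n_subjects=6, fs=250.0, film_duration_s=10.0,
                      baseline_duration_s=6.0, seed=7)
    recordings, ratings = generate_cohort(cfg)
    return process_cohort(recordings), ratings


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
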