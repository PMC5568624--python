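import numpy as np
import pytest

from psgrank.features import FeatureConfig
from psgrank.synthetic_data import (StageSpec, SyntheticCohortConfig,
                                    default_stage_specs, generate_feature_table,
                                    generate_recording)
from psgrank.types import EpochSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return FeatureConfig()


@pytest.fixture
def random_epoch(rng):
    return EpochSignal(rng.standard_normal(3000), 100.0, "EEG")


@pytest.fixture(scope="session")
def small_cohort():
    """Three tiny subjects with all five stages present."""
    counts = [
        {"W": 12, "REM": 10, "S1": 8, "S2": 20, "SWS": 10},
        {"W": 10, "REM": 12, "S1": 9, "S2": 18, "SWS": 11},
        {"W": 11, "REM": 9, "S1": 10, "S2": 19, "SWS": 12},
    ]
    config = SyntheticCohortConfig(n_subjects=3, stage_counts=counts, seed=42)
    return config, generate_recording(config)


@pytest.fixture(scope="session")
def toy_table():
    """500-row table with 5 informative, 5 redundant, 39 noise columns."""
    return generate_feature_table(500, 5, 5, 39, effect=2.0, seed=7)


@pytest.fixture
def stage_specs():
    return default_stage_specs()


@pytest.fixture
def delta_spec():
    return StageSpec(
        "SWS",
        {"delta": 1.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0},
        emg_tone=0.5,
    )
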