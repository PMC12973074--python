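import numpy as np
import pytest

from eeg2bold.datatypes import EegRecording
from eeg2bold.synth import SourceSpec, SyntheticConfig, simulate_session, smooth_pattern
from eeg2bold.workbench import desk_scale_config, prepare_session


@pytest.fixture(scope="session")
def tiny_cfg() -> SyntheticConfig:
    """A very small session (8 channels, 4 short runs) for fast unit tests."""
    return SyntheticConfig(
        n_channels=8,
        n_runs=4,
        trials_per_run=6,
        volumes_per_run=30,
        sources=[SourceSpec(spatial_pattern=smooth_pattern(8))],
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_cfg):
    return simulate_session(tiny_cfg)


@pytest.fixture(scope="session")
def desk_session():
    """Prepared desk-scale session shared by alignment/baseline tests."""
    return prepare_session(desk_scale_config(3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_eeg(rng) -> EegRecording:
    data = rng.standard_normal((6, 800))
    return EegRecording(data, [f"e{i+1}" for i in range(6)], 100.0, "run1")
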