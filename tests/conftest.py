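import numpy as np
import pytest

from ghostpeat.chronology import AgeDepthConfig, fit_age_depth, mix_calibration_curves
from ghostpeat.synthetic import WorldConfig, synth_climate, synth_core, synth_curve_pair


@pytest.fixture(scope="session")
def world() -> WorldConfig:
    return WorldConfig(seed=7)


@pytest.fixture(scope="session")
def mixed_curve(world):
    north, south = synth_curve_pair(seed=world.seed)
    return mix_calibration_curves(north, south, 0.5)


@pytest.fixture(scope="session")
def core(world):
    return synth_core(world)


@pytest.fixture(scope="session")
def climate(world):
    return synth_climate(world)


@pytest.fixture(scope="session")
def age_model(world, core, mixed_curve):
    """One fitted age-depth model shared by the read-only tests."""
    cfg = AgeDepthConfig(section_thickness=10.0, n_iter=4000, burn=1000, seed=world.seed)
    return fit_age_depth(
        core.radiocarbon_dates(), mixed_curve, top_age=world.top_age, config=cfg
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
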