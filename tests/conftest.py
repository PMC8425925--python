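import numpy as np
import pytest

from logqa import (
    SimConfig,
    default_geometry,
    make_fixture_plan,
    simulate_delivery,
)


@pytest.fixture
def geometry40():
    return default_geometry(40)


@pytest.fixture
def zero_noise():
    """Noise-free simulation: positions reproduce the plan exactly."""
    return SimConfig(leaf_noise_sd_mm=0.0, gantry_noise_sd_deg=0.0)


@pytest.fixture
def rect_plan(geometry40):
    return make_fixture_plan("rect_field", geometry40)


@pytest.fixture
def prostate_plan():
    return make_fixture_plan("prostate_like", seed=7)


@pytest.fixture
def prostate_log(prostate_plan, zero_noise):
    return simulate_delivery(prostate_plan, zero_noise)
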