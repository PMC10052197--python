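import numpy as np
import pytest
from scipy.constants import c as C_LIGHT

from radarvitals import simulate as sim


@pytest.fixture(scope="session")
def radar_config() -> sim.RadarConfig:
    """Default radar with a couple of static reflectors."""
    return sim.RadarConfig(
        clutter=[(1.5, 2 * 0.8 / C_LIGHT), (0.9, 2 * 2.4 / C_LIGHT)],
        noise_sd=0.02,
    )


@pytest.fixture(scope="session")
def quadrature_scenario(radar_config) -> sim.VitalScenario:
    """Constant-rate subject at a carrier-quadrature distance (maximum
    first-order amplitude sensitivity to chest displacement)."""
    d0 = sim.quadrature_distance(radar_config, 1.0)
    return sim.VitalScenario(
        duration=120.0, d0=d0, mr=5e-3, fr_trace=0.3, mh=4e-4, fh_trace=1.2, seed=7
    )


@pytest.fixture(scope="session")
def clean_recording(quadrature_scenario, radar_config):
    """120 s noise-bearing rendering with known constant rates."""
    return sim.render_recording(quadrature_scenario, radar_config)
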