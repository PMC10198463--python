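import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ramancode as rc
from ramancode.simulate import diagonal_codes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return rc.default_scheme()


@pytest.fixture(scope="session")
def cfg(scheme):
    return rc.SimulationConfig(scheme=scheme)


@pytest.fixture(scope="session")
def quiet_cfg(scheme):
    """Default config with all noise sources off."""
    return rc.SimulationConfig(scheme=scheme, noise=rc.NoiseModel(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def noise_free_calibration(cfg, scheme):
    """Calibration from one noise-free standard per level (diagonal codes)."""
    standards = rc.simulate_standards(
        cfg, replicates_per_code=1, codes=diagonal_codes(scheme), noise=False
    )
    return rc.calibrate_levels(standards, scheme)


@pytest.fixture(scope="session")
def noisy_calibration(cfg, scheme):
    """Calibration from 5 noisy replicates per level, as in practice."""
    standards = rc.simulate_standards(
        cfg, replicates_per_code=5, codes=diagonal_codes(scheme), rng=20011
    )
    return rc.calibrate_levels(standards, scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
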