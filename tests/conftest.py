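import numpy as np
import pytest

from cellmech import AcquisitionSettings, CantileverCalibration


@pytest.fixture(scope="session")
def calib():
    """Mid-range soft-cantilever calibration."""
    return CantileverCalibration(sensitivity_nm_per_V=15.2,
                                 spring_constant_pN_per_nm=18.0,
                                 alpha_deg=18.0, nu=0.5)


@pytest.fixture(scope="session")
def acq():
    """Default force-mapping acquisition (1 nN, 15 um at 30 um/s, 2 kHz)."""
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def acq4():
    """Small 4x4 grid for map-level tests."""
    return AcquisitionSettings(grid_points=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
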