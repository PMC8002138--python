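import numpy as np
import pytest

import retmorph as rm


@pytest.fixture
def control_phantom_spec() -> rm.VesselPhantomSpec:
    """Phantom with the control-group mean geometry, blurred and noisy."""
    return rm.VesselPhantomSpec(
        raod_um=130.71, rald_um=97.21, psf_sigma_um=4.0, noise_sd=100.0 / 33.0
    )


@pytest.fixture
def clean_phantom() -> tuple:
    """Noise-free, blur-free phantom with round-number geometry."""
    spec = rm.VesselPhantomSpec(
        raod_um=130.0, rald_um=97.0, psf_sigma_um=0.0, noise_sd=0.0
    )
    profile, truth = rm.generate_vessel_profile(spec, seed=0)
    return spec, profile, truth


@pytest.fixture
def walls_bright_config() -> rm.DensitometryConfig:
    return rm.DensitometryConfig(polarity="walls-bright")


@pytest.fixture
def unit_calibration() -> rm.ScaleCalibration:
    """200 px per 200 µm, i.e. 1 µm per pixel."""
    return rm.calibrate_scale(200.0)


def random_diameter_pairs(rng: np.random.Generator, n: int) -> np.ndarray:
    """Valid (raod, rald) pairs spanning realistic arteriolar geometry."""
    rald = rng.uniform(40.0, 140.0, n)
    awt = rng.uniform(2.0, 40.0, n)
    return np.column_stack([rald + 2 * awt, rald])
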