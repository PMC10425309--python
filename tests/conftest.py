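import numpy as np
import pytest

from mpitrack import ScanConfig, run_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small cubic FOV for fast unit tests; PSF support fits inside."""
    # PSF support (3 x FWHM + blob extent) must stay well under half of each
    # Y slab for the joint gauge anchor's background assumption to hold.
    return ScanConfig(
        fov_z_mm=24.0, fov_x_mm=24.0, fov_y_mm=24.0, fov_center_z_mm=0.0,
        voxel_mm=1.0, psf_fwhm_mm=2.0,
        noise_abs_sd=0.0, noise_rel_coeff=0.0, name="tiny",
    )


@pytest.fixture(scope="session")
def tiny_noisy_config(tiny_config):
    from dataclasses import replace

    return replace(tiny_config, noise_abs_sd=0.05, noise_rel_coeff=0.002, name="tinyn")


@pytest.fixture(scope="session")
def focused_config():
    return ScanConfig.focused_fov()


@pytest.fixture(scope="session")
def full_config():
    return ScanConfig.full_fov()


@pytest.fixture(scope="session")
def default_cohort():
    """One shared 6-mouse cohort under study-default conditions (seed 7)."""
    return run_cohort(6, [3e5, 5e5], master_seed=7, include_day0=False)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
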