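import pytest

from ctpos.synthetic_data import (
    AcquisitionSpec,
    TerritorySpec,
    centered_nucleus,
    simulate_cell,
)


@pytest.fixture
def coarse_acq():
    """Fast, coarse calibration for unit tests (noise on)."""
    return AcquisitionSpec(
        voxel_size_um=(0.4, 0.2, 0.2),
        psf_sigma_um=(0.3, 0.15, 0.15),
        seed=11,
    )


@pytest.fixture
def noiseless_acq():
    """Deterministic rendering: no PSF, no shot/read noise."""
    return AcquisitionSpec(
        voxel_size_um=(0.4, 0.2, 0.2),
        psf_sigma_um=(0.0, 0.0, 0.0),
        read_noise_sd=0.0,
        shot_noise=False,
        seed=11,
    )


@pytest.fixture
def small_cell(coarse_acq):
    """One noisy cell: spherical-ish nucleus, a 2-copy territory channel."""
    nucleus, shape = centered_nucleus((3.0, 3.6, 3.4), coarse_acq)
    territories = [
        TerritorySpec("CT19", 0.5, (0.0, 0.0, 1.0), copy_index=1),
        TerritorySpec("CT19", 0.6, (0.0, -1.0, 0.0), copy_index=2),
    ]
    stack, truth = simulate_cell(
        nucleus, territories, coarse_acq, lamina_thickness_um=0.5, shape=shape
    )
    return stack, truth, nucleus
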