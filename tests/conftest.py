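import numpy as np
import pytest

from phasorsnap import (
    CameraModel,
    Fluorophore,
    WavelengthGrid,
    gaussian_spectrum,
    ideal_filter,
    spectrum_phasor,
)

# Synthetic stand-ins for the six reference dye solutions: Gaussian bands
# spanning the blue-to-red detection range with realistic widths.
SIX_DYES = [
    Fluorophore("NADH", peak=460.0, fwhm=90.0),
    Fluorophore("FAD", peak=535.0, fwhm=70.0),
    Fluorophore("Rhodamine110", peak=525.0, fwhm=35.0),
    Fluorophore("Rhodamine6G", peak=555.0, fwhm=40.0),
    Fluorophore("TAMRA", peak=580.0, fwhm=45.0),
    Fluorophore("Alexa594", peak=617.0, fwhm=50.0),
]


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid(400.0, 700.0, 300)


@pytest.fixture(scope="session")
def fine_grid():
    """10x resolution grid for independent quadrature oracles."""
    return WavelengthGrid(400.0, 700.0, 3000)


@pytest.fixture(scope="session")
def sine_filter(grid):
    return ideal_filter("sine", grid)


@pytest.fixture(scope="session")
def cosine_filter(grid):
    return ideal_filter("cosine", grid)


@pytest.fixture(scope="session")
def six_dyes():
    return SIX_DYES


@pytest.fixture
def camera():
    return CameraModel(offset=100.0, seed=42)


@pytest.fixture
def noiseless_camera():
    return CameraModel(offset=100.0, seed=0)


def dye_phasor(fluor, grid):
    return spectrum_phasor(gaussian_spectrum(fluor, grid))
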