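"""Forward model of the three-exposure snapshot acquisition on synthetic phantoms.

A scene is a 3-D label field over voxels; each label carries a fluorophore
mixture and each voxel a brightness (photon budget multiplier).  Rendering
integrates the voxel's mixed emission spectrum against each filter's
transmission to get expected photon counts, then applies shot noise, camera
gain and offset, Gaussian read noise, and hot pixels.  The same machinery
renders a multichannel spectral stack (the conventional hyperspectral
detection path) for cross-validation against the filter path.

Axis order is ``(z, y, x)`` with 0-based indexing throughout, matching
plane-by-plane acquisition and multi-page TIFF layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectral import (
    EmissionSpectrum,
    FilterCurve,
    Fluorophore,
    WavelengthGrid,
    gaussian_spectrum,
    mix_spectra,
)

__all__ = [
    "CameraModel",
    "ScenePhantom",
    "TripletStack",
    "render_triplet",
    "render_spectral_stack",
    "make_uniform_phantom",
    "make_layered_phantom",
    "make_gradient_phantom",
    "DEFAULT_PHOTONS",
]

# Default expected photon count per voxel per exposure for a brightness-1 voxel
# in the phantom builders.  A fixture choice representative of a bright,
# well-exposed sCMOS acquisition.
DEFAULT_PHOTONS = 1.0e4


@dataclass(frozen=True)
class CameraModel:
    """Detector model: offset, gain, read noise, and hot pixels.

    ``offset`` is the additive electronic baseline b that the phasor transform
    subtracts before forming ratios.  Hot pixels are planted independently per
    channel because the three exposures are distinct camera frames (filter
    wheel acquisition).  One seed drives every stochastic element so a full
    simulation is reproducible.
    """

    offset: float = 100.0
    gain: float = 1.0
    read_noise_sd: float = 0.0
    hot_pixel_rate: float = 0.0
    hot_pixel_value: float = 4095.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if not 0 <= self.hot_pixel_rate < 1:
            raise ValueError("hot_pixel_rate must be in [0, 1)")


@dataclass
class ScenePhantom:
    """Synthetic 3-D scene: label field + per-label composition + brightness.

    ``composition`` maps each label to a list of ``(Fluorophore,
    concentration)`` pairs; the label's emission spectrum is the
    concentration-weighted sum of the (truncated) Gaussian bands.
    ``brightness`` scales each voxel's expected photon count.
    """

    shape: tuple[int, int, int]
    labels: np.ndarray
    composition: Mapping[int, Sequence[tuple[Fluorophore, float]]]
    brightness: np.ndarray
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.brightness = np.asarray(self.brightness, dtype=float)
        if self.labels.shape != tuple(self.shape):
            raise ValueError("labels shape does not match scene shape")
        if self.brightness.shape != tuple(self.shape):
            raise ValueError("brightness shape does not match scene shape")
        if np.any(self.brightness < 0):
            raise ValueError("brightness must be nonnegative")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.composition)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from composition map")

    def label_spectrum(self, label: int) -> EmissionSpectrum:
        """Mixed emission spectrum (per unit brightness) for one label."""
        parts = self.composition[label]
        if not parts:
            # empty composition = dark label
            return EmissionSpectrum(self.grid, np.zeros(self.grid.n_samples))
        spectra = [gaussian_spectrum(fl, self.grid, conc) for fl, conc in parts]
        return mix_spectra(spectra, np.ones(len(spectra)))

    def label_spectra(self) -> dict[int, np.ndarray]:
        out = {}
        for label in np.unique(self.labels):
            label = int(label)
            parts = self.composition[label]
            if parts:
                out[label] = self.label_spectrum(label).intensity
            else:
                out[label] = np.zeros(self.grid.n_samples)
        return out


@dataclass
class TripletStack:
    """Co-registered sine / cosine / open-channel recordings of one scene."""

    I_sin: np.ndarray
    I_cos: np.ndarray
    I_total: np.ndarray
    camera: CameraModel
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        if not (self.I_sin.shape == self.I_cos.shape == self.I_total.shape):
            raise ValueError("triplet channel shapes must match")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.I_total.shape


def _record_channel(expected: np.ndarray, camera: CameraModel, rng: np.random.Generator) -> np.ndarray:
    """One noisy camera exposure from expected photon counts."""
    counts = rng.poisson(expected).astype(float)
    out = camera.gain * counts + camera.offset
    if camera.read_noise_sd > 0:
        out = out + rng.normal(0.0, camera.read_noise_sd, size=out.shape)
    if camera.hot_pixel_rate > 0:
        hot = rng.random(out.shape) < camera.hot_pixel_rate
        out[hot] = camera.hot_pixel_value
    return np.maximum(out, 0.0)


def _expected_photons(scene: ScenePhantom, transmissions: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Expected photons per voxel per channel, via per-label rates."""
    spectra = scene.label_spectra()
    out = []
    for T in transmissions:
        rates = {label: float(np.dot(spec, T)) for label, spec in spectra.items()}
        rate_map = np.zeros(scene.shape)
        for label, rate in rates.items():
            rate_map[scene.labels == label] = rate
        out.append(scene.brightness * rate_map)
    return out


def render_triplet(
    scene: ScenePhantom,
    sine: FilterCurve,
    cosine: FilterCurve,
    camera: CameraModel,
    noiseless: bool = False,
) -> TripletStack:
    """Render the three-exposure acquisition: sine filter, cosine filter, open.

    The open channel uses unit transmission across the grid (the fixed
    detection bandpass).  With ``noiseless=True`` the recorded value is
    exactly ``gain * expected_photons + offset`` per voxel.
    """
    if sine.grid != scene.grid or cosine.grid != scene.grid:
        raise ValueError("filter grids must match the scene grid")
    T_open = np.ones(scene.grid.n_samples)
    expected = _expected_photons(scene, [sine.transmission, cosine.transmission, T_open])
    if noiseless:
        channels = [camera.gain * e + camera.offset for e in expected]
    else:
        rng = np.random.default_rng(camera.seed)
        channels = [_record_channel(e, camera, rng) for e in expected]
    return TripletStack(
        I_sin=channels[0], I_cos=channels[1], I_total=channels[2],
        camera=camera, grid=scene.grid,
    )


def spectral_channel_centers(grid: WavelengthGrid, n_channels: int) -> np.ndarray:
    """Center wavelengths of ``n_channels`` equal bins spanning the grid."""
    width = grid.span / n_channels
    return grid.lambda_min + (np.arange(n_channels) + 0.5) * width


def render_spectral_stack(
    scene: ScenePhantom,
    n_channels: int,
    camera: CameraModel,
    noiseless: bool = False,
) -> np.ndarray:
    """Render a conventional multichannel spectral acquisition.

    Photons are integrated over ``n_channels`` equal wavelength bins spanning
    the grid; each channel receives the same per-exposure noise model as the
    filter path.  Returns an array of shape ``(n_channels, nz, ny, nx)``
    (channel-major, matching the channel-major multi-page TIFF layout).
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    width = scene.grid.span / n_channels
    # assign each grid sample to the channel bin containing its center
    assignment = np.floor(
        (scene.grid.wavelengths - scene.grid.lambda_min) / width
    ).astype(int)
    assignment = np.clip(assignment, 0, n_channels - 1)
    transmissions = [(assignment == c).astype(float) for c in range(n_channels)]
    expected = _expected_photons(scene, transmissions)
    if noiseless:
        channels = [camera.gain * e + camera.offset for e in expected]
    else:
        rng = np.random.default_rng(camera.seed)
        channels = [_record_channel(e, camera, rng) for e in expected]
    return np.stack(channels, axis=0)


def _intensity_normalized(fluor: Fluorophore, grid: WavelengthGrid) -> tuple[Fluorophore, float]:
    """Concentration that makes the truncated band integrate to 1."""
    total = gaussian_spectrum(fluor, grid).total
    return fluor, 1.0 / total


def _fraction_composition(
    fractions: Sequence[tuple[Fluorophore, float]], grid: WavelengthGrid
) -> list[tuple[Fluorophore, float]]:
    """Convert (fluorophore, intensity fraction) pairs into concentrations.

    The resulting label spectrum integrates to 1 with exactly the requested
    intensity fractions after detection-range truncation, so a brightness of
    N photons yields N expected open-channel photons split as programmed.
    """
    out = []
    for fluor, frac in fractions:
        if frac < 0:
            raise ValueError("intensity fractions must be nonnegative")
        if frac == 0:
            continue
        _, unit_conc = _intensity_normalized(fluor, grid)
        out.append((fluor, frac * unit_conc))
    return out


def make_uniform_phantom(
    composition: Sequence[tuple[Fluorophore, float]],
    shape: tuple[int, int, int] = (4, 16, 16),
    grid: WavelengthGrid | None = None,
    photons: float = DEFAULT_PHOTONS,
) -> ScenePhantom:
    """Homogeneous scene of one mixture, given as intensity fractions."""
    grid = grid or WavelengthGrid()
    return ScenePhantom(
        shape=shape,
        labels=np.zeros(shape, dtype=int),
        composition={0: _fraction_composition(composition, grid)},
        brightness=np.full(shape, float(photons)),
        grid=grid,
    )


def make_layered_phantom(
    layers: Sequence[tuple[int, Sequence[tuple[Fluorophore, float]]]],
    ny: int = 16,
    nx: int = 16,
    grid: WavelengthGrid | None = None,
    photons: float = DEFAULT_PHOTONS,
) -> ScenePhantom:
    """Axial stack of homogeneous layers, each ``(thickness_in_z, fractions)``.

    Emulates stratified tissue (e.g. retinal cell layers) where each stratum
    carries its own fluorophore mixture.
    """
    if not layers:
        raise ValueError("need at least one layer")
    grid = grid or WavelengthGrid()
    thicknesses = [t for t, _ in layers]
    if any(t <= 0 for t in thicknesses):
        raise ValueError("layer thickness must be positive")
    nz = sum(thicknesses)
    labels = np.zeros((nz, ny, nx), dtype=int)
    z0 = 0
    composition = {}
    for i, (t, fractions) in enumerate(layers):
        labels[z0 : z0 + t] = i
        composition[i] = _fraction_composition(fractions, grid)
        z0 += t
    return ScenePhantom(
        shape=(nz, ny, nx),
        labels=labels,
        composition=composition,
        brightness=np.full((nz, ny, nx), float(photons)),
        grid=grid,
    )


def make_gradient_phantom(
    axis: str = "z",
    t_start: float = 0.2,
    t_end: float = 0.8,
    endpoint_fluors: tuple[Fluorophore, Fluorophore] | None = None,
    shape: tuple[int, int, int] = (16, 16, 16),
    grid: WavelengthGrid | None = None,
    photons: float = DEFAULT_PHOTONS,
) -> ScenePhantom:
    """Two-fluorophore scene with a linear intensity-fraction ramp along one axis.

    Slice ``i`` along ``axis`` carries intensity fraction ``t_i`` of the first
    endpoint fluorophore, with ``t_i`` running linearly from ``t_start`` to
    ``t_end``.  Emulates, e.g., an axial metabolic gradient along a crypt.
    """
    if axis not in ("z", "y", "x"):
        raise ValueError(f"axis must be 'z', 'y' or 'x', got {axis!r}")
    if not (0 <= t_start <= 1 and 0 <= t_end <= 1):
        raise ValueError("t_start and t_end must be in [0, 1]")
    grid = grid or WavelengthGrid()
    if endpoint_fluors is None:
        endpoint_fluors = (
            Fluorophore("A", peak=460.0, fwhm=60.0),
            Fluorophore("B", peak=560.0, fwhm=50.0),
        )
    fa, fb = endpoint_fluors
    ax = "zyx".index(axis)
    n = shape[ax]
    ts = np.full(n, t_start) if n == 1 else np.linspace(t_start, t_end, n)
    labels = np.zeros(shape, dtype=int)
    idx = [None, None, None]
    composition = {}
    for i, t in enumerate(ts):
        idx[ax] = i
        sl = tuple(slice(None) if j is None else j for j in idx)
        labels[sl] = i
        composition[i] = _fraction_composition([(fa, float(t)), (fb, float(1 - t))], grid)
    return ScenePhantom(
        shape=shape,
        labels=labels,
        composition=composition,
        brightness=np.full(shape, float(photons)),
        grid=grid,
    )


def gradient_fractions(axis: str, n: int, t_start: float, t_end: float) -> np.ndarray:
    """Programmed per-slice fractions of :func:`make_gradient_phantom`."""
    return np.full(n, t_start) if n == 1 else np.linspace(t_start, t_end, n)
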