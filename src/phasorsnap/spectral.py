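"""Wavelength grids, emission spectra, filter transmission curves, and the
reference spectral phasor transform.

The spectral phasor maps an emission spectrum :math:`I(\\lambda)` recorded on a
detection range :math:`[\\lambda_{min}, \\lambda_{max}]` to a point in the unit
disk via its first-harmonic Fourier projections,

.. math::

    G = \\frac{\\sum_\\lambda I(\\lambda)\\cos\\theta(\\lambda)}
              {\\sum_\\lambda I(\\lambda)}, \\qquad
    S = \\frac{\\sum_\\lambda I(\\lambda)\\sin\\theta(\\lambda)}
              {\\sum_\\lambda I(\\lambda)},

with the phase axis :math:`\\theta(\\lambda) = 2\\pi(\\lambda -
\\lambda_{min})/(\\lambda_{max}-\\lambda_{min})` wrapping one full period
across the detection range.  The angular coordinate (phase) encodes the
spectral center of mass; the radial coordinate (modulation) shrinks as the
spectrum broadens.  Because the transform is linear in the spectrum, the
phasor of a mixture is the intensity-fraction-weighted convex combination of
the component phasors — the rule of linear addition that underlies every
fit-free analysis in this package.

Sine/cosine interference filters realize this transform in hardware: a filter
whose transmission follows one raised sine (or cosine) period across the
detection range records an intensity whose ratio to the unfiltered intensity
encodes S (or G) directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "WavelengthGrid",
    "EmissionSpectrum",
    "FilterCurve",
    "Fluorophore",
    "PhasorPoint",
    "PhaseModulation",
    "phase_axis",
    "ideal_filter",
    "minimum_transmission_phase",
    "gaussian_spectrum",
    "mix_spectra",
    "spectrum_phasor",
    "phase_modulation",
    "wavelength_to_phase",
    "phase_to_wavelength",
]

FilterKind = Literal["sine", "cosine"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform sampling of the detection range that defines the phase axis.

    Samples sit at bin centers, ``lambda_min + (k + 0.5) * delta`` with
    ``delta = (lambda_max - lambda_min) / n_samples``.  The bin-center
    convention makes the full-period sums ``sum(cos theta)`` and
    ``sum(sin theta)`` vanish exactly, so a flat spectrum maps to the phasor
    origin with no discretization residue.
    """

    lambda_min: float = 400.0
    lambda_max: float = 700.0
    n_samples: int = 300

    def __post_init__(self) -> None:
        if not self.lambda_min < self.lambda_max:
            raise ValueError(
                f"lambda_min ({self.lambda_min}) must be < lambda_max ({self.lambda_max})"
            )
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")

    @property
    def span(self) -> float:
        return self.lambda_max - self.lambda_min

    @property
    def delta(self) -> float:
        """Bin width in nm."""
        return self.span / self.n_samples

    @property
    def wavelengths(self) -> np.ndarray:
        """Bin-center wavelengths, shape ``(n_samples,)``."""
        k = np.arange(self.n_samples)
        return self.lambda_min + (k + 0.5) * self.delta

    @property
    def bin_edges(self) -> np.ndarray:
        return self.lambda_min + np.arange(self.n_samples + 1) * self.delta

    @property
    def phases(self) -> np.ndarray:
        """Phase axis theta at the bin centers, in radians in (0, 2*pi)."""
        return phase_axis(self)


def phase_axis(grid: WavelengthGrid) -> np.ndarray:
    """Per-sample phase ``theta = 2*pi*(lambda - lambda_min)/span`` at bin centers."""
    return wavelength_to_phase(grid.wavelengths, grid)


def wavelength_to_phase(wavelength, grid: WavelengthGrid):
    """Map wavelength (nm) to phase (radians) on the grid's single-period axis."""
    return 2.0 * np.pi * (np.asarray(wavelength, dtype=float) - grid.lambda_min) / grid.span


def phase_to_wavelength(phase, grid: WavelengthGrid):
    """Inverse of :func:`wavelength_to_phase`."""
    return grid.lambda_min + np.asarray(phase, dtype=float) / (2.0 * np.pi) * grid.span


@dataclass(frozen=True)
class Fluorophore:
    """A fluorescent species modeled by a Gaussian emission band.

    ``brightness`` is the relative photon yield per unit concentration; it
    scales the integral of the emission spectrum before truncation to the
    detection range.
    """

    name: str
    peak: float
    fwhm: float
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.brightness < 0:
            raise ValueError(f"brightness must be >= 0, got {self.brightness}")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Nonnegative intensity tabulated on a :class:`WavelengthGrid`."""

    grid: WavelengthGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (self.grid.n_samples,):
            raise ValueError(
                f"intensity shape {arr.shape} does not match grid n_samples {self.grid.n_samples}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensity must be finite")
        if np.any(arr < 0):
            raise ValueError("intensity must be nonnegative")
        object.__setattr__(self, "intensity", arr)

    @property
    def total(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class FilterCurve:
    """Transmission in [0, 1] tabulated on a :class:`WavelengthGrid`.

    When the curve is an analytic raised sinusoid, ``kind``, ``offset`` and
    ``amplitude`` record the descriptor ``T(theta) = offset +
    amplitude * sin(theta)`` (or cos); they are ``None`` for measured curves.
    """

    grid: WavelengthGrid
    transmission: np.ndarray
    kind: FilterKind | None = None
    offset: float | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.transmission, dtype=float)
        if arr.shape != (self.grid.n_samples,):
            raise ValueError(
                f"transmission shape {arr.shape} does not match grid n_samples {self.grid.n_samples}"
            )
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("transmission must lie in [0, 1]")
        object.__setattr__(self, "transmission", np.clip(arr, 0.0, 1.0))

    def evaluate(self, phase) -> np.ndarray:
        """Transmission at arbitrary phase (radians); analytic curves only."""
        if self.kind is None:
            raise ValueError("evaluate() requires an analytic sinusoid descriptor")
        trig = np.sin if self.kind == "sine" else np.cos
        return self.offset + self.amplitude * trig(np.asarray(phase, dtype=float))


def ideal_filter(
    kind: FilterKind,
    grid: WavelengthGrid,
    offset: float = 0.5,
    amplitude: float = 0.5,
) -> FilterCurve:
    """Raised sine/cosine filter ``T = offset + amplitude * sin/cos(theta)``.

    With the default ``offset = amplitude = 0.5`` the sine filter reaches its
    zero minimum at phase 270 deg and the cosine filter at 180 deg, matching
    the single-period design over the detection range.

    Raises
    ------
    ValueError
        If the transmission would leave [0, 1] (requires ``offset - amplitude
        >= 0`` and ``offset + amplitude <= 1``) or ``amplitude <= 0``.
    """
    if kind not in ("sine", "cosine"):
        raise ValueError(f"kind must be 'sine' or 'cosine', got {kind!r}")
    if amplitude <= 0:
        raise ValueError(f"amplitude must be > 0, got {amplitude}")
    if offset - amplitude < -1e-12 or offset + amplitude > 1 + 1e-12:
        raise ValueError(
            f"infeasible filter: offset={offset}, amplitude={amplitude} leaves [0, 1]"
        )
    theta = phase_axis(grid)
    trig = np.sin if kind == "sine" else np.cos
    return FilterCurve(
        grid=grid,
        transmission=offset + amplitude * trig(theta),
        kind=kind,
        offset=offset,
        amplitude=amplitude,
    )


def minimum_transmission_phase(curve: FilterCurve) -> float:
    """Phase (radians, in [0, 2*pi)) at which transmission is minimal.

    Dense sampling of the curve brackets the minimum; a bounded scalar
    minimisation refines it.  Analytic curves are evaluated continuously;
    measured curves fall back to the tabulated samples with parabolic
    refinement between neighbours.
    """
    if curve.kind is not None:
        thetas = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
        values = curve.evaluate(thetas)
        k = int(np.argmin(values))
        lo = thetas[max(k - 1, 0)]
        hi = thetas[min(k + 1, len(thetas) - 1)]
        res = optimize.minimize_scalar(
            lambda t: float(curve.evaluate(t)), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        return float(res.x) % (2.0 * np.pi)
    theta = phase_axis(curve.grid)
    k = int(np.argmin(curve.transmission))
    if 0 < k < len(theta) - 1:
        # parabola through the three samples around the discrete minimum
        y0, y1, y2 = curve.transmission[k - 1 : k + 2]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        return float(theta[k] + shift * (theta[1] - theta[0])) % (2.0 * np.pi)
    return float(theta[k])


def gaussian_spectrum(fluor: Fluorophore, grid: WavelengthGrid, concentration: float = 1.0) -> EmissionSpectrum:
    """Gaussian emission band integrated over the grid bins.

    Out-of-range emission is silently truncated (no renormalisation): the
    detection bandpass physically discards light outside the grid, which
    shifts the apparent center of mass of red- or blue-edge emitters exactly
    as a real truncated detection range does.

    Raises
    ------
    ValueError
        If the band lies entirely outside the grid (zero total intensity).
    """
    sigma = fluor.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    edges = grid.bin_edges
    cdf = norm.cdf(edges, loc=fluor.peak, scale=sigma)
    mass = np.diff(cdf)  # exact per-bin integral of the unit Gaussian
    intensity = fluor.brightness * concentration * mass
    if intensity.sum() <= 0:
        raise ValueError(
            f"fluorophore {fluor.name!r} (peak {fluor.peak} nm) has no emission inside "
            f"[{grid.lambda_min}, {grid.lambda_max}] nm"
        )
    return EmissionSpectrum(grid=grid, intensity=intensity)


def mix_spectra(spectra: Sequence[EmissionSpectrum], weights: Sequence[float]) -> EmissionSpectrum:
    """Pointwise weighted sum of spectra sharing one grid."""
    if len(spectra) != len(weights):
        raise ValueError("spectra and weights must have equal length")
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("at least one weight must be positive")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("all spectra must share one WavelengthGrid")
    intensity = np.zeros(grid.n_samples)
    for wi, s in zip(w, spectra):
        intensity += wi * s.intensity
    return EmissionSpectrum(grid=grid, intensity=intensity)


@dataclass(frozen=True)
class PhasorPoint:
    """A point (G, S) on the spectral phasor plot."""

    G: float
    S: float

    def __iter__(self):
        return iter((self.G, self.S))

    @property
    def modulation(self) -> float:
        return float(np.hypot(self.G, self.S))


def spectrum_phasor(spec: EmissionSpectrum) -> PhasorPoint:
    """First-harmonic phasor coordinates of an emission spectrum.

    Raises
    ------
    ValueError
        If the spectrum has zero total intensity (phasor undefined).
    """
    total = spec.total
    if total <= 0:
        raise ValueError("phasor undefined for zero-total spectrum")
    theta = phase_axis(spec.grid)
    g = float(np.dot(spec.intensity, np.cos(theta)) / total)
    s = float(np.dot(spec.intensity, np.sin(theta)) / total)
    return PhasorPoint(G=g, S=s)


@dataclass(frozen=True)
class PhaseModulation:
    """Polar phasor coordinates plus the equivalent spectral center wavelength.

    ``phase`` is NaN (scalar) or NaN-filled (array) where (G, S) = (0, 0);
    modulation is always defined.
    """

    phase: float | np.ndarray
    modulation: float | np.ndarray
    center_wavelength: float | np.ndarray


def phase_modulation(point, grid: WavelengthGrid) -> PhaseModulation:
    """Polar decomposition of phasor coordinates.

    Parameters
    ----------
    point
        A :class:`PhasorPoint` or a ``(G, S)`` pair of scalars/arrays.
    grid
        Detection grid defining the phase-to-wavelength mapping.
    """
    if isinstance(point, PhasorPoint):
        g, s = point.G, point.S
    else:
        g, s = point
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    modulation = np.hypot(g, s)
    phase = np.mod(np.arctan2(s, g), 2.0 * np.pi)
    undefined = modulation == 0
    phase = np.where(undefined, np.nan, phase)
    center = phase_to_wavelength(phase, grid)
    if phase.ndim == 0:
        return PhaseModulation(float(phase), float(modulation), float(center))
    return PhaseModulation(phase, modulation, center)
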