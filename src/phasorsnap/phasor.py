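"""The in-hardware phasor transform with filter calibration, preprocessing,
and phasor histograms.

Per voxel, the recorded sine/cosine/open intensity triplet maps to phasor
coordinates

.. math::

    G = \\frac{1}{m_c}\\left(\\frac{I_{cos} - b}{I_{total} - b} - o_c\\right),
    \\qquad
    S = \\frac{1}{m_s}\\left(\\frac{I_{sin} - b}{I_{total} - b} - o_s\\right),

where ``b`` is the camera offset and ``(o, m)`` the offset/amplitude of each
filter's raised-sinusoid transmission.  The default calibration ``o = m =
0.5`` gives the familiar form ``G = 2((I_cos - b)/(I_total - b) - 0.5)``.
Filters manufactured with a nonzero transmission floor shift the coordinates;
:func:`fit_calibration` recovers ``(o, m)`` from a measured transmission
curve so the shift can be corrected.

Voxels whose offset-subtracted total intensity falls at or below an intensity
threshold carry no usable signal (the ratio of two near-zero numbers is
noise) and are masked out rather than clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .simulate import TripletStack
from .spectral import FilterCurve, WavelengthGrid, phase_axis, wavelength_to_phase
from .simulate import spectral_channel_centers

__all__ = [
    "FilterCalibration",
    "FilterFit",
    "PhasorField",
    "PhasorHistogram",
    "triplet_to_phasor",
    "spectral_stack_to_phasor",
    "median3",
    "bin2",
    "phasor_histogram",
    "fit_calibration",
    "DEFAULT_THRESHOLD",
    "HISTOGRAM_BINS",
]

# Default intensity threshold (a.u. above offset); sample-dependent values of
# 25-100 a.u. are typical, configurable per run.
DEFAULT_THRESHOLD = 50.0
HISTOGRAM_BINS = 256


@dataclass(frozen=True)
class FilterCalibration:
    """Offset/amplitude of the sine and cosine filter transmissions."""

    o_s: float = 0.5
    m_s: float = 0.5
    o_c: float = 0.5
    m_c: float = 0.5

    def __post_init__(self) -> None:
        if self.m_s <= 0 or self.m_c <= 0:
            raise ValueError("calibration amplitudes must be > 0")


@dataclass
class PhasorField:
    """Per-voxel (G, S) coordinates with a validity mask.

    Invalid voxels hold NaN in G and S and ``False`` in ``valid``; downstream
    operations must consult the mask.  Values outside the unit square are
    retained (noise can push estimates past the ideal bounds; clamping would
    bias statistics) — only histogram display clips.
    """

    G: np.ndarray
    S: np.ndarray
    valid: np.ndarray
    threshold: float
    offset: float
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def __post_init__(self) -> None:
        if not (self.G.shape == self.S.shape == self.valid.shape):
            raise ValueError("G, S and valid must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.G.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class PhasorHistogram:
    """2-D histogram of phasor coordinates on [-1, 1] x [-1, 1].

    ``counts[i, j]`` covers the i-th G bin and j-th S bin (left-closed,
    right-open; the last bin closed).  The display jitter applied before
    binning is recorded; jittered coordinates never feed quantitative
    analysis.  Jittered points leaving the unit square are dropped from
    ``counts`` but tallied in ``n_out_of_range`` so that ``counts.sum() +
    n_out_of_range`` equals the number of valid voxels.
    """

    counts: np.ndarray
    jitter_halfwidth: float
    seed: int
    n_out_of_range: int

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.counts.shape[0] + 1)


def triplet_to_phasor(
    triplet: TripletStack,
    offset: float | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    calibration: FilterCalibration | None = None,
) -> PhasorField:
    """Transform a recorded triplet to a per-voxel phasor field.

    Parameters
    ----------
    triplet
        Sine / cosine / open-channel stacks.
    offset
        Camera offset b subtracted from every channel; defaults to the value
        recorded in the triplet's camera metadata.
    threshold
        Voxels with ``I_total - b <= threshold`` are marked invalid.
    calibration
        Filter offset/amplitude; the default reproduces the ideal
        ``G = 2(ratio - 0.5)`` form.
    """
    if offset is None:
        offset = triplet.camera.offset
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cal = calibration or FilterCalibration()
    net_total = triplet.I_total - offset
    valid = net_total > threshold
    G = np.full(triplet.shape, np.nan)
    S = np.full(triplet.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_cos = (triplet.I_cos - offset) / net_total
        ratio_sin = (triplet.I_sin - offset) / net_total
    G[valid] = (ratio_cos[valid] - cal.o_c) / cal.m_c
    S[valid] = (ratio_sin[valid] - cal.o_s) / cal.m_s
    return PhasorField(G=G, S=S, valid=valid, threshold=threshold, offset=offset,
                       grid=triplet.grid)


def spectral_stack_to_phasor(
    stack: np.ndarray,
    grid: WavelengthGrid,
    offset: float = 0.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> PhasorField:
    """Computational phasor transform of a multichannel spectral stack.

    ``stack`` has shape ``(n_channels, nz, ny, nx)``; the offset-subtracted
    channel values are treated as a sampled spectrum with phases at the
    channel-bin centers.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_channels >= 2, nz, ny, nx)")
    n_channels = stack.shape[0]
    theta = wavelength_to_phase(spectral_channel_centers(grid, n_channels), grid)
    net = stack - offset
    total = net.sum(axis=0)
    valid = total > threshold
    G = np.full(stack.shape[1:], np.nan)
    S = np.full(stack.shape[1:], np.nan)
    cosw = np.cos(theta)[:, None, None, None]
    sinw = np.sin(theta)[:, None, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        g_all = (net * cosw).sum(axis=0) / total
        s_all = (net * sinw).sum(axis=0) / total
    G[valid] = g_all[valid]
    S[valid] = s_all[valid]
    return PhasorField(G=G, S=S, valid=valid, threshold=threshold, offset=offset,
                       grid=grid)


def median3(stack: np.ndarray) -> np.ndarray:
    """3x3 median within each z-plane, edge-reflected (symmetric) padding.

    Applied to the raw intensity stacks before the phasor division: hot and
    cold pixels corrupt the ratio nonlinearly, so they must be removed from
    the intensities, not from G/S.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return ndimage.median_filter(stack, size=(3, 3), mode="reflect")
    if stack.ndim != 3:
        raise ValueError("expected a 2-D plane or 3-D (z, y, x) stack")
    return ndimage.median_filter(stack, size=(1, 3, 3), mode="reflect")


def bin2(stack: np.ndarray) -> np.ndarray:
    """2x2 binning in (y, x): each output value is the sum of a 2x2 block.

    Summing (not averaging) preserves photon statistics.  An odd trailing row
    or column is dropped with a warning.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D (z, y, x) stack")
    nz, ny, nx = stack.shape
    if ny % 2 or nx % 2:
        warnings.warn(
            f"bin2: dropping odd trailing row/column of ({ny}, {nx}) plane",
            stacklevel=2,
        )
        stack = stack[:, : ny - ny % 2, : nx - nx % 2]
        nz, ny, nx = stack.shape
    return stack.reshape(nz, ny // 2, 2, nx // 2, 2).sum(axis=(2, 4))


def _bin_index(values: np.ndarray, bins: int) -> np.ndarray:
    """Left-closed right-open bins on [-1, 1]; value exactly 1 joins the last bin."""
    idx = np.floor((values + 1.0) * (bins / 2.0)).astype(int)
    idx[values == 1.0] = bins - 1
    return idx


def phasor_histogram(
    f: PhasorField,
    jitter_halfwidth: float = 0.02,
    seed: int = 0,
    bins: int = HISTOGRAM_BINS,
    mask: np.ndarray | None = None,
) -> PhasorHistogram:
    """2-D histogram of the valid voxels' phasor coordinates.

    A uniform display jitter in ``[-jitter_halfwidth, +jitter_halfwidth]`` is
    added independently to G and S before binning to break up the banding
    artifacts that quantised coordinates produce in a 2-D histogram.  The
    jitter is display-only; no quantitative operation consumes jittered
    coordinates.
    """
    if jitter_halfwidth < 0:
        raise ValueError("jitter_halfwidth must be >= 0")
    select = f.valid if mask is None else (f.valid & np.asarray(mask, dtype=bool))
    g = f.G[select]
    s = f.S[select]
    if jitter_halfwidth > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.uniform(-jitter_halfwidth, jitter_halfwidth, size=g.shape)
        s = s + rng.uniform(-jitter_halfwidth, jitter_halfwidth, size=s.shape)
    in_range = (g >= -1.0) & (g <= 1.0) & (s >= -1.0) & (s <= 1.0)
    n_out = int((~in_range).sum())
    gi = _bin_index(g[in_range], bins)
    si = _bin_index(s[in_range], bins)
    counts = np.zeros((bins, bins), dtype=np.int64)
    np.add.at(counts, (gi, si), 1)
    return PhasorHistogram(counts=counts, jitter_halfwidth=jitter_halfwidth,
                           seed=seed, n_out_of_range=n_out)


@dataclass(frozen=True)
class FilterFit:
    """Least-squares raised-sinusoid fit to a measured filter transmission."""

    kind: str
    offset: float
    amplitude: float
    residual: float


def fit_calibration(measured: FilterCurve, kind: str | None = None) -> FilterFit:
    """Fit ``o + m * sin(theta)`` (or cos) to a measured transmission curve.

    Used to calibrate real filters whose minima sit above zero (e.g. a 5-10%
    transmission floor): transforming with the fitted ``(o, m)`` instead of
    the ideal 0.5/0.5 removes the phasor-coordinate shift such filters cause.

    Raises
    ------
    ValueError
        If the fitted amplitude is not positive (curve is not a usable
        sinusoid of the requested kind).
    """
    kind = kind or measured.kind
    if kind not in ("sine", "cosine"):
        raise ValueError("kind must be 'sine' or 'cosine' (pass explicitly for measured curves)")
    theta = phase_axis(measured.grid)
    basis = np.sin(theta) if kind == "sine" else np.cos(theta)
    A = np.column_stack([np.ones_like(theta), basis])
    coef, _, _, _ = np.linalg.lstsq(A, measured.transmission, rcond=None)
    o, m = float(coef[0]), float(coef[1])
    residual = float(np.linalg.norm(A @ coef - measured.transmission))
    if m <= 0:
        raise ValueError(f"calibration failure: fitted amplitude {m} <= 0")
    return FilterFit(kind=kind, offset=o, amplitude=m, residual=residual)


def fit_triplet_calibration(sine: FilterCurve, cosine: FilterCurve) -> FilterCalibration:
    """Calibration from measured sine and cosine transmission curves."""
    fs = fit_calibration(sine, "sine")
    fc = fit_calibration(cosine, "cosine")
    return FilterCalibration(o_s=fs.offset, m_s=fs.amplitude,
                             o_c=fc.offset, m_c=fc.amplitude)
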