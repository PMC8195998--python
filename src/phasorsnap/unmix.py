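"""Fit-free linear-combination analyses on phasor coordinates.

By the rule of linear addition, a voxel containing a mixture of species lies
at the intensity-fraction-weighted combination of the pure-species phasor
positions: two species span a line segment, three a triangle.  Fractions are
therefore read off geometrically — a projection along the mixing line, or a
barycentric solve inside the triangle — without spectral fitting or a priori
spectra.  Two trajectory-projection indices build on the segment case:

* optical redox ratio ``rr = t / (1 - t)`` with ``t`` the projected fraction
  toward the NADH endpoint of the NADH-FAD trajectory (NADH emits mainly at
  420-500 nm, FAD at 520-600 nm); reports glycolysis vs oxidative
  phosphorylation balance;
* dipolar relaxation index ``dr``, the same construction on the
  relaxed-unrelaxed trajectory of a solvatochromic probe (green vs blue
  emission), reporting water dipolar relaxation.

All fractions are intensity fractions; converting to molar fractions would
require the species' brightness ratios and is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .phasor import PhasorField
from .spectral import PhasorPoint, WavelengthGrid, phase_modulation

__all__ = [
    "Segment",
    "Triangle",
    "FractionMap",
    "IndexMap",
    "fraction_on_segment",
    "barycentric_fractions",
    "redox_ratio",
    "dipolar_relaxation",
    "halfplane_pair_coloring",
    "wavelength_window_mapping",
    "slice_profile",
    "rank_sum_compare",
]

_DEGENERATE_SEGMENT = 1e-6
_DEGENERATE_TRIANGLE = 1e-9


@dataclass(frozen=True)
class Segment:
    """Mixing line between two pure-species phasor positions.

    Projection coordinate t runs from 0 at ``endpoint_b`` to 1 at
    ``endpoint_a``.
    """

    endpoint_a: PhasorPoint
    endpoint_b: PhasorPoint

    def __post_init__(self) -> None:
        dx = self.endpoint_a.G - self.endpoint_b.G
        dy = self.endpoint_a.S - self.endpoint_b.S
        if np.hypot(dx, dy) <= _DEGENERATE_SEGMENT:
            raise ValueError("degenerate segment: endpoints coincide")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.endpoint_a.G - self.endpoint_b.G,
                         self.endpoint_a.S - self.endpoint_b.S])

    @property
    def midpoint(self) -> PhasorPoint:
        return PhasorPoint((self.endpoint_a.G + self.endpoint_b.G) / 2,
                           (self.endpoint_a.S + self.endpoint_b.S) / 2)


@dataclass(frozen=True)
class Triangle:
    """Three pure-species phasor positions spanning a mixing triangle."""

    vertices: tuple[PhasorPoint, PhasorPoint, PhasorPoint]

    def __post_init__(self) -> None:
        (a, b, c) = self.vertices
        area2 = (b.G - a.G) * (c.S - a.S) - (c.G - a.G) * (b.S - a.S)
        if abs(area2) <= _DEGENERATE_TRIANGLE:
            raise ValueError("degenerate triangle: vertices are collinear")


@dataclass
class FractionMap:
    """Per-voxel intensity fraction along a mixing geometry.

    ``raw`` holds the unclamped projection (noise can push it outside [0, 1]);
    ``value`` is the clamped copy.  Both are kept so out-of-range mass can be
    audited.
    """

    value: np.ndarray
    raw: np.ndarray
    valid: np.ndarray


@dataclass
class IndexMap:
    """Per-voxel trajectory-projection index (redox ratio or dipolar relaxation).

    ``cap`` bounds the ratio ``t / (1 - t)``, which diverges as t -> 1; the
    cap keeps maps displayable and is recorded here.
    """

    value: np.ndarray
    kind: Literal["redox", "dipolar"]
    cap: float
    valid: np.ndarray


def fraction_on_segment(f: PhasorField, seg: Segment) -> FractionMap:
    """Orthogonal projection of each valid voxel onto the segment's line.

    t = 1 at ``endpoint_a``, 0 at ``endpoint_b``.  Orthogonal projection is
    used (rather than nearest point in the disk) because noise displaces
    points symmetrically perpendicular to the mixing line, making the
    projection the unbiased estimator of position along it.
    """
    v = seg.vector
    denom = float(v @ v)
    raw = np.full(f.shape, np.nan)
    dg = f.G - seg.endpoint_b.G
    ds = f.S - seg.endpoint_b.S
    t = (dg * v[0] + ds * v[1]) / denom
    raw[f.valid] = t[f.valid]
    value = np.clip(raw, 0.0, 1.0)
    return FractionMap(value=value, raw=raw, valid=f.valid.copy())


def barycentric_fractions(f: PhasorField, tri: Triangle) -> tuple[FractionMap, FractionMap, FractionMap]:
    """Barycentric fractions of each valid voxel with respect to the triangle.

    Solves ``P = f1*V1 + f2*V2 + f3*V3`` with ``f1 + f2 + f3 = 1``.  Raw
    fractions sum to 1 exactly; negative coordinates (voxels outside the
    triangle) are clamped to 0 and the clamped triple renormalised.
    """
    (a, b, c) = tri.vertices
    det = (b.S - c.S) * (a.G - c.G) + (c.G - b.G) * (a.S - c.S)
    dg = f.G - c.G
    ds = f.S - c.S
    f1 = ((b.S - c.S) * dg + (c.G - b.G) * ds) / det
    f2 = ((c.S - a.S) * dg + (a.G - c.G) * ds) / det
    f3 = 1.0 - f1 - f2
    maps = []
    clamped = [np.clip(x, 0.0, None) for x in (f1, f2, f3)]
    norm = clamped[0] + clamped[1] + clamped[2]
    for raw_i, cl_i in zip((f1, f2, f3), clamped):
        raw = np.full(f.shape, np.nan)
        raw[f.valid] = raw_i[f.valid]
        value = np.full(f.shape, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            val_i = cl_i / norm
        value[f.valid] = val_i[f.valid]
        maps.append(FractionMap(value=value, raw=raw, valid=f.valid.copy()))
    return tuple(maps)


def _trajectory_index(
    f: PhasorField, toward: PhasorPoint, away: PhasorPoint,
    kind: Literal["redox", "dipolar"], cap: float,
) -> tuple[IndexMap, FractionMap]:
    seg = Segment(endpoint_a=toward, endpoint_b=away)
    frac = fraction_on_segment(f, seg)
    t = frac.value
    ratio = np.full(f.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = t / (1.0 - t)
    r = np.where(t >= 1.0, cap, r)
    r = np.minimum(r, cap)
    ratio[f.valid] = r[f.valid]
    return IndexMap(value=ratio, kind=kind, cap=cap, valid=f.valid.copy()), frac


def redox_ratio(
    f: PhasorField, nadh: PhasorPoint, fad: PhasorPoint, cap: float = 100.0,
) -> tuple[IndexMap, FractionMap]:
    """Optical redox ratio rr = t/(1-t) with t the fraction toward NADH.

    Endpoints come from pure-solution measurements (or simulations) of NADH
    and FAD; both the capped ratio and the projection coordinate t are
    returned since either may be plotted.
    """
    return _trajectory_index(f, toward=nadh, away=fad, kind="redox", cap=cap)


def dipolar_relaxation(
    f: PhasorField, relaxed: PhasorPoint, unrelaxed: PhasorPoint, cap: float = 100.0,
) -> tuple[IndexMap, FractionMap]:
    """Dipolar relaxation index dr: green-to-blue ratio along the probe trajectory.

    t is the fraction toward the relaxed (green-shifted) endpoint; dr =
    t/(1-t) capped as for the redox ratio.
    """
    return _trajectory_index(f, toward=relaxed, away=unrelaxed, kind="dipolar", cap=cap)


def halfplane_pair_coloring(
    f: PhasorField, pair1: Segment, pair2: Segment,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the phasor plane between two fluorophore pairs and project within each.

    The dividing line runs through the midpoints of the segments connecting
    the corresponding pure points of the two pairs (endpoint_a of pair1 to
    endpoint_a of pair2, and likewise for endpoint_b).  Each valid voxel is
    assigned to the half containing it (label 1 for pair1's side, 2 for
    pair2's; voxels exactly on the line go to half 1), then given its
    fraction t along that half's mixing segment.

    Returns
    -------
    (labels, t)
        ``labels`` int array (0 where invalid); ``t`` clamped fraction along
        the assigned pair's segment (NaN where invalid).
    """
    m1 = np.array([(pair1.endpoint_a.G + pair2.endpoint_a.G) / 2,
                   (pair1.endpoint_a.S + pair2.endpoint_a.S) / 2])
    m2 = np.array([(pair1.endpoint_b.G + pair2.endpoint_b.G) / 2,
                   (pair1.endpoint_b.S + pair2.endpoint_b.S) / 2])
    d = m2 - m1
    if np.hypot(*d) <= _DEGENERATE_SEGMENT:
        raise ValueError("undefined dividing line: pair midpoints coincide")
    def side(g, s):
        return d[0] * (s - m1[1]) - d[1] * (g - m1[0])
    ref = side(pair1.midpoint.G, pair1.midpoint.S)
    if ref == 0:
        raise ValueError("pair1 midpoint lies on the dividing line; halves undefined")
    sign = side(f.G, f.S) * np.sign(ref)
    labels = np.zeros(f.shape, dtype=int)
    labels[f.valid & (sign >= 0)] = 1
    labels[f.valid & (sign < 0)] = 2
    t1 = fraction_on_segment(f, pair1).value
    t2 = fraction_on_segment(f, pair2).value
    t = np.full(f.shape, np.nan)
    t[labels == 1] = t1[labels == 1]
    t[labels == 2] = t2[labels == 2]
    return labels, t


def wavelength_window_mapping(
    f: PhasorField, windows: list[tuple[float, float]],
) -> np.ndarray:
    """Label each valid voxel by the wavelength window containing its spectral
    center of mass.

    Each voxel's phase maps back to a center wavelength; ``windows`` is an
    ordered list of half-open ranges ``[lo, hi)`` in nm.  Voxels whose center
    falls in no window — and invalid voxels — get label -1.

    Raises
    ------
    ValueError
        If windows overlap or leave the grid range.
    """
    for lo, hi in windows:
        if not (f.grid.lambda_min <= lo < hi <= f.grid.lambda_max):
            raise ValueError(f"window [{lo}, {hi}) must lie within the grid range")
    ordered = sorted(windows)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 > lo2:
            raise ValueError(f"windows [{lo1},{hi1}) and [{lo2},{hi2}) overlap")
    pm = phase_modulation((f.G, f.S), f.grid)
    center = np.asarray(pm.center_wavelength)
    labels = np.full(f.shape, -1, dtype=int)
    for i, (lo, hi) in enumerate(windows):
        inside = f.valid & (center >= lo) & (center < hi)
        labels[inside] = i
    return labels


def _map_values(m) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, (FractionMap, IndexMap)):
        return m.value, m.valid
    arr = np.asarray(m, dtype=float)
    return arr, np.isfinite(arr)


def slice_profile(m, axis: str = "z", mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-slice mean/sd/count of a fraction or index map along one axis.

    Each row summarises one orthogonal plane (one xy plane for ``axis='z'``,
    etc.) over the valid, optionally masked voxels.  Empty slices report
    ``n = 0`` with NaN mean and sd.
    """
    if axis not in ("z", "y", "x"):
        raise ValueError(f"axis must be 'z', 'y' or 'x', got {axis!r}")
    values, valid = _map_values(m)
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    ax = "zyx".index(axis)
    n_slices = values.shape[ax]
    rows = []
    for i in range(n_slices):
        sl = [slice(None)] * values.ndim
        sl[ax] = i
        v = values[tuple(sl)][valid[tuple(sl)]]
        if v.size == 0:
            rows.append((i, np.nan, np.nan, 0))
        else:
            rows.append((i, float(v.mean()), float(v.std(ddof=0)), int(v.size)))
    return pd.DataFrame(rows, columns=["slice", "mean", "sd", "n"])


def rank_sum_compare(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value between two groups of index values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
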