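"""Reciprocity between image space and phasor space.

A region drawn on the phasor plot selects the voxels whose (unjittered)
coordinates fall inside it; conversely, a voxel mask drawn on the image
restricts the phasor histogram to that region.  Selections always respect
the phasor field's validity mask and never see display jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasor import PhasorField, PhasorHistogram, phasor_histogram

__all__ = [
    "PhasorPolygon",
    "select_by_polygon",
    "points_in_polygon",
    "histogram_from_mask",
    "masked_pseudocolor",
]


@dataclass
class PhasorPolygon:
    """Closed polygon on the phasor plot, with a name and display color tag."""

    vertices: np.ndarray
    name: str = ""
    color: str = "C0"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (G, S) vertices")
        x, y = v[:, 0], v[:, 1]
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if abs(area2) <= 1e-12:
            raise ValueError("polygon has zero area")
        self.vertices = v


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, boundary-inclusive.

    A horizontal ray is cast to +x from each point; crossing parity decides
    interior membership, and points lying exactly on an edge or vertex count
    as inside.  Vectorised over points.
    """
    pts = np.asarray(points, dtype=float)
    verts = np.asarray(vertices, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary test: point within the edge's bounding box and collinear
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        within = (
            (np.minimum(x1, x2) - 1e-12 <= x) & (x <= np.maximum(x1, x2) + 1e-12)
            & (np.minimum(y1, y2) - 1e-12 <= y) & (y <= np.maximum(y1, y2) + 1e-12)
        )
        on_edge |= within & (np.abs(cross) <= 1e-12)
        # crossing test (half-open in y to count shared vertices once)
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at_y = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
        inside ^= crosses & (x < np.where(crosses, x_at_y, np.inf))
    return inside | on_edge


def select_by_polygon(f: PhasorField, poly: PhasorPolygon) -> np.ndarray:
    """Boolean voxel mask: valid voxels whose (G, S) lies in/on the polygon."""
    mask = np.zeros(f.shape, dtype=bool)
    idx = np.nonzero(f.valid)
    if idx[0].size == 0:
        return mask
    pts = np.column_stack([f.G[idx], f.S[idx]])
    mask[idx] = points_in_polygon(pts, poly.vertices)
    return mask


def histogram_from_mask(
    f: PhasorField,
    image_mask: np.ndarray,
    jitter_halfwidth: float = 0.02,
    seed: int = 0,
) -> PhasorHistogram:
    """Phasor histogram restricted to an image-space voxel mask."""
    image_mask = np.asarray(image_mask, dtype=bool)
    if image_mask.shape != f.shape:
        raise ValueError("mask shape must match the phasor field")
    return phasor_histogram(f, jitter_halfwidth=jitter_halfwidth, seed=seed,
                            mask=image_mask)


def masked_pseudocolor(
    f: PhasorField,
    polygons: list[PhasorPolygon],
    intensity: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudocolor voxels by polygon membership, modulated by intensity.

    Each valid voxel is tagged by the first polygon (in list order)
    containing its phasor coordinates — list order is the explicit precedence
    rule for overlapping selections.  Returns ``(labels, rgb)`` where
    ``labels`` is -1 for unselected voxels and ``rgb`` is a float
    ``(..., 3)`` volume: selected voxels take their polygon's color, the rest
    grayscale, both scaled by normalised intensity.
    """
    import matplotlib.colors as mcolors

    if len({p.color for p in polygons}) != len(polygons):
        raise ValueError("polygons must carry pairwise distinct color tags")
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != f.shape:
        raise ValueError("intensity shape must match the phasor field")
    labels = np.full(f.shape, -1, dtype=int)
    for i, poly in reversed(list(enumerate(polygons))):
        labels[select_by_polygon(f, poly)] = i  # earlier polygons overwrite later
    peak = intensity.max()
    norm = intensity / peak if peak > 0 else np.zeros_like(intensity)
    rgb = np.repeat(norm[..., None], 3, axis=-1)  # grayscale base
    for i, poly in enumerate(polygons):
        color = np.asarray(mcolors.to_rgb(poly.color))
        sel = labels == i
        rgb[sel] = norm[sel][:, None] * color[None, :]
    return labels, rgb
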