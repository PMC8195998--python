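"""File formats and display utilities: TIFF stacks, CSV tables, projections."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phasor import PhasorField, PhasorHistogram
from .select import PhasorPolygon
from .simulate import TripletStack
from .spectral import EmissionSpectrum, FilterCurve, PhasorPoint, WavelengthGrid

__all__ = [
    "read_stack",
    "write_stack",
    "write_triplet",
    "read_triplet",
    "mip",
    "percentile_clip",
    "write_curve_csv",
    "read_filter_csv",
    "read_spectrum_csv",
    "write_endpoints_csv",
    "read_endpoints_csv",
    "write_polygons_csv",
    "read_polygons_csv",
    "read_windows_csv",
    "write_histogram_csv",
    "write_phasor_field",
    "read_phasor_field",
]


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a (z, y, x) stack, dtype preserved.

    A single-page file yields shape ``(1, ny, nx)``.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise OSError(f"{path}: expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    return arr


def write_stack(grid: np.ndarray, path) -> None:
    """Write a (z, y, x) stack as a multi-page TIFF (one page per plane)."""
    path = Path(path)
    arr = np.asarray(grid)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D array, got shape {arr.shape}")
    path.parent.mkdir(parents=True, exist_ok=True)
    # ImageJ-compatible layout where the dtype allows it
    if arr.dtype in (np.uint8, np.uint16, np.float32):
        tifffile.imwrite(path, arr, imagej=True)
    else:
        tifffile.imwrite(path, arr, photometric="minisblack")


def write_triplet(t: TripletStack, stem) -> dict[str, Path]:
    """Write the three channels as ``<stem>_sin/_cos/_open.tif``."""
    stem = Path(stem)
    paths = {}
    for suffix, arr in (("sin", t.I_sin), ("cos", t.I_cos), ("open", t.I_total)):
        p = stem.parent / f"{stem.name}_{suffix}.tif"
        write_stack(arr.astype(np.float32), p)
        paths[suffix] = p
    return paths


def read_triplet(stem, camera, grid: WavelengthGrid) -> TripletStack:
    """Read a triplet written by :func:`write_triplet`."""
    stem = Path(stem)
    arrays = {
        suffix: read_stack(stem.parent / f"{stem.name}_{suffix}.tif").astype(float)
        for suffix in ("sin", "cos", "open")
    }
    return TripletStack(I_sin=arrays["sin"], I_cos=arrays["cos"],
                        I_total=arrays["open"], camera=camera, grid=grid)


def mip(grid: np.ndarray, axis: str = "z") -> np.ndarray:
    """Maximum intensity projection of a (z, y, x) stack along one axis."""
    if axis not in ("z", "y", "x"):
        raise ValueError(f"axis must be 'z', 'y' or 'x', got {axis!r}")
    return np.asarray(grid).max(axis="zyx".index(axis))


def percentile_clip(image: np.ndarray, upper_percent: float = 5.0) -> np.ndarray:
    """Clip the brightest ``upper_percent`` % of values to the cutoff.

    A display-only transform (it aids visualisation of dim structure next to
    bright outliers); never feed the result back into quantification.
    """
    if not 0 <= upper_percent < 100:
        raise ValueError("upper_percent must be in [0, 100)")
    image = np.asarray(image, dtype=float)
    cutoff = np.percentile(image, 100.0 - upper_percent)
    return np.minimum(image, cutoff)


# --- CSV formats -----------------------------------------------------------

def write_curve_csv(curve, path) -> None:
    """Write a FilterCurve or EmissionSpectrum as `wavelength_nm,value` CSV."""
    values = curve.transmission if isinstance(curve, FilterCurve) else curve.intensity
    df = pd.DataFrame({"wavelength_nm": curve.grid.wavelengths, "value": values})
    df.to_csv(path, index=False)


def _read_curve(path) -> tuple[WavelengthGrid, np.ndarray]:
    df = pd.read_csv(path)
    if list(df.columns) != ["wavelength_nm", "value"]:
        raise OSError(f"{path}: expected header 'wavelength_nm,value'")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise OSError(f"{path}: wavelengths must be strictly ascending")
    n = len(wl)
    delta = wl[1] - wl[0]
    grid = WavelengthGrid(lambda_min=wl[0] - delta / 2,
                         lambda_max=wl[-1] + delta / 2, n_samples=n)
    return grid, df["value"].to_numpy(dtype=float)


def read_filter_csv(path, kind=None) -> FilterCurve:
    grid, values = _read_curve(path)
    return FilterCurve(grid=grid, transmission=values, kind=kind)


def read_spectrum_csv(path) -> EmissionSpectrum:
    grid, values = _read_curve(path)
    return EmissionSpectrum(grid=grid, intensity=values)


def write_endpoints_csv(points: dict[str, PhasorPoint], path) -> None:
    """Named phasor endpoints as `name,G,S` CSV."""
    df = pd.DataFrame(
        [(name, p.G, p.S) for name, p in points.items()], columns=["name", "G", "S"]
    )
    df.to_csv(path, index=False)


def read_endpoints_csv(path) -> dict[str, PhasorPoint]:
    df = pd.read_csv(path)
    return {row["name"]: PhasorPoint(float(row["G"]), float(row["S"]))
            for _, row in df.iterrows()}


def write_polygons_csv(polygons: list[PhasorPolygon], path) -> None:
    """Polygon files as `name,vertex_index,G,S` CSV."""
    rows = []
    for poly in polygons:
        for i, (g, s) in enumerate(poly.vertices):
            rows.append((poly.name, i, g, s))
    pd.DataFrame(rows, columns=["name", "vertex_index", "G", "S"]).to_csv(path, index=False)


def read_polygons_csv(path) -> list[PhasorPolygon]:
    df = pd.read_csv(path)
    polys = []
    for i, (name, group) in enumerate(df.groupby("name", sort=False)):
        group = group.sort_values("vertex_index")
        polys.append(PhasorPolygon(vertices=group[["G", "S"]].to_numpy(float),
                                   name=str(name), color=f"C{i}"))
    return polys


def read_windows_csv(path) -> list[tuple[float, float]]:
    """Wavelength windows as `label,lambda_lo_nm,lambda_hi_nm` CSV."""
    df = pd.read_csv(path)
    return [(float(r["lambda_lo_nm"]), float(r["lambda_hi_nm"]))
            for _, r in df.iterrows()]


def write_histogram_csv(h: PhasorHistogram, path) -> None:
    np.savetxt(path, h.counts, fmt="%d", delimiter=",")


def write_phasor_field(f: PhasorField, stem) -> dict[str, Path]:
    """Write G/S as float32 TIFFs and the validity mask as 8-bit TIFF."""
    stem = Path(stem)
    paths = {}
    for suffix, arr, dtype in (
        ("G", f.G, np.float32), ("S", f.S, np.float32),
        ("mask", f.valid.astype(np.uint8) * 255, np.uint8),
    ):
        p = stem.parent / f"{stem.name}_{suffix}.tif"
        write_stack(arr.astype(dtype), p)
        paths[suffix] = p
    return paths


def read_phasor_field(stem, threshold: float, offset: float,
                      grid: WavelengthGrid | None = None) -> PhasorField:
    stem = Path(stem)
    G = read_stack(stem.parent / f"{stem.name}_G.tif").astype(float)
    S = read_stack(stem.parent / f"{stem.name}_S.tif").astype(float)
    valid = read_stack(stem.parent / f"{stem.name}_mask.tif") > 0
    return PhasorField(G=G, S=S, valid=valid, threshold=threshold, offset=offset,
                       grid=grid or WavelengthGrid())
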