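"""Contour extraction and canonicalisation for labelled cell images.

A cell outline is an ordered, closed polygon of boundary points. Before any
spectral analysis the outline is brought into a canonical form: traversal is
counter-clockwise (positive signed area, x right / y up) and the enclosed
area is scaled to pi, so that all amplitudes downstream are expressed in
units of the equivalent-circle radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "LabelImage",
    "extract_contours",
    "resample_contour",
    "canonicalise",
    "signed_area",
    "rasterize_polygon",
    "read_contour_csv",
    "write_contour_csv",
    "read_label_image",
]


@dataclass
class Contour:
    """Closed polygon boundary of one cell.

    ``points`` is an (n, 2) float array of (x, y) vertices in physical
    units; the edge from the last to the first point is implicit. After
    :func:`canonicalise` the traversal is counter-clockwise and the
    enclosed area equals pi.
    """

    points: np.ndarray
    cell_id: Optional[int] = None
    touches_border: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        # drop consecutive duplicates (closure is implicit)
        keep = np.ones(len(pts), dtype=bool)
        if len(pts) > 1:
            keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
        pts = pts[keep]
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 distinct points")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    @property
    def area(self) -> float:
        """Unsigned enclosed area (shoelace)."""
        return abs(signed_area(self.points))

    def is_ccw(self) -> bool:
        return signed_area(self.points) > 0


@dataclass
class LabelImage:
    """Integer cell-ID raster; 0 is background."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("label image must be 2D")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("label image must have an integer dtype")
        if px.min() < 0:
            raise ValueError("cell IDs must be non-negative")
        self.pixels = px


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise traversal."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _trace_component(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a binary mask at sub-pixel precision.

    Marching squares on the zero-padded mask at iso-level 0.5, so the
    vertices sit at pixel-edge midpoints. Returns (n, 2) (x, y) vertices
    with x = column index, y = row index of the unpadded image.
    """
    padded = np.pad(mask, 1).astype(float)
    rings = measure.find_contours(padded, 0.5)
    if not rings:
        return np.empty((0, 2))
    # outer boundary is the longest ring; inner rings (holes) are ignored
    ring = max(rings, key=len)
    rc = ring - 1.0  # undo padding
    return np.column_stack([rc[:, 1], rc[:, 0]])  # (row, col) -> (x, y)


def extract_contours(image: LabelImage) -> list[Contour]:
    """One closed, CCW contour per connected cell region.

    Regions of the same ID that are disconnected yield separate contours,
    each carrying that ID. Cells touching the image border are traced but
    flagged via ``touches_border``.
    """
    px = image.pixels
    ids = np.unique(px)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("no cells: label image contains no nonzero IDs")
    out: list[Contour] = []
    struct = np.ones((3, 3), dtype=int)  # 8-connectivity for grouping
    for cid in ids:
        labelled, n_comp = ndimage.label(px == cid, structure=struct)
        for k in range(1, n_comp + 1):
            comp = labelled == k
            pts = _trace_component(comp)
            if len(pts) < 3:
                logger.warning("cell %d: region too small to trace, skipped", cid)
                continue
            if signed_area(pts) < 0:
                pts = pts[::-1]
            border = bool(
                comp[0, :].any() or comp[-1, :].any()
                or comp[:, 0].any() or comp[:, -1].any()
            )
            out.append(
                Contour(pts * image.pixel_size, cell_id=int(cid), touches_border=border)
            )
    if not out:
        raise ValueError("no cells: all regions were too small to trace")
    return out


def resample_contour(c: Contour, n_points: int) -> Contour:
    """Resample to ``n_points`` vertices equally spaced in arc length."""
    if n_points < 16:
        raise ValueError("n_points must be at least 16")
    closed = np.vstack([c.points, c.points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return Contour(
        np.column_stack([x, y]), cell_id=c.cell_id, touches_border=c.touches_border
    )


def canonicalise(c: Contour, check_simple: bool = True) -> tuple[Contour, float]:
    """Fix orientation to CCW and scale the enclosed area to pi.

    Lengths are afterwards in units of the equivalent-circle radius. The
    centroid is deliberately left in place: translation is absorbed by the
    offset term of the elliptic Fourier decomposition. Returns the contour
    and the applied scale factor.
    """
    pts = c.points
    if check_simple:
        from shapely.geometry import LinearRing

        if not LinearRing(pts).is_simple:
            raise ValueError("self-intersecting contour cannot be canonicalised")
    a = signed_area(pts)
    if a < 0:
        pts = pts[::-1]
        a = -a
    if a == 0:
        raise ValueError("degenerate contour with zero area")
    scale = float(np.sqrt(np.pi / a))
    return (
        Contour(pts * scale, cell_id=c.cell_id, touches_border=c.touches_border),
        scale,
    )


def rasterize_polygon(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd scanline fill of a closed polygon on a pixel grid.

    Pixel (r, c) has its centre at x = c, y = r (the convention used by
    :func:`extract_contours`); a pixel is filled when its centre lies
    inside the polygon under the even-odd rule. Self-intersecting polygons
    (which truncated reconstructions can produce) are handled correctly.
    """
    pts = np.asarray(points, dtype=float)
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if len(pts) < 3:
        return mask
    x0, y0 = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    r_lo = max(0, int(np.ceil(y0.min())))
    r_hi = min(h - 1, int(np.floor(y0.max())))
    dy = y1 - y0
    nz = dy != 0.0
    x0n, y0n, x1n, y1n, dyn = x0[nz], y0[nz], x1[nz], y1[nz], dy[nz]
    for r in range(r_lo, r_hi + 1):
        yc = float(r)
        crosses = (y0n > yc) != (y1n > yc)  # half-open rule at vertices
        if not crosses.any():
            continue
        t = (yc - y0n[crosses]) / dyn[crosses]
        xs = np.sort(x0n[crosses] + t * (x1n[crosses] - x0n[crosses]))
        for i in range(0, len(xs) - 1, 2):
            lo = int(np.ceil(xs[i]))
            hi = int(np.ceil(xs[i + 1]))  # exclusive
            if hi > lo:
                mask[r, max(lo, 0):min(hi, w)] = True
    return mask


def read_contour_csv(path) -> Contour:
    """Read a contour from CSV with header ``x,y``, one vertex per row."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: expected columns 'x' and 'y'")
    df.columns = cols
    return Contour(df[["x", "y"]].to_numpy(dtype=float))


def write_contour_csv(c: Contour, path) -> None:
    pd.DataFrame(c.points, columns=["x", "y"]).to_csv(path, index=False)


def read_label_image(path, pixel_size: float = 1.0) -> LabelImage:
    """Read a TIFF/PNG integer label raster."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # palette/RGB PNG encoding of labels is not supported
        raise ValueError(f"{path}: expected a single-channel integer label image")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int32)
        else:
            raise ValueError(f"{path}: label image must contain integers")
    return LabelImage(arr.astype(np.int32), pixel_size=pixel_size)
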