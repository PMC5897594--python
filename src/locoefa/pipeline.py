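"""End-to-end per-cell analysis: image/contour in, spectra and metrics out.

The driver chains boundary extraction, canonicalisation, elliptic Fourier
decomposition, lobe-mode reassignment and the complexity metrics, and
produces one record per analysed cell. The analysis path contains no
randomness: identical input and configuration give identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .contours import (
    Contour,
    LabelImage,
    canonicalise,
    extract_contours,
    rasterize_polygon,
    read_contour_csv,
    read_label_image,
    resample_contour,
)
from .efa import efa_decompose
from .loco import LocoSpectrum, loco_spectrum
from .metrics import (
    DEFAULT_MODES,
    SYNTHETIC_GRID,
    XORProfile,
    cumulative_difference,
    entropy,
    xor_profile,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CellAnalysis",
    "analyze",
    "analyze_label_image",
    "analyze_contour",
    "records_dataframe",
    "long_dataframe",
    "render_mode_map",
]

DEFAULT_RESAMPLE = 1000  # vertices per analysed contour
DEFAULT_HARMONICS = DEFAULT_MODES + 1  # EFA harmonics needed for 50 lobe modes


@dataclass
class CellAnalysis:
    """Everything computed for one cell (or the reason it was skipped)."""

    cell_id: int
    status: str = "ok"  # or an exclusion reason
    area_px: float = np.nan
    area: float = np.nan
    touches_border: bool = False
    spectrum: Optional[LocoSpectrum] = None
    profile: Optional[XORProfile] = None
    cd: float = np.nan
    entropy: float = np.nan
    argmax_md: Optional[int] = None
    cutoff: Optional[int] = None


def _analyse_one(
    contour: Contour,
    mask: np.ndarray,
    n_modes: int,
    spacing: str,
    area_px: float,
    pixel_size: float,
) -> CellAnalysis:
    resampled = resample_contour(contour, DEFAULT_RESAMPLE)
    canon, scale = canonicalise(resampled)
    coef = efa_decompose(canon, DEFAULT_HARMONICS, scale=scale, spacing=spacing)
    spectrum = loco_spectrum(coef)
    # canonical coords -> physical (/scale) -> pixel indices (/pixel_size)
    inv = 1.0 / (scale * pixel_size)

    def to_grid(pts: np.ndarray, _inv=inv) -> np.ndarray:
        return pts * _inv

    profile = xor_profile(mask, spectrum, to_grid, N_max=n_modes)
    return CellAnalysis(
        cell_id=contour.cell_id if contour.cell_id is not None else 0,
        area_px=area_px,
        area=area_px * pixel_size**2,
        touches_border=contour.touches_border,
        spectrum=spectrum,
        profile=profile,
        cd=cumulative_difference(profile, n_modes),
        entropy=entropy(spectrum, n_modes, l_min=2, noise_floor=1e-6),
        argmax_md=profile.argmax_marginal(),
        cutoff=profile.cutoff,
    )


def analyze_label_image(
    image: LabelImage, n_modes: int = DEFAULT_MODES, spacing: str = "chord"
) -> list[CellAnalysis]:
    """Analyse every connected cell region of a label raster.

    The XOR metrics are computed on the source grid itself, at the
    resolution the cells were imaged/simulated at. Cells whose outline
    cannot be analysed (too small, self-touching trace) are reported with
    an exclusion reason instead of numbers.
    """
    out: list[CellAnalysis] = []
    px = image.pixels
    for contour in extract_contours(image):
        cid = contour.cell_id
        # exact pixel membership of this connected region
        grid_pts = contour.points / image.pixel_size
        mask = rasterize_polygon(grid_pts, px.shape) & (px == cid)
        area_px = float(mask.sum())
        try:
            res = _analyse_one(
                contour, mask, n_modes, spacing, area_px, image.pixel_size
            )
        except ValueError as exc:
            logger.warning("cell %s excluded: %s", cid, exc)
            res = CellAnalysis(cell_id=cid or 0, status=str(exc),
                               touches_border=contour.touches_border)
        out.append(res)
    return out


def analyze_contour(
    contour: Contour,
    n_modes: int = DEFAULT_MODES,
    spacing: str = "chord",
    grid: int = SYNTHETIC_GRID,
    resample: bool = True,
) -> CellAnalysis:
    """Analyse a free-standing contour (no source image).

    The XOR metrics need a grid, so the shape is placed on a
    ``grid`` x ``grid`` raster spanning ~60% of the field. Shapes sampled
    at equal polar angle should pass ``spacing="uniform"`` and
    ``resample=False`` to be analysed in their native polar
    parameterisation (see :func:`locoefa.efa.efa_decompose`).
    """
    work = resample_contour(contour, DEFAULT_RESAMPLE) if resample else contour
    canon, scale = canonicalise(work)
    coef = efa_decompose(canon, DEFAULT_HARMONICS, scale=scale, spacing=spacing)
    spectrum = loco_spectrum(coef)

    pts = canon.points
    centre = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    half_extent = np.max(np.abs(pts - centre))
    g = 0.3 * grid / half_extent  # shape spans ~60% of the field

    def to_grid(p: np.ndarray, _c=centre, _g=g, _grid=grid) -> np.ndarray:
        return (p - _c) * _g + _grid / 2.0

    mask = rasterize_polygon(to_grid(pts), (grid, grid))
    area_px = float(mask.sum())
    profile = xor_profile(mask, spectrum, to_grid, N_max=n_modes)
    return CellAnalysis(
        cell_id=contour.cell_id if contour.cell_id is not None else 0,
        area_px=area_px,
        area=contour.area,
        touches_border=contour.touches_border,
        spectrum=spectrum,
        profile=profile,
        cd=cumulative_difference(profile, n_modes),
        entropy=entropy(spectrum, n_modes, l_min=2, noise_floor=1e-6),
        argmax_md=profile.argmax_marginal(),
        cutoff=profile.cutoff,
    )


def analyze(
    input_path,
    n_modes: int = DEFAULT_MODES,
    pixel_size: float = 1.0,
    grid: int = SYNTHETIC_GRID,
) -> list[CellAnalysis]:
    """Analyse a label image (TIFF/PNG) or a contour CSV by extension."""
    path = Path(input_path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff", ".png"):
        return analyze_label_image(read_label_image(path, pixel_size), n_modes)
    if suffix in (".csv", ".txt"):
        return [analyze_contour(read_contour_csv(path), n_modes, grid=grid)]
    raise ValueError(f"unsupported input type: {path.suffix}")


def records_dataframe(results: list[CellAnalysis], n_modes: int = DEFAULT_MODES) -> pd.DataFrame:
    """Wide per-cell table: id, area, flags, L_1..L_n, summary metrics."""
    rows = []
    for r in results:
        row: dict = {
            "cell_id": r.cell_id,
            "status": r.status,
            "area_px": r.area_px,
            "area": r.area,
            "border": r.touches_border,
        }
        L = (
            r.spectrum.mode_amplitudes(n_modes)
            if r.spectrum is not None
            else np.full(n_modes, np.nan)
        )
        row.update({f"L{l}": L[l - 1] for l in range(1, n_modes + 1)})
        row["argmax_md_mode"] = r.argmax_md if r.argmax_md is not None else np.nan
        row["cd"] = r.cd
        row["entropy"] = r.entropy
        row["cutoff"] = r.cutoff if r.cutoff is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def long_dataframe(results: list[CellAnalysis], n_modes: int = DEFAULT_MODES) -> pd.DataFrame:
    """Long format (cell_id, l, L) for plotting."""
    rows = []
    for r in results:
        if r.spectrum is None:
            continue
        L = r.spectrum.mode_amplitudes(n_modes)
        rows.extend(
            {"cell_id": r.cell_id, "l": l, "L": L[l - 1]} for l in range(1, n_modes + 1)
        )
    return pd.DataFrame(rows)


_CATEGORICAL = {"argmax_md_mode"}


def render_mode_map(
    image: LabelImage,
    records: pd.DataFrame,
    metric: str,
    out_path,
    cmap: Optional[str] = None,
) -> None:
    """Colour each cell of a label image by a per-cell quantity.

    ``metric`` is a records column ("cd", "entropy", "argmax_md_mode",
    "area_px", ...) or "L:<l>" for lobe mode l. Continuous metrics use a
    perceptual colormap scaled 0..max; the argmax-mode map is
    categorical. A JSON sidecar stores the colour scale.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = f"L{metric.split(':', 1)[1]}" if metric.startswith("L:") else metric
    if col not in records.columns:
        valid = [c for c in records.columns if c not in ("cell_id", "status", "border")]
        raise ValueError(f"unknown metric {metric!r}; choose from {valid}")
    lut = np.full(int(image.pixels.max()) + 1, np.nan)
    for _, row in records.iterrows():
        lut[int(row["cell_id"])] = row[col]
    values = lut[image.pixels]
    values[image.pixels == 0] = np.nan

    categorical = col in _CATEGORICAL
    cmap_name = cmap or ("tab20" if categorical else "viridis")
    vmin = 0.0
    vmax = float(np.nanmax(lut)) if np.isfinite(lut).any() else 1.0
    if vmax <= vmin:
        vmax = vmin + 1.0
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(values, cmap=cmap_name, vmin=vmin, vmax=vmax, origin="lower")
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, shrink=0.8, label=col)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    sidecar = Path(str(out_path)).with_suffix(".scale.json")
    sidecar.write_text(
        json.dumps(
            {"metric": col, "vmin": vmin, "vmax": vmax, "cmap": cmap_name,
             "categorical": categorical},
            indent=2,
        )
    )
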