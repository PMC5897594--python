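"""Shape-complexity metrics derived from truncated lobe-mode reconstructions.

Four quantities summarise how many modes a shape needs and how evenly it
spreads over them:

- XOR(n): area of the symmetric difference between the original cell mask
  and the rasterised n-mode reconstruction, as a fraction of cell area.
- marginal difference md(n) = XOR(n-1) - XOR(n): how much area mode n
  explains; peaks pick out feature-carrying lobe numbers.
- cumulative difference cd = sum of XOR(n) for n >= 2: a scalar measure of
  lobe richness (mode 1, the overall circle/size, is excluded).
- entropy E: Shannon entropy of the normalised L spectrum, a measure of
  shape irregularity.

The XOR grid should be the source image grid when the cell came from a
segmentation; synthetic contours are rasterised on a 512x512 grid with the
shape spanning about 60% of the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .contours import Contour, rasterize_polygon
from .loco import LocoSpectrum, loco_reconstruct

__all__ = [
    "XORProfile",
    "xor_difference",
    "xor_profile",
    "cumulative_difference",
    "entropy",
    "DEFAULT_MODES",
    "SYNTHETIC_GRID",
]

DEFAULT_MODES = 50  # mode cap used for cd, entropy and reported spectra
SYNTHETIC_GRID = 512  # rasterisation grid for shapes with no source image


@dataclass
class XORProfile:
    """Mismatch-versus-modes profile for one cell.

    ``xor[n]`` holds XOR(n) for n = 0..N, with XOR(0) := 1 by convention
    (the empty reconstruction misses the whole cell), so the marginal
    difference is defined from n = 1 and sums to 1 - XOR(N).
    """

    xor: np.ndarray
    cutoff: Optional[int]  # smallest n with XOR(n) == 0 on the grid, if reached

    @property
    def marginal(self) -> np.ndarray:
        """md(n) = XOR(n-1) - XOR(n) for n = 1..N."""
        return -np.diff(self.xor)

    @property
    def n_max(self) -> int:
        return len(self.xor) - 1

    def argmax_marginal(self, n_min: int = 2) -> int:
        """Mode with the largest marginal difference among n >= n_min.

        Mode 1 explains the bulk circular shape and is excluded by
        default, so the answer reflects lobed features; lowest mode wins
        exact ties.
        """
        md = self.marginal
        return int(np.argmax(md[n_min - 1:])) + n_min


def xor_difference(original: np.ndarray, reconstruction: Contour | np.ndarray,
                   grid_shape: Optional[tuple[int, int]] = None) -> float:
    """|symmetric difference| / |cell|, both in grid points.

    ``reconstruction`` is a polygon in the same pixel coordinates as the
    mask (pixel centre (r, c) at x = c, y = r) or an already-rasterised
    boolean mask of the same shape.
    """
    original = np.asarray(original, dtype=bool)
    n_cell = int(original.sum())
    if n_cell == 0:
        raise ValueError("empty original mask")
    if isinstance(reconstruction, Contour):
        rec = rasterize_polygon(reconstruction.points, grid_shape or original.shape)
    else:
        rec = np.asarray(reconstruction, dtype=bool)
    return float(np.logical_xor(original, rec).sum()) / n_cell


def xor_profile(
    mask: np.ndarray,
    spectrum: LocoSpectrum,
    to_grid,
    N_max: int = DEFAULT_MODES,
) -> XORProfile:
    """XOR(n) for n = 0..N_max using successive lobe-mode truncations.

    ``to_grid`` maps reconstruction points from the spectrum's
    (area-normalised) coordinates back onto the mask's pixel grid — it
    undoes the canonicalisation scale and any synthetic-grid placement.
    Reconstruction polygons are sampled at four points per grid-diagonal
    pixel to avoid aliasing.
    """
    mask = np.asarray(mask, dtype=bool)
    n_samples = int(4 * np.hypot(*mask.shape))
    xor = np.empty(N_max + 1)
    xor[0] = 1.0
    n_avail = spectrum.n_modes
    cutoff = None
    for n in range(1, N_max + 1):
        rec = loco_reconstruct(spectrum, min(n, n_avail), n_samples)
        pts = to_grid(rec.points)
        xor[n] = xor_difference(mask, rasterize_polygon(pts, mask.shape))
        if cutoff is None and xor[n] == 0.0:
            cutoff = n
    return XORProfile(xor=xor, cutoff=cutoff)


def cumulative_difference(profile: XORProfile, N_max: int = DEFAULT_MODES) -> float:
    """cd = sum of XOR(n) from n = 2 to N_max.

    Starting at n = 2 removes the contribution of overall size/position
    (mode 1), so cd grows with protrusion number and amplitude rather
    than with mere existence of the cell.
    """
    if profile.n_max < 2:
        raise ValueError("profile must extend to at least mode 2")
    hi = min(N_max, profile.n_max)
    return float(np.sum(profile.xor[2 : hi + 1]))


def entropy(
    spectrum: LocoSpectrum | np.ndarray,
    L_max: int = DEFAULT_MODES,
    squared: bool = False,
    base: float = 2.0,
    l_min: int = 1,
    noise_floor: float = 0.0,
) -> float:
    """Shannon entropy of the normalised lobe spectrum.

    E = -sum f_l log_base f_l with f_l = L_l / sum(L), l = l_min..L_max.
    A single-mode spectrum gives 0; a spectrum uniform over k modes gives
    log_base(k). ``squared=True`` switches the weights to power
    (amplitude-squared) proportions.

    The per-cell pipeline passes ``l_min=2``: mode 1 is the overall
    circle and carries no shape complexity, and keeping it in the
    proportions would turn E into little more than a lobe-to-circle
    ratio — an elongated but simple cell would then outscore a genuinely
    multi-lobed irregular one.

    ``noise_floor`` (in equivalent-radius units) zeroes amplitudes that
    are numerically indistinguishable from no feature; a spectrum that is
    entirely below an explicit floor denotes a perfectly regular shape
    and returns 0 rather than the entropy of rounding noise.
    """
    if isinstance(spectrum, LocoSpectrum):
        L = spectrum.mode_amplitudes(L_max)[l_min - 1 :]
    else:
        L = np.asarray(spectrum, dtype=float)[l_min - 1 : L_max]
    if np.any(L < 0):
        raise ValueError("mode amplitudes must be non-negative")
    if noise_floor > 0.0:
        L = np.where(L >= noise_floor, L, 0.0)
        if not np.any(L > 0):
            return 0.0
    w = L**2 if squared else L
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum has no defined entropy")
    f = w / total
    nz = f > 0
    return float(-(f[nz] * np.log(f[nz])).sum() / np.log(base))
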