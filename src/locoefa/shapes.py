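"""Synthetic shape and tissue generators.

Everything the test-bench needs without microscopy data: Gielis
superformula stars, cosine-lobed circles for amplitude calibration, and
seeded-Voronoi label images standing in for segmented confluent tissue.

Polar generators sample theta uniformly; the returned contours therefore
carry the polar parameterisation natively (see `efa_decompose(spacing=...)`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .contours import Contour, LabelImage, canonicalise

__all__ = [
    "SuperformulaParams",
    "superformula_shape",
    "cosine_lobed_circle",
    "synthetic_tissue",
    "STAR_PARAMS",
]


@dataclass
class SuperformulaParams:
    """Gielis superformula parameters.

    r(theta) = [ |cos(m theta/4)/a|^n2 + |sin(m theta/4)/b|^n3 ]^(-1/n1).
    ``m`` sets the rotational symmetry (use n2 == n3 for an m-fold star);
    n1 controls overall pointedness.
    """

    m: float
    n1: float
    n2: float
    n3: float
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("axis scales a, b must be positive")
        if self.n1 == 0:
            raise ValueError("exponent n1 must be nonzero")


# Curated star parameter sets: k-lobed shapes at three protrusion
# amplitudes (version-pinned; the contract is that the dominant lobe mode
# of each shape equals its symmetry count).
STAR_PARAMS: dict[tuple[int, str], SuperformulaParams] = {
    **{(k, "low"): SuperformulaParams(m=k, n1=9.0, n2=7.0, n3=7.0) for k in range(3, 10)},
    **{(k, "mid"): SuperformulaParams(m=k, n1=5.0, n2=9.0, n3=9.0) for k in range(3, 10)},
    **{(k, "high"): SuperformulaParams(m=k, n1=3.0, n2=12.0, n3=12.0) for k in range(3, 10)},
}


def superformula_shape(
    p: SuperformulaParams, n_points: int = 1000, normalise: bool = True
) -> Contour:
    """Sample the superformula at equal polar angles, CCW, area pi."""
    th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    term1 = np.abs(np.cos(p.m * th / 4.0) / p.a) ** p.n2
    term2 = np.abs(np.sin(p.m * th / 4.0) / p.b) ** p.n3
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (term1 + term2) ** (-1.0 / p.n1)
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("superformula parameters give non-finite or non-positive radius")
    c = Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    if normalise:
        c, _ = canonicalise(c)
    return c


def cosine_lobed_circle(
    epsilon: float, l: int, n_points: int = 1000, normalise: bool = True
) -> Contour:
    """r(theta) = 1 + epsilon*cos(l*theta), canonicalised to area pi.

    The calibration fixture: after area normalisation, lobe mode l of
    this shape has amplitude epsilon (peak-to-trough radial excursion of
    2*epsilon equivalent-circle radii).
    """
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must be in [0, 1) to keep the contour simple")
    if l < 2:
        raise ValueError("lobe count l must be >= 2")
    th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = 1.0 + epsilon * np.cos(l * th)
    c = Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    if normalise:
        c, _ = canonicalise(c)
    return c


def synthetic_tissue(
    n_cells: int,
    field_size: int = 256,
    jitter: float = 0.5,
    seed: int = 0,
    margin: int = 0,
) -> LabelImage:
    """Seeded-Voronoi label raster of confluent cell regions.

    Seeds sit on a jittered grid; each pixel takes the ID of its nearest
    seed, which makes every region convex-discrete and hence 4-connected.
    ``margin`` pixels of background can be left around the tissue;
    with the default 0 the tissue fills the field and rim cells touch the
    image border (and are flagged as such on extraction).
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    side = int(np.ceil(np.sqrt(n_cells)))
    usable = field_size - 2 * margin
    if usable < 2 * side:
        raise ValueError("field too small for the requested number of cells")
    rng = np.random.default_rng(seed)
    step = usable / side
    centres = []
    for k in range(n_cells):
        gy, gx = divmod(k, side)
        cx = margin + (gx + 0.5) * step
        cy = margin + (gy + 0.5) * step
        centres.append(
            (
                cx + rng.uniform(-jitter, jitter) * step,
                cy + rng.uniform(-jitter, jitter) * step,
            )
        )
    centres = np.clip(np.asarray(centres), margin, field_size - 1 - margin)
    yy, xx = np.mgrid[0:field_size, 0:field_size]
    pix = np.column_stack([xx.ravel(), yy.ravel()])
    _, nearest = cKDTree(centres).query(pix)
    labels = (nearest + 1).astype(np.int32).reshape(field_size, field_size)
    if margin > 0:
        m = np.zeros_like(labels)
        m[margin:-margin, margin:-margin] = labels[margin:-margin, margin:-margin]
        labels = m
    return LabelImage(labels)
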