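import numpy as np
import pytest

from locoefa import (
    Contour,
    LabelImage,
    STAR_PARAMS,
    canonicalise,
    cosine_lobed_circle,
    efa_decompose,
    loco_spectrum,
    rasterize_polygon,
    resample_contour,
    superformula_shape,
)


def circle_contour(n=1000, radius=1.0, centre=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(
        np.column_stack(
            [centre[0] + radius * np.cos(th), centre[1] + radius * np.sin(th)]
        )
    )


def polar_spectrum(contour, n_harmonics=51):
    """Spectrum of a theta-uniformly sampled shape, polar parameterisation."""
    canon, scale = canonicalise(contour)
    coef = efa_decompose(canon, n_harmonics, scale=scale, spacing="uniform")
    return loco_spectrum(coef)


def chord_spectrum(contour, n_harmonics=51, n_points=1000):
    """Spectrum via the default raster-style path (arc-length resampling)."""
    canon, scale = canonicalise(resample_contour(contour, n_points))
    coef = efa_decompose(canon, n_harmonics, scale=scale, spacing="chord")
    return loco_spectrum(coef)


def star_label_image(k=6, amplitude="mid", grid=512):
    """A k-lobed star rasterised as a single-cell label image."""
    star = superformula_shape(STAR_PARAMS[(k, amplitude)])
    pts = star.points
    centre = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    g = 0.3 * grid / np.max(np.abs(pts - centre))
    mask = rasterize_polygon((pts - centre) * g + grid / 2.0, (grid, grid))
    return LabelImage(mask.astype(np.int32))


@pytest.fixture(scope="session")
def star6():
    return superformula_shape(STAR_PARAMS[(6, "mid")])


@pytest.fixture(scope="session")
def star6_image():
    return star_label_image(6, "mid")


@pytest.fixture(scope="session")
def star6_smooth_image():
    """A gentle six-lobed star: smooth enough that 50 modes reproduce it
    exactly at the rasterisation resolution."""
    return star_label_image(6, "low")


@pytest.fixture(scope="session")
def lobed15():
    """The calibration fixture: r = 1 + 0.15 cos(6 theta), area pi."""
    return cosine_lobed_circle(0.15, 6)
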