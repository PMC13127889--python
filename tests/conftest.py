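import numpy as np
import pytest

from ki67quant import StainModel, generate_slide
from ki67quant.fixtures import FixtureSpec, spec_for_counts


@pytest.fixture(scope="session")
def small_fixture():
    """A 100-nucleus slide with ground truth, shared across read-only tests."""
    spec = spec_for_counts(25, 75, seed=42)
    return generate_slide(spec)


@pytest.fixture(scope="session")
def default_model():
    return StainModel.default(background_rgb=(243, 243, 243))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def h_vec_with_red(red: float) -> np.ndarray:
    """Default hematoxylin vector rotated in-plane so its red component = red."""
    from ki67quant import DEFAULT_H_VEC

    rest = np.array([0.0, DEFAULT_H_VEC[1], DEFAULT_H_VEC[2]])
    rest /= np.linalg.norm(rest)
    return red * np.array([1.0, 0.0, 0.0]) + np.sqrt(1 - red**2) * rest


def true_tissue_mask(slide, truth):
    """Rasterize the ground-truth tissue ellipse at the slide's resolution."""
    ys, xs = np.mgrid[0 : slide.height, 0 : slide.width]
    cx, cy = truth.tissue_polygon.centroid.x, truth.tissue_polygon.centroid.y
    minx, miny, maxx, maxy = truth.tissue_polygon.bounds
    a, b = (maxx - minx) / 2, (maxy - miny) / 2
    x_um = (xs + 0.5) * slide.mpp
    y_um = (ys + 0.5) * slide.mpp
    return ((x_um - cx) / a) ** 2 + ((y_um - cy) / b) ** 2 <= 1.0
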