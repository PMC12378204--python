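import numpy as np
import pytest

from ladkit.geometry import NucleusGeometry, make_geometry
from ladkit.model import CompositionField, ModelParams


@pytest.fixture(scope="session")
def params():
    return ModelParams(c=8e-3, kappa=0.8, phi_h0=0.8, d0=2.5)


@pytest.fixture(scope="session")
def small_geom():
    """16x16-cell square-ish nucleus for brute-force oracles."""
    mask = np.ones((16, 16), dtype=bool)
    boundary = np.array([[0.0, 0.0], [160.0, 0.0], [160.0, 160.0],
                         [0.0, 160.0]])
    from scipy import ndimage
    dist = np.maximum(ndimage.distance_transform_edt(
        np.pad(mask, 1)[1:-1, 1:-1]) * 10.0 - 5.0, 0.0)
    # pad trick keeps edges as boundary cells
    dist = np.minimum.reduce([
        (np.arange(16)[:, None] + 0.5) * 10.0 * np.ones((16, 16)),
        ((15 - np.arange(16))[:, None] + 0.5) * 10.0 * np.ones((16, 16)),
        (np.arange(16)[None, :] + 0.5) * 10.0 * np.ones((16, 16)),
        ((15 - np.arange(16))[None, :] + 0.5) * 10.0 * np.ones((16, 16)),
    ])
    return NucleusGeometry(h=10.0, mask=mask, boundary=boundary,
                           distance=dist)


@pytest.fixture
def random_field(small_geom):
    rng = np.random.default_rng(42)
    phi_n = 0.4 + 0.05 * rng.standard_normal(small_geom.mask.shape)
    phi_d = 0.1 + 0.05 * rng.standard_normal(small_geom.mask.shape)
    return CompositionField(small_geom.h, phi_n, phi_d, small_geom.mask)


@pytest.fixture(scope="session")
def circle_geom():
    return make_geometry("circle", 500.0, 5.0)
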