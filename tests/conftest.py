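"""Shared fixtures: analytic circle/ellipse pairs on adaptive grids.

Everything is generated programmatically; expensive pairs are session
scoped so several test modules can share them.
"""

import numpy as np
import pytest

from shellmatch.energies import EnergyParams, ShapePair
from shellmatch.geometry import build_geometry_fields
from shellmatch.grid import AdaptiveGrid, refine_around_surfaces
from shellmatch.shapes import circle, ellipse
from shellmatch.signed_distance import signed_distance_field


def circle_polygon(center, radius, m=1500):
    th = np.linspace(0, 2 * np.pi, m, endpoint=False)
    return np.c_[center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]


def band_grid(shapes, level, coarse=4, width_cells=4.0):
    g = AdaptiveGrid(2, level=min(coarse, level))
    bands = [(s.sdf, width_cells * 2.0**-level) for s in shapes]
    return refine_around_surfaces(g, bands, level)


def make_pair(shape1, shape2, level, m=1500) -> ShapePair:
    g = band_grid([shape1, shape2], level)
    p1 = shape1.polygon(m)
    p2 = shape2.polygon(m)
    s1 = signed_distance_field(p1, g)
    s2 = signed_distance_field(p2, g)
    return ShapePair(
        g, s1.field, s2.field,
        build_geometry_fields(s1.field), build_geometry_fields(s2.field),
    )


@pytest.fixture(scope="session")
def circle_shape():
    return circle((0.5, 0.5), 0.25)


@pytest.fixture(scope="session")
def same_circle_pair(circle_shape):
    """Identical circles at level 6: the identity is the exact minimizer."""
    return make_pair(circle_shape, circle_shape, 6)


@pytest.fixture(scope="session")
def translated_circle_pair():
    """Circle translated by 0.05 at level 6."""
    return make_pair(circle((0.5, 0.5), 0.22), circle((0.55, 0.5), 0.22), 6)


@pytest.fixture(scope="session")
def circle_ellipse_pair():
    return make_pair(circle((0.5, 0.5), 0.24), ellipse((0.5, 0.5), (0.3, 0.19)), 6)


@pytest.fixture
def band_params():
    return EnergyParams(band_width=2 * 2.0**-6, penalty=0.02, volume_weight=0.025)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170626)
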