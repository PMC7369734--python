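"""Shared fixtures: expensive point sets and histograms are built once per
session; everything is generated programmatically from fixed seeds."""

import numpy as np
import pytest

import cgrsas as c

SEED = 20250918


@pytest.fixture(scope="session")
def uniform_points():
    """2e4 uniform points in the unit square (Euclidean reference object)."""
    rng = np.random.default_rng(SEED)
    return c.PointSet2D(rng.random((20_000, 2)), edge=1.0, label="uniform")


@pytest.fixture(scope="session")
def uniform_hist(uniform_points):
    return c.pair_distance_histogram(uniform_points)


@pytest.fixture(scope="session")
def sierpinski_points():
    """2e4 chaos-game points on the Sierpinski gasket (3 of 4 square maps)."""
    return c.chaos_game_attractor(
        c.square_ifs_maps()[:3], [1 / 3] * 3, 20_000, SEED + 1
    )


@pytest.fixture(scope="session")
def sierpinski_hist(sierpinski_points):
    return c.pair_distance_histogram(sierpinski_points)


@pytest.fixture(scope="session")
def m5_binarized():
    """Equalized + binarized (t=0.4) M5 cascade at n=7."""
    grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M5"], 7))
    return c.binarize(c.equalize_histogram(grid), 0.4)


@pytest.fixture(scope="session")
def m5_binarized_curve(m5_binarized):
    hist = c.pair_distance_histogram(m5_binarized, bin_width=m5_binarized.edge / 1000)
    q = c.default_q_grid(m5_binarized.edge, 1.0)
    return c.debye_intensity(hist, q)
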