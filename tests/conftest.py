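import numpy as np
import pytest

import afmsim as a
from afmsim import fixtures


@pytest.fixture
def cloud_model():
    """20 random spheres (seed 7) grounded on the substrate."""
    return a.orient_and_ground(fixtures.make_random_cloud(20, seed=7))


@pytest.fixture
def small_grid():
    return a.ScanGrid(x0=-3.0, y0=-3.0, spacing=0.6, nx=11, ny=11)


@pytest.fixture
def default_tip():
    return a.TipParameters(radius_nm=0.5, half_angle_deg=10.0)


@pytest.fixture
def blob_model():
    """Asymmetric 3-domain fixture used for orientation-recovery tests."""
    return fixtures.make_multi_blob(3, asymmetric=True, seed=2)


@pytest.fixture
def make_target():
    """Scan a model at a given orientation onto its own auto grid."""

    def _make(model, orientation, tip, spacing=0.4, margin=1.0):
        grounded = a.orient_and_ground(model, orientation)
        grid = a.auto_grid(grounded, spacing=spacing, margin=margin)
        return a.scan(grounded, tip, grid)

    return _make


@pytest.fixture
def random_heightmap():
    """A height map with a square foreground of random positive heights."""

    def _make(seed=0, size=16, lo=4, hi=12):
        rng = np.random.default_rng(seed)
        h = np.zeros((size, size))
        h[lo:hi, lo:hi] = rng.uniform(0.5, 3.0, (hi - lo, hi - lo))
        return a.HeightMap(a.ScanGrid(0.0, 0.0, 1.0, size, size), h)

    return _make
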