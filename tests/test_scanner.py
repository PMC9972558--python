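import math

import numpy as np
import pytest

import afmsim as a
from afmsim import fixtures


class TestTipParameters:
    @pytest.mark.parametrize("radius,angle", [(-1.0, 10.0), (0.0, 10.0), (1.0, 0.0), (1.0, 90.0)])
    def test_invalid_parameters_rejected(self, radius, angle):
        with pytest.raises(ValueError):
            a.TipParameters(radius_nm=radius, half_angle_deg=angle)


class TestContactHeight:
    @pytest.mark.parametrize("radius,angle", [(0.3, 5.0), (1.0, 10.0), (5.0, 45.0)])
    def test_apex_on_top_of_sphere_independent_of_tip(self, radius, angle):
        # directly over the atom the apex rests on the sphere top: h = z + r
        tip = a.TipParameters(radius, angle)
        h = a.tip_contact_height(np.array([0.0, 0.0, 2.0]), 0.15, (0.0, 0.0), tip)
        assert h == pytest.approx(2.15, abs=1e-12)

    def test_sphere_regime_closed_form(self):
        tip = a.TipParameters(1.0, 10.0)
        h = a.tip_contact_height(np.array([0.6, 0.0, 0.0]), 0.2, (0.0, 0.0), tip)
        assert h == pytest.approx(-1.0 + math.sqrt(1.2**2 - 0.6**2), abs=1e-12)

    @pytest.mark.parametrize(
        "z,r,R,theta,d",
        [
            (0.0, 0.2, 1.0, 10.0, 0.6),  # sphere regime
            (0.5, 0.15, 0.5, 15.0, 1.5),  # cone regime
            (0.3, 0.3, 0.8, 30.0, 1.05),  # near the regime boundary
        ],
    )
    def test_closed_form_agrees_with_descent_oracle(self, z, r, R, theta, d):
        tip = a.TipParameters(R, theta)
        model = a.AtomModel(positions=[[d, 0.0, z]], elements=["C"], radii=[r])
        grid = a.ScanGrid(0.0, 0.0, 1.0, 1, 1)
        dz = 1e-4
        analytic = a.scan(model, tip, grid).heights[0, 0]
        oracle = a.scan_oracle(model, tip, grid, dz=dz).heights[0, 0]
        assert analytic == pytest.approx(oracle, abs=2 * dz)

    def test_far_atom_gives_no_contact(self):
        tip = a.TipParameters(1.0, 10.0)
        h = a.tip_contact_height(np.array([50.0, 0.0, 0.5]), 0.2, (0.0, 0.0), tip)
        assert h is None


class TestScan:
    def test_windowed_and_full_paths_identical(self, cloud_model, default_tip, small_grid):
        fast = a.scan(cloud_model, default_tip, small_grid)
        reference = a.scan(cloud_model, default_tip, small_grid, method="full")
        np.testing.assert_array_equal(fast.heights, reference.heights)

    def test_matches_descent_oracle_per_cell(self, cloud_model, default_tip, small_grid):
        dz = 1e-4
        analytic = a.scan(cloud_model, default_tip, small_grid)
        oracle = a.scan_oracle(cloud_model, default_tip, small_grid, dz=dz)
        assert np.max(np.abs(analytic.heights - oracle.heights)) <= 2 * dz

    def test_empty_model_gives_zero_map(self, default_tip, small_grid):
        empty = a.AtomModel(positions=np.zeros((0, 3)), elements=[], radii=np.zeros(0))
        hm = a.scan(empty, default_tip, small_grid)
        assert np.all(hm.heights == 0.0)

    def test_single_atom_peak_is_twice_radius(self, default_tip):
        model = a.orient_and_ground(
            a.AtomModel(positions=[[0.0, 0.0, 0.0]], elements=["C"], radii=[0.2])
        )
        grid = a.ScanGrid(-1.0, -1.0, 0.5, 5, 5)  # cell center exactly at (0, 0)
        hm = a.scan(model, default_tip, grid)
        assert hm.heights[2, 2] == pytest.approx(0.4, abs=1e-12)
        assert hm.max_height == pytest.approx(0.4, abs=1e-12)

    def test_heights_never_negative(self, cloud_model, small_grid):
        hm = a.scan(cloud_model, a.TipParameters(3.0, 40.0), small_grid)
        assert np.all(hm.heights >= 0.0)

    def test_lateral_shift_by_whole_cells_shifts_map(self, cloud_model, default_tip):
        grid = a.ScanGrid(-6.0, -6.0, 0.5, 25, 25)
        base = a.scan(cloud_model, default_tip, grid)
        moved = cloud_model.with_positions(
            cloud_model.positions + np.array([2 * 0.5, -1 * 0.5, 0.0])
        )
        shifted = a.scan(moved, default_tip, grid)
        # interior cells: map content moves by (+2, -1) cells
        np.testing.assert_allclose(
            shifted.heights[:-1, 2:], base.heights[1:, :-2], atol=1e-12
        )

    @pytest.mark.parametrize("radii", [(0.5, 1.0, 2.0)])
    def test_pointwise_monotone_in_tip_radius(self, cloud_model, small_grid, radii):
        maps = [
            a.scan(cloud_model, a.TipParameters(r, 10.0), small_grid).heights
            for r in radii
        ]
        assert np.all(maps[1] >= maps[0] - 1e-12)
        assert np.all(maps[2] >= maps[1] - 1e-12)

    @pytest.mark.parametrize("angles", [(5.0, 15.0, 30.0)])
    def test_pointwise_monotone_in_half_angle(self, cloud_model, small_grid, angles):
        maps = [
            a.scan(cloud_model, a.TipParameters(1.0, t), small_grid).heights
            for t in angles
        ]
        assert np.all(maps[1] >= maps[0] - 1e-12)
        assert np.all(maps[2] >= maps[1] - 1e-12)


class TestEnvelope:
    def test_single_atom_envelope_peak(self):
        model = a.orient_and_ground(
            a.AtomModel(positions=[[0.0, 0.0, 0.0]], elements=["C"], radii=[0.2])
        )
        grid = a.ScanGrid(-1.0, -1.0, 0.5, 5, 5)
        env = a.vdw_envelope(model, grid)
        assert env.heights[2, 2] == pytest.approx(0.4, abs=1e-12)

    def test_any_scan_dominates_envelope(self, cloud_model, small_grid):
        env = a.vdw_envelope(cloud_model, small_grid).heights
        for tip in (a.TipParameters(0.5, 10.0), a.TipParameters(2.0, 30.0)):
            assert np.all(a.scan(cloud_model, tip, small_grid).heights >= env - 1e-12)

    def test_vanishing_tip_recovers_envelope(self, cloud_model, small_grid):
        env = a.vdw_envelope(cloud_model, small_grid).heights
        tiny = a.scan(cloud_model, a.TipParameters(1e-6, 0.01), small_grid).heights
        assert np.max(np.abs(tiny - env)) <= 1e-3


class TestAutoGrid:
    def test_centered_with_odd_counts(self, cloud_model):
        grid = a.auto_grid(cloud_model, spacing=0.5)
        assert grid.nx % 2 == 1 and grid.ny % 2 == 1
        assert 0.0 in grid.x_centers() and 0.0 in grid.y_centers()

    def test_covers_model_footprint_with_margin(self, cloud_model):
        grid = a.auto_grid(cloud_model, spacing=0.5, margin=2.0)
        xmin, xmax, ymin, ymax = grid.extent()
        x, y = cloud_model.positions[:, 0], cloud_model.positions[:, 1]
        r = cloud_model.radii
        assert xmin <= np.min(x - r) and xmax >= np.max(x + r)
        assert ymin <= np.min(y - r) and ymax >= np.max(y + r)

    def test_cell_budget_enforced(self, cloud_model):
        with pytest.raises(ValueError):
            a.auto_grid(cloud_model, spacing=0.001, max_cells=64)
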