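import numpy as np
import pytest

import afmsim as a
from afmsim.fitting import (
    fibonacci_sphere,
    global_search,
    refine,
    sample_orientations,
    score_orientation,
)


class TestSimilarity:
    def test_self_similarity_is_exactly_one(self, random_heightmap):
        hm = random_heightmap(seed=0)
        s = a.similarity(hm, hm)
        assert s.value == 1.0
        assert s.translation == (0, 0)
        assert s.n_pixels >= 2

    @pytest.mark.parametrize("shift", [(3, 2), (-2, 1), (0, -3)])
    def test_shifted_copy_registered_exactly(self, random_heightmap, shift):
        hm = random_heightmap(seed=1, size=20, lo=6, hi=14)
        dx, dy = shift
        shifted = np.roll(np.roll(hm.heights, dy, axis=0), dx, axis=1)
        s = a.similarity(hm, a.HeightMap(hm.grid, shifted))
        assert s.value == 1.0
        assert s.translation == shift

    def test_anticorrelated_map_scores_minus_one(self, random_heightmap):
        hm = random_heightmap(seed=2)
        anti = np.where(hm.heights > 0, 4.0 - hm.heights, 0.0)
        s = a.similarity(a.HeightMap(hm.grid, anti), hm, max_shift=(0, 0))
        assert s.value == pytest.approx(-1.0, abs=1e-9)

    def test_all_zero_target_rejected(self, random_heightmap):
        zero = a.HeightMap(random_heightmap().grid, np.zeros((16, 16)))
        with pytest.raises(a.SimilarityError):
            a.similarity(random_heightmap(), zero)

    def test_pixel_size_mismatch_rejected(self, random_heightmap):
        hm = random_heightmap()
        other = a.HeightMap(a.ScanGrid(0.0, 0.0, 0.5, 16, 16), hm.heights)
        with pytest.raises(ValueError):
            a.similarity(hm, other)

    @pytest.mark.parametrize("seed", range(4))
    def test_score_bounded(self, random_heightmap, seed):
        x = random_heightmap(seed=seed)
        y = random_heightmap(seed=seed + 100, lo=2, hi=13)
        assert -1.0 <= a.similarity(x, y).value <= 1.0

    def test_rmsd_score_of_identical_maps_is_zero(self, random_heightmap):
        hm = random_heightmap(seed=3)
        assert a.similarity(hm, hm, score="rmsd").value == 0.0


class TestOrientationSampling:
    def test_single_sample_is_identity(self):
        (only,) = sample_orientations(1, 1)
        assert only.angle_to(a.Orientation.identity()) < 1e-9

    def test_deterministic(self):
        lib1 = sample_orientations(30, 4)
        lib2 = sample_orientations(30, 4)
        assert all(o1.angle_to(o2) < 1e-12 for o1, o2 in zip(lib1, lib2))

    def test_directions_distinct(self):
        points = fibonacci_sphere(100)
        dots = points @ points.T
        np.fill_diagonal(dots, -1.0)
        # minimal pairwise angular separation strictly positive
        assert np.arccos(np.clip(dots.max(), -1, 1)) > 1e-3

    def test_cap_discrepancy_below_random(self):
        """Fibonacci directions cover the sphere more evenly than random ones."""

        def cap_discrepancy(points, n_caps=400):
            rng = np.random.default_rng(0)
            centers = rng.normal(size=(n_caps, 3))
            centers /= np.linalg.norm(centers, axis=1, keepdims=True)
            cuts = rng.uniform(-1.0, 1.0, n_caps)
            inside = (points @ centers.T) > cuts[None, :]
            return np.max(np.abs(inside.mean(axis=0) - (1.0 - cuts) / 2.0))

        fib = cap_discrepancy(fibonacci_sphere(100))
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            random_points = rng.normal(size=(100, 3))
            random_points /= np.linalg.norm(random_points, axis=1, keepdims=True)
            assert fib < cap_discrepancy(random_points)


class TestGlobalSearch:
    def test_sampled_truth_ranks_first(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        lib = sample_orientations(20, 6)
        target = make_target(blob_model, lib[37], tip)
        table = global_search(blob_model, target, tip, lib)
        assert table.iloc[0]["sample_index"] == 37
        assert table.iloc[0]["score"] >= 0.999
        assert (table["score"].values[:-1] >= table["score"].values[1:]).all()

    def test_zero_target_propagates_error(self, blob_model):
        tip = a.TipParameters(1.0, 10.0)
        zero = a.HeightMap(a.ScanGrid(-5.0, -5.0, 0.4, 26, 26), np.zeros((26, 26)))
        with pytest.raises(a.SimilarityError):
            global_search(blob_model, zero, tip, sample_orientations(2, 2))


class TestRefine:
    def test_fixed_point_at_truth(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        true = a.Orientation.random(7)
        target = make_target(blob_model, true, tip)
        out, best, trace = refine(
            blob_model, target, tip, true, initial_step_deg=4.0, tol_deg=0.5
        )
        assert best.value >= 0.9999
        assert out.angle_to(true) < 1e-9 or best.value >= 0.9999

    def test_recovers_from_five_degrees_off(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        true = a.Orientation.random(7)
        target = make_target(blob_model, true, tip)
        start = a.Orientation.from_axis_angle_deg([0.3, 0.8, 0.52], 5.0).compose(true)
        out, best, trace = refine(
            blob_model, target, tip, start,
            initial_step_deg=4.0, shrink=0.5, tol_deg=0.1,
        )
        assert out.angle_to(true) <= 0.5
        assert best.value >= 0.999

    def test_trace_monotone_nondecreasing(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        target = make_target(blob_model, a.Orientation.random(9), tip)
        _, _, trace = refine(
            blob_model, target, tip, a.Orientation.random(4),
            initial_step_deg=8.0, tol_deg=1.0,
        )
        scores = [s for _, _, s in trace]
        assert all(b >= a_ for a_, b in zip(scores, scores[1:]))

    def test_invalid_step_configuration(self, blob_model, random_heightmap):
        tip = a.TipParameters(1.0, 10.0)
        with pytest.raises(ValueError):
            refine(blob_model, random_heightmap(), tip, a.Orientation.identity(),
                   initial_step_deg=0.1, tol_deg=1.0)


class TestFit:
    CFG = a.FitConfig(n_tip_directions=100, n_spins=12, top_k=3)

    def test_end_to_end_recovery_of_unsampled_orientation(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        true = a.Orientation.random(11)
        target = make_target(blob_model, true, tip)
        result = a.fit(blob_model, target, tip, self.CFG)
        assert result.best_score.value >= 0.99
        assert result.best_orientation.angle_to(true) <= 2.0

    def test_top1_fit_equals_refining_best_candidate(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        target = make_target(blob_model, a.Orientation.random(5), tip)
        cfg = a.FitConfig(n_tip_directions=40, n_spins=6, top_k=1)
        result = a.fit(blob_model, target, tip, cfg)
        lib = sample_orientations(40, 6)
        table = global_search(blob_model, target, tip, lib)
        out, best, _ = refine(
            blob_model, target, tip, table.iloc[0]["orientation"],
            initial_step_deg=cfg.initial_step_deg, shrink=cfg.shrink,
            tol_deg=cfg.tol_deg,
        )
        assert result.best_score.value == best.value
        assert result.best_orientation.angle_to(out) < 1e-12

    def test_deterministic(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        target = make_target(blob_model, a.Orientation.random(8), tip)
        cfg = a.FitConfig(n_tip_directions=30, n_spins=4, top_k=2)
        r1 = a.fit(blob_model, target, tip, cfg)
        r2 = a.fit(blob_model, target, tip, cfg)
        assert r1.best_score == r2.best_score
        np.testing.assert_array_equal(
            r1.best_orientation.as_quat(), r2.best_orientation.as_quat()
        )

    def test_best_score_dominates_candidate_table(self, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        target = make_target(blob_model, a.Orientation.random(3), tip)
        cfg = a.FitConfig(n_tip_directions=30, n_spins=4, top_k=2)
        result = a.fit(blob_model, target, tip, cfg)
        assert result.best_score.value >= result.candidates["score"].max()

    def test_result_serialization(self, tmp_path, blob_model, make_target):
        tip = a.TipParameters(1.0, 10.0)
        target = make_target(blob_model, a.Orientation.random(3), tip)
        cfg = a.FitConfig(n_tip_directions=10, n_spins=4, top_k=1)
        result = a.fit(blob_model, target, tip, cfg)
        out = tmp_path / "fit.json"
        csv = tmp_path / "candidates.csv"
        result.save(out, candidates_csv=csv)
        import json

        payload = json.loads(out.read_text())
        assert "best_orientation" in payload and "best_score" in payload
        assert csv.read_text().count("\n") == len(result.candidates) + 1


class TestSelfFitDiscrimination:
    def test_asymmetric_fixture_has_no_rotational_self_similarity(
        self, blob_model, make_target
    ):
        """Away from the identity, no orientation of the asymmetric fixture
        scores close to the perfect self-match."""
        tip = a.TipParameters(1.0, 10.0)
        target = make_target(blob_model, a.Orientation.identity(), tip)
        lib = sample_orientations(60, 8)
        scores = np.array(
            [score_orientation(blob_model, o, tip, target).value for o in lib]
        )
        angles = np.array([o.angle_to(a.Orientation.identity()) for o in lib])
        assert scores[angles > 25.0].max() <= 1.0 - 0.05
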