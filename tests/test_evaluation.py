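import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinenav.evaluation import (
    CLASS_FAILURE,
    CLASS_MISMATCH,
    CLASS_SUCCESS,
    EvaluationConfig,
    IntensityProfile,
    PropagationMatrix,
    TREResult,
    classify_alignment,
    compute_tre,
    cumulative_level_distances,
    fit_tre_vs_distance,
    intensity_profile,
    profile_ensemble_stats,
    propagation_matrix,
    summarize_rates,
)
from spinenav.geometry import RigidTransform, compose, perturb_transform
from spinenav.volume import Volume

from conftest import random_rigid

STUDY_GAPS = (69.36, 35.33, 38.21, 39.38, 39.46)


def result(level=1, tre=1.0, all_levels=None, depth=5.0, freq=12.0, rep=0, res=0.5):
    tre_by_level = all_levels or {l: tre for l in range(1, 7)}
    return TREResult(level=level, depth_cm=depth, frequency_mhz=freq,
                     repetition=rep, resolution_mm=res, tre_by_level=tre_by_level)


class TestComputeTRE:
    def test_equal_transforms_give_zero(self):
        t = random_rigid(np.random.default_rng(0))
        pts = np.random.default_rng(1).uniform(-50, 50, (7, 3))
        assert compute_tre(t, t, pts) == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_pure_translation_gives_its_norm(self, seed):
        """TRE under a relative translation t is exactly ||t||, for any
        landmarks."""
        rng = np.random.default_rng(seed)
        t_gt = random_rigid(rng)
        shift = rng.uniform(-20, 20, 3)
        t_est = compose(RigidTransform.from_translation(shift), t_gt)
        pts = rng.uniform(-100, 100, (7, 3))
        assert compute_tre(t_est, t_gt, pts) == pytest.approx(
            np.linalg.norm(shift), abs=1e-9
        )

    def test_three_four_translation_is_five(self):
        t_gt = RigidTransform.identity()
        t_est = RigidTransform.from_translation((3, 4, 0))
        pts = np.random.default_rng(2).uniform(-100, 100, (7, 3))
        assert compute_tre(t_est, t_gt, pts) == pytest.approx(5.0, abs=1e-12)

    def test_rotation_chord_closed_form(self):
        """Single landmark at radius d under pure rotation theta about the
        centroid: TRE = 2 d sin(theta/2), to 1e-9."""
        d, theta = 50.0, 10.0
        t_gt = RigidTransform.identity()
        t_est = perturb_transform(t_gt, theta, (0, 0, 1), (0, 0, 0), (0, 0, 0))
        tre = compute_tre(t_est, t_gt, np.array([[d, 0.0, 0.0]]))
        assert tre == pytest.approx(2 * d * np.sin(np.radians(theta / 2)), abs=1e-9)

    def test_empty_landmarks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_tre(RigidTransform.identity(), RigidTransform.identity(),
                        np.empty((0, 3)))


class TestClassifyAlignment:
    @pytest.mark.parametrize(
        "tre,expected",
        [
            (0.0, CLASS_SUCCESS),
            (1.5, CLASS_SUCCESS),
            (1.999999, CLASS_SUCCESS),
            (2.0, CLASS_FAILURE),  # success is strictly below 2 mm
            (9.999, CLASS_FAILURE),
            (10.0, CLASS_MISMATCH),  # mismatch threshold is inclusive
            (67.17, CLASS_MISMATCH),
        ],
    )
    def test_boundaries(self, tre, expected):
        assert classify_alignment(tre) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_alignment(-0.1)

    @given(tre=st.floats(0, 1000, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_partitions_the_half_line(self, tre):
        assert classify_alignment(tre) in {CLASS_SUCCESS, CLASS_FAILURE, CLASS_MISMATCH}

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            EvaluationConfig(success_threshold_mm=11.0, mismatch_threshold_mm=10.0)


class TestSummarizeRates:
    def _batch(self, tres):
        return [result(level=1 + i % 6, tre=t, rep=i) for i, t in enumerate(tres)]

    def test_success_percentages_match_fractions(self):
        """84 of 120 successes -> 70.00%; 14 mismatches -> 11.67%."""
        tres = [1.0] * 84 + [5.0] * 22 + [50.0] * 14
        df = summarize_rates(self._batch(tres), strata=("resolution",))
        row = df.iloc[0]
        assert row["n"] == 120
        assert row["success_pct"] == pytest.approx(70.00, abs=1e-9)
        assert round(row["mismatch_pct"], 2) == 11.67
        assert row["success_pct"] + row["failure_pct"] + row["mismatch_pct"] == (
            pytest.approx(100.0, abs=1e-9)
        )

    def test_all_failures(self):
        df = summarize_rates(self._batch([5.0] * 10), strata=("resolution",))
        assert df.iloc[0]["success_pct"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_rates([])

    @given(n_success=st.integers(0, 30), n_fail=st.integers(0, 30),
           n_mism=st.integers(0, 30))
    @settings(max_examples=30, deadline=None)
    def test_rates_always_sum_to_100(self, n_success, n_fail, n_mism):
        tres = [1.0] * n_success + [5.0] * n_fail + [20.0] * n_mism
        if not tres:
            return
        df = summarize_rates(self._batch(tres), strata=("resolution",))
        total = df[["success_pct", "failure_pct", "mismatch_pct"]].sum(axis=1)
        np.testing.assert_allclose(total, 100.0, atol=1e-9)


class TestPropagationMatrix:
    def test_constant_result_gives_constant_matrix(self):
        results = [result(level=l, tre=3.0) for l in range(1, 7)]
        mat = propagation_matrix(results)
        np.testing.assert_allclose(mat.cells, 3.0)

    def test_perfect_registrations_give_zero_matrix(self):
        results = [result(level=l, tre=0.0) for l in range(1, 7)]
        np.testing.assert_allclose(propagation_matrix(results).cells, 0.0)

    def test_lever_arm_makes_off_diagonal_larger(self):
        """Pure rotation about each acquisition level's centroid: TRE grows
        away from the diagonal."""
        dist = cumulative_level_distances(STUDY_GAPS)
        results = []
        for i in range(6):
            tre_by_level = {j + 1: 0.1 + 0.02 * dist[i, j] for j in range(6)}
            results.append(result(level=i + 1, all_levels=tre_by_level))
        mat = propagation_matrix(results)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert mat.cells[i, j] > mat.cells[i, i]

    def test_missing_levels_rejected(self):
        r = result(level=1, all_levels={1: 1.0})
        r2 = result(level=2, all_levels={1: 1.0, 2: 1.0})
        with pytest.raises(ValueError, match="lacks TRE"):
            propagation_matrix([r, r2])


class TestCumulativeDistances:
    def test_study_gaps_span(self):
        """The five printed gaps sum to the printed L1-L6 span, 221.74 mm."""
        dist = cumulative_level_distances(STUDY_GAPS)
        assert dist[0, 5] == pytest.approx(221.74, abs=1e-9)

    def test_single_gap(self):
        dist = cumulative_level_distances([12.5])
        assert dist[0, 1] == 12.5

    def test_symmetric_with_zero_diagonal(self):
        dist = cumulative_level_distances(STUDY_GAPS)
        np.testing.assert_allclose(dist, dist.T)
        np.testing.assert_allclose(np.diag(dist), 0.0)

    def test_non_positive_gap_rejected(self):
        with pytest.raises(ValueError):
            cumulative_level_distances([10.0, 0.0])


class TestFitTREvsDistance:
    def test_exact_linear_data(self):
        dist = cumulative_level_distances(STUDY_GAPS)
        mat = PropagationMatrix(levels=list(range(1, 7)), cells=0.02 * dist + 1.0)
        fit = fit_tre_vs_distance(mat, dist)
        assert fit.slope == pytest.approx(0.02, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.residual_rms < 1e-9

    def test_constant_matrix_gives_zero_slope(self):
        dist = cumulative_level_distances(STUDY_GAPS)
        mat = PropagationMatrix(levels=list(range(1, 7)), cells=np.full((6, 6), 2.0))
        assert fit_tre_vs_distance(mat, dist).slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        dist = cumulative_level_distances(STUDY_GAPS)
        cells = np.abs(0.02 * dist + 1.0 + rng.normal(0, 0.1, (6, 6)))
        mat = PropagationMatrix(levels=list(range(1, 7)), cells=cells)
        fit = fit_tre_vs_distance(mat, dist)
        x, y = dist.ravel(), cells.ravel()
        a = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(a.T @ a, a.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-9)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-9)

    def test_degenerate_distances_rejected(self):
        mat = PropagationMatrix(levels=[1], cells=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            fit_tre_vs_distance(mat, np.zeros((1, 1)))


class TestIntensityProfile:
    def _ramp_volume(self):
        arr = np.broadcast_to(np.arange(20, dtype=float)[:, None, None],
                              (20, 10, 10)).copy()
        return Volume(arr, np.ones(3), np.zeros(3))

    def test_constant_volume(self):
        vol = Volume(np.full((10, 10, 10), 4.5), np.ones(3), np.zeros(3))
        prof = intensity_profile(vol, (1, 1, 1), (8, 8, 8), 20)
        np.testing.assert_allclose(prof.values, 4.5)

    def test_linear_ramp_is_linear(self):
        """Trilinear sampling of an axis-aligned ramp is exactly linear."""
        prof = intensity_profile(self._ramp_volume(), (2, 5, 5), (15, 5, 5), 27)
        expected = np.linspace(2, 15, 27)
        np.testing.assert_allclose(prof.values, expected, atol=1e-9)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            intensity_profile(self._ramp_volume(), (1, 1, 1), (1, 1, 1), 5)

    def test_out_of_volume_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            intensity_profile(self._ramp_volume(), (1, 1, 1), (100, 1, 1), 5)


def test_sweep_profile_spread_peaks_at_bone_interface(study_phantom):
    """Across 20 simulated acquisitions of L5, the intensity spread (IQR)
    along a line crossing the lamina is widest near the bone interface:
    echo position varies with probe pose while cavity speckle and shadow
    are stable."""
    from spinenav.evaluation import sample_sweep_profile
    from spinenav.ultrasound import SweepConfig, simulate_sweep

    z5 = study_phantom.config.apex_z_positions()[4]
    lam_top_y = study_phantom.config.shape.lam_y_range[1]
    p0 = np.array([6.0, 12.0, z5])
    p1 = np.array([6.0, -10.0, z5])
    profiles = []
    for rep in range(20):
        cfg = SweepConfig(depth_cm=5 if rep % 2 == 0 else 7,
                          frequency_mhz=6 if (rep // 2) % 2 == 0 else 12,
                          seed=100 + rep)
        sweep = simulate_sweep(study_phantom, 5, cfg)
        profiles.append(
            sample_sweep_profile(sweep, RigidTransform.identity(), p0, p1, 60)
        )
    stats = profile_ensemble_stats(profiles)
    interface = p0[1] - lam_top_y  # distance along the segment to the surface
    peak_pos = stats.positions_mm[np.argmax(stats.iqr)]
    assert abs(peak_pos - interface) <= 3.0
    assert stats.iqr.max() > 3 * stats.iqr[:5].mean()
    assert stats.iqr.max() > 3 * stats.iqr[-5:].mean()


class TestProfileEnsemble:
    def _profile(self, values):
        return IntensityProfile(np.arange(len(values), dtype=float), np.asarray(values))

    def test_single_profile_has_zero_iqr(self):
        stats = profile_ensemble_stats([self._profile([1.0, 2.0, 3.0])])
        np.testing.assert_allclose(stats.values, [1, 2, 3])
        np.testing.assert_allclose(stats.iqr, 0.0)

    def test_two_offset_profiles(self):
        """Median of {c, c+2} is c+1; IQR follows the linear-interpolation
        quantile rule: Q3-Q1 = 1."""
        stats = profile_ensemble_stats(
            [self._profile([1.0, 1.0]), self._profile([3.0, 3.0])]
        )
        np.testing.assert_allclose(stats.values, 2.0)
        q1, q3 = np.quantile([1.0, 3.0], [0.25, 0.75], method="linear")
        np.testing.assert_allclose(stats.iqr, q3 - q1)

    def test_mismatched_grids_rejected(self):
        a = self._profile([1.0, 2.0])
        b = IntensityProfile(np.array([0.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="mismatched"):
            profile_ensemble_stats([a, b])
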