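import numpy as np
import pandas as pd
import pytest

from spinenav.coverage import (
    COVERAGE_BINS,
    LABELS,
    CoverageHistogram,
    build_accuracy_design,
    build_misalignment_response,
    compute_coverage,
    fit_accuracy_model,
    fit_mismatch_model,
    simulate_coverage_design,
)
from spinenav.evaluation import TREResult
from spinenav.geometry import RigidTransform, compose
from spinenav.phantom import region_code
from spinenav.ultrasound import SweepConfig, TrackedFrame, TrackedSweep
from spinenav.volume import Volume

from conftest import random_rigid
from test_ultrasound import probe_pose_at, zero_jitter


def coverage_oracle(sweep, labelmap, t_gt, level, step_mm):
    """Brute-force per-ray marching with explicit python loops and the same
    unique-voxel and binning rules; the independent check for
    compute_coverage."""
    cfg = sweep.config
    u = cfg.column_positions_mm()
    shape = np.array(labelmap.shape)
    hit_sets = {b: set() for b in COVERAGE_BINS}
    n_steps = int(np.ceil(cfg.depth_mm / step_mm))
    for frame in sweep.frames:
        pose_ct = compose(t_gt, frame.pose)
        lateral = pose_ct.rotation[:, 0]
        depth = pose_ct.rotation[:, 1]
        for j in range(cfg.n_cols):
            origin = pose_ct.translation + u[j] * lateral
            for k in range(n_steps):
                p = origin + (k + 0.5) * step_mm * depth
                idx = np.rint((p - labelmap.origin) / labelmap.spacing).astype(int)
                if np.any(idx < 0) or np.any(idx >= shape):
                    continue
                lab = int(labelmap.array[idx[0], idx[1], idx[2]])
                if lab == 0:
                    continue
                hit_level = (lab - 1) // 5 + 1
                region = (lab - 1) % 5
                if hit_level == level:
                    hit_sets[LABELS[region]].add(tuple(idx))
                elif hit_level == level + 1:
                    hit_sets["Inf"].add(tuple(idx))
                elif hit_level == level - 1:
                    hit_sets["Sup"].add(tuple(idx))
                break  # first labelled voxel stops the ray
    return {b: len(s) for b, s in hit_sets.items()}


def random_scene(seed: int):
    """A small random labelled scene and a 1-3 frame synthetic sweep."""
    rng = np.random.default_rng(seed)
    n = rng.integers(16, 33)
    labels = np.zeros((n, n, n), dtype=np.int16)
    for _ in range(rng.integers(2, 6)):
        lvl = rng.integers(1, 4)
        reg = rng.integers(1, 6)
        c = rng.uniform(4, n - 4, 3)
        r = rng.uniform(2, 6)
        g = np.arange(n)
        x, y, z = np.meshgrid(g, g, g, indexing="ij")
        ball = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r**2
        labels[ball] = (lvl - 1) * 5 + reg
    vol = Volume(labels, np.ones(3), np.zeros(3))
    cfg = zero_jitter(n_frames=1, n_cols=16, n_rows=32)
    frames = []
    for i in range(rng.integers(1, 4)):
        x0 = rng.uniform(2, n - 2)
        z0 = rng.uniform(2, n - 2)
        frames.append(TrackedFrame(np.zeros((cfg.n_rows, cfg.n_cols), np.float32),
                                   probe_pose_at(x0, n + 2.0, z0)))
    sweep = TrackedSweep(frames=frames, config=cfg, level=2)
    return sweep, vol


class TestComputeCoverage:
    def test_empty_sweep_outside_volume(self):
        sweep, vol = random_scene(0)
        far = RigidTransform.from_translation((500.0, 0, 0))
        hist = compute_coverage(sweep, vol, far, level=2)
        assert all(v == 0 for v in hist.counts.values())

    def test_single_slab_column(self):
        """One ray into a one-voxel slab of region L counts exactly {L: 1}."""
        labels = np.zeros((3, 9, 3), dtype=np.int16)
        labels[1, 4, 1] = region_code(1, "L")
        vol = Volume(labels, np.ones(3), np.zeros(3))
        cfg = zero_jitter(n_frames=1, n_cols=1, n_rows=16, frame_width_mm=1.0)
        sweep = TrackedSweep(
            frames=[TrackedFrame(np.zeros((16, 1), np.float32),
                                 probe_pose_at(1.0, 12.0, 1.0))],
            config=cfg, level=1,
        )
        hist = compute_coverage(sweep, vol, RigidTransform.identity())
        assert hist.counts == {"SP": 0, "L": 1, "AP": 0, "TP": 0, "VB": 0,
                               "Inf": 0, "Sup": 0}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        """Vectorized marching equals the per-ray oracle at a fine step."""
        sweep, vol = random_scene(seed)
        step = float(vol.spacing.min()) / 10
        hist = compute_coverage(sweep, vol, RigidTransform.identity(), level=2,
                                step_mm=step)
        oracle = coverage_oracle(sweep, vol, RigidTransform.identity(), 2, step)
        assert hist.counts == oracle

    def test_adding_frames_never_decreases_counts(self):
        sweep, vol = random_scene(5)
        if len(sweep.frames) < 2:
            sweep.frames.append(sweep.frames[0])
        partial = TrackedSweep(frames=sweep.frames[:1], config=sweep.config,
                               level=2)
        h1 = compute_coverage(partial, vol, RigidTransform.identity())
        h2 = compute_coverage(sweep, vol, RigidTransform.identity())
        for b in COVERAGE_BINS:
            assert h2.counts[b] >= h1.counts[b]

    def test_determinism(self):
        sweep, vol = random_scene(7)
        a = compute_coverage(sweep, vol, RigidTransform.identity())
        b = compute_coverage(sweep, vol, RigidTransform.identity())
        assert a.counts == b.counts

    def test_occluded_voxel_never_counted(self):
        """A slab strictly behind another on every ray contributes nothing."""
        labels = np.zeros((5, 12, 5), dtype=np.int16)
        labels[:, 8, :] = region_code(1, "SP")  # posterior slab (hit first)
        labels[:, 3, :] = region_code(1, "VB")  # occluded deeper slab
        vol = Volume(labels, np.ones(3), np.zeros(3))
        cfg = zero_jitter(n_frames=1, n_cols=16, n_rows=32)
        sweep = TrackedSweep(
            frames=[TrackedFrame(np.zeros((32, 16), np.float32),
                                 probe_pose_at(2.0, 15.0, 2.0))],
            config=cfg, level=1,
        )
        hist = compute_coverage(sweep, vol, RigidTransform.identity())
        assert hist.counts["VB"] == 0
        assert hist.counts["SP"] > 0

    def test_too_large_step_rejected(self):
        sweep, vol = random_scene(1)
        with pytest.raises(ValueError, match="step"):
            compute_coverage(sweep, vol, RigidTransform.identity(), step_mm=10.0)


def make_hist(level=1, **counts):
    base = {b: 0 for b in COVERAGE_BINS}
    base.update(counts)
    return CoverageHistogram(level=level, counts=base, depth_cm=5.0,
                             frequency_mhz=12.0)


def make_result(level=1, tre=1.0):
    return TREResult(level=level, depth_cm=5.0, frequency_mhz=12.0, repetition=0,
                     resolution_mm=0.5, tre_by_level={level: tre})


class TestDesignConstruction:
    def test_five_main_plus_ten_interactions(self):
        hists = [make_hist(SP=1, L=2, AP=3)]
        res = [make_result(tre=1.0)]
        design = build_accuracy_design(hists, res)
        fixed = [c for c in design.columns
                 if c in LABELS or ":" in c]
        assert len(fixed) == 15
        assert design.loc[0, "L:AP"] == 6.0

    def test_mismatch_rows_excluded(self):
        hists = [make_hist(), make_hist()]
        res = [make_result(tre=1.0), make_result(tre=50.0)]
        design = build_accuracy_design(hists, res)
        assert len(design) == 1

    def test_all_zero_coverage_row_retained(self):
        design = build_accuracy_design([make_hist()], [make_result()])
        assert len(design) == 1
        assert design[list(LABELS)].to_numpy().sum() == 0

    def test_empty_after_removal_rejected(self):
        with pytest.raises(ValueError, match="no acquisitions"):
            build_accuracy_design([make_hist()], [make_result(tre=50.0)])


class TestMisalignmentResponse:
    def test_threshold_rule(self):
        res = [make_result(tre=1.4), make_result(tre=67.17)]
        hists = [make_hist(), make_hist()]
        df = build_misalignment_response(res, hists)
        assert df["mismatch"].tolist() == [0, 1]

    def test_covariate_excludes_adjacent_levels(self):
        h = make_hist(SP=2, L=3, Inf=9, Sup=9)
        df = build_misalignment_response([make_result()], [h])
        assert df["coverage_sum"].iloc[0] == 5


class TestAccuracyModel:
    def test_recovers_planted_laminae_effect(self):
        """TRE generated with a -0.001 mm/voxel laminae slope: estimate is
        negative and within 2 SE of truth (majority of seeds)."""
        hits = 0
        for seed in range(10):
            design, _ = simulate_coverage_design(seed, beta_l_per_voxel=-0.001)
            fit = fit_accuracy_model(design)
            row = fit.term("L")
            if row["estimate"] < 0 and abs(row["estimate"] + 0.001) <= 2 * row["se"]:
                hits += 1
        assert hits >= 8

    def test_zero_variance_response_gives_zero_slopes(self):
        design, _ = simulate_coverage_design(0)
        design["tre"] = 2.0
        fit = fit_accuracy_model(design)
        np.testing.assert_allclose(fit.coefficients["estimate"], 0.0)

    def test_null_type_I_error_controlled(self):
        """Pure-noise response: the laminae term is significant at 5% in at
        most ~10% of simulated datasets."""
        sig = 0
        n_rep = 60
        for seed in range(n_rep):
            design, _ = simulate_coverage_design(3_000 + seed, beta_l_per_voxel=0.0)
            fit = fit_accuracy_model(design)
            if fit.term("L")["pvalue"] < 0.05:
                sig += 1
        assert sig / n_rep <= 0.10


class TestMismatchModel:
    def test_null_type_I_error_controlled(self):
        sig = 0
        used = 0
        for seed in range(40):
            _, mm = simulate_coverage_design(7_000 + seed, mismatch_logit_slope=0.0)
            if mm["mismatch"].nunique() < 2:
                continue
            fit = fit_mismatch_model(mm)
            p = fit.term("coverage_sum")["pvalue"]
            if np.isfinite(p):
                used += 1
                if p < 0.05:
                    sig += 1
        assert used >= 30
        assert sig / used <= 0.10

    def test_separation_flagged(self):
        df = pd.DataFrame({
            "mismatch": [0] * 10 + [1] * 10,
            "coverage_sum": list(range(10)) + list(range(100, 110)),
            "level": [1, 2] * 10,
            "depth_cm": [5.0] * 20,
            "frequency_mhz": [6.0] * 20,
        })
        fit = fit_mismatch_model(df)
        assert not fit.converged

    def test_slope_invariant_to_covariate_shift(self):
        _, mm = simulate_coverage_design(11, mismatch_logit_slope=-0.002)
        if mm["mismatch"].nunique() < 2:
            pytest.skip("degenerate draw")
        fit_a = fit_mismatch_model(mm)
        shifted = mm.copy()
        shifted["coverage_sum"] = shifted["coverage_sum"] + 500.0
        fit_b = fit_mismatch_model(shifted)
        assert fit_a.term("coverage_sum")["estimate"] == pytest.approx(
            fit_b.term("coverage_sum")["estimate"], rel=1e-6, abs=1e-12
        )

    def test_requires_both_classes(self):
        df = pd.DataFrame({"mismatch": [0, 0], "coverage_sum": [1.0, 2.0],
                           "level": [1, 2], "depth_cm": [5.0, 5.0],
                           "frequency_mhz": [6.0, 6.0]})
        with pytest.raises(ValueError):
            fit_mismatch_model(df)
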