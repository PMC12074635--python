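"""Whisker video generation, tracking and Z/AUC scoring."""

import numpy as np
import pytest

from optopair import whisker_kinematics as wk
from optopair.opsin_models import Trace


def constant_fns(angles):
    return [lambda t, a=a: np.full_like(t, a) for a in angles]


class TestGenerator:
    def test_frame_count_at_750_fps(self):
        stack, _ = wk.generate_whisker_video(
            n_whiskers=1, duration=1.0, fps=750.0, noise_sd=0.0, seed=0,
            angle_fns=constant_fns([55.0]),
        )
        assert stack.n_frames == 750

    def test_noiseless_constant_angle_frames_identical(self):
        stack, _ = wk.generate_whisker_video(
            n_whiskers=2, duration=0.1, noise_sd=0.0, seed=0,
            angle_fns=constant_fns([40.0, 60.0]),
        )
        assert all(np.array_equal(stack.frames[0], f) for f in stack.frames)

    def test_seed_determinism(self):
        mk = lambda: wk.generate_whisker_video(
            n_whiskers=1, duration=0.05, noise_sd=8.0, seed=11,
            angle_fns=constant_fns([55.0]),
        )[0].frames
        assert np.array_equal(mk(), mk())

    def test_too_close_pivots_rejected(self):
        with pytest.raises(ValueError):
            wk.generate_whisker_video(n_whiskers=2, pivot_spacing=20, roi_width=56)

    def test_whisker_count_bounds(self):
        with pytest.raises(ValueError):
            wk.generate_whisker_video(n_whiskers=0)


class TestTracker:
    @pytest.mark.parametrize("angle", [0.0, 45.0, 27.5])
    def test_single_frame_angle_recovery(self, angle):
        stack, truth = wk.generate_whisker_video(
            n_whiskers=1, duration=0.01, fps=750.0, noise_sd=0.0, seed=0,
            angle_fns=constant_fns([angle]),
        )
        roi = wk.default_rois(truth, stack.frames.shape[1:])[0]
        est, resid = wk.angle_from_frame(stack.frames[0], roi)
        assert est == pytest.approx(angle, abs=0.5)

    def test_noisy_frame_within_half_degree(self):
        stack, truth = wk.generate_whisker_video(
            n_whiskers=1, duration=0.01, noise_sd=8.0, seed=3,
            angle_fns=constant_fns([27.5]),
        )
        roi = wk.default_rois(truth, stack.frames.shape[1:])[0]
        est, _ = wk.angle_from_frame(stack.frames[0], roi)
        assert est == pytest.approx(27.5, abs=0.5)

    def test_empty_roi_flags_missing(self):
        frame = np.zeros((56, 56), dtype=np.uint8)
        est, resid = wk.angle_from_frame(frame, (0, 56, 0, 56))
        assert np.isnan(est) and np.isnan(resid)

    def test_static_video_constant_trace(self):
        stack, truth = wk.generate_whisker_video(
            n_whiskers=1, duration=0.05, noise_sd=0.0, seed=0,
            angle_fns=constant_fns([55.0]),
        )
        tr = wk.track_angles(stack, wk.default_rois(truth, stack.frames.shape[1:]))
        assert np.nanstd(tr.angles[0]) < 1e-9

    def test_sinusoidal_rmse_below_one_degree(self):
        fns = [lambda t: 45.0 + 15.0 * np.sin(2 * np.pi * 5.0 * t)]
        stack, truth = wk.generate_whisker_video(
            n_whiskers=1, duration=0.3, noise_sd=8.0, seed=5, angle_fns=fns,
        )
        tr = wk.track_angles(stack, wk.default_rois(truth, stack.frames.shape[1:]))
        rmse = np.sqrt(np.nanmean((tr.angles - truth.angles) ** 2))
        assert rmse < 1.0

    def test_two_whiskers_no_roi_cross_talk(self):
        fns = [
            lambda t: 40.0 + 10.0 * np.sin(2 * np.pi * 4.0 * t),
            lambda t: 65.0 - 12.0 * np.sin(2 * np.pi * 7.0 * t),
        ]
        stack, truth = wk.generate_whisker_video(
            n_whiskers=2, duration=0.2, noise_sd=4.0, seed=7, angle_fns=fns,
        )
        tr = wk.track_angles(stack, wk.default_rois(truth, stack.frames.shape[1:]))
        for w in range(2):
            rmse = np.sqrt(np.nanmean((tr.angles[w] - truth.angles[w]) ** 2))
            assert rmse < 1.0

    def test_rotation_equivariance_of_error(self):
        # tracker accuracy does not depend on the absolute whisker angle
        errs = []
        for base in (10.0, 30.0, 55.0):
            stack, truth = wk.generate_whisker_video(
                n_whiskers=1, duration=0.05, noise_sd=8.0, seed=9,
                angle_fns=constant_fns([base]),
            )
            tr = wk.track_angles(stack, wk.default_rois(truth, stack.frames.shape[1:]))
            errs.append(np.sqrt(np.nanmean((tr.angles - truth.angles) ** 2)))
        assert max(errs) < 1.0


def make_angle_trace(angles, fps=750.0):
    arr = np.asarray(angles, dtype=float)[None, :]
    return wk.AngleTrace(fps=fps, whisker_ids=[0], angles=arr,
                         quality=np.zeros_like(arr))


class TestZScore:
    def test_hand_computed_example(self):
        # baseline angles [10,12,11,9,8] deg; response at 20 deg:
        # d = 10, z = (10 - 1.2)/0.8367 = 10.52
        base = [10.0, 12.0, 11.0, 9.0, 8.0] * 10  # 50 frames
        tr = make_angle_trace(base + [20.0])
        z = wk.zscore_trace(tr, (0.0, 50.0 / 750.0))
        mu = np.mean(base)
        d_base = np.abs(np.array(base) - mu)
        expected = (10.0 - d_base.mean()) / d_base.std(ddof=1)
        assert z.values[-1] == pytest.approx(expected, rel=1e-9)

    def test_baseline_standardization_mean_zero(self):
        rng = np.random.default_rng(0)
        tr = make_angle_trace(55.0 + rng.normal(0, 1.0, 300))
        z = wk.zscore_trace(tr, (0.0, 300.0 / 750.0))
        assert abs(np.mean(z.values[:300])) < 0.15

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        a = 55.0 + rng.normal(0, 1.0, 200)
        z1 = wk.zscore_trace(make_angle_trace(a), (0.0, 100.0 / 750.0))
        z2 = wk.zscore_trace(make_angle_trace(a + 17.0), (0.0, 100.0 / 750.0))
        assert np.allclose(z1.values, z2.values, atol=1e-9)

    def test_short_baseline_rejected(self):
        tr = make_angle_trace(np.arange(100.0))
        with pytest.raises(ValueError):
            wk.zscore_trace(tr, (0.0, 30.0 / 750.0))

    def test_degenerate_baseline_rejected(self):
        tr = make_angle_trace(np.full(200, 55.0))
        with pytest.raises(wk.DegenerateBaselineError):
            wk.zscore_trace(tr, (0.0, 100.0 / 750.0))


class TestAUC:
    def test_constant_z_auc(self):
        z = Trace(0.0, 1 / 750.0, np.full(750, 5.0), "dimensionless", "zscore")
        res = wk.response_auc(z, onset=0.2, window=200.0)
        assert res.auc == pytest.approx(1.0, rel=1e-9)
        assert res.auc == pytest.approx(res.z_mean * res.window)

    def test_zero_z_auc(self):
        z = Trace(0.0, 1 / 750.0, np.zeros(750), "dimensionless", "zscore")
        assert wk.response_auc(z, 0.2).auc == 0.0

    def test_ramp_z_hand_integral(self):
        dt = 1e-4
        t = np.arange(5000) * dt
        z = Trace(0.0, dt, np.clip(t / 0.2, 0, None), "dimensionless", "zscore")
        res = wk.response_auc(z, onset=0.0, window=200.0)
        assert res.z_mean == pytest.approx(0.5, abs=1e-3)
        assert res.auc == pytest.approx(0.1, abs=2e-4)

    def test_window_beyond_trace_rejected(self):
        z = Trace(0.0, 1 / 750.0, np.zeros(100), "dimensionless", "zscore")
        with pytest.raises(ValueError):
            wk.response_auc(z, onset=0.1, window=200.0)


class TestAUCRatio:
    def test_identical_wavelength_responses_ratio_one(self):
        data = {f"a{i}": {450.0: [2.0, 2.1, 1.9], 638.0: [2.0, 2.1, 1.9]}
                for i in range(3)}
        res = wk.auc_ratio_analysis(data)
        assert all(r == pytest.approx(1.0) for r in res.ratios.values())

    def test_known_per_animal_ratios(self):
        ratios = [0.1, 0.15, 0.2, 0.15]
        data = {
            f"a{i}": {450.0: [r], 638.0: [1.0]} for i, r in enumerate(ratios)
        }
        res = wk.auc_ratio_analysis(data)
        assert res.mean == pytest.approx(0.15)

    def test_group_comparison_t_test(self):
        g1 = {f"a{i}": {450.0: [0.6 + 0.02 * i], 638.0: [1.0]} for i in range(4)}
        g2 = {f"b{i}": {450.0: [0.1 + 0.02 * i], 638.0: [1.0]} for i in range(4)}
        res = wk.auc_ratio_analysis(g1, comparison=g2)
        t, df, p, paired = res.ttest
        assert t > 0 and p < 0.01 and not paired

    def test_zero_red_auc_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wk.auc_ratio_analysis({"a": {450.0: [1.0], 638.0: [0.0]}})


def test_pure_noise_auc_mean_near_zero():
    # with no response the windowed Z has zero expectation; over seeds the
    # mean AUC must lie within two standard errors of zero
    aucs = []
    for seed in range(8):
        stack, truth = wk.generate_whisker_video(
            n_whiskers=1, duration=0.4, noise_sd=8.0, seed=seed,
            angle_fns=[lambda t: np.full_like(t, 55.0)],
        )
        tr = wk.track_angles(stack, wk.default_rois(truth, stack.frames.shape[1:]))
        z = wk.zscore_trace(tr, (0.0, 0.2))
        aucs.append(wk.response_auc(z, 0.2).auc)
    aucs = np.array(aucs)
    sem = aucs.std(ddof=1) / np.sqrt(aucs.size)
    assert abs(aucs.mean()) < 2 * sem + 1e-9
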