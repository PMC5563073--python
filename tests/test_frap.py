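"""Drift/bleach correction, recovery normalization, fits, F test, FVI."""

import numpy as np
import pytest
import scipy.ndimage as ndi

import axodyn as ax
from axodyn.frap import FitResult, FviSeries, RecoveryCurve


def textured_frame(shape=(64, 64), seed=0):
    rng = np.random.default_rng(seed)
    frame = rng.random(shape)
    return ndi.gaussian_filter(frame, 2) * 100 + 10


class TestDriftCorrect:
    def test_known_shifts_recovered(self):
        base = textured_frame()
        shifts_true = [(0, 0), (3, -2), (-4, 1)]
        stack = np.stack([ndi.shift(base, s, order=1, mode="nearest") for s in shifts_true])
        corrected, shifts = ax.drift_correct(stack)
        for got, true in zip(shifts[1:], shifts_true[1:]):
            assert np.allclose(got, [-true[0], -true[1]], atol=0.5)
        # after correction every frame matches the reference closely
        for frame in corrected[1:]:
            inner = (slice(8, -8), slice(8, -8))
            assert np.corrcoef(frame[inner].ravel(), base[inner].ravel())[0, 1] > 0.97

    def test_identical_frames_zero_shift(self):
        base = textured_frame(seed=1)
        _, shifts = ax.drift_correct(np.stack([base, base, base]))
        assert np.allclose(shifts, 0.0)

    def test_random_shift_round_trip(self):
        """Applying known shifts and correcting recovers them within 0.5 px."""
        rng = np.random.default_rng(7)
        base = textured_frame(seed=2)
        true = rng.integers(-5, 6, size=(5, 2))
        true[0] = 0
        stack = np.stack([ndi.shift(base, s, order=0, mode="nearest") for s in true])
        _, shifts = ax.drift_correct(stack)
        assert np.allclose(shifts, -true, atol=0.5)

    def test_featureless_frames_warn(self):
        with pytest.warns(UserWarning, match="featureless"):
            ax.drift_correct(np.zeros((2, 16, 16)))


class TestBleachCorrect:
    def test_exponential_decay_flattened(self):
        base = textured_frame(seed=3)
        stack = np.stack([base * np.exp(-0.1 * k) for k in range(8)])
        corrected = ax.bleach_correct(stack)
        ref_mean = corrected[0].mean()
        for frame in corrected:
            assert frame.mean() == pytest.approx(ref_mean, rel=0.01)

    def test_reference_frame_unchanged(self):
        base = textured_frame(seed=4)
        stack = np.stack([base, base * 0.7])
        corrected = ax.bleach_correct(stack)
        assert np.allclose(corrected[0], base)

    def test_constant_stack_unchanged(self):
        stack = np.full((4, 16, 16), 7.0)
        assert np.allclose(ax.bleach_correct(stack), stack)


def synthetic_series(post_values, pre_value=100.0, background=10.0, dt=1.0):
    """Minimal FrapSeries with flat frames at prescribed roi intensities."""
    shape = (24, 24)
    roi = np.zeros(shape, bool)
    roi[8:16, 4:20] = True
    shaft = np.zeros(shape, bool)
    shaft[8:16, 4:12] = True
    branch = np.zeros(shape, bool)
    branch[8:16, 12:20] = True
    bg = np.zeros(shape, bool)
    bg[0:4, :] = True
    def frame(v):
        f = np.full(shape, background)
        f[roi] = v + background
        return f
    return ax.FrapSeries(
        pre_bleach=np.stack([frame(pre_value)] * 3),
        post_bleach=np.stack([frame(v) for v in post_values]),
        t_s=np.arange(len(post_values), dtype=float) * dt,
        roi_mask=roi, shaft_mask=shaft, branch_mask=branch, background_region=bg,
        frame_interval_s=dt,
    )


class TestNormalizeRecovery:
    def test_flat_series_gives_zero(self):
        series = synthetic_series([20.0] * 6)
        curve = ax.normalize_recovery(series)
        assert np.allclose(curve.r, 0.0)

    def test_full_return_from_zero_gives_one(self):
        series = synthetic_series([0.0, 50.0, 100.0])
        curve = ax.normalize_recovery(series)
        assert curve.r[-1] == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self):
        """Gain/offset applied to every frame leaves R(t) unchanged."""
        values = [5.0, 20.0, 40.0, 55.0]
        a = ax.normalize_recovery(synthetic_series(values))
        series_b = synthetic_series(values)
        gain, offset = 3.7, 25.0
        series_b.pre_bleach = series_b.pre_bleach * gain + offset
        series_b.post_bleach = series_b.post_bleach * gain + offset
        b = ax.normalize_recovery(series_b)
        assert np.allclose(a.r, b.r)

    def test_invalid_bleach_reference_rejected(self):
        series = synthetic_series([10.0], pre_value=0.0)
        with pytest.raises(ValueError, match="background"):
            ax.normalize_recovery(series)

    def test_masks_must_be_disjoint(self):
        series = synthetic_series([10.0])
        with pytest.raises(ValueError, match="disjoint"):
            ax.FrapSeries(
                pre_bleach=series.pre_bleach, post_bleach=series.post_bleach,
                t_s=series.t_s, roi_mask=series.roi_mask,
                shaft_mask=series.roi_mask, branch_mask=series.roi_mask,
                background_region=series.background_region,
            )


class TestExponentialFit:
    def test_noiseless_parameters_recovered(self):
        t = np.arange(0, 300, 5.0)
        a_true, tau_true = 0.1958, 100.0
        curve = RecoveryCurve(t_s=t, r=a_true * (1 - np.exp(-t / tau_true)))
        fit = ax.fit_single_exponential(curve)
        assert fit.params["A"] == pytest.approx(a_true, abs=1e-6)
        assert fit.params["tau_s"] == pytest.approx(tau_true, abs=1e-3)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.df == len(t) - 2

    def test_flat_curve_hits_zero_boundary(self):
        t = np.arange(0, 100, 5.0)
        fit = ax.fit_single_exponential(RecoveryCurve(t_s=t, r=np.zeros(len(t))))
        assert fit.params["at_zero_boundary"]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ax.fit_single_exponential(RecoveryCurve(np.arange(3.0), np.zeros(3)))

    def test_noisy_amplitude_unbiased(self):
        """Amplitude estimate over Monte-Carlo replicates is within 3 SE of
        the generating value at 1% noise."""
        rng = np.random.default_rng(11)
        t = np.arange(0, 300, 5.0)
        a_true, tau_true = 0.1958, 100.0
        truth = a_true * (1 - np.exp(-t / tau_true))
        estimates = [
            ax.fit_single_exponential(
                RecoveryCurve(t_s=t, r=truth + rng.normal(0, 0.01 * a_true, len(t)))
            ).params["A"]
            for _ in range(100)
        ]
        se = np.std(estimates, ddof=1) / 10.0
        assert abs(np.mean(estimates) - a_true) <= 3 * se


class TestQuadraticFit:
    def test_exact_quadratic_recovered(self):
        t = np.linspace(0, 300, 40)
        y = 1.0 + 0.002 * t + 1e-5 * t**2
        fit = ax.fit_quadratic((t, y))
        assert fit.params["c0"] == pytest.approx(1.0)
        assert fit.params["c1"] == pytest.approx(0.002)
        assert fit.params["c2"] == pytest.approx(1e-5)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_zero_slope_and_curvature(self):
        t = np.linspace(0, 300, 20)
        fit = ax.fit_quadratic((t, np.full(20, 1.3)))
        assert fit.params["c1"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["c2"] == pytest.approx(0.0, abs=1e-14)

    def test_noisy_coefficients_unbiased(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 300, 60)
        c = (1.0, 0.003, 2e-5)
        truth = c[0] + c[1] * t + c[2] * t**2
        c2s = [
            ax.fit_quadratic((t, truth + rng.normal(0, 0.05, len(t)))).params["c2"]
            for _ in range(100)
        ]
        se = np.std(c2s, ddof=1) / 10.0
        assert abs(np.mean(c2s) - c[2]) <= 3 * se

    def test_nan_frames_dropped(self):
        t = np.linspace(0, 10, 10)
        y = 2.0 + t
        y[3] = np.nan
        fit = ax.fit_quadratic(FviSeries(t_s=t, fvi=y))
        assert fit.n == 9


class TestExtraSosFTest:
    def test_identical_datasets_give_f_near_zero(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 300, 50)
        y = 1 + 0.001 * t + rng.normal(0, 0.02, len(t))
        sep = [ax.fit_quadratic((t, y)), ax.fit_quadratic((t, y))]
        pooled = ax.fit_quadratic((np.concatenate([t, t]), np.concatenate([y, y])))
        f, p = ax.extra_sos_f_test(pooled, sep)
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_statistic(self):
        shared = FitResult(model="m", params={}, sse=12.0, df=97)
        sep = [FitResult(model="m", params={}, sse=4.0, df=47),
               FitResult(model="m", params={}, sse=5.0, df=47)]
        f, p = ax.extra_sos_f_test(shared, sep)
        # ((12-9)/3) / (9/94)
        assert f == pytest.approx((3.0 / 3.0) / (9.0 / 94.0))
        assert 0.0 < p < 1.0

    def test_distinct_curves_detected(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 300, 3.0)
        y1 = 0.20 * (1 - np.exp(-t / 100)) + rng.normal(0, 0.01, len(t))
        y2 = 0.05 * (1 - np.exp(-t / 100)) + rng.normal(0, 0.01, len(t))
        f1 = ax.fit_single_exponential(RecoveryCurve(t, y1))
        f2 = ax.fit_single_exponential(RecoveryCurve(t, y2))
        pooled = ax.fit_single_exponential(
            RecoveryCurve(np.concatenate([t, t]), np.concatenate([y1, y2]))
        )
        f, p = ax.extra_sos_f_test(pooled, [f1, f2])
        assert p < 0.001

    def test_non_nested_misuse_rejected(self):
        shared = FitResult(model="m", params={}, sse=5.0, df=97)
        sep = [FitResult(model="m", params={}, sse=4.0, df=47),
               FitResult(model="m", params={}, sse=5.0, df=47)]
        with pytest.raises(ValueError):
            ax.extra_sos_f_test(shared, sep)


class TestFvi:
    def test_two_point_masks_hand_value(self):
        frame = np.array([[0.0, 10.0], [0.0, 5.0]])
        branch = np.array([[True, True], [False, False]])
        shaft = np.array([[False, False], [True, True]])
        assert ax.compute_fvi(frame, branch, shaft) == pytest.approx(2.0)

    def test_zero_shaft_variance_is_nan(self):
        frame = np.ones((4, 4))
        branch = np.zeros((4, 4), bool); branch[0] = True
        shaft = np.zeros((4, 4), bool); shaft[1] = True
        assert np.isnan(ax.compute_fvi(frame, branch, shaft))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ax.compute_fvi(np.ones((4, 4)), np.zeros((4, 4), bool), np.ones((4, 4), bool))

    @pytest.mark.parametrize("n", [100, 1000, 10000])
    def test_iid_noise_fvi_near_one_shrinking(self, n):
        """FVI of identically distributed noise approaches 1 as masks grow."""
        rng = np.random.default_rng(n)
        side = int(np.sqrt(2 * n))
        vals = []
        for _ in range(40):
            frame = rng.normal(50, 5, (side, 2 * side))
            branch = np.zeros_like(frame, bool); branch[:, :side] = True
            shaft = ~branch
            vals.append(ax.compute_fvi(frame, branch, shaft))
        dev = abs(np.mean(vals) - 1.0)
        assert dev < 4.0 / np.sqrt(n)

    def test_hotspots_increase_fvi_with_amplitude(self):
        """Gaussian hotspots confined to the branch mask raise FVI
        monotonically with their amplitude."""
        rng = np.random.default_rng(3)
        base = rng.normal(50, 2, (60, 60))
        branch = np.zeros((60, 60), bool); branch[:, 30:] = True
        shaft = ~branch
        rr, cc = np.mgrid[0:60, 0:60]
        spot = np.exp(-((rr - 30) ** 2 + (cc - 45) ** 2) / (2 * 3**2))
        fvis = [
            ax.compute_fvi(base + amp * spot, branch, shaft)
            for amp in (0.0, 5.0, 15.0, 40.0)
        ]
        assert fvis[0] == pytest.approx(1.0, abs=0.1)
        assert all(a < b for a, b in zip(fvis, fvis[1:]))

    def test_series_marks_undefined_frames(self):
        stack = np.stack([np.ones((4, 4)), np.arange(16.0).reshape(4, 4)])
        branch = np.zeros((4, 4), bool); branch[0] = True
        shaft = np.zeros((4, 4), bool); shaft[2] = True
        out = ax.fvi_series(stack, branch, shaft)
        assert np.isnan(out.fvi[0]) and np.isfinite(out.fvi[1])
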