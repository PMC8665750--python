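import math

import numpy as np
import pytest
from scipy import integrate

from peakline import (EIC, ROI, FitConfig, PeakSpec, RunRecipe, ShapeParams,
                      extract_eic, fallback_area, fit_curve, guess_initial,
                      measure_peak, model_area, model_eval, peak_metrics,
                      simulate_run)
from peakline.errors import (InsufficientDataError, NoSignalError,
                             UndefinedMetricsError)

from conftest import naive_emg, naive_skewed_gaussian

SQRT_2PI = math.sqrt(2.0 * math.pi)


class TestModelEval:
    def test_gaussian_apex_identity(self):
        p = ShapeParams(model="gaussian", amplitude=1.0, mu=0.0, sigma=1.0)
        assert model_eval(p, np.array([0.0]))[0] == pytest.approx(1.0)

    def test_gaussian_baseline_added(self):
        p = ShapeParams(model="gaussian", amplitude=1.0, mu=0.0, sigma=1.0,
                        baseline=5.0)
        assert model_eval(p, np.array([100.0]))[0] == pytest.approx(5.0)

    def test_skewed_alpha0_equals_gaussian(self):
        t = np.linspace(-10, 10, 501)
        g = ShapeParams(model="gaussian", amplitude=2.0, mu=1.0, sigma=1.5)
        s = ShapeParams(model="skewed_gaussian", amplitude=2.0, mu=1.0,
                        sigma=1.5, shape=0.0)
        np.testing.assert_allclose(model_eval(s, t), model_eval(g, t),
                                   atol=1e-12)

    def test_skewed_matches_naive(self):
        t = np.linspace(-5, 15, 301)
        p = ShapeParams(model="skewed_gaussian", amplitude=3.0, mu=2.0,
                        sigma=1.2, shape=2.5)
        np.testing.assert_allclose(
            model_eval(p, t), naive_skewed_gaussian(t, 3.0, 2.0, 1.2, 2.5),
            rtol=1e-12)

    def test_emg_matches_naive_moderate_params(self):
        # naive erfc form is exact where it does not overflow
        t = np.linspace(30, 60, 301)
        p = ShapeParams(model="emg", amplitude=1e5, mu=40.0, sigma=3.0,
                        shape=2.0)
        np.testing.assert_allclose(model_eval(p, t),
                                   naive_emg(t, 1e5, 40.0, 3.0, 2.0),
                                   rtol=1e-10)

    def test_emg_small_tau_limit_is_gaussian(self):
        # tolerance is relative to apex amplitude: the EMG mean is shifted by
        # tau, so a pointwise-relative check in the far tail measures the
        # shift, not shape convergence
        sigma = 2.0
        t = 10.0 + np.linspace(-3 * sigma, 3 * sigma, 121)
        emg = ShapeParams(model="emg", amplitude=1.0, mu=10.0, sigma=sigma,
                          shape=sigma / 100.0)
        gau = ShapeParams(model="gaussian", amplitude=1.0, mu=10.0, sigma=sigma)
        assert np.max(np.abs(model_eval(emg, t) - model_eval(gau, t))) <= 0.01

    def test_emg_finite_for_extreme_arguments(self):
        # naive form overflows for sigma/tau >> 1 far left of the peak
        p = ShapeParams(model="emg", amplitude=1.0, mu=0.0, sigma=5.0,
                        shape=0.01)
        t = np.linspace(-1000, 1000, 101)
        y = model_eval(p, t)
        assert np.all(np.isfinite(y))
        assert np.all(y >= 0)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            ShapeParams(model="gaussian", amplitude=1.0, mu=0.0, sigma=-1.0)
        with pytest.raises(ValueError):
            ShapeParams(model="emg", amplitude=1.0, mu=0.0, sigma=1.0,
                        shape=0.0)
        with pytest.raises(ValueError):
            ShapeParams(model="gaussian", amplitude=float("nan"), mu=0.0,
                        sigma=1.0)


class TestGuessInitial:
    def test_noiseless_gaussian_recovery(self, gaussian_eic):
        p = guess_initial(gaussian_eic, "gaussian")
        assert abs(p.mu - 50.0) <= 1.0          # one scan interval
        assert abs(p.sigma - 4.0) / 4.0 <= 0.15
        assert p.amplitude == pytest.approx(1000.0, rel=0.05)

    def test_flat_zero_eic_raises(self):
        eic = EIC(sample_id="s", cpd_id="c", rt=np.arange(10.0),
                  intensity=np.zeros(10))
        with pytest.raises(NoSignalError):
            guess_initial(eic)

    def test_two_peak_mu_at_global_max(self):
        t = np.arange(0.0, 100.0)
        y = (500.0 * np.exp(-0.5 * ((t - 30) / 3.0) ** 2)
             + 900.0 * np.exp(-0.5 * ((t - 70) / 3.0) ** 2))
        eic = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        assert guess_initial(eic).mu == pytest.approx(70.0, abs=1.0)

    def test_too_few_points(self):
        eic = EIC(sample_id="s", cpd_id="c", rt=np.arange(4.0),
                  intensity=np.ones(4))
        with pytest.raises(InsufficientDataError):
            guess_initial(eic)


class TestFitCurve:
    def test_noiseless_emg_recovery(self):
        # oracle: true area by quadrature of the generating curve
        A, mu, sigma, tau = 1e5, 40.0, 3.0, 2.0
        t = np.arange(0.0, 80.0, 80.0 / 60.0)[:60]
        y = naive_emg(t, A, mu, sigma, tau)
        eic = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        fit = fit_curve(eic, "emg")
        assert fit.converged
        assert fit.residual_rel_rmse < 1e-4
        assert fit.params.mu == pytest.approx(mu, abs=0.1)
        true_area, _ = integrate.quad(
            lambda x: naive_emg(x, A, mu, sigma, tau), mu - 40, mu + 60)
        fitted_area = model_area(fit.params, mu - 40, mu + 60)
        assert fitted_area == pytest.approx(true_area, rel=0.01)

    def test_noisy_gaussian_converges(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 80.0)
        clean = 1000.0 * np.exp(-0.5 * ((t - 40.0) / 4.0) ** 2)
        y = np.clip(clean + rng.normal(0, 20.0, t.size), 0, None)  # 2% noise
        eic = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        fit = fit_curve(eic, "gaussian")
        assert fit.converged
        assert fit.residual_rel_rmse < 0.05

    def test_pure_noise_never_crashes(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            y = np.clip(rng.normal(50, 20, 60), 0, None)
            eic = EIC(sample_id="s", cpd_id="c", rt=np.arange(60.0), intensity=y)
            fit = fit_curve(eic, "emg")
            assert (not fit.converged) or fit.residual_rel_rmse > 0.0

    def test_insufficient_points_raise(self):
        eic = EIC(sample_id="s", cpd_id="c", rt=np.arange(3.0),
                  intensity=np.array([1.0, 2.0, 1.0]))
        with pytest.raises(InsufficientDataError):
            fit_curve(eic, "gaussian")


class TestModelArea:
    def test_gaussian_full_support_closed_form(self):
        p = ShapeParams(model="gaussian", amplitude=1.0, mu=0.0, sigma=1.0)
        assert model_area(p, -8.0, 8.0) == pytest.approx(SQRT_2PI, abs=1e-4)

    def test_gaussian_scales_with_A_sigma(self):
        p = ShapeParams(model="gaussian", amplitude=3.0, mu=5.0, sigma=2.0)
        assert model_area(p, 5 - 16, 5 + 16) == pytest.approx(
            3.0 * 2.0 * SQRT_2PI, rel=1e-6)

    def test_baseline_excluded(self):
        p = ShapeParams(model="gaussian", amplitude=1.0, mu=0.0, sigma=1.0,
                        baseline=100.0)
        assert model_area(p, -8.0, 8.0) == pytest.approx(SQRT_2PI, abs=1e-4)

    def test_emg_full_support_vs_quadrature_oracle(self):
        A, mu, sigma, tau = 2.0, 10.0, 1.5, 2.5
        p = ShapeParams(model="emg", amplitude=A, mu=mu, sigma=sigma, shape=tau)
        oracle, _ = integrate.quad(lambda t: naive_emg(t, A, mu, sigma, tau),
                                   mu - 20 * sigma, mu + 20 * sigma + 30 * tau,
                                   limit=400)
        got = model_area(p, mu - 20 * sigma, mu + 20 * sigma + 30 * tau)
        assert got == pytest.approx(oracle, rel=1e-6)
        # EMG convolution preserves the gaussian area
        assert got == pytest.approx(A * sigma * SQRT_2PI, rel=1e-6)

    def test_zero_length_interval(self):
        p = ShapeParams(model="gaussian", amplitude=1.0, mu=0.0, sigma=1.0)
        assert model_area(p, 3.0, 3.0) == 0.0


class TestFallbackArea:
    def test_triangle(self):
        eic = EIC(sample_id="s", cpd_id="c", rt=np.array([0.0, 1.0, 2.0]),
                  intensity=np.array([0.0, 1.0, 0.0]))
        area, apex_rt, apex_h = fallback_area(eic, 0.0, 2.0)
        assert area == pytest.approx(1.0)
        assert apex_rt == pytest.approx(1.0)
        assert apex_h == pytest.approx(1.0)

    def test_rectangle(self):
        h, w = 5.0, 10.0
        t = np.arange(0.0, w + 3.0)
        y = np.where((t >= 1.0) & (t <= 1.0 + w), h, 0.0)
        eic = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        area, _, _ = fallback_area(eic, 0.0, w + 2.0)
        # trapezoid on the sampled grid: h*w matches within one edge bin
        assert area == pytest.approx(h * w, rel=0.15)
        expected = np.trapezoid(y, t)  # independent direct oracle
        assert area == pytest.approx(float(expected))

    def test_edge_baseline_subtracted(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 2.0, 6.0, 2.0, 2.0])
        eic = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        area, apex_rt, apex_h = fallback_area(eic, 0.0, 4.0)
        assert area == pytest.approx(4.0)  # triangle of height 4, width 2
        assert apex_h == pytest.approx(4.0)

    def test_no_points_in_window(self):
        eic = EIC(sample_id="s", cpd_id="c", rt=np.arange(5.0),
                  intensity=np.ones(5))
        assert fallback_area(eic, 100.0, 200.0) == (None, None, None)

    def test_invariant_to_zero_points_outside_window(self):
        t = np.arange(0.0, 10.0)
        y = np.array([0, 0, 1, 4, 9, 4, 1, 0, 0, 0.0])
        e1 = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        t2 = np.arange(-5.0, 15.0)
        y2 = np.concatenate([np.zeros(5), y, np.zeros(5)])
        e2 = EIC(sample_id="s", cpd_id="c", rt=t2, intensity=y2)
        a1, r1, h1 = fallback_area(e1, 1.0, 8.0)
        a2, r2, h2 = fallback_area(e2, 1.0, 8.0)
        assert a1 == a2 and r1 == r2 and h1 == h2

    def test_noisy_emg_within_10pct_of_truth(self):
        recipe = RunRecipe(
            n_scans=80, rt_start=0.0, scan_interval=1.0,
            peaks=[PeakSpec(cpd_id="X", mz=150.05, mu=40.0, sigma=3.0,
                            amplitude=1e5, tau=2.0)],
            noise_sd=2000.0, baseline=1000.0, seed=3)  # SNR 50
        run, ledger = simulate_run(recipe)
        roi = ROI(cpd_id="X", cpd_name="X", rt_min=20.0, rt_max=70.0,
                  mz_min=150.0, mz_max=150.1)
        eic = extract_eic(run, roi)
        area, _, _ = fallback_area(eic, 20.0, 70.0)
        assert area == pytest.approx(ledger["peaks"].true_area[0], rel=0.10)


class TestPeakMetrics:
    def test_gaussian_fwhm_closed_form(self, gaussian_eic):
        fit = fit_curve(gaussian_eic, "gaussian")
        fwhm, tailing, lo, hi = peak_metrics(fit)
        assert fwhm == pytest.approx(4.0 * 2.0 * math.sqrt(2 * math.log(2)),
                                     abs=1e-3)

    def test_gaussian_tailing_is_one(self, gaussian_eic):
        fit = fit_curve(gaussian_eic, "gaussian")
        _, tailing, _, _ = peak_metrics(fit)
        assert tailing == pytest.approx(1.0, abs=1e-3)

    def test_extent_brackets_apex(self, gaussian_eic):
        fit = fit_curve(gaussian_eic, "gaussian")
        _, _, lo, hi = peak_metrics(fit)
        assert lo < 50.0 < hi
        # 5% crossings of a gaussian sit at mu +/- sigma*sqrt(2 ln 20)
        d = 4.0 * math.sqrt(2 * math.log(20))
        assert lo == pytest.approx(50.0 - d, abs=1e-3)
        assert hi == pytest.approx(50.0 + d, abs=1e-3)

    def test_emg_tailing_vs_bruteforce_oracle(self):
        A, mu, sigma, tau = 1e4, 40.0, 3.0, 3.0
        t = np.arange(0.0, 120.0, 0.5)
        y = naive_emg(t, A, mu, sigma, tau)
        eic = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        fit = fit_curve(eic, "emg")
        assert fit.converged
        fwhm, tailing, lo, hi = peak_metrics(fit)
        assert tailing > 1.0
        # oracle: 10x-oversampled brute-force crossing search on the true curve
        tt = np.arange(0.0, 200.0, 0.005)
        yy = naive_emg(tt, A, mu, sigma, tau)
        apex_i = np.argmax(yy)
        level = 0.05 * yy[apex_i]
        left = tt[np.nonzero(yy[:apex_i] >= level)[0][0]]
        right = tt[apex_i + np.nonzero(yy[apex_i:] >= level)[0][-1]]
        a = tt[apex_i] - left
        b = right - tt[apex_i]
        assert tailing == pytest.approx((a + b) / (2 * a), abs=0.01)
        assert lo == pytest.approx(left, abs=0.02)
        assert hi == pytest.approx(right, abs=0.02)

    def test_nonconverged_raises(self, gaussian_eic):
        fit = fit_curve(gaussian_eic, "gaussian")
        fit.converged = False
        with pytest.raises(UndefinedMetricsError):
            peak_metrics(fit)


class TestMeasurePeak:
    def test_clean_emg_found_with_model(self, emg_run, ):
        run, ledger = emg_run
        roi = ROI(cpd_id="X", cpd_name="X", rt_min=25.0, rt_max=65.0,
                  mz_min=150.0, mz_max=150.1, rt=41.6, mz=150.05)
        m = measure_peak(extract_eic(run, roi), roi)
        assert m.found and not m.fallback_used
        assert m.area == pytest.approx(ledger["peaks"].true_area[0], rel=0.05)
        assert m.apex_rt == pytest.approx(ledger["peaks"].apex_rt[0], abs=1.0)
        assert m.mz_obs == pytest.approx(150.05, abs=0.01)
        assert m.ppm_error is not None and abs(m.ppm_error) < 100
        assert m.rt_min_obs < m.apex_rt < m.rt_max_obs

    def test_bimodal_falls_back_to_trapezoid(self):
        t = np.arange(0.0, 100.0)
        y = (1000.0 * np.exp(-0.5 * ((t - 35) / 3.0) ** 2)
             + 950.0 * np.exp(-0.5 * ((t - 60) / 3.0) ** 2))
        eic = EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)
        roi = ROI(cpd_id="c", cpd_name="c", rt_min=20.0, rt_max=80.0,
                  mz_min=100.0, mz_max=100.1)
        cfg = FitConfig(max_residual=0.05)  # strict: bimodal must fail
        m = measure_peak(eic, roi, cfg)
        assert m.found and m.fallback_used
        oracle_area, _, _ = fallback_area(eic, 20.0, 80.0)
        assert m.area == pytest.approx(oracle_area)
        assert m.fwhm is None and m.tailing_factor is None

    def test_blank_noise_below_threshold_not_found(self):
        rng = np.random.default_rng(21)
        y = np.clip(rng.normal(100.0, 30.0, 80), 0, None)
        eic = EIC(sample_id="s", cpd_id="c", rt=np.arange(80.0), intensity=y)
        roi = ROI(cpd_id="c", cpd_name="c", rt_min=0.0, rt_max=79.0,
                  mz_min=100.0, mz_max=100.1)
        m = measure_peak(eic, roi, FitConfig(min_height_k=10.0))
        assert not m.found
        assert m.area is None and m.apex_rt is None and m.fwhm is None

    def test_empty_eic_not_found(self, simple_roi):
        eic = EIC(sample_id="s", cpd_id="c", rt=np.zeros(0),
                  intensity=np.zeros(0))
        m = measure_peak(eic, simple_roi)
        assert not m.found

    def test_fuzz_never_raises(self):
        # any EIC the generator can produce must be handled without raising
        rng = np.random.default_rng(99)
        roi = ROI(cpd_id="X", cpd_name="X", rt_min=0.0, rt_max=79.0,
                  mz_min=150.0, mz_max=150.1)
        for trial in range(15):
            recipe = RunRecipe(
                n_scans=int(rng.integers(10, 120)), rt_start=0.0,
                scan_interval=float(rng.uniform(0.3, 2.0)),
                peaks=[PeakSpec(cpd_id="X", mz=150.05,
                                mu=float(rng.uniform(0, 80)),
                                sigma=float(rng.uniform(0.5, 10)),
                                amplitude=float(rng.uniform(1, 1e6)),
                                tau=float(rng.uniform(0, 10)))],
                noise_sd=float(rng.uniform(0, 1e4)),
                baseline=float(rng.uniform(0, 1e4)),
                mz_jitter_sd=0.001, seed=int(rng.integers(0, 1 << 31)))
            run, _ = simulate_run(recipe)
            m = measure_peak(extract_eic(run, roi), roi)
            assert isinstance(m.found, bool)


class TestParameterRecoveryBenchmark:
    def test_seeded_emg_recovery_medians(self):
        # 100 seeded EMG sims at SNR 50, 40-80 scans
        rng = np.random.default_rng(2024)
        rt_errors, area_errors = [], []
        for i in range(100):
            n_scans = int(rng.integers(40, 81))
            sigma = float(rng.uniform(2.0, 4.0))
            tau = float(rng.uniform(0.5, 1.0)) * sigma
            amp = 1e5
            mu = n_scans * 0.5
            recipe = RunRecipe(
                n_scans=n_scans, rt_start=0.0, scan_interval=1.0,
                peaks=[PeakSpec(cpd_id="X", mz=150.05, mu=mu, sigma=sigma,
                                amplitude=amp, tau=tau)],
                noise_sd=amp / 50.0, baseline=500.0, mz_jitter_sd=0.001,
                seed=int(rng.integers(0, 1 << 31)))
            run, ledger = simulate_run(recipe)
            roi = ROI(cpd_id="X", cpd_name="X", rt_min=0.0,
                      rt_max=float(n_scans - 1), mz_min=150.0, mz_max=150.1)
            m = measure_peak(extract_eic(run, roi), roi)
            assert m.found
            truth = ledger["peaks"].iloc[0]
            rt_errors.append(abs(m.apex_rt - truth.apex_rt))
            area_errors.append(abs(m.area - truth.true_area) / truth.true_area)
        assert np.median(rt_errors) < 1.0       # one scan interval
        assert np.median(area_errors) < 0.05
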