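import math

import numpy as np
import pytest

from accelalign import drift_model as dm
from accelalign.lag_estimation import LagObservation


def obs_from_line(t, beta0, beta1, noise=None, rng=None):
    lag = beta0 + beta1 * np.asarray(t, float)
    if noise is not None:
        lag = lag + noise
    return [LagObservation(block_index=i, time_s=float(ti),
                           lag_samples=float(li), peak_corr=0.9)
            for i, (ti, li) in enumerate(zip(t, lag))]


def statsmodels_ols(t, y):
    import statsmodels.api as sm
    res = sm.OLS(np.asarray(y, float),
                 sm.add_constant(np.asarray(t, float))).fit()
    return res.params[0], res.params[1]


class TestFitDrift:
    def test_exact_line_no_exclusions(self):
        t = np.arange(10) * 3600.0
        fit = dm.fit_drift(obs_from_line(t, 5.0, 0.001))
        assert fit.beta1 == pytest.approx(0.001, abs=1e-12)
        assert fit.beta0 == pytest.approx(5.0, abs=1e-9)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.excluded == []
        assert fit.iterations == 0          # zero-residual guard terminates
        assert fit.n_used == 10

    def test_gross_outliers_excluded_and_clean_ols_recovered(self):
        t = np.arange(20) * 3600.0
        obs = obs_from_line(t, 5.0, 0.001)
        spoiled = list(obs)
        for i in (3, 11, 17):
            o = spoiled[i]
            spoiled[i] = LagObservation(o.block_index, o.time_s,
                                        o.lag_samples + 500.0, o.peak_corr)
        fit = dm.fit_drift(spoiled)
        clean_t = [o.time_s for i, o in enumerate(obs) if i not in (3, 11, 17)]
        clean_y = [o.lag_samples for i, o in enumerate(obs) if i not in (3, 11, 17)]
        b0, b1 = statsmodels_ols(clean_t, clean_y)
        assert fit.beta0 == pytest.approx(b0, abs=1e-9)
        assert fit.beta1 == pytest.approx(b1, abs=1e-9)
        assert sorted(e.block_index for e in fit.excluded) == [3, 11, 17]
        assert fit.n_used + len(fit.excluded) == 20

    def test_noisy_matches_statsmodels_when_nothing_excluded(self):
        # tiny noise: every standardized residual stays below 1, so the
        # robust fit must equal plain OLS on all points
        t = np.arange(12) * 3600.0
        # the [+,-,-,+] pattern is orthogonal to both intercept and slope
        # on an equally spaced grid, so residuals equal the noise exactly
        # and every |standardized residual| is 0.5/sqrt(12*0.25/10) < 1
        noise = 0.5 * np.tile([1.0, -1.0, -1.0, 1.0], 3)
        obs = obs_from_line(t, -12.0, 0.0005, noise=noise)
        fit = dm.fit_drift(obs)
        b0, b1 = statsmodels_ols(t, [o.lag_samples for o in obs])
        assert fit.excluded == []
        assert fit.beta0 == pytest.approx(b0, abs=1e-9)
        assert fit.beta1 == pytest.approx(b1, abs=1e-9)

    def test_threshold_sequence_grows_exponentially(self):
        gen = dm.exclusion_thresholds()
        t0, t1, t2 = next(gen), next(gen), next(gen)
        assert t0 == 1.0
        assert t1 == pytest.approx(math.e)
        assert t2 == pytest.approx(math.exp(math.e))  # ≈ 15.15
        # exclusions recorded at iteration k exceeded threshold t_k
        t = np.arange(20) * 3600.0
        obs = obs_from_line(t, 0.0, 0.001,
                            noise=np.r_[np.zeros(19), 900.0])
        fit = dm.fit_drift(obs)
        seq = [1.0, math.e, math.exp(math.e)]
        for e in fit.excluded:
            assert abs(e.standardized_residual) > seq[e.iteration]

    def test_insufficient_observations(self):
        with pytest.raises(ValueError):
            dm.fit_drift(obs_from_line([0.0], 0.0, 0.0))

    def test_singular_design(self):
        obs = [LagObservation(0, 100.0, 1.0, 0.9),
               LagObservation(1, 100.0, 2.0, 0.9)]
        with pytest.raises(ValueError, match="singular"):
            dm.fit_drift(obs)

    def test_degenerate_endgame_keeps_previous_fit(self):
        # an absurdly aggressive threshold would drop every point at
        # once; the fit must keep the previous iteration's result and
        # flag itself instead
        rng = np.random.default_rng(3)
        t = np.arange(8) * 3600.0
        obs = obs_from_line(t, 2.0, 0.001, noise=rng.normal(0, 0.5, 8))
        fit = dm.fit_drift(obs, threshold_sequence=[1e-6])
        assert fit.degenerate
        assert fit.n_used == 8
        b0, b1 = statsmodels_ols(t, [o.lag_samples for o in obs])
        assert fit.beta0 == pytest.approx(b0, abs=1e-9)
        assert fit.beta1 == pytest.approx(b1, abs=1e-9)

    def test_parameter_recovery_with_outliers(self):
        # synthetic lag series straight from the clock model: Gaussian
        # lag noise plus a minority of gross outliers; the robust fit
        # recovers the line in nearly all replicates
        n_pass_b1 = n_pass_b0 = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t = np.sort(rng.uniform(0, 604800, 24))
            beta0 = rng.uniform(-300, 300)
            beta1 = rng.uniform(-1.5e-3, 1.5e-3)
            noise = rng.normal(0, 1.0, len(t))
            n_out = int(0.2 * len(t))
            idx = rng.choice(len(t), n_out, replace=False)
            noise[idx] = rng.uniform(-1000, 1000, n_out)
            fit = dm.fit_drift(obs_from_line(t, beta0, beta1, noise=noise))
            if abs(fit.beta1 - beta1) < 3 * fit.beta1_se + 1e-12:
                n_pass_b1 += 1
            if abs(fit.beta0 - beta0) < 2.0:
                n_pass_b0 += 1
        assert n_pass_b1 >= 95
        assert n_pass_b0 >= 95


class TestConversions:
    @pytest.mark.parametrize("beta1,expected", [
        (0.001, 20.16),
        (0.0, 0.0),
    ])
    def test_accumulated_day7(self, beta1, expected):
        assert dm.accumulated_day7_drift_s(beta1) == pytest.approx(expected)

    def test_to_alignment_estimate(self):
        fit = dm.DriftFit(beta0=-12.8, beta1=0.001, rmse=0.1, r2=0.99,
                          n_used=10, excluded=[], iterations=1)
        est = dm.to_alignment_estimate(fit)
        assert est.initial_offset_s == pytest.approx(-12.8 / 30.0)   # −0.4267 s
        assert est.accumulated_day7_s == pytest.approx(20.16)
        assert est.beta0_samples == pytest.approx(-12.8)


class TestManualMarks:
    def test_documented_example(self):
        est = dm.reference_from_manual_marks(10.0, 40.0, 3600.0, 603600.0)
        assert est.drift_samples_per_s == pytest.approx(5e-5)
        assert est.fit.beta0 == pytest.approx(9.82)
        assert est.accumulated_day7_s == pytest.approx(1.008)

    def test_flat_marks(self):
        est = dm.reference_from_manual_marks(7.0, 7.0, 100.0, 1000.0)
        assert est.drift_samples_per_s == 0.0
        assert est.fit.beta0 == 7.0

    def test_negation_linearity(self):
        a = dm.reference_from_manual_marks(10.0, 40.0, 3600.0, 603600.0)
        b = dm.reference_from_manual_marks(-10.0, -40.0, 3600.0, 603600.0)
        assert b.drift_samples_per_s == -a.drift_samples_per_s
        assert b.fit.beta0 == -a.fit.beta0
        assert b.accumulated_day7_s == -a.accumulated_day7_s

    def test_equal_times_rejected(self):
        with pytest.raises(ValueError):
            dm.reference_from_manual_marks(1.0, 2.0, 50.0, 50.0)


class TestRtcArithmetic:
    def test_single_device_week_drift(self):
        assert dm.skew_drift_s(20.0) == pytest.approx(12.096)

    def test_two_device_worst_case(self):
        rel = dm.relative_skew_ppm(-20.0, 20.0)
        assert dm.skew_drift_s(rel) == pytest.approx(24.192)

    def test_temperature_contribution_is_negligible(self):
        assert abs(dm.temperature_skew_ppm(5.0)) == pytest.approx(1.0)
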