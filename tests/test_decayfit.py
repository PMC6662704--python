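"""Per-core exponential decay fits, transition ages and the C:N correlation."""

import warnings

import numpy as np
import pytest
from scipy import optimize, stats

from sedch4 import decayfit
from sedch4.decayfit import DecayFit


def _curve(a, b, c, ages):
    return a * np.exp(-b * ages) + c


class TestFitDecay:
    def test_noiseless_recovery(self):
        ages = np.arange(1.0, 41.0)
        fit = decayfit.fit_decay(ages, _curve(5, 0.25, 0.8, ages))
        assert fit.converged
        assert (fit.a, fit.b, fit.c) == pytest.approx((5, 0.25, 0.8), rel=1e-6)

    def test_interval_coverage_under_lognormal_noise(self):
        """Wald intervals from the ln-scale fit cover the truth >=90% of runs."""
        rng = np.random.default_rng(42)
        ages = np.linspace(1, 40, 28)
        truth = np.array([5.0, 0.25, 0.8])
        mu = _curve(*truth, ages)
        tcrit = stats.t.ppf(0.975, len(ages) - 3)
        hits = np.zeros(3)
        n_conv = 0
        for _ in range(200):
            y = mu * np.exp(rng.normal(0, np.sqrt(0.28), ages.size))
            fit = decayfit.fit_decay(ages, y, n_restarts=6)
            if not fit.converged:
                continue
            n_conv += 1
            est = np.array([fit.a, fit.b, fit.c])
            se = np.array(fit.param_se)
            hits += (est - tcrit * se <= truth) & (truth <= est + tcrit * se)
        assert n_conv >= 190
        assert np.all(hits / n_conv >= 0.90)

    def test_median_bias_small_on_well_covered_cores(self):
        """a and b are recovered with <10% median bias at study-like noise.

        The sampling distribution of a is strongly right-skewed at this noise
        level, so the median (not the mean) is the meaningful location
        measure; 1000 runs keep its Monte-Carlo error well below the bound.
        """
        rng = np.random.default_rng(0)
        ages = np.linspace(1, 40, 28)
        truth = np.array([5.0, 0.25, 0.8])
        mu = _curve(*truth, ages)
        rel = []
        for _ in range(1000):
            y = mu * np.exp(rng.normal(0, np.sqrt(0.28), ages.size))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = decayfit.fit_decay(ages, y, n_restarts=6)
            if fit.converged:
                rel.append(np.array([fit.a, fit.b, fit.c]) / truth - 1)
        med = np.median(rel, axis=0)
        assert abs(med[0]) < 0.10
        assert abs(med[1]) < 0.10

    def test_constant_data_is_flagged_unidentifiable(self):
        ages = np.arange(1.0, 11.0)
        with pytest.warns(UserWarning, match="not identifiable"):
            fit = decayfit.fit_decay(ages, np.full_like(ages, 2.0))
        assert not fit.converged

    def test_too_few_distinct_ages_not_fittable(self):
        with pytest.warns(UserWarning, match="not fittable"):
            fit = decayfit.fit_decay([1.0, 1.0, 2.0], [3.0, 3.1, 2.5])
        assert not fit.converged
        assert np.isnan(fit.a)

    def test_fitted_curve_at_age_zero_is_a_plus_c(self):
        fit = DecayFit("x", 5.0, 0.25, 0.8, 0.0, 10, True)
        assert fit.predict(0.0) == pytest.approx(5.8)


class TestTransitionAge:
    def test_closed_form_example(self):
        fit = DecayFit("x", 10.0, 0.3, 0.5, 0.0, 10, True)
        res = decayfit.transition_age(fit)
        assert res.transition_age == pytest.approx(17.156, abs=1e-3)

    def test_already_flat_curve_transitions_immediately(self):
        # a*b below tan(1 deg) ~ 0.017455: slope never steeper than criterion
        fit = DecayFit("x", 0.05, 0.3, 0.5, 0.0, 10, True)
        assert decayfit.transition_age(fit).transition_age == 0.0

    def test_closed_form_agrees_with_root_finder_on_random_draws(self):
        """|d rate/d age| = tan(1 deg) solved numerically, 1000 draws, 1e-9."""
        rng = np.random.default_rng(123)
        thr = np.tan(np.radians(1.0))
        n_checked = 0
        for _ in range(1000):
            a = float(np.exp(rng.uniform(np.log(0.5), np.log(40.0))))
            b = float(rng.uniform(0.02, 1.5))
            fit = DecayFit("x", a, b, rng.uniform(0, 2), 0.0, 10, True)
            t_closed = decayfit.transition_age(fit).transition_age
            if a * b <= thr:
                assert t_closed == 0.0
                continue
            t_num = optimize.brentq(lambda t: a * b * np.exp(-b * t) - thr,
                                    0.0, 2000.0, xtol=1e-12, rtol=1e-15)
            assert t_closed == pytest.approx(t_num, rel=1e-9, abs=1e-9)
            n_checked += 1
        assert n_checked > 500

    def test_invariant_to_background_pool(self):
        f1 = DecayFit("x", 10.0, 0.3, 0.0, 0.0, 10, True)
        f2 = DecayFit("x", 10.0, 0.3, 5.0, 0.0, 10, True)
        assert (decayfit.transition_age(f1).transition_age
                == decayfit.transition_age(f2).transition_age)

    def test_strictly_increasing_in_a_at_fixed_b(self):
        ts = [decayfit.transition_age(
            DecayFit("x", a, 0.3, 0.5, 0.0, 10, True)).transition_age
            for a in (1.0, 2.0, 5.0, 20.0)]
        assert np.all(np.diff(ts) > 0)

    def test_nonpositive_b_rejected(self):
        with pytest.raises(ValueError):
            decayfit.transition_age(DecayFit("x", 10.0, -0.1, 0.5, 0.0, 10, True))


class TestTransitionDepth:
    def test_zero_transition_age_is_surface(self):
        assert decayfit.transition_depth(0.0, 25.0, 22.0) == 0.0

    def test_reservoir_age_maps_to_interface(self):
        assert decayfit.transition_depth(22.0, 25.0, 22.0) == pytest.approx(25.0)

    def test_linear_map_arithmetic(self):
        assert decayfit.transition_depth(11.4, 25.0, 22.0) == pytest.approx(
            12.95, abs=0.01)

    def test_transition_beyond_reservoir_age_caps_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            depth = decayfit.transition_depth(30.0, 25.0, 22.0)
        assert depth == 25.0


class TestTransitionVsCn:
    def test_perfectly_collinear_gives_r_one(self):
        cn = np.array([10.0, 12.0, 14.0, 16.0])
        slope, intercept, r, p, n = decayfit.transition_vs_cn(2 * cn + 1, cn)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert n == 4

    def test_slope_recovery_under_noise(self):
        """Generated transition age = alpha + beta*C:N + noise; slope recovers
        beta within 2 Monte-Carlo SE over 200 runs."""
        rng = np.random.default_rng(9)
        alpha, beta = 2.0, 0.8
        cn = np.linspace(9, 24, 17)
        slopes = []
        for _ in range(200):
            t = alpha + beta * cn + rng.normal(0, 2.0, cn.size)
            slopes.append(decayfit.transition_vs_cn(t, cn)[0])
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(beta, abs=2 * mc_se + 1e-9)

    def test_two_cores_insufficient(self):
        with pytest.raises(ValueError):
            decayfit.transition_vs_cn([1.0, 2.0], [10.0, 12.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            decayfit.transition_vs_cn([1.0, 1.0, 1.0], [10.0, 12.0, 14.0])


def test_fit_all_cores_uses_only_included_ch4(pooled_rates):
    fits = decayfit.fit_all_cores(pooled_rates)
    assert len(fits) == 17
    assert fits["converged"].sum() >= 12
    ok = fits[fits["converged"]]
    assert (ok["a"] >= 0).all() and (ok["b"] > 0).all() and (ok["c"] >= 0).all()
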