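"""Survival-distribution evaluation, fitting and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from psmcea import (
    FitResult,
    SurvivalDistribution,
    fit_parametric,
    select_best_fit,
)
from psmcea.ipd import PseudoIPD
from psmcea.survival import FAMILIES, ParametricSurvivalModel

# frozen with 30-digit rational arithmetic (sympy): 1/(1 + 0.04461 * 12**1.2879)
S12_CAM_OS = 0.477386925472432503542019828079


def _random_dist(family, rng):
    shape = float(rng.uniform(0.5, 3.0))
    scale = float(rng.uniform(0.01, 0.5))
    return SurvivalDistribution(family, shape, scale)


class TestEvaluation:
    def test_survival_starts_at_one(self):
        for family in FAMILIES:
            d = SurvivalDistribution(family, 1.3, 0.08)
            assert d.survival_probability(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_loglogistic_closed_form_at_12_months(self, loglogistic_os):
        assert loglogistic_os.survival_probability(12.0) == pytest.approx(
            S12_CAM_OS, rel=1e-12
        )

    def test_loglogistic_median_is_scale_root(self):
        d = SurvivalDistribution("loglogistic", 2.0011, 0.1471)
        t_med = (1.0 / d.scale) ** (1.0 / d.shape)
        assert d.survival_probability(t_med) == pytest.approx(0.5, abs=1e-12)
        assert d.median() == pytest.approx(t_med, rel=1e-9)

    def test_negative_time_rejected(self, loglogistic_pfs):
        with pytest.raises(ValueError):
            loglogistic_pfs.survival_probability(-0.1)

    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("bad", [(0.0, 0.1), (1.0, -0.2), (np.nan, 0.1), (1.0, np.inf)])
    def test_invalid_parameters_rejected(self, family, bad):
        if family == "exponential" and bad[0] in (0.0, np.nan) and np.isfinite(bad[1]):
            pytest.skip("exponential ignores the shape parameter")
        with pytest.raises(ValueError):
            SurvivalDistribution(family, *bad)

    @given(
        family=st.sampled_from(FAMILIES),
        shape=st.floats(0.3, 4.0),
        scale=st.floats(0.005, 1.0),
        t1=st.floats(0.0, 60.0),
        dt=st.floats(0.001, 60.0),
    )
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_survival_monotone_non_increasing(self, family, shape, scale, t1, dt):
        d = SurvivalDistribution(family, shape, scale)
        s1, s2 = d.survival_probability([t1, t1 + dt])
        assert 0.0 <= s2 <= s1 <= 1.0 + 1e-12

    @pytest.mark.parametrize("family", FAMILIES)
    def test_monte_carlo_mean_matches_quadrature(self, family):
        """E[T] from sampling agrees with the integral of S(t) within 3 SE."""
        d = SurvivalDistribution(family, 1.6, 0.09)
        rng = np.random.default_rng(42)
        draws = d.rvs(100_000, rng)
        analytic = d.mean_survival()
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - analytic) < 3.0 * se

    def test_loglogistic_hazard_unimodal_when_shape_above_one(self):
        d = SurvivalDistribution("loglogistic", 2.0011, 0.1471)
        t = np.linspace(0.05, 60, 800)
        h = d.hazard(t)
        peak = int(np.argmax(h))
        assert 0 < peak < len(t) - 1
        assert np.all(np.diff(h[: peak + 1]) > -1e-12)
        assert np.all(np.diff(h[peak:]) < 1e-12)


class TestFitting:
    def test_parameter_recovery_loglogistic(self, uncensored_loglogistic_ipd):
        fr = fit_parametric(uncensored_loglogistic_ipd, "loglogistic")
        assert fr.converged
        assert 1.8 <= fr.distribution.shape <= 2.2
        assert 0.12 <= fr.distribution.scale <= 0.18

    def test_information_criteria_identities(self, uncensored_loglogistic_ipd):
        fr = fit_parametric(uncensored_loglogistic_ipd, "weibull")
        n = len(uncensored_loglogistic_ipd)
        assert fr.aic == pytest.approx(2 * fr.n_params - 2 * fr.log_likelihood)
        assert fr.bic == pytest.approx(fr.n_params * np.log(n) - 2 * fr.log_likelihood)

    def test_nested_model_aic_bound(self):
        """Exponential data: the one-extra-parameter Weibull cannot beat the
        exponential AIC by more than the 2-unit parameter penalty."""
        rng = np.random.default_rng(5)
        t = rng.exponential(1 / 0.2, 400)
        ipd = PseudoIPD(t, np.ones_like(t))
        aic_exp = fit_parametric(ipd, "exponential").aic
        aic_wei = fit_parametric(ipd, "weibull").aic
        assert aic_exp <= aic_wei + 2.0

    def test_censored_likelihood_uses_survival_contribution(self):
        """Heavily censored data must yield a flatter fitted curve than the
        same times treated as events."""
        t = np.linspace(1, 20, 60)
        cens = fit_parametric(PseudoIPD(t, [1] * 30 + [0] * 30), "exponential")
        evts = fit_parametric(PseudoIPD(t, np.ones_like(t)), "exponential")
        assert cens.distribution.scale < evts.distribution.scale

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            PseudoIPD(np.array([]), np.array([]))
        no_events = PseudoIPD([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError):
            fit_parametric(no_events, "weibull")

    def test_fit_recovers_curve_better_with_more_data(self):
        true = SurvivalDistribution("weibull", 1.4, 0.08)
        grid = np.linspace(0.0, 36.0, 100)
        sup = {}
        for n in (100, 1000):
            rng = np.random.default_rng(99)
            ipd = PseudoIPD(true.rvs(n, rng), np.ones(n))
            fr = fit_parametric(ipd, "weibull")
            sup[n] = np.max(
                np.abs(
                    fr.distribution.survival_probability(grid)
                    - true.survival_probability(grid)
                )
            )
        assert sup[1000] < sup[100]

    def test_cross_check_against_lifelines(self, uncensored_loglogistic_ipd):
        """Independent MLE oracle: lifelines' fitters on the same data."""
        lifelines = pytest.importorskip("lifelines")
        t, e = uncensored_loglogistic_ipd.time, uncensored_loglogistic_ipd.event
        llf = lifelines.LogLogisticFitter().fit(t, e)
        ours = fit_parametric(uncensored_loglogistic_ipd, "loglogistic").distribution
        # lifelines: S(t) = 1/(1 + (t/alpha)^beta)  ->  shape=beta, scale=alpha^-beta
        assert ours.shape == pytest.approx(llf.beta_, rel=1e-3)
        assert ours.scale == pytest.approx(llf.alpha_ ** -llf.beta_, rel=1e-3)
        wf = lifelines.WeibullFitter().fit(t, e)
        ours_w = fit_parametric(uncensored_loglogistic_ipd, "weibull").distribution
        assert ours_w.shape == pytest.approx(wf.rho_, rel=1e-3)
        assert ours_w.scale == pytest.approx(wf.lambda_ ** -wf.rho_, rel=1e-3)


class TestSelection:
    def _fr(self, aic, bic, n_params=2, converged=True):
        return FitResult(
            distribution=SurvivalDistribution("weibull", 1.0, 0.1),
            log_likelihood=0.0,
            aic=aic,
            bic=bic,
            n_params=n_params,
            n_obs=100,
            converged=converged,
        )

    def test_lowest_aic_wins(self):
        fits = [self._fr(310.2, 320), self._fr(305.7, 315), self._fr(311.0, 321)]
        assert select_best_fit(fits).aic == 305.7

    def test_aic_tie_broken_by_bic(self):
        fits = [self._fr(300.0, 320.0), self._fr(300.0, 318.0)]
        assert select_best_fit(fits).bic == 318.0

    def test_all_non_converged_raises(self):
        fits = [self._fr(300, 310, converged=False)]
        with pytest.raises(ValueError, match="no converged"):
            select_best_fit(fits)

    def test_model_comparison_summary_sorted(self, uncensored_loglogistic_ipd):
        cmp_ = ParametricSurvivalModel(uncensored_loglogistic_ipd).fit_all(
            families=("exponential", "weibull", "loglogistic")
        )
        df = cmp_.summary()
        assert list(df.columns[:3]) == ["family", "shape", "scale"]
        assert df["aic"].is_monotonic_increasing
        assert cmp_.best().distribution.family == "loglogistic"
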