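"""Partitioned-survival engine: occupancy, accrual, discounting, ICER."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from psmcea import (
    CostInputs,
    DrugRegimen,
    ModelConfig,
    StrategyArm,
    SurvivalDistribution,
    UtilityInputs,
    build_trace,
    compute_icer,
    evaluate_arm,
)
from psmcea.engine import compute_exposures


def _arm(pfs, os, regimens=None, sae=None, name="arm"):
    if regimens is None:
        regimens = (
            DrugRegimen("drug", 200.0, "flat", 14.0, 2.16, course_cap=6, weight=1.0),
        )
    return StrategyArm(name, regimens, pfs, os, sae or {})


_CAM_PFS = SurvivalDistribution("loglogistic", 2.0011, 0.1471)
_CAM_OS = SurvivalDistribution("loglogistic", 1.2879, 0.04461)


class TestTrace:
    def test_everyone_starts_progression_free(self):
        tr = build_trace(_arm(_CAM_PFS, _CAM_OS), ModelConfig())
        assert (tr.pfd[0], tr.pd[0], tr.dead[0]) == (1.0, 0.0, 0.0)

    def test_identical_curves_leave_pd_empty(self):
        tr = build_trace(_arm(_CAM_OS, _CAM_OS), ModelConfig())
        assert np.all(tr.pd == 0.0)

    def test_occupancy_conserved_and_death_monotone(self):
        tr = build_trace(_arm(_CAM_PFS, _CAM_OS), ModelConfig())
        np.testing.assert_allclose(tr.pfd + tr.pd + tr.dead, 1.0, atol=1e-12)
        assert np.all(np.diff(tr.dead) >= -1e-12)

    @given(
        shape=st.floats(0.8, 3.0),
        scale_os=st.floats(0.01, 0.2),
        ratio=st.floats(1.0, 10.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_occupancy_invariants_on_random_curve_pairs(self, shape, scale_os, ratio):
        # same shape, larger scale -> S_PFS <= S_OS everywhere (consistent pair)
        pfs = SurvivalDistribution("loglogistic", shape, scale_os * ratio)
        os_ = SurvivalDistribution("loglogistic", shape, scale_os)
        tr = build_trace(_arm(pfs, os_), ModelConfig())
        np.testing.assert_allclose(tr.pfd + tr.pd + tr.dead, 1.0, atol=1e-12)
        assert np.all(tr.pd >= 0.0)
        assert np.all(np.diff(tr.dead) >= -1e-12)

    def test_inconsistent_curve_pair_rejected(self):
        # PFS clearly slower than OS -> S_PFS > S_OS by >> 0.02
        pfs = SurvivalDistribution("loglogistic", 1.5, 0.01)
        os_ = SurvivalDistribution("loglogistic", 1.5, 0.2)
        with pytest.raises(ValueError, match="S_PFS exceeds S_OS"):
            build_trace(_arm(pfs, os_), ModelConfig())

    def test_life_years_match_fine_grid_quadrature(self):
        """Undiscounted LY equal the integral of S_OS to within 0.5%."""
        cfg = ModelConfig(annual_discount_rate=0.0)
        arm = _arm(_CAM_PFS, _CAM_OS)
        res = evaluate_arm(arm, cfg, CostInputs(), UtilityInputs(), "fixed_courses")
        t_fine = np.arange(0.0, 120.0 + 1e-9, 0.01)
        oracle = np.trapezoid(_CAM_OS.survival_probability(t_fine), t_fine) / 12.0
        assert res.life_years == pytest.approx(oracle, rel=0.005)


class TestCostAccrual:
    def test_zero_prices_zero_cost(self):
        regs = (DrugRegimen("free", 200.0, "flat", 14.0, 0.0, 6),)
        arm = _arm(_CAM_PFS, _CAM_OS, regimens=regs)
        costs = CostInputs(followup_per_cycle=0.0, bsc_per_cycle=0.0)
        res = evaluate_arm(arm, ModelConfig(), costs, UtilityInputs(), "fixed_courses")
        assert res.cost_total == 0.0

    def test_one_cycle_flat_dose_hand_arithmetic(self):
        """200 mg at 2.16 $/mg, 2 administrations, full occupancy, no
        discounting: drug cost = 200 * 2.16 * 2 = 864.00."""
        cfg = ModelConfig(horizon=1.0, annual_discount_rate=0.0)
        near_one = SurvivalDistribution("loglogistic", 1.0, 1e-12)
        regs = (
            DrugRegimen("drug", 200.0, "flat", cfg.days_per_month / 2.0, 2.16, None),
        )
        arm = _arm(near_one, near_one, regimens=regs)
        res = evaluate_arm(
            arm, cfg, CostInputs(followup_per_cycle=0.0, bsc_per_cycle=0.0),
            UtilityInputs(), "fixed_courses",
        )
        assert res.cost_drug == pytest.approx(864.00, abs=1e-6)

    def test_bsa_dosing_scales_with_surface_area(self):
        regs = (DrugRegimen("doc", 75.0, "bsa", 21.0, 1.77, 3),)
        arm = _arm(_CAM_PFS, _CAM_OS, regimens=regs)
        r1 = evaluate_arm(arm, ModelConfig(body_surface_area=1.72), CostInputs(0, 0),
                          UtilityInputs(), "fixed_courses")
        r2 = evaluate_arm(arm, ModelConfig(body_surface_area=1.90), CostInputs(0, 0),
                          UtilityInputs(), "fixed_courses")
        assert r2.cost_drug / r1.cost_drug == pytest.approx(1.90 / 1.72, rel=1e-12)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            compute_exposures(_arm(_CAM_PFS, _CAM_OS), ModelConfig(), "forever")

    def test_treat_to_progression_costs_at_least_fixed_courses(self):
        """With course caps shorter than the mean PFS duration, continuing to
        progression cannot be cheaper."""
        arm = _arm(_CAM_PFS, _CAM_OS, sae={"anemia": 0.03})
        costs = CostInputs(sae_costs={"anemia": 73.68})
        r1 = evaluate_arm(arm, ModelConfig(), costs, UtilityInputs(), "fixed_courses")
        r2 = evaluate_arm(arm, ModelConfig(), costs, UtilityInputs(),
                          "treat_to_progression")
        assert r2.cost_total >= r1.cost_total

    def test_zero_discount_never_decreases_totals(self):
        arm = _arm(_CAM_PFS, _CAM_OS, sae={"anemia": 0.03})
        costs = CostInputs(sae_costs={"anemia": 73.68})
        disc = evaluate_arm(arm, ModelConfig(), costs, UtilityInputs(), "fixed_courses")
        undisc = evaluate_arm(arm, ModelConfig(annual_discount_rate=0.0), costs,
                              UtilityInputs(), "fixed_courses")
        assert undisc.cost_total >= disc.cost_total
        assert undisc.qaly_total >= disc.qaly_total
        assert undisc.life_years >= disc.life_years

    def test_halving_cycle_length_is_discretization_stable(self):
        arm = _arm(_CAM_PFS, _CAM_OS)
        r1 = evaluate_arm(arm, ModelConfig(cycle_length=1.0), CostInputs(),
                          UtilityInputs(), "treat_to_progression")
        r2 = evaluate_arm(arm, ModelConfig(cycle_length=0.5), CostInputs(),
                          UtilityInputs(), "treat_to_progression")
        for attr in ("cost_total", "qaly_total", "life_years"):
            assert getattr(r2, attr) == pytest.approx(getattr(r1, attr), rel=0.01)


class TestQalyAccrual:
    def test_full_utility_no_disutility_equals_life_years(self):
        arm = _arm(_CAM_PFS, _CAM_OS)
        res = evaluate_arm(arm, ModelConfig(), CostInputs(),
                          UtilityInputs(u_pfd=1.0, u_pd=1.0), "fixed_courses")
        assert res.qaly_total == pytest.approx(res.life_years, rel=1e-12)

    def test_zero_utilities_zero_qalys(self):
        arm = _arm(_CAM_PFS, _CAM_OS)
        res = evaluate_arm(arm, ModelConfig(), CostInputs(),
                          UtilityInputs(u_pfd=0.0, u_pd=0.0), "fixed_courses")
        assert res.qaly_total == 0.0

    def test_qalys_never_exceed_life_years(self):
        arm = _arm(_CAM_PFS, _CAM_OS, sae={"anemia": 0.05})
        res = evaluate_arm(
            arm, ModelConfig(), CostInputs(sae_costs={"anemia": 73.68}),
            UtilityInputs(disutilities={"anemia": -0.074}), "fixed_courses",
        )
        assert res.qaly_total <= res.life_years

    def test_utility_bounds_enforced(self):
        with pytest.raises(ValueError):
            UtilityInputs(u_pfd=1.2)
        with pytest.raises(ValueError):
            UtilityInputs(disutilities={"anemia": 0.1})


class TestTwoCycleOracle:
    """Spreadsheet-style hand computation of every component for a 2-cycle
    model with exponential curves; engine must agree to 1e-9."""

    def test_all_components_match_hand_computation(self):
        lam_p, lam_o = 0.2, 0.1
        pfs = SurvivalDistribution("exponential", 1.0, lam_p)
        os_ = SurvivalDistribution("exponential", 1.0, lam_o)
        cfg = ModelConfig(horizon=2.0, annual_discount_rate=0.05)
        regs = (DrugRegimen("drug", 100.0, "flat", 15.21875, 2.0, None),)  # 2/cycle
        arm = _arm(pfs, os_, regimens=regs, sae={"ae": 0.1})
        costs = CostInputs(followup_per_cycle=10.0, bsc_per_cycle=20.0,
                           sae_costs={"ae": 50.0})
        utils = UtilityInputs(u_pfd=0.8, u_pd=0.6, disutilities={"ae": -0.1})
        res = evaluate_arm(arm, cfg, costs, utils, "treat_to_progression")

        # hand computation -------------------------------------------------
        import math

        S_p = [math.exp(-lam_p * t) for t in (0, 1, 2)]
        S_o = [math.exp(-lam_o * t) for t in (0, 1, 2)]
        w_pfd = [(S_p[0] + S_p[1]) / 2, (S_p[1] + S_p[2]) / 2]
        w_alive = [(S_o[0] + S_o[1]) / 2, (S_o[1] + S_o[2]) / 2]
        w_pd = [a - p for a, p in zip(w_alive, w_pfd)]
        d = [1.05 ** (-0.5 / 12), 1.05 ** (-1.5 / 12)]

        drug = sum(2.0 * 100.0 * 2.0 * w * dk for w, dk in zip(w_pfd, d))
        fu = sum(10.0 * w * dk for w, dk in zip(w_alive, d))
        bsc = sum(20.0 * w * dk for w, dk in zip(w_pd, d))
        sae = sum(0.1 * 50.0 * w * dk for w, dk in zip(w_pfd, d))
        qaly = sum(
            (0.8 * wp + 0.6 * wq + 0.1 * -0.1 * wp) * dk / 12
            for wp, wq, dk in zip(w_pfd, w_pd, d)
        )
        ly = sum(wa * dk / 12 for wa, dk in zip(w_alive, d))

        assert res.cost_drug == pytest.approx(drug, abs=1e-9)
        assert res.cost_followup == pytest.approx(fu, abs=1e-9)
        assert res.cost_bsc == pytest.approx(bsc, abs=1e-9)
        assert res.cost_sae == pytest.approx(sae, abs=1e-9)
        assert res.qaly_total == pytest.approx(qaly, abs=1e-9)
        assert res.life_years == pytest.approx(ly, abs=1e-9)


class TestIcer:
    def _result(self, cost, qaly, name="a", scenario="fixed_courses"):
        from psmcea.engine import ArmResult

        return ArmResult(
            name=name, scenario=scenario, cost_total=cost, cost_drug=cost,
            cost_followup=0.0, cost_bsc=0.0, cost_sae=0.0, cost_by_regimen={},
            qaly_total=qaly, qaly_pfd=qaly, qaly_pd=0.0, qaly_sae=0.0,
            life_years=qaly,
        )

    def test_identical_arms_undefined_icer(self):
        ce = compute_icer(self._result(100, 1.0), self._result(100, 1.0, "b"))
        assert ce.icer is None
        assert ce.delta_cost == 0.0 and ce.delta_qaly == 0.0

    def test_published_ratio_arithmetic(self):
        ce = compute_icer(self._result(1439.64, 0.36), self._result(0.0, 0.0, "b"))
        assert ce.icer == pytest.approx(3999.0, abs=0.01)

    def test_strict_dominance_flagged(self):
        ce = compute_icer(self._result(100, 2.0, "a"), self._result(200, 1.0, "b"))
        assert ce.dominant == "a"
        ce2 = compute_icer(self._result(200, 1.0, "a"), self._result(100, 2.0, "b"))
        assert ce2.dominant == "b"

    def test_scenario_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            compute_icer(
                self._result(1, 1), self._result(1, 1, "b", "treat_to_progression")
            )
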