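"""Partitioned-survival cohort engine.

State occupancy is read directly off the survival curves on a monthly cycle
grid: ``PFD = S_PFS(t)``, ``PD = max(S_OS(t) - S_PFS(t), 0)``,
``dead = 1 - S_OS(t)``.  Costs and QALYs accrue per cycle with compound
annual discounting.  Two treatment-duration scenarios are supported:

* ``fixed_courses`` (scenario 1): each regimen is given for its course cap
  (cap x administration interval), after which drug/SAE accrual stops;
* ``treat_to_progression`` (scenario 2): drug/SAE accrual continues while
  patients remain progression-free.

Accrual conventions (all exposed on :class:`ModelConfig`):

* ``half_cycle_correction=True`` uses trapezoidal occupancy (mean of the
  cycle's start and end occupancy), approximating the continuous integral;
  ``False`` uses start-of-cycle occupancy.
* discounting is compound, evaluated at the cycle midpoint by default.
* administrations per cycle are fractional: cycle days / interval days with a
  30.4375-day month.
* ``drug_population`` chooses whether fixed-course drug/SAE accrual is
  weighted by PFD occupancy (default, treatment stops on progression) or by
  alive occupancy (courses completed unless dead).

All engine quantities are computed as *exposures* (discounted
occupancy-weighted cycle sums) first; monetary and utility totals are linear
combinations of those exposures, which the sensitivity module exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survival import SurvivalDistribution

__all__ = [
    "ModelConfig",
    "DrugRegimen",
    "StrategyArm",
    "CostInputs",
    "UtilityInputs",
    "CohortTrace",
    "ArmExposures",
    "ArmResult",
    "CEResult",
    "SCENARIOS",
    "build_trace",
    "compute_exposures",
    "evaluate_arm",
    "compute_icer",
]

SCENARIOS = ("fixed_courses", "treat_to_progression")

#: largest tolerated excess of S_PFS over S_OS before the curve pair is rejected
CURVE_CONSISTENCY_TOL = 0.02


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings (time unit: months; money: USD)."""

    cycle_length: float = 1.0
    horizon: float = 120.0
    annual_discount_rate: float = 0.05
    wtp_thresholds: tuple = (10503.52, 21007.04, 31510.56)
    body_surface_area: float = 1.72
    half_cycle_correction: bool = True
    discount_timing: str = "midpoint"  # or "start"
    days_per_month: float = 30.4375
    drug_population: str = "pfd"  # or "alive"

    def __post_init__(self) -> None:
        if self.cycle_length <= 0 or self.horizon <= 0:
            raise ValueError("cycle_length and horizon must be positive")
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be a positive multiple of cycle_length")
        if not 0.0 <= self.annual_discount_rate <= 0.08:
            raise ValueError("annual_discount_rate must lie in [0, 0.08]")
        if self.discount_timing not in ("midpoint", "start"):
            raise ValueError("discount_timing must be 'midpoint' or 'start'")
        if self.drug_population not in ("pfd", "alive"):
            raise ValueError("drug_population must be 'pfd' or 'alive'")
        if self.body_surface_area <= 0:
            raise ValueError("body_surface_area must be positive")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))


@dataclass(frozen=True)
class DrugRegimen:
    """One drug's dosing rule and price.

    ``dose_per_admin`` is mg for ``dose_basis='flat'`` or mg/m^2 for
    ``dose_basis='bsa'``; ``course_cap`` is the number of administrations in
    the fixed-course scenario (None = unlimited).
    """

    name: str
    dose_per_admin: float
    dose_basis: str  # "flat" | "bsa"
    admin_interval_days: float
    price_per_mg: float
    course_cap: int | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_basis not in ("flat", "bsa"):
            raise ValueError("dose_basis must be 'flat' or 'bsa'")
        for attr in ("dose_per_admin", "admin_interval_days", "price_per_mg", "weight"):
            if getattr(self, attr) <= 0 and attr != "price_per_mg":
                raise ValueError(f"{attr} must be positive")
        if self.price_per_mg < 0:
            raise ValueError("price_per_mg must be non-negative")
        if self.course_cap is not None and self.course_cap < 1:
            raise ValueError("course_cap must be >= 1 when finite")

    def dose_mg(self, bsa: float) -> float:
        return self.dose_per_admin * (bsa if self.dose_basis == "bsa" else 1.0)

    def admins_per_cycle(self, config: ModelConfig) -> float:
        return config.cycle_length * config.days_per_month / self.admin_interval_days

    def treatment_duration_months(self, config: ModelConfig) -> float:
        """Fixed-course treatment duration: cap x interval (months)."""
        if self.course_cap is None:
            return config.horizon
        return self.course_cap * self.admin_interval_days / config.days_per_month


@dataclass(frozen=True)
class StrategyArm:
    """A treatment strategy: weighted regimens, survival curves, SAE profile.

    ``sae_incidence`` maps SAE name -> per-patient incidence of the grade >=3
    event; costs and disutilities for each SAE live in :class:`CostInputs` /
    :class:`UtilityInputs`.
    """

    name: str
    regimens: tuple
    pfs: SurvivalDistribution
    os: SurvivalDistribution
    sae_incidence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimens", tuple(self.regimens))
        w = sum(r.weight for r in self.regimens)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"regimen weights must sum to 1 (got {w})")
        for name, p in self.sae_incidence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"SAE incidence for {name!r} outside [0, 1]")


@dataclass(frozen=True)
class CostInputs:
    """Non-drug unit costs (USD unless ``non_drug_unit_scale`` rescales them).

    ``non_drug_unit_scale`` multiplies follow-up, BSC and SAE unit costs before
    accrual.  The packaged replication fixture sets it to the source analysis's
    CNY/USD rate (6.8974) because the published outcome table embeds these
    costs at their yuan magnitudes; see docs/methods.md.
    """

    followup_per_cycle: float = 7.47
    bsc_per_cycle: float = 16.98
    sae_costs: Mapping[str, float] = field(default_factory=dict)
    non_drug_unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.followup_per_cycle < 0 or self.bsc_per_cycle < 0:
            raise ValueError("per-cycle costs must be non-negative")
        if any(c < 0 for c in self.sae_costs.values()):
            raise ValueError("SAE costs must be non-negative")
        if self.non_drug_unit_scale <= 0:
            raise ValueError("non_drug_unit_scale must be positive")


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and SAE disutilities (disutilities <= 0)."""

    u_pfd: float = 0.741
    u_pd: float = 0.581
    disutilities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u in (self.u_pfd, self.u_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")
        if any(d > 0 for d in self.disutilities.values()):
            raise ValueError("disutilities must be <= 0")


# ---------------------------------------------------------------------------
# trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTrace:
    """Per-grid-point state occupancy (fractions of the cohort)."""

    times: np.ndarray
    pfd: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        total = self.pfd + self.pd + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-12:
            raise ValueError("occupancy must sum to 1 at every grid point")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "pfd": self.pfd, "pd": self.pd, "dead": self.dead}
        )


def build_trace(arm: StrategyArm, config: ModelConfig) -> CohortTrace:
    """Occupancy on the cycle grid from the arm's PFS/OS curves.

    Raises if S_PFS exceeds S_OS by more than ``CURVE_CONSISTENCY_TOL``
    anywhere on the grid (inconsistent curve pair); smaller excesses are
    clamped and counted.
    """
    t = np.arange(config.n_cycles + 1) * config.cycle_length
    s_pfs = arm.pfs.survival_probability(t)
    s_os = arm.os.survival_probability(t)
    excess = s_pfs - s_os
    if np.any(excess > CURVE_CONSISTENCY_TOL):
        k = int(np.argmax(excess))
        raise ValueError(
            f"arm {arm.name!r}: S_PFS exceeds S_OS by {excess[k]:.4f} at "
            f"t={t[k]:.4g} months (> {CURVE_CONSISTENCY_TOL}); curve pair is inconsistent"
        )
    n_clamped = int(np.sum(excess > 0))
    pfd = np.minimum(s_pfs, s_os)
    pd_ = s_os - pfd
    dead = 1.0 - s_os
    return CohortTrace(times=t, pfd=pfd, pd=pd_, dead=dead, n_clamped=n_clamped)


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmExposures:
    """Discounted occupancy-weighted cycle sums for one arm and scenario.

    Monetary/utility totals are linear in these:

    * drug cost      = sum_r weight_r * price_r * mg_r * ``admin_exposure[r]``
    * follow-up cost = unit * ``alive_cycles``
    * BSC cost       = unit * ``pd_cycles``
    * SAE cost       = (sum inc*cost) * ``treat_cycles``
    * QALYs          = u_pfd * ``pfd_years`` + u_pd * ``pd_years``
                       + (sum inc*disutility) * ``pfd_treat_years``
    * LY             = ``pfd_years`` + ``pd_years``
    """

    arm_name: str
    scenario: str
    admin_exposure: Mapping[str, float]
    treat_cycles: float
    alive_cycles: float
    pd_cycles: float
    pfd_years: float
    pd_years: float
    pfd_treat_years: float


def _cycle_weights(x: np.ndarray, half_cycle: bool) -> np.ndarray:
    return 0.5 * (x[:-1] + x[1:]) if half_cycle else x[:-1]


def _treat_fraction(duration: float, config: ModelConfig) -> np.ndarray:
    """Fraction of each cycle spent on treatment for a duration in months."""
    t0 = np.arange(config.n_cycles) * config.cycle_length
    return np.clip((duration - t0) / config.cycle_length, 0.0, 1.0)


def compute_exposures(
    arm: StrategyArm,
    config: ModelConfig,
    scenario: str,
    trace: CohortTrace | None = None,
) -> ArmExposures:
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if trace is None:
        trace = build_trace(arm, config)

    cyc = config.cycle_length
    k = np.arange(config.n_cycles)
    t_disc = (k + 0.5) * cyc if config.discount_timing == "midpoint" else k * cyc
    disc = (1.0 + config.annual_discount_rate) ** (-t_disc / 12.0)

    hc = config.half_cycle_correction
    w_pfd = _cycle_weights(trace.pfd, hc)
    w_alive = _cycle_weights(trace.pfd + trace.pd, hc)
    w_pd = _cycle_weights(trace.pd, hc)
    w_drug = w_pfd if config.drug_population == "pfd" else w_alive

    admin_exposure: dict[str, float] = {}
    treat_cycles = 0.0
    pfd_treat_cycles = 0.0
    for reg in arm.regimens:
        if scenario == "fixed_courses":
            frac = _treat_fraction(reg.treatment_duration_months(config), config)
            occ = w_drug
        else:
            frac = np.ones(config.n_cycles)
            occ = w_pfd
        e = float(np.sum(occ * disc * frac))
        admin_exposure[reg.name] = e * reg.admins_per_cycle(config)
        treat_cycles += reg.weight * e
        pfd_treat_cycles += reg.weight * float(np.sum(w_pfd * disc * frac))

    months_per_year = 12.0 / cyc  # cycles per year when cycle_length != 1
    to_years = cyc / 12.0
    return ArmExposures(
        arm_name=arm.name,
        scenario=scenario,
        admin_exposure=admin_exposure,
        treat_cycles=treat_cycles * cyc,
        alive_cycles=float(np.sum(w_alive * disc)) * cyc,
        pd_cycles=float(np.sum(w_pd * disc)) * cyc,
        pfd_years=float(np.sum(w_pfd * disc)) * to_years,
        pd_years=float(np.sum(w_pd * disc)) * to_years,
        pfd_treat_years=pfd_treat_cycles * to_years,
    )


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmResult:
    """Discounted totals and breakdowns for one arm under one scenario."""

    name: str
    scenario: str
    cost_total: float
    cost_drug: float
    cost_followup: float
    cost_bsc: float
    cost_sae: float
    cost_by_regimen: Mapping[str, float]
    qaly_total: float
    qaly_pfd: float
    qaly_pd: float
    qaly_sae: float
    life_years: float
    exposures: ArmExposures = field(compare=False, repr=False, default=None)

    def __post_init__(self) -> None:
        parts = self.cost_drug + self.cost_followup + self.cost_bsc + self.cost_sae
        if abs(parts - self.cost_total) > 1e-9 * max(1.0, abs(self.cost_total)):
            raise ValueError("cost breakdown does not sum to total")
        if self.qaly_total > self.life_years + 1e-12:
            raise ValueError("QALYs cannot exceed life-years")


def evaluate_arm(
    arm: StrategyArm,
    config: ModelConfig,
    costs: CostInputs,
    utilities: UtilityInputs,
    scenario: str,
    trace: CohortTrace | None = None,
) -> ArmResult:
    exp = compute_exposures(arm, config, scenario, trace=trace)

    bsa = config.body_surface_area
    cost_by_regimen = {
        reg.name: reg.weight * reg.price_per_mg * reg.dose_mg(bsa)
        * exp.admin_exposure[reg.name]
        for reg in arm.regimens
    }
    cost_drug = float(sum(cost_by_regimen.values()))
    scale = costs.non_drug_unit_scale
    cost_followup = scale * costs.followup_per_cycle * exp.alive_cycles
    cost_bsc = scale * costs.bsc_per_cycle * exp.pd_cycles
    sae_rate = sum(
        p * costs.sae_costs.get(name, 0.0) for name, p in arm.sae_incidence.items()
    )
    cost_sae = scale * sae_rate * exp.treat_cycles

    disut_rate = sum(
        p * utilities.disutilities.get(name, 0.0)
        for name, p in arm.sae_incidence.items()
    )
    qaly_pfd = utilities.u_pfd * exp.pfd_years
    qaly_pd = utilities.u_pd * exp.pd_years
    qaly_sae = disut_rate * exp.pfd_treat_years
    return ArmResult(
        name=arm.name,
        scenario=scenario,
        cost_total=cost_drug + cost_followup + cost_bsc + cost_sae,
        cost_drug=cost_drug,
        cost_followup=cost_followup,
        cost_bsc=cost_bsc,
        cost_sae=cost_sae,
        cost_by_regimen=cost_by_regimen,
        qaly_total=qaly_pfd + qaly_pd + qaly_sae,
        qaly_pfd=qaly_pfd,
        qaly_pd=qaly_pd,
        qaly_sae=qaly_sae,
        life_years=exp.pfd_years + exp.pd_years,
        exposures=exp,
    )


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of a reference arm against a comparator."""

    reference: ArmResult
    comparator: ArmResult
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominant: str | None  # arm name if one arm is cheaper AND more effective

    def summary(self) -> pd.DataFrame:
        rows = []
        for a in (self.reference, self.comparator):
            rows.append(
                {
                    "arm": a.name,
                    "cost_total": a.cost_total,
                    "cost_drug": a.cost_drug,
                    "cost_followup": a.cost_followup,
                    "cost_bsc": a.cost_bsc,
                    "cost_sae": a.cost_sae,
                    "qaly_total": a.qaly_total,
                    "qaly_pfd": a.qaly_pfd,
                    "qaly_pd": a.qaly_pd,
                    "life_years": a.life_years,
                }
            )
        return pd.DataFrame(rows)


def compute_icer(reference: ArmResult, comparator: ArmResult) -> CEResult:
    """Incremental cost per QALY of ``reference`` over ``comparator``.

    The ICER is None (undefined) when the QALY difference is zero; the
    ``dominant`` field names the arm that is both cheaper and more effective
    when strict dominance occurs.
    """
    if reference.scenario != comparator.scenario:
        raise ValueError("arms evaluated under different scenarios")
    d_cost = reference.cost_total - comparator.cost_total
    d_qaly = reference.qaly_total - comparator.qaly_total
    icer = d_cost / d_qaly if d_qaly != 0.0 else None
    dominant = None
    if d_cost < 0 and d_qaly > 0:
        dominant = reference.name
    elif d_cost > 0 and d_qaly < 0:
        dominant = comparator.name
    return CEResult(reference, comparator, d_cost, d_qaly, icer, dominant)
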