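"""One-way (tornado) and probabilistic sensitivity analysis.

OWSA re-evaluates the deterministic model at each parameter's bounds with all
other inputs at base, reporting the ICER swing per parameter.  PSA draws every
distributed parameter from a moment-matched distribution (beta for utilities,
disutilities and probabilities; gamma for costs), evaluates the model per
draw, and summarizes the (delta cost, delta QALY) cloud as a
cost-effectiveness acceptability curve (CEAC): the probability of positive net
monetary benefit as a function of willingness to pay.

Dispersion convention: when a published range exists the standard error is
``(high - low) / (2 * 1.96)`` (the range read as a 95% interval); otherwise
25% of the mean.  Survival-curve parameters have no published ranges and are
held fixed by default; ``vary_survival=True`` samples them log-normally with a
10% log-scale sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config as _config
from .engine import compute_exposures, evaluate_arm
from .model import CostEffectivenessModel
from .survival import SurvivalDistribution

__all__ = [
    "ParamRange",
    "default_owsa_ranges",
    "default_psa_ranges",
    "run_owsa",
    "run_psa",
    "ceac",
    "PSAResults",
]

_Z95 = 2.0 * 1.959963984540054  # width of a 95% normal interval in se units


@dataclass(frozen=True)
class ParamRange:
    """A model input with base value, deterministic bounds and PSA family."""

    name: str
    base: float
    low: float
    high: float
    psa_family: str = "fixed"  # beta | gamma | fixed

    def __post_init__(self) -> None:
        lo, hi = sorted((float(self.low), float(self.high)))
        object.__setattr__(self, "low", lo)
        object.__setattr__(self, "high", hi)
        if not lo <= self.base <= hi:
            raise ValueError(f"{self.name}: base {self.base} outside [{lo}, {hi}]")
        if self.psa_family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"{self.name}: unknown psa_family {self.psa_family!r}")

    def se(self, default_fraction: float = 0.25) -> float:
        if self.high > self.low:
            return (self.high - self.low) / _Z95
        return default_fraction * abs(self.base)

    def sample(self, n: int, rng: np.random.Generator,
               default_fraction: float = 0.25) -> np.ndarray:
        """Moment-matched draws with mean equal to the base value."""
        m, s = self.base, self.se(default_fraction)
        if self.psa_family == "fixed" or s == 0.0 or m == 0.0:
            return np.full(n, m)
        if self.psa_family == "beta":
            mag, sign = (abs(m), math.copysign(1.0, m))
            if not 0.0 < mag < 1.0:
                raise ValueError(f"{self.name}: beta requires a mean in (0, 1), got {m}")
            nu = mag * (1.0 - mag) / s**2 - 1.0
            if nu <= 0:
                raise ValueError(
                    f"{self.name}: se {s:.4g} too large for a beta with mean {mag:.4g}"
                )
            return sign * rng.beta(mag * nu, (1.0 - mag) * nu, size=n)
        # gamma
        k = (m / s) ** 2
        return rng.gamma(shape=k, scale=s**2 / m, size=n)


# ---------------------------------------------------------------------------
# default parameter sets from a configuration
# ---------------------------------------------------------------------------

def _rng_or(v, base):
    r = _config._range(v)
    return r if r is not None else (base, base)


def _table_ranges(cfg: Mapping) -> list[ParamRange]:
    """Parameters carrying published ranges (utilities, disutilities, costs)."""
    out: list[ParamRange] = []
    u = cfg["utilities"]
    for key in ("pfd", "pd"):
        b = _config._base(u[key])
        lo, hi = _rng_or(u[key], b)
        out.append(ParamRange(f"utilities.{key}", b, lo, hi, "beta"))
    for dname, v in u.get("disutilities", {}).items():
        b = _config._base(v)
        lo, hi = _rng_or(v, b)
        out.append(ParamRange(f"utilities.disutilities.{dname}", b, lo, hi, "beta"))
    c = cfg["costs"]
    for key in ("followup_per_cycle", "bsc_per_cycle"):
        b = _config._base(c[key])
        lo, hi = _rng_or(c[key], b)
        out.append(ParamRange(f"costs.{key}", b, lo, hi, "gamma"))
    for sname, v in c.get("sae", {}).items():
        b = _config._base(v)
        lo, hi = _rng_or(v, b)
        out.append(ParamRange(f"costs.sae.{sname}", b, lo, hi, "gamma"))
    for arm_name, arm in cfg["arms"].items():
        for rname, r in arm["regimens"].items():
            b = float(r["price_per_mg"])
            lo, hi = r.get("price_range", (b, b))
            out.append(
                ParamRange(
                    f"arms.{arm_name}.regimens.{rname}.price_per_mg",
                    b, float(lo), float(hi), "gamma",
                )
            )
    return out


def default_owsa_ranges(cfg: Mapping) -> list[ParamRange]:
    """Published-range parameters plus discount rate and body surface area."""
    sens = cfg.get("sensitivity", {})
    out = _table_ranges(cfg)
    dr = float(cfg["model"]["annual_discount_rate"])
    lo, hi = sens.get("discount_rate_range", (dr, dr))
    out.append(ParamRange("model.annual_discount_rate", dr, float(lo), float(hi), "fixed"))
    bsa = float(cfg["model"]["body_surface_area_m2"])
    lo, hi = sens.get("bsa_range", (bsa, bsa))
    out.append(ParamRange("model.body_surface_area_m2", bsa, float(lo), float(hi), "fixed"))
    return out


def default_psa_ranges(cfg: Mapping) -> list[ParamRange]:
    """Distributed parameters for the PSA: table-range params + incidences."""
    out = [r for r in _table_ranges(cfg)]
    for arm_name, arm in cfg["arms"].items():
        for sname, p in arm.get("sae_incidence", {}).items():
            p = float(p)
            out.append(
                ParamRange(f"arms.{arm_name}.sae_incidence.{sname}", p, p, p, "beta")
            )
    return out


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

def _icer_for(cfg: Mapping, scenario, family: str) -> float | None:
    model = CostEffectivenessModel.from_config(cfg, family=family)
    return model.fit(scenario).icer


def run_owsa(
    cfg: Mapping,
    ranges: Sequence[ParamRange] | None = None,
    scenario=1,
    family: str = "loglogistic",
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's bounds, sorted by bar width."""
    if ranges is None:
        ranges = default_owsa_ranges(cfg)
    base_icer = _icer_for(cfg, scenario, family)
    rows = []
    for pr in ranges:
        _config.resolve_path(cfg, pr.name)  # raises with valid choices if bad
        lo_icer = _icer_for(_config.apply_override(cfg, pr.name, pr.low), scenario, family)
        hi_icer = _icer_for(_config.apply_override(cfg, pr.name, pr.high), scenario, family)
        rows.append(
            {
                "parameter": pr.name,
                "low_value": pr.low,
                "high_value": pr.high,
                "low_icer": lo_icer,
                "high_icer": hi_icer,
                "width": abs((hi_icer or 0.0) - (lo_icer or 0.0)),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["width", "parameter"], ascending=[False, True]).reset_index(drop=True)
    df.attrs["base_icer"] = base_icer
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSAResults:
    """Monte-Carlo samples of the incremental cost/QALY pair."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    scenario: str
    n_iterations: int
    wtp_grid: tuple = ()

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> pd.DataFrame:
        grid = self.wtp_grid if wtp_grid is None else tuple(wtp_grid)
        return ceac(self, grid)

    def probability_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0.0))

    def summary(self) -> str:
        return (
            f"PSA ({self.n_iterations} iterations, seed {self.seed}, {self.scenario}): "
            f"mean dCost {self.delta_cost.mean():,.2f}, "
            f"mean dQALY {self.delta_qaly.mean():.4f}"
        )


def ceac(psa: PSAResults, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """P(net monetary benefit > 0) over a willingness-to-pay grid.

    A draw with NMB exactly zero counts as not cost-effective.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if psa.n_iterations == 0:
        raise ValueError("PSA has no iterations")
    probs = [
        float(np.mean(w * psa.delta_qaly - psa.delta_cost > 0.0)) for w in grid
    ]
    return pd.DataFrame({"wtp": grid, "probability": probs})


def _sampled_value(samples: Mapping[str, np.ndarray], name: str, base: float):
    return samples.get(name, base)


def _arm_totals_vector(cfg, arm_name, exposures, samples, costs, utilities, bsa):
    """Vectorized per-draw (cost, qaly) for one arm with frozen curves."""
    arm_cfg = cfg["arms"][arm_name]
    cost = 0.0
    for rname, r in arm_cfg["regimens"].items():
        price = _sampled_value(
            samples, f"arms.{arm_name}.regimens.{rname}.price_per_mg",
            float(r["price_per_mg"]),
        )
        mg = float(r["dose_per_admin"]) * (bsa if r["dose_basis"] == "bsa" else 1.0)
        cost = cost + float(r["weight"]) * price * mg * exposures.admin_exposure[rname]
    scale = costs.non_drug_unit_scale
    fu = _sampled_value(samples, "costs.followup_per_cycle", costs.followup_per_cycle)
    bsc = _sampled_value(samples, "costs.bsc_per_cycle", costs.bsc_per_cycle)
    cost = cost + scale * (fu * exposures.alive_cycles + bsc * exposures.pd_cycles)
    sae_rate = 0.0
    disut_rate = 0.0
    for sname, p0 in arm_cfg.get("sae_incidence", {}).items():
        inc = _sampled_value(samples, f"arms.{arm_name}.sae_incidence.{sname}", float(p0))
        sc = _sampled_value(samples, f"costs.sae.{sname}", costs.sae_costs.get(sname, 0.0))
        du = _sampled_value(
            samples, f"utilities.disutilities.{sname}",
            utilities.disutilities.get(sname, 0.0),
        )
        sae_rate = sae_rate + inc * sc
        disut_rate = disut_rate + inc * du
    cost = cost + scale * sae_rate * exposures.treat_cycles
    u_pfd = _sampled_value(samples, "utilities.pfd", utilities.u_pfd)
    u_pd = _sampled_value(samples, "utilities.pd", utilities.u_pd)
    qaly = (
        u_pfd * exposures.pfd_years
        + u_pd * exposures.pd_years
        + disut_rate * exposures.pfd_treat_years
    )
    return cost, qaly


def run_psa(
    cfg: Mapping,
    n: int | None = None,
    seed: int = 0,
    scenario=1,
    family: str = "loglogistic",
    ranges: Sequence[ParamRange] | None = None,
    vary_survival: bool | None = None,
) -> PSAResults:
    """Monte-Carlo PSA; fully reproducible from ``seed``.

    With frozen survival curves (default) the state-occupancy exposures are
    computed once and per-draw totals are vectorized; with
    ``vary_survival=True`` each draw re-extrapolates the curves from
    log-normally perturbed parameters.
    """
    sens = cfg.get("sensitivity", {})
    if n is None:
        n = int(sens.get("n_iterations", 10000))
    if n < 1:
        raise ValueError("n must be >= 1")
    if vary_survival is None:
        vary_survival = bool(sens.get("vary_survival", False))
    frac = float(sens.get("psa_default_se_fraction", 0.25))
    if ranges is None:
        ranges = default_psa_ranges(cfg)

    rng = np.random.default_rng(seed)
    samples = {pr.name: pr.sample(n, rng, frac) for pr in ranges}

    model = CostEffectivenessModel.from_config(cfg, family=family)
    key = model.fit(scenario).scenario  # normalizes 1/2 -> names
    bsa = model.config.body_surface_area

    if not vary_survival:
        exp_ref = compute_exposures(model.reference, model.config, key)
        exp_cmp = compute_exposures(model.comparator, model.config, key)
        c_ref, q_ref = _arm_totals_vector(
            cfg, model.reference.name, exp_ref, samples, model.costs, model.utilities, bsa
        )
        c_cmp, q_cmp = _arm_totals_vector(
            cfg, model.comparator.name, exp_cmp, samples, model.costs, model.utilities, bsa
        )
        d_cost = np.broadcast_to(np.asarray(c_ref - c_cmp, float), (n,)).copy()
        d_qaly = np.broadcast_to(np.asarray(q_ref - q_cmp, float), (n,)).copy()
    else:
        log_se = float(sens.get("survival_log_se", 0.10))
        d_cost = np.empty(n)
        d_qaly = np.empty(n)
        base_curves = {
            ("reference", "pfs"): model.reference.pfs,
            ("reference", "os"): model.reference.os,
            ("comparator", "pfs"): model.comparator.pfs,
            ("comparator", "os"): model.comparator.os,
        }
        curve_draws = {
            k: (
                d.shape * np.exp(rng.normal(0.0, log_se * abs(math.log(d.shape)) or log_se, n)),
                d.scale * np.exp(rng.normal(0.0, log_se * abs(math.log(d.scale)) or log_se, n)),
            )
            for k, d in base_curves.items()
        }
        for i in range(n):
            draw_i = {k: v[i] if isinstance(v, np.ndarray) else v for k, v in samples.items()}
            arms = {}
            for role in ("reference", "comparator"):
                arm = getattr(model, role)
                sh_p, sc_p = curve_draws[(role, "pfs")]
                sh_o, sc_o = curve_draws[(role, "os")]
                from dataclasses import replace as _replace

                arms[role] = _replace(
                    arm,
                    pfs=SurvivalDistribution(arm.pfs.family, sh_p[i], sc_p[i]),
                    os=SurvivalDistribution(arm.os.family, sh_o[i], sc_o[i]),
                )
            try:
                exp_ref = compute_exposures(arms["reference"], model.config, key)
                exp_cmp = compute_exposures(arms["comparator"], model.config, key)
            except ValueError:  # inconsistent sampled curve pair: skip-and-hold base
                exp_ref = compute_exposures(model.reference, model.config, key)
                exp_cmp = compute_exposures(model.comparator, model.config, key)
            c_r, q_r = _arm_totals_vector(
                cfg, model.reference.name, exp_ref, draw_i, model.costs, model.utilities, bsa
            )
            c_c, q_c = _arm_totals_vector(
                cfg, model.comparator.name, exp_cmp, draw_i, model.costs, model.utilities, bsa
            )
            d_cost[i] = c_r - c_c
            d_qaly[i] = q_r - q_c

    grid = tuple(sens.get("ceac_wtp_grid", model.config.wtp_thresholds))
    return PSAResults(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        seed=seed,
        scenario=key,
        n_iterations=n,
        wtp_grid=grid,
    )
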