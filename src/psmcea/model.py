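"""Model / Results interface for the cost-effectiveness analysis.

:class:`CostEffectivenessModel` holds the two strategy arms and all inputs;
``fit(scenario=...)`` evaluates the partitioned-survival engine and returns a
:class:`CEResults` carrying the per-arm totals, breakdowns, increments, the
ICER and a printable summary table.

>>> from psmcea import CostEffectivenessModel
>>> model = CostEffectivenessModel.from_config()        # packaged base case
>>> res = model.fit(scenario=1)
>>> print(res.summary())                                # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import config as _config
from .engine import (
    ArmResult,
    CEResult,
    CohortTrace,
    CostInputs,
    ModelConfig,
    StrategyArm,
    UtilityInputs,
    build_trace,
    compute_icer,
    evaluate_arm,
)

__all__ = ["CostEffectivenessModel", "CEResults"]

_SCENARIO_NAMES = {1: "fixed_courses", 2: "treat_to_progression"}


def _scenario_key(scenario) -> str:
    if scenario in _SCENARIO_NAMES:
        return _SCENARIO_NAMES[scenario]
    if scenario in _SCENARIO_NAMES.values():
        return str(scenario)
    raise ValueError(
        f"unknown scenario {scenario!r}; use 1/2 or {tuple(_SCENARIO_NAMES.values())}"
    )


class CostEffectivenessModel:
    """Two-arm partitioned-survival cost-effectiveness model.

    Parameters
    ----------
    reference, comparator : StrategyArm
        The intervention and the comparator strategy.
    costs, utilities : CostInputs, UtilityInputs
    config : ModelConfig
    """

    def __init__(
        self,
        reference: StrategyArm,
        comparator: StrategyArm,
        costs: CostInputs,
        utilities: UtilityInputs,
        config: ModelConfig,
    ):
        self.reference = reference
        self.comparator = comparator
        self.costs = costs
        self.utilities = utilities
        self.config = config
        self.warnings: list[str] = []

    @classmethod
    def from_config(
        cls,
        cfg: Mapping | str | None = None,
        family: str = "loglogistic",
        **config_overrides,
    ) -> "CostEffectivenessModel":
        """Build the model from a configuration mapping or YAML path.

        ``family`` selects the survival family (``loglogistic`` or
        ``weibull``); keyword overrides are forwarded to
        :class:`~psmcea.engine.ModelConfig` (e.g. ``horizon=36.0``).
        """
        if cfg is None or isinstance(cfg, str):
            cfg = _config.load_config(cfg)
        warn: list[str] = []
        model = cls(
            reference=_config.build_arm(cfg, _config.ARM_REFERENCE, family, warn),
            comparator=_config.build_arm(cfg, _config.ARM_COMPARATOR, family, warn),
            costs=_config.build_costs(cfg),
            utilities=_config.build_utilities(cfg),
            config=_config.build_model_config(cfg, **config_overrides),
        )
        model.warnings.extend(warn)
        model._cfg = cfg
        model._family = family
        return model

    # ------------------------------------------------------------------
    def trace(self, arm: str = "reference") -> CohortTrace:
        return build_trace(getattr(self, arm), self.config)

    def fit(self, scenario=1) -> "CEResults":
        """Evaluate both arms and return the incremental results."""
        key = _scenario_key(scenario)
        ref = evaluate_arm(self.reference, self.config, self.costs, self.utilities, key)
        cmp_ = evaluate_arm(self.comparator, self.config, self.costs, self.utilities, key)
        ce = compute_icer(ref, cmp_)
        return CEResults(model=self, scenario=key, ce=ce, warnings=tuple(self.warnings))

    run = fit


@dataclass(frozen=True)
class CEResults:
    """Deterministic cost-effectiveness results for one scenario."""

    model: CostEffectivenessModel = field(repr=False, compare=False)
    scenario: str = "fixed_courses"
    ce: CEResult = None
    warnings: tuple = ()

    # convenience accessors -------------------------------------------------
    @property
    def reference(self) -> ArmResult:
        return self.ce.reference

    @property
    def comparator(self) -> ArmResult:
        return self.ce.comparator

    @property
    def delta_cost(self) -> float:
        return self.ce.delta_cost

    @property
    def delta_qaly(self) -> float:
        return self.ce.delta_qaly

    @property
    def icer(self) -> float | None:
        return self.ce.icer

    def net_monetary_benefit(self, wtp: float) -> float:
        return wtp * self.delta_qaly - self.delta_cost

    # tables ----------------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        """Outcome-table-shaped frame: one row per quantity, one column per arm."""
        ref, cmp_ = self.reference, self.comparator
        rows = {
            "QALYs total": (ref.qaly_total, cmp_.qaly_total),
            "QALYs PFD": (ref.qaly_pfd + ref.qaly_sae, cmp_.qaly_pfd + cmp_.qaly_sae),
            "QALYs PD": (ref.qaly_pd, cmp_.qaly_pd),
            "Life-years": (ref.life_years, cmp_.life_years),
            "Cost total": (ref.cost_total, cmp_.cost_total),
            "Cost drug": (ref.cost_drug, cmp_.cost_drug),
            "Cost follow-up": (ref.cost_followup, cmp_.cost_followup),
            "Cost BSC": (ref.cost_bsc, cmp_.cost_bsc),
            "Cost SAE": (ref.cost_sae, cmp_.cost_sae),
        }
        df = pd.DataFrame(rows, index=[ref.name, cmp_.name]).T
        df["incremental"] = df[ref.name] - df[cmp_.name]
        return df

    def summary(self) -> str:
        df = self.summary_frame()
        icer = "dominant" if self.ce.dominant else (
            f"{self.icer:,.2f}" if self.icer is not None else "undefined (dQALY = 0)"
        )
        lines = [
            f"Partitioned-survival cost-effectiveness results [{self.scenario}]",
            df.to_string(float_format=lambda v: f"{v:,.4f}"),
            f"ICER ($/QALY): {icer}",
        ]
        if self.warnings:
            lines.append("warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ref, cmp_ = self.reference, self.comparator

        def arm_dict(a: ArmResult) -> dict:
            return {
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

        return {
            "scenario": self.scenario,
            "arms": {ref.name: arm_dict(ref), cmp_.name: arm_dict(cmp_)},
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominant": self.ce.dominant,
            "warnings": list(self.warnings),
        }
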