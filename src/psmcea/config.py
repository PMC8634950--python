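"""Configuration loading, validation and object construction.

The configuration is a plain nested mapping (YAML on disk) mirroring the
published input table: model settings, survival parameters per family / arm /
endpoint, regimens, unit costs with sensitivity ranges, utilities, and
sensitivity-analysis settings.  ``load_config()`` with no argument returns the
packaged replication fixture.

Dotted-path overrides (``apply_override(cfg, "utilities.pfd.base", 0.7)``) are
the mechanism both sensitivity analyses use to perturb single inputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from typing import Any, Mapping

import yaml

from .engine import (
    CostInputs,
    DrugRegimen,
    ModelConfig,
    StrategyArm,
    UtilityInputs,
)
from .survival import SurvivalDistribution

__all__ = [
    "load_config",
    "save_config",
    "validate_config",
    "config_digest",
    "apply_override",
    "resolve_path",
    "build_model_config",
    "build_arm",
    "build_costs",
    "build_utilities",
    "ConfigError",
]

_FIXTURE = "escc_camrelizumab.yaml"

FAMILY_CHOICES = ("loglogistic", "weibull")
ARM_REFERENCE = "camrelizumab"
ARM_COMPARATOR = "chemotherapy"


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


def load_config(path: str | None = None) -> dict:
    """Load a configuration mapping (packaged fixture when ``path`` is None)."""
    if path is None:
        text = resources.files("psmcea.data").joinpath(_FIXTURE).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    errors = validate_config(cfg)
    if errors:
        raise ConfigError(errors)
    return cfg


def save_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def config_digest(cfg: Mapping) -> str:
    """Stable SHA-256 digest of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _base(v) -> float:
    """A value entry is either a scalar or a {base, range} mapping."""
    if isinstance(v, Mapping):
        return float(v["base"])
    return float(v)


def _range(v):
    if isinstance(v, Mapping) and "range" in v:
        lo, hi = v["range"]
        return float(lo), float(hi)
    return None


def validate_config(cfg) -> list[str]:
    """Return a list of human-readable problems (empty = valid)."""
    errors: list[str] = []
    if not isinstance(cfg, Mapping):
        return ["configuration root must be a mapping"]

    for section in ("model", "survival", "arms", "costs", "utilities"):
        if section not in cfg:
            errors.append(f"missing section {section!r}")
    if errors:
        return errors

    m = cfg["model"]
    try:
        build_model_config(cfg)
    except Exception as e:  # noqa: BLE001 - aggregate for the user
        errors.append(f"model: {e}")

    surv = cfg["survival"]
    for fam, arms in surv.items():
        for arm, endpoints in arms.items():
            for ep, p in endpoints.items():
                shape, scale = float(p["shape"]), float(p["scale"])
                if shape <= 0:
                    errors.append(f"survival.{fam}.{arm}.{ep}: shape must be positive")
                if scale == 0 or not abs(scale) > 0:
                    errors.append(f"survival.{fam}.{arm}.{ep}: scale must be nonzero")
                if scale < 0 and fam != "weibull":
                    errors.append(
                        f"survival.{fam}.{arm}.{ep}: negative scale {scale} is invalid"
                    )

    for arm_name, arm in cfg["arms"].items():
        w = sum(float(r["weight"]) for r in arm["regimens"].values())
        if abs(w - 1.0) > 1e-9:
            errors.append(f"arms.{arm_name}: regimen weights sum to {w}, expected 1")
        for rname, r in arm["regimens"].items():
            for key in ("dose_per_admin", "admin_interval_days", "price_per_mg"):
                if float(r[key]) <= 0:
                    errors.append(f"arms.{arm_name}.regimens.{rname}.{key} must be positive")
        for sname, p in arm.get("sae_incidence", {}).items():
            if not 0.0 <= float(p) <= 1.0:
                errors.append(f"arms.{arm_name}.sae_incidence.{sname} outside [0, 1]")

    c = cfg["costs"]
    for key in ("followup_per_cycle", "bsc_per_cycle"):
        if _base(c[key]) < 0:
            errors.append(f"costs.{key} must be non-negative")
    for sname, v in c.get("sae", {}).items():
        if _base(v) < 0:
            errors.append(f"costs.sae.{sname} must be non-negative")

    u = cfg["utilities"]
    for key in ("pfd", "pd"):
        if not 0.0 <= _base(u[key]) <= 1.0:
            errors.append(f"utilities.{key} must lie in [0, 1]")
    for dname, v in u.get("disutilities", {}).items():
        if _base(v) > 0:
            errors.append(f"utilities.disutilities.{dname} must be <= 0")

    return errors


# ---------------------------------------------------------------------------
# dotted-path access
# ---------------------------------------------------------------------------

def resolve_path(cfg: Mapping, dotted: str):
    """Return (parent, key) for a dotted path; raises KeyError with choices."""
    node: Any = cfg
    parts = dotted.split(".")
    for i, part in enumerate(parts[:-1]):
        if not isinstance(node, Mapping) or part not in node:
            raise KeyError(
                f"cannot resolve {dotted!r}: {'.'.join(parts[: i + 1])!r} not found; "
                f"valid keys here: {sorted(node) if isinstance(node, Mapping) else 'scalar'}"
            )
        node = node[part]
    last = parts[-1]
    if not isinstance(node, Mapping) or last not in node:
        raise KeyError(
            f"cannot resolve {dotted!r}; valid keys here: "
            f"{sorted(node) if isinstance(node, Mapping) else 'scalar'}"
        )
    return node, last


def apply_override(cfg: Mapping, dotted: str, value) -> dict:
    """Return a deep copy of ``cfg`` with one dotted path replaced.

    If the target entry is a {base, range} mapping, its ``base`` is replaced.
    """
    new = copy.deepcopy(dict(cfg))
    parent, key = resolve_path(new, dotted)
    if isinstance(parent[key], Mapping) and "base" in parent[key]:
        parent[key] = dict(parent[key], base=value)
    else:
        parent[key] = value
    return new


# ---------------------------------------------------------------------------
# object construction
# ---------------------------------------------------------------------------

def build_model_config(cfg: Mapping, **overrides) -> ModelConfig:
    m = cfg["model"]
    kwargs = dict(
        cycle_length=float(m.get("cycle_length_months", 1.0)),
        horizon=float(m.get("horizon_months", 120.0)),
        annual_discount_rate=float(m.get("annual_discount_rate", 0.05)),
        wtp_thresholds=tuple(m.get("wtp_thresholds", (10503.52,))),
        body_surface_area=float(m.get("body_surface_area_m2", 1.72)),
        half_cycle_correction=bool(m.get("half_cycle_correction", True)),
        discount_timing=str(m.get("discount_timing", "midpoint")),
        days_per_month=float(m.get("days_per_month", 30.4375)),
        drug_population=str(m.get("drug_population", "pfd")),
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def build_survival(cfg: Mapping, family: str, arm: str, endpoint: str,
                   warnings_out: list | None = None) -> SurvivalDistribution:
    p = cfg["survival"][family][arm][endpoint]
    shape, scale = float(p["shape"]), float(p["scale"])
    if scale < 0:
        if warnings_out is not None:
            warnings_out.append(
                f"survival.{family}.{arm}.{endpoint}: negative scale {scale} "
                f"replaced by |scale| = {abs(scale)} (published value is invalid)"
            )
        scale = abs(scale)
    return SurvivalDistribution("loglogistic" if family == "loglogistic" else family,
                                shape, scale)


def build_arm(cfg: Mapping, arm_name: str, family: str = "loglogistic",
              warnings_out: list | None = None) -> StrategyArm:
    arm_cfg = cfg["arms"][arm_name]
    regimens = tuple(
        DrugRegimen(
            name=rname,
            dose_per_admin=float(r["dose_per_admin"]),
            dose_basis=str(r["dose_basis"]),
            admin_interval_days=float(r["admin_interval_days"]),
            price_per_mg=float(r["price_per_mg"]),
            course_cap=(int(r["course_cap"]) if r.get("course_cap") is not None else None),
            weight=float(r["weight"]),
        )
        for rname, r in arm_cfg["regimens"].items()
    )
    return StrategyArm(
        name=arm_name,
        regimens=regimens,
        pfs=build_survival(cfg, family, arm_name, "pfs", warnings_out),
        os=build_survival(cfg, family, arm_name, "os", warnings_out),
        sae_incidence={k: float(v) for k, v in arm_cfg.get("sae_incidence", {}).items()},
    )


def build_costs(cfg: Mapping) -> CostInputs:
    c = cfg["costs"]
    return CostInputs(
        followup_per_cycle=_base(c["followup_per_cycle"]),
        bsc_per_cycle=_base(c["bsc_per_cycle"]),
        sae_costs={k: _base(v) for k, v in c.get("sae", {}).items()},
        non_drug_unit_scale=float(c.get("non_drug_unit_scale", 1.0)),
    )


def build_utilities(cfg: Mapping) -> UtilityInputs:
    u = cfg["utilities"]
    return UtilityInputs(
        u_pfd=_base(u["pfd"]),
        u_pd=_base(u["pd"]),
        disutilities={k: _base(v) for k, v in u.get("disutilities", {}).items()},
    )
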