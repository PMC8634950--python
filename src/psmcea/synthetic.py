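"""Synthetic trial data with known ground truth.

No individual-patient data from the source trial are available, so the
reconstruction/fitting pipeline is exercised on simulated cohorts: latent
PFS/OS times drawn from known parametric laws (coupled so PFS <= OS always),
censored administratively at the accrual horizon and optionally by a random
exponential censoring process, then "digitized" into step-function KM
coordinates with bounded jitter plus a numbers-at-risk table -- the same shape
of evidence a graph digitizer extracts from a published figure.

The default cohort mimics the source trial's scale: 228 and 220 patients per
arm, administrative censoring at 24 months, risk table every 2 months.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ipd import PseudoIPD
from .reconstruct import MONOTONE_TOL, DigitizedCurve, km_estimate
from .survival import SurvivalDistribution

__all__ = ["SimSpec", "simulate_ipd", "digitize", "write_fixture_dir"]

_TRIAL_N = {"camrelizumab": 228, "chemotherapy": 220}


@dataclass(frozen=True)
class SimSpec:
    """Ground-truth laws and censoring scheme for one simulated arm."""

    true_pfs: SurvivalDistribution
    true_os: SurvivalDistribution
    n_per_arm: int = 228
    accrual_censoring: float = 24.0  # administrative cut-off, months
    random_censoring_rate: float = 0.0  # per-month hazard of loss to follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.accrual_censoring < 0 or self.random_censoring_rate < 0:
            raise ValueError("censoring parameters must be non-negative")


def simulate_ipd(spec: SimSpec) -> tuple[PseudoIPD, PseudoIPD]:
    """Simulate (pfs, os) pseudo-IPD for one arm.

    OS is drawn by inverse-CDF from a shared uniform; the latent PFS draw uses
    the same uniform (comonotone coupling) and is truncated at OS so
    progression never follows death.  Observation applies administrative
    censoring at ``accrual_censoring`` months plus, when
    ``random_censoring_rate > 0``, an independent exponential censoring time.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n_per_arm)
    os_lat = spec.true_os._frozen().ppf(1.0 - u)  # sf-inverse: high u = early death
    pfs_lat = np.minimum(spec.true_pfs._frozen().ppf(1.0 - u), os_lat)

    cens = np.full(spec.n_per_arm, float(spec.accrual_censoring))
    if spec.random_censoring_rate > 0:
        cens = np.minimum(
            cens, rng.exponential(1.0 / spec.random_censoring_rate, spec.n_per_arm)
        )

    def observe(lat: np.ndarray, label: str) -> PseudoIPD:
        t_obs = np.minimum(lat, cens)
        ev = (lat <= cens).astype(int)
        return PseudoIPD(t_obs, ev, label=label)

    return observe(pfs_lat, "pfs"), observe(os_lat, "os")


def digitize(
    ipd: PseudoIPD,
    grid,
    jitter: float = 0.0,
    seed: int = 0,
) -> DigitizedCurve:
    """Emulate graph-digitizer output: the KM curve sampled on a time grid.

    Survival values carry bounded uniform noise (|noise| <= ``jitter``) and
    are re-monotonized; the risk table holds the true numbers at risk at the
    grid times.  ``jitter`` above the reconstruction tolerance (0.005) is
    refused.
    """
    if jitter < 0 or jitter > MONOTONE_TOL:
        raise ValueError(
            f"jitter must lie in [0, {MONOTONE_TOL}] (reconstruction tolerance)"
        )
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    if grid[0] < 0 or grid[-1] > float(ipd.time.max()) + 1e-9:
        raise ValueError("grid must lie within the observed time range")

    km = km_estimate(ipd)
    vals = np.array([km.survival_at(t) for t in grid])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.uniform(-jitter, jitter, size=grid.size)
    vals = np.minimum.accumulate(np.clip(vals, 0.0, 1.0))
    if grid[0] > 0:
        grid = np.concatenate([[0.0], grid])
        vals = np.concatenate([[1.0], vals])
    n_at_risk = np.array([int(np.sum(ipd.time >= t)) for t in grid])
    return DigitizedCurve(grid, vals, grid, n_at_risk, n_total=len(ipd), label=ipd.label)


def write_fixture_dir(
    path,
    cfg=None,
    family: str = "loglogistic",
    n_per_arm=None,
    accrual_censoring: float = 24.0,
    grid_step: float = 2.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> dict:
    """Write a complete synthetic study directory (CSV schemas as consumed by
    the reconstruction and fitting stages) and return the file map."""
    from . import config as _cfgmod

    if cfg is None:
        cfg = _cfgmod.load_config()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for i, arm in enumerate(cfg["arms"]):
        n = (n_per_arm or _TRIAL_N).get(arm, 200) if isinstance(
            n_per_arm or _TRIAL_N, dict
        ) else int(n_per_arm)
        spec = SimSpec(
            true_pfs=_cfgmod.build_survival(cfg, family, arm, "pfs"),
            true_os=_cfgmod.build_survival(cfg, family, arm, "os"),
            n_per_arm=n,
            accrual_censoring=accrual_censoring,
            seed=seed + i,
        )
        pfs, os_ = simulate_ipd(spec)
        for endpoint, ipd in (("pfs", pfs), ("os", os_)):
            ipd_path = path / f"{arm}_{endpoint}_ipd.csv"
            ipd.to_csv(ipd_path)
            files[f"{arm}_{endpoint}_ipd"] = str(ipd_path)
            grid = np.arange(grid_step, accrual_censoring + 1e-9, grid_step)
            grid = grid[grid <= ipd.time.max()]
            curve = digitize(ipd, grid, jitter=jitter, seed=seed + i)
            cpath = path / f"{arm}_{endpoint}_curve.csv"
            rpath = path / f"{arm}_{endpoint}_risk.csv"
            curve.to_csv(cpath, rpath)
            files[f"{arm}_{endpoint}_curve"] = str(cpath)
            files[f"{arm}_{endpoint}_risk"] = str(rpath)
    return files
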