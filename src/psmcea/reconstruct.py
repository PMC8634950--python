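"""Kaplan-Meier estimation and pseudo-IPD reconstruction from digitized curves.

Published trial curves are usually available only as digitized step-function
coordinates plus a numbers-at-risk table.  :func:`reconstruct_ipd` inverts the
product-limit estimator interval by interval: within each risk-table interval
censorings are assumed uniformly spread, event counts are solved from the
published survival drops, and the censoring total is iterated until the
reconstructed number at risk matches the published count at the interval end.
The procedure is deterministic and conserves patients exactly.

Conventions
-----------
* The KM step function is right-continuous; S(t) is the value *after* all
  events at t.
* At tied times events are processed before censorings.
* Digitization jitter: survival coordinates that increase by at most
  ``MONOTONE_TOL`` (absolute) are clamped to a running minimum; larger
  violations raise :class:`CurveValidationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ipd import PseudoIPD

__all__ = [
    "MONOTONE_TOL",
    "CurveValidationError",
    "DigitizedCurve",
    "km_estimate",
    "reconstruct_ipd",
]

#: largest absolute upward wobble in digitized survival values that is treated
#: as graph-reading jitter and clamped rather than rejected
MONOTONE_TOL = 0.005


class CurveValidationError(ValueError):
    """A digitized curve violates a Kaplan-Meier invariant."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Step-function KM coordinates with a numbers-at-risk table.

    ``times``/``survival`` hold the digitized coordinates (months,
    probability); ``risk_times``/``n_at_risk`` the risk table; ``n_total`` the
    number of patients at time zero.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    n_total: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float).copy()
        rt = np.asarray(self.risk_times, dtype=float)
        nr = np.asarray(self.n_at_risk, dtype=int)
        if times.shape != surv.shape or times.ndim != 1:
            raise CurveValidationError("times and survival must be equal-length 1-d arrays")
        if rt.shape != nr.shape or rt.ndim != 1 or rt.size == 0:
            raise CurveValidationError("risk table must be a non-empty pair of 1-d arrays")
        if np.any(np.diff(times) <= 0):
            raise CurveValidationError("curve times must be strictly increasing")
        if np.any(np.diff(rt) <= 0):
            raise CurveValidationError("risk-table times must be strictly increasing")
        if surv.size and (surv[0] > 1.0 + 1e-12 or np.any(surv < -1e-12)):
            raise CurveValidationError("survival values must lie in [0, 1]")
        rises = np.diff(surv)
        bad = np.nonzero(rises > MONOTONE_TOL)[0]
        if bad.size:
            i = int(bad[0])
            raise CurveValidationError(
                f"survival increases by {rises[i]:.4f} between rows {i} and {i + 1} "
                f"(t={times[i]:.4g} -> {times[i + 1]:.4g}); exceeds jitter tolerance "
                f"{MONOTONE_TOL}"
            )
        # clamp sub-tolerance digitization jitter
        surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
        if np.any(np.diff(nr) > 0):
            j = int(np.nonzero(np.diff(nr) > 0)[0][0])
            raise CurveValidationError(
                f"numbers at risk increase between rows {j} and {j + 1}"
            )
        if nr[0] != self.n_total:
            raise CurveValidationError(
                f"first risk count {nr[0]} must equal n_total {self.n_total}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        object.__setattr__(self, "risk_times", rt)
        object.__setattr__(self, "n_at_risk", nr)

    def survival_at(self, t: float) -> float:
        """Step-function value at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame({"time": self.times, "survival": self.survival}),
            pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk}),
        )

    def to_csv(self, curve_path, risk_path) -> None:
        cf, rf = self.to_frames()
        cf.to_csv(curve_path, index=False)
        rf.to_csv(risk_path, index=False)

    @classmethod
    def from_csv(cls, curve_path, risk_path, label: str = "") -> "DigitizedCurve":
        cf = pd.read_csv(curve_path)
        rf = pd.read_csv(risk_path)
        return cls(
            cf["time"].to_numpy(float),
            cf["survival"].to_numpy(float),
            rf["time"].to_numpy(float),
            rf["n_at_risk"].to_numpy(int),
            n_total=int(rf["n_at_risk"].iloc[0]),
            label=label,
        )


# ---------------------------------------------------------------------------
# Kaplan-Meier estimation (product-limit)
# ---------------------------------------------------------------------------

def km_estimate(ipd: PseudoIPD, risk_times=None) -> DigitizedCurve:
    """Product-limit estimate of an IPD sample as a :class:`DigitizedCurve`.

    The curve carries one coordinate per distinct event time (plus the origin)
    and a risk table at ``risk_times`` (default: the origin and every event
    time).  Ties between events and censorings are resolved events-first.
    """
    if len(ipd) == 0:  # pragma: no cover - PseudoIPD forbids this
        raise ValueError("empty IPD")
    time, event = ipd.time, ipd.event
    order = np.lexsort((1 - event, time))  # time asc, events before censorings
    t_sorted, e_sorted = time[order], event[order]

    ev_times = np.unique(t_sorted[e_sorted == 1])
    s = 1.0
    times, surv = [0.0], [1.0]
    for te in ev_times:
        at_risk = int(np.sum(t_sorted >= te))
        d = int(np.sum((t_sorted == te) & (e_sorted == 1)))
        s *= 1.0 - d / at_risk
        times.append(float(te))
        surv.append(s)

    if risk_times is None:
        risk_times = np.asarray(times)
    risk_times = np.asarray(risk_times, dtype=float)
    n_at_risk = np.array([int(np.sum(t_sorted >= rt)) for rt in risk_times])
    return DigitizedCurve(
        np.asarray(times), np.asarray(surv), risk_times, n_at_risk,
        n_total=len(ipd), label=ipd.label,
    )


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``."""
    if total <= 0 or weights.sum() <= 0:
        return np.zeros_like(weights, dtype=int)
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        frac = quota - base
        top = np.argsort(-frac, kind="stable")[:rem]
        base[top] += 1
    return base


def reconstruct_ipd(curve: DigitizedCurve) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized KM curve and risk table.

    For each risk-table interval the number of censorings is iterated until
    the reconstructed number at risk at the interval end equals the published
    count; censor times are spread uniformly across the interval and event
    counts at each digitized step are solved from the relative survival drop.
    Patients still at risk after the last interval are censored at the last
    observed time.  The output always contains exactly ``n_total`` records.
    """
    rt, nr = curve.risk_times, curve.n_at_risk
    t_pts, s_pts = curve.times, curve.survival
    t_max = max(float(t_pts[-1]) if t_pts.size else 0.0, float(rt[-1]))

    events: list[tuple[float, int]] = []
    censors: list[tuple[float, int]] = []

    n_cur = int(nr[0])
    s_km = 1.0  # reconstructed KM level entering the interval

    bounds = list(zip(rt, list(rt[1:]) + [np.inf], list(nr[1:]) + [None]))
    for t_lo, t_hi, n_target in bounds:
        in_int = (t_pts >= t_lo) & (t_pts < t_hi) & (s_pts < s_km - 1e-12)
        step_t = t_pts[in_int]
        step_s = s_pts[in_int]
        K = step_t.size

        if n_target is None:
            # final interval: place events, censor the remainder at t_max
            n, s = n_cur, s_km
            for tk, sk in zip(step_t, step_s):
                if n <= 0:
                    break
                d = int(round(n * (1.0 - sk / s))) if s > 0 else 0
                d = min(max(d, 0), n)
                if d:
                    events.append((float(tk), d))
                    s *= 1.0 - d / n
                    n -= d
            if n > 0:
                censors.append((t_max, n))
                n = 0
            n_cur, s_km = n, s
            continue

        c_total = max(n_cur - int(n_target), 0) if K == 0 else 0
        lo_gap, hi_gap = t_lo, min(t_hi, t_max)
        for _ in range(200):
            # spread c_total censor times uniformly over the interval
            if c_total > 0:
                c_times = lo_gap + (np.arange(1, c_total + 1) - 0.5) * (
                    (hi_gap - lo_gap) / c_total
                )
            else:
                c_times = np.empty(0)
            n, s = n_cur, s_km
            d_counts = np.zeros(K, dtype=int)
            c_before = np.array(
                [np.sum(c_times < tk - 1e-12) for tk in step_t], dtype=int
            )
            used_c = 0
            for k, (tk, sk) in enumerate(zip(step_t, step_s)):
                drop_c = int(c_before[k]) - used_c
                drop_c = min(drop_c, n)
                n -= drop_c
                used_c += drop_c
                if n <= 0 or s <= 0:
                    break
                d = int(round(n * (1.0 - sk / s)))
                d = min(max(d, 0), n)
                d_counts[k] = d
                if d:
                    s *= 1.0 - d / n
                    n -= d
            n -= min(c_total - used_c, n)  # censors after the last step
            if n == n_target:
                break
            c_total = max(c_total + (n - int(n_target)), 0)
        # commit
        n, s = n_cur, s_km
        used_c = 0
        ci = 0
        for k, (tk, sk) in enumerate(zip(step_t, step_s)):
            while ci < c_times.size and c_times[ci] < tk - 1e-12 and n > 0:
                censors.append((float(c_times[ci]), 1))
                ci += 1
                n -= 1
            d = int(d_counts[k])
            d = min(d, n)
            if d:
                events.append((float(tk), d))
                s *= 1.0 - d / n
                n -= d
        while ci < c_times.size and n > n_target:
            censors.append((float(c_times[ci]), 1))
            ci += 1
            n -= 1
        if n > n_target:  # residual mismatch: censor at interval end
            censors.append((float(min(t_hi, t_max)), n - int(n_target)))
            n = int(n_target)
        n_cur, s_km = n, s

    times: list[float] = []
    flags: list[int] = []
    for t, d in events:
        times.extend([t] * d)
        flags.extend([1] * d)
    for t, c in censors:
        times.extend([t] * c)
        flags.extend([0] * c)
    short = curve.n_total - len(times)
    if short > 0:  # conservation guard (should not trigger)
        times.extend([t_max] * short)
        flags.extend([0] * short)
    order = np.lexsort((1 - np.asarray(flags), np.asarray(times)))
    return PseudoIPD(
        np.asarray(times, float)[order], np.asarray(flags, int)[order],
        label=curve.label,
    )
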