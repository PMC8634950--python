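"""Pseudo individual-patient data (IPD) containers.

Reconstructed or simulated survival records are held as parallel arrays of
observation times (months) and event indicators (1 = event, 0 = right
censored).  CSV round-trips use the two-column ``time,event`` schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PseudoIPD"]


@dataclass(frozen=True)
class PseudoIPD:
    """Right-censored survival records with times in months."""

    time: np.ndarray
    event: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if time.size == 0:
            raise ValueError("PseudoIPD requires at least one record")
        if np.any(~np.isfinite(time)) or np.any(time < 0):
            raise ValueError("times must be finite and non-negative")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "PseudoIPD":
        df = pd.read_csv(path)
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"IPD CSV missing columns: {sorted(missing)}")
        return cls(df["time"].to_numpy(float), df["event"].to_numpy(int), label=label)
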