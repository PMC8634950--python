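"""Standard figures: tornado diagram, incremental-CE scatter, CEAC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_tornado", "plot_scatter", "plot_ceac"]


def plot_tornado(owsa: pd.DataFrame, base_icer: float, path, top: int = 15) -> None:
    df = owsa.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(df) + 1.5))
    y = np.arange(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted((row["low_icer"], row["high_icer"]))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label=f"base ICER {base_icer:,.0f}")
    ax.set_yticks(y)
    ax.set_yticklabels(df["parameter"])
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(psa, wtp: float, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.25, color="#4878d0")
    q = np.linspace(min(0, psa.delta_qaly.min()), psa.delta_qaly.max() * 1.05, 50)
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP {wtp:,.0f} $/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost ($)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac_df: pd.DataFrame, path, thresholds=()) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_df["wtp"], ceac_df["probability"], "-o", ms=3, color="#4878d0")
    for w in thresholds:
        ax.axvline(w, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
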