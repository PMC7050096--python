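"""Optional figure export: tornado diagram, CE plane, acceptability curves.

All functions write an image file and return the path; they are thin
matplotlib wrappers and deliberately unstyled.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .sensitivity import PsaResult  # noqa: E402

__all__ = ["plot_tornado", "plot_ce_plane", "plot_ceac"]


def plot_tornado(tornado: pd.DataFrame, path: str | Path, top: int = 12) -> Path:
    """Horizontal bars of ICER at each parameter's low/high bound."""
    df = tornado.dropna(subset=["icer_low", "icer_high"]).head(top).iloc[::-1]
    base = df[["icer_low", "icer_high"]].mean(axis=1).median()
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted((row["icer_low"], row["icer_high"]))
        ax.barh(i, hi - lo, left=lo, height=0.6)
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.axvline(base, color="k", lw=0.8, ls="--")
    ax.set_xlabel("ICER (USD/QALY)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_ce_plane(psa: PsaResult, reference: str, path: str | Path) -> Path:
    """Incremental cost vs incremental QALYs of each draw vs a reference."""
    cost, qaly = psa.pivot()
    fig, ax = plt.subplots(figsize=(6, 5))
    for name in cost.columns:
        if name == reference:
            continue
        ax.scatter(qaly[name] - qaly[reference], cost[name] - cost[reference],
                   s=6, alpha=0.4, label=name)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_ceac(curves: pd.DataFrame, path: str | Path,
              wtp_marker: float | None = None) -> Path:
    """Probability cost-effective vs willingness to pay, per strategy."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in curves.columns:
        ax.plot(curves.index / 1000.0, curves[name], label=name)
    if wtp_marker is not None:
        ax.axvline(wtp_marker / 1000.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("willingness to pay (thousand USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
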