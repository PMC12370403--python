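"""Figure analogues: per-bin DRL bars, CBT distribution, step-vs-curve overlay.

Plots are artifacts for human inspection, not analysis surfaces; all return
the matplotlib figure and optionally save to a path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def binned_drl_bars(binned, path: str | Path | None = None):
    """Bar chart of the per-10-mm-bin DRLs for one view."""
    rows = binned.nonempty_rows()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(
        [f"{int(r.lo)}-{int(r.hi)}" for r in rows],
        [r.drl for r in rows],
        color="steelblue",
    )
    ax.set_xlabel("CBT range [mm]")
    ax.set_ylabel("DRL [mGy]")
    ax.set_title(f"DRL per CBT range — {binned.view}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def cbt_histogram(table, modal_window: tuple[int, int] | None = None, path=None):
    """CBT distribution with the modal 10-mm window annotated."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(table.df["cbt"].dropna(), bins=40, color="gray", edgecolor="white")
    if modal_window:
        center, count = modal_window
        ax.axvspan(center - 5, center + 5, color="orange", alpha=0.3)
        ax.annotate(
            f"modal window {center}±5 mm (n={count})",
            xy=(center, ax.get_ylim()[1] * 0.9),
            ha="center",
        )
    ax.set_xlabel("CBT [mm]")
    ax.set_ylabel("records")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def step_vs_curve(binned, curve, path=None, limits=None):
    """Overlay of the 10-mm-range step DRL and the continuous DRL curve."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for r in binned.nonempty_rows():
        ax.hlines(r.drl, r.lo, r.hi, colors="steelblue", lw=2)
    grid = np.linspace(curve.domain[0], curve.domain[1], 200)
    ax.plot(grid, curve.evaluate(grid), "k-", label="equation approach")
    if limits is not None:
        for arr, lab, style in (
            (limits.acceptable, "acceptable limit", "r--"),
            (limits.achievable, "achievable limit", "g--"),
        ):
            ax.plot(arr[:, 0], arr[:, 1], style, label=lab)
    ax.hlines([], [], [], colors="steelblue", label="10-mm range approach")
    ax.set_xlabel("CBT [mm]")
    ax.set_ylabel("DRL [mGy]")
    ax.set_title(f"DRL approaches — {curve.view}")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
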