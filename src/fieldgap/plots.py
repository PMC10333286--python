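"""Headless-safe figures for the persistence, driver and scenario results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — never require a display
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_decile_boxes",
    "plot_importance",
    "plot_pdp",
    "plot_scenarios",
]


def plot_decile_boxes(decile_table: pd.DataFrame, path=None):
    """Boxplot-style summary of later-year yields per base-year decile."""
    fig, ax = plt.subplots(figsize=(7, 4))
    stats = [
        {
            "label": str(int(r.decile)),
            "whislo": r.min,
            "q1": r.q1,
            "med": r.median,
            "q3": r.q3,
            "whishi": r.max,
            "fliers": [],
        }
        for r in decile_table.itertuples()
    ]
    ax.bxp(stats, showfliers=False)
    ax.set_xlabel("base-year yield decile (1 = lowest)")
    ax.set_ylabel("later-year yield (kg/ha)")
    return _finish(fig, path)


def plot_importance(importance: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    imp = importance.sort_values("pct_inc_mse")
    ax.barh(imp["predictor"], imp["pct_inc_mse"], color="tab:green")
    ax.set_xlabel("%IncMSE (permutation importance)")
    return _finish(fig, path)


def plot_pdp(curves, path=None):
    """One panel per partial-dependence curve."""
    curves = list(curves)
    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2), squeeze=False)
    for ax, c in zip(axes[0], curves):
        ax.plot(c.grid, c.values, marker="o", ms=3)
        ax.set_xlabel(c.predictor)
        ax.set_ylabel("predicted yield gap (kg/ha)")
    fig.tight_layout()
    return _finish(fig, path)


def plot_scenarios(summary: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(summary))
    ax.bar(x, summary["mean_gain_kgha"], color="tab:orange")
    ax.set_xticks(x, summary["scenario"])
    ax.set_ylabel("mean yield gain (kg/ha)")
    for xi, (g, c) in enumerate(zip(summary["mean_gain_kgha"], summary["closure_percent"])):
        ax.annotate(f"{c:.0f}%", (xi, g), ha="center", va="bottom")
    return _finish(fig, path)


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
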