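"""Figure analogues: overlap/balance across windows, the OWRD series per
threshold, and individual predicted risk-difference distributions."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_overlap_balance(balance: pd.DataFrame, path=None):
    """Two panels: ESS per window per threshold (top) and median weighted SMD
    (bottom) with dashed reference lines at 0.10 and 0.20."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 7), sharex=True)
    for t, g in balance.groupby("threshold"):
        g = g.sort_values("window")
        ax1.plot(g["window_label"], g["ess"], marker="o", label=f">={t:g} mg/3d")
        ax2.plot(g["window_label"], g["median_smd"], marker="o", linestyle="",
                 label=f">={t:g} mg/3d")
    ax1.set_ylabel("effective sample size")
    ax1.legend(fontsize=8)
    ax2.axhline(0.10, linestyle="--", color="grey")
    ax2.axhline(0.20, linestyle="--", color="grey")
    ax2.set_ylabel("median |SMD| (weighted)")
    ax2.set_xlabel("window (days from ARDS onset)")
    plt.setp(ax2.get_xticklabels(), rotation=45)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_owrd_series(results: pd.DataFrame, path=None, smoother: bool = False):
    """Window-specific risk differences with 95% CI ribbons, one facet per
    threshold; optional cosmetic moving-average smoother."""
    res = results[(results["status"] == "ok") & (results["estimand"] == "owrd")]
    thresholds = sorted(res["threshold"].unique())
    fig, axes = plt.subplots(1, max(len(thresholds), 1), figsize=(4 * max(len(thresholds), 1), 4),
                             sharey=True, squeeze=False)
    for ax, t in zip(axes[0], thresholds):
        g = res[res["threshold"] == t].sort_values("window")
        x = g["window"].to_numpy()
        ax.fill_between(x, g["ci_low"], g["ci_high"], alpha=0.25)
        ax.plot(x, g["estimate"], marker="o")
        if smoother and len(g) >= 3:
            sm = g["estimate"].rolling(3, center=True, min_periods=1).mean()
            ax.plot(x, sm, linestyle=":", color="black")
        ax.axhline(0.0, linestyle="--", color="grey")
        ax.set_title(f">={t:g} mg/3d PE")
        ax.set_xticks(x)
        ax.set_xticklabels(g["window_label"], rotation=45, fontsize=7)
        ax.set_xlabel("window")
    axes[0][0].set_ylabel("risk difference (OWRD)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_individual_rd(individual: dict, path=None):
    """Distributions of individualised predicted risk differences per
    window x threshold (violin-style summaries)."""
    keys = sorted(individual, key=lambda k: (k[1], k[0]))
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(keys)), 4))
    data = [np.asarray(individual[k]) for k in keys]
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(keys) + 1))
        ax.set_xticklabels([f"{w}@{t:g}" for w, t in keys], rotation=90, fontsize=6)
    ax.axhline(0.0, linestyle="--", color="grey")
    ax.set_ylabel("predicted m1(x) - m0(x)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
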