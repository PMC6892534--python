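"""Figures: z-score profiles and fitted-versus-observed group trajectories."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

AGES = np.array([0.0, 1.0, 2.0])
_STYLES = {"diabetic": dict(ls=":", marker="o"), "non_diabetic": dict(ls="--", marker="^")}


def _cell(summary: pd.DataFrame, scen: str, method: str, param: str):
    row = summary[
        (summary["scenario"] == scen)
        & (summary["method"] == method)
        & (summary["parameter"] == param)
    ].iloc[0]
    return row["mean"], row["centile_2_5"], row["centile_97_5"]


def plot_zscore_profiles(summary: pd.DataFrame, path) -> Path:
    """Mean weight z-scores by age and outcome group, with empirical 95% CIs."""
    scens = sorted(summary["scenario"].unique())
    fig, axes = plt.subplots(1, len(scens), figsize=(4 * len(scens), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, scen in zip(axes, scens):
        for grp, style in _STYLES.items():
            means, los, his = zip(
                *[_cell(summary, scen, "zscore", f"z_age{a}_{grp}") for a in range(3)]
            )
            err = np.vstack([np.subtract(means, los), np.subtract(his, means)])
            ax.errorbar(AGES, means, yerr=err, capsize=3,
                        label=grp.replace("_", "-"), **style)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(f"Scenario {scen}")
        ax.set_xlabel("age (years)")
        ax.set_xticks(AGES)
    axes[0].set_ylabel("mean weight z-score")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_fitted_lines(summary: pd.DataFrame, path) -> Path:
    """Model-fitted group lines (outcome-covariate mixed model) overlaid with
    observed group mean weights, per scenario."""
    scens = sorted(summary["scenario"].unique())
    t = AGES - 1.0  # age centred at 1 year
    fig, axes = plt.subplots(1, len(scens), figsize=(4 * len(scens), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, scen in zip(axes, scens):
        b0, *_ = _cell(summary, scen, "outcome_covariate", "intercept")
        b1, *_ = _cell(summary, scen, "outcome_covariate", "time")
        b2, *_ = _cell(summary, scen, "outcome_covariate", "diabetes")
        b3, *_ = _cell(summary, scen, "outcome_covariate", "time:diabetes")
        for grp, d in (("non_diabetic", 0.0), ("diabetic", 1.0)):
            fitted = b0 + b1 * t + b2 * d + b3 * t * d
            obs = [
                _cell(summary, scen, "moments", f"mean_weight_{a}_{grp}")[0]
                for a in range(3)
            ]
            style = _STYLES[grp]
            ax.plot(AGES, fitted, ls=style["ls"], label=f"fitted {grp.replace('_', '-')}")
            ax.plot(AGES, obs, style["marker"], mfc="none")
        ax.set_title(f"Scenario {scen}")
        ax.set_xlabel("age (years)")
        ax.set_xticks(AGES)
    axes[0].set_ylabel("weight (kg)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
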