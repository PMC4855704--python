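"""Plots of the grid analyses (CI grid, precision curves, decile shapes)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns


def plot_ci_grid(summaries: pd.DataFrame, path: str | Path) -> Path:
    """Mean cut-score with 95 % CI by judges, faceted by items and round."""
    g = sns.FacetGrid(
        summaries, col="n_items", hue="round", col_wrap=4, height=2.2,
        sharey=True,
    )

    def _panel(data, color=None, **kw):
        ax = plt.gca()
        off = {1: -0.6, 2: 0.6}[data["round"].iloc[0]]
        ax.errorbar(
            data["n_judges"] + off,
            data["mean_score"],
            yerr=[
                data["mean_score"] - data["ci_low"],
                data["ci_high"] - data["mean_score"],
            ],
            fmt="o", ms=3, capsize=2, color=color,
        )
        ax.axhline(0.0, lw=0.6, color="grey")

    g.map_dataframe(_panel)
    g.add_legend(title="round")
    g.set_axis_labels("judges", "mean cut-score (95% CI)")
    g.savefig(path, dpi=120)
    plt.close(g.figure)
    return Path(path)


def plot_precision_curves(curves: pd.DataFrame, path: str | Path) -> Path:
    """Mean |cut-score| vs number of judges, one line per test length."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, rnd in zip(axes, (1, 2)):
        sub = curves[curves["round"] == rnd]
        sns.lineplot(
            data=sub, x="n_judges", y="mean_abs_score", hue="n_items",
            marker="o", palette="viridis", ax=ax, legend=(rnd == 2),
        )
        ax.set_title(f"round {rnd}")
        ax.set_xlabel("judges")
        ax.set_ylabel("mean |cut-score|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_decile_curves(
    decile_tables: Iterable[pd.DataFrame], path: str | Path
) -> Path:
    """Mean |cut-score| per attribute decile, one panel per attribute."""
    tables = list(decile_tables)
    fig, axes = plt.subplots(
        1, len(tables), figsize=(3.2 * len(tables), 3.2), sharey=True
    )
    if len(tables) == 1:
        axes = [axes]
    for ax, dt in zip(axes, tables):
        ax.errorbar(
            dt["decile"], dt["mean_abs_score"], yerr=dt["se_abs_score"],
            fmt="o-", ms=4, capsize=2,
        )
        ax.set_title(dt["attribute"].iloc[0])
        ax.set_xlabel("decile")
    axes[0].set_ylabel("mean |cut-score|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
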