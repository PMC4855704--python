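"""Statistical analysis of a grid results table.

Reproduces the downstream statistics of the simulation study from the
long-format panel table: per-combination means with Student-t 95 % CIs,
precision curves, attribute-decile tables (with a stringency-by-accuracy
cross-tabulation for the interaction), the paired round-1 vs round-2
comparison, and partial correlations controlling for panel size and test
length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import validate_results

__all__ = [
    "ATTRIBUTE_COLUMNS",
    "RoundComparison",
    "PartialCorrelation",
    "combo_summary",
    "precision_curves",
    "decile_analysis",
    "stringency_accuracy_crosstab",
    "paired_round_comparison",
    "partial_correlation",
    "attribute_score_correlations",
    "build_report",
]

logger = logging.getLogger(__name__)

ATTRIBUTE_COLUMNS = ("mean_accuracy", "mean_stringency", "mean_leadership")
DEFAULT_COVARIATES = ("n_judges", "n_items")


@dataclass(frozen=True)
class RoundComparison:
    """Paired comparison of absolute cut-scores from the two rounds.

    ``cohens_d`` is mean(diff)/sd(diff) with diff = |score1| − |score2|:
    negative when the second round deviates more from the true cut-score
    (i.e. is less precise) than the first.
    """

    mean_abs_round1: float
    mean_abs_round2: float
    t_statistic: float
    p_value: float
    cohens_d: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PartialCorrelation:
    """Pearson correlation of two variables after removing covariates.

    Both variables are residualised on an intercept plus the covariates by
    least squares; r is the Pearson correlation of the residuals and the
    p-value comes from the t distribution with df = n − 2 − #covariates.
    """

    x: str
    y: str
    covariates: tuple[str, ...]
    r: float
    p_value: float
    n: int

    @property
    def variance_explained(self) -> float:
        return self.r ** 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["variance_explained"] = self.variance_explained
        return d


def _score_column(round: int, absolute: bool = False) -> str:
    if round not in (1, 2):
        raise ValueError("round must be 1 or 2")
    return f"{'abs_' if absolute else ''}score{round}"


def combo_summary(table: pd.DataFrame, round: int = 1) -> pd.DataFrame:
    """Per-combination mean cut-score with a Student-t 95 % CI.

    One row per (n_judges, n_items) combination.  The CI uses the t
    critical value with df = n_panels − 1 on the per-panel cut-scores; for
    a combination with a single panel the CI is undefined (NaN) and a
    warning is logged.
    """
    col = _score_column(round)
    abs_col = _score_column(round, absolute=True)
    rows = []
    for (nj, ni), grp in table.groupby(["n_judges", "n_items"], sort=True):
        scores = grp[col].to_numpy()
        n = scores.size
        mean = scores.mean()
        if n > 1:
            sd = scores.std(ddof=1)
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            sd, lo, hi = np.nan, np.nan, np.nan
            logger.warning(
                "combination (%d judges, %d items) has a single panel; "
                "CI undefined", nj, ni,
            )
        rows.append(
            (nj, ni, round, mean, lo, hi, grp[abs_col].mean(), sd, n)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "n_judges", "n_items", "round", "mean_score",
            "ci_low", "ci_high", "mean_abs_score", "sd_score", "n_panels",
        ],
    )


def precision_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute cut-score by (n_items, n_judges) for both rounds.

    The precision curves show how adding judges sharpens the cut-score for
    each test length; sorted by (n_items, n_judges).
    """
    parts = []
    for rnd in (1, 2):
        agg = (
            table.groupby(["n_items", "n_judges"], sort=True)[
                _score_column(rnd, absolute=True)
            ]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )
        agg.insert(2, "round", rnd)
        agg = agg.rename(
            columns={"mean": "mean_abs_score", "sem": "se", "count": "n_panels"}
        )
        parts.append(agg)
    return pd.concat(parts, ignore_index=True)


def _rank_groups(table: pd.DataFrame, attribute: str, n_groups: int) -> np.ndarray:
    """Assign 1..n_groups by ranking on the attribute with a stable sort.

    Group sizes are as equal as possible (exactly equal when the row count
    divides evenly, e.g. 4900 panels → 10 deciles of 490).
    """
    order = np.argsort(table[attribute].to_numpy(), kind="stable")
    sizes = np.full(n_groups, len(table) // n_groups)
    sizes[: len(table) % n_groups] += 1
    labels = np.empty(len(table), dtype=int)
    labels[order] = np.repeat(np.arange(1, n_groups + 1), sizes)
    return labels


def decile_analysis(
    table: pd.DataFrame,
    attribute: str,
    n_deciles: int = 10,
    round: int = 1,
) -> pd.DataFrame:
    """Rank panels by a panel-mean attribute and summarise precision per decile.

    Panels are sorted by the attribute and split into ``n_deciles`` equal
    groups (490 panels each on the default grid); each group reports its
    mean attribute value and mean absolute cut-score, exposing non-linear
    attribute–precision associations (e.g. the stringency U-shape).
    """
    if attribute not in ATTRIBUTE_COLUMNS:
        raise ValueError(
            f"attribute must be one of {ATTRIBUTE_COLUMNS}, got {attribute!r}"
        )
    abs_col = _score_column(round, absolute=True)
    work = table.copy()
    work["decile"] = _rank_groups(work, attribute, n_deciles)
    out = (
        work.groupby("decile", sort=True)
        .agg(
            n_panels=(attribute, "size"),
            mean_attribute=(attribute, "mean"),
            mean_abs_score=(abs_col, "mean"),
            se_abs_score=(abs_col, "sem"),
        )
        .reset_index()
    )
    out.insert(0, "attribute", attribute)
    return out


def stringency_accuracy_crosstab(
    table: pd.DataFrame,
    n_stringency_bins: int = 10,
    n_accuracy_bins: int = 3,
    round: int = 1,
) -> pd.DataFrame:
    """Stringency deciles × accuracy tertiles interaction table.

    Each cell holds the mean absolute cut-score of the panels falling in
    that (stringency decile, accuracy tertile) cell, exposing whether
    expertise matters once panels are neither too stringent nor too
    lenient.
    """
    abs_col = _score_column(round, absolute=True)
    work = table.copy()
    work["stringency_bin"] = _rank_groups(work, "mean_stringency", n_stringency_bins)
    work["accuracy_bin"] = _rank_groups(work, "mean_accuracy", n_accuracy_bins)
    out = (
        work.groupby(["stringency_bin", "accuracy_bin"], sort=True)
        .agg(
            n_panels=(abs_col, "size"),
            mean_abs_score=(abs_col, "mean"),
        )
        .reset_index()
    )
    return out


def paired_round_comparison(table: pd.DataFrame) -> RoundComparison:
    """Paired t-test between absolute round-1 and round-2 cut-scores."""
    a1 = table["abs_score1"].to_numpy()
    a2 = table["abs_score2"].to_numpy()
    diff = a1 - a2
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return RoundComparison(
                mean_abs_round1=float(a1.mean()),
                mean_abs_round2=float(a2.mean()),
                t_statistic=0.0,
                p_value=1.0,
                cohens_d=0.0,
                n=len(diff),
            )
        raise ValueError("paired differences have zero variance but non-zero mean")
    t_stat, p = stats.ttest_rel(a1, a2)
    return RoundComparison(
        mean_abs_round1=float(a1.mean()),
        mean_abs_round2=float(a2.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        cohens_d=float(diff.mean() / sd),
        n=len(diff),
    )


def partial_correlation(
    table: pd.DataFrame,
    x: str,
    y: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> PartialCorrelation:
    """Partial Pearson correlation of x and y controlling for covariates.

    Residualises both variables on an intercept plus the covariates by
    ordinary least squares and correlates the residuals.  With an empty
    covariate list this reduces exactly to the plain Pearson correlation.
    """
    covariates = tuple(covariates)
    for col in (x, y, *covariates):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    n = len(table)
    if n <= len(covariates) + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack(
        [np.ones(n)] + [table[c].to_numpy(dtype=float) for c in covariates]
    )

    def _residualize(col: str) -> np.ndarray:
        v = table[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = _residualize(x), _residualize(y)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - len(covariates)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t_stat = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t_stat), df))
    return PartialCorrelation(
        x=x, y=y, covariates=covariates, r=r, p_value=p, n=n
    )


def attribute_score_correlations(
    table: pd.DataFrame,
    score_column: str = "score1",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> list[PartialCorrelation]:
    """Partial correlations of each panel-mean attribute with the cut-score."""
    return [
        partial_correlation(table, attr, score_column, covariates)
        for attr in ATTRIBUTE_COLUMNS
    ]


def build_report(
    table: pd.DataFrame,
    out_dir: str | Path,
    round: int = 1,
    crosstab_bins: tuple[int, int] = (10, 3),
    plots: bool = True,
) -> dict:
    """Run every analysis and write CSV/JSON (and optionally plot) artifacts.

    Returns the report dictionary that is also serialised to
    ``report.json``.  Deterministic given the input table.  Decile and
    cross-tab analyses are skipped, with a logged warning, when the table
    is too small to split meaningfully (fewer than 20 panels).
    """
    table = validate_results(table)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summaries = pd.concat(
        [combo_summary(table, r) for r in (1, 2)], ignore_index=True
    )
    summaries.to_csv(out / "combo_summary.csv", index=False)

    curves = precision_curves(table)
    curves.to_csv(out / "precision_curves.csv", index=False)

    decile_tables = {}
    crosstab = None
    if len(table) >= 20:
        for attr in ATTRIBUTE_COLUMNS:
            dt = decile_analysis(table, attr, round=round)
            dt.to_csv(out / f"deciles_{attr}.csv", index=False)
            decile_tables[attr] = dt
        crosstab = stringency_accuracy_crosstab(
            table, *crosstab_bins, round=round
        )
        crosstab.to_csv(out / "stringency_accuracy_crosstab.csv", index=False)
    else:
        logger.warning(
            "table has %d panels; decile and cross-tab analyses skipped",
            len(table),
        )

    comparison = paired_round_comparison(table)
    with open(out / "round_comparison.json", "w") as fh:
        json.dump(comparison.to_dict(), fh, indent=2)

    agreement = partial_correlation(
        table, "within_panel_sd", _score_column(round, absolute=True)
    )
    attr_corrs = attribute_score_correlations(table, _score_column(round))
    corr_df = pd.DataFrame(
        [c.to_dict() for c in [agreement, *attr_corrs]]
    )
    corr_df["covariates"] = corr_df["covariates"].map("+".join)
    corr_df.to_csv(out / "partial_correlations.csv", index=False)

    if plots:
        from . import plotting

        plotting.plot_ci_grid(summaries, out / "fig_combo_ci.png")
        plotting.plot_precision_curves(curves, out / "fig_precision.png")
        if decile_tables:
            plotting.plot_decile_curves(
                decile_tables.values(), out / "fig_deciles.png"
            )

    report = {
        "n_panels": int(len(table)),
        "n_combinations": int(
            table.groupby(["n_judges", "n_items"]).ngroups
        ),
        "round_comparison": comparison.to_dict(),
        "agreement_precision": agreement.to_dict(),
        "attribute_correlations": [c.to_dict() for c in attr_corrs],
        "mean_abs_score1": float(table["abs_score1"].mean()),
        "mean_abs_score2": float(table["abs_score2"].mean()),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
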