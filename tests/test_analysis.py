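"""Downstream statistics: CIs, deciles, paired rounds, partial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from angoffsim import analysis
from angoffsim.analysis import (
    combo_summary,
    decile_analysis,
    paired_round_comparison,
    partial_correlation,
    precision_curves,
    stringency_accuracy_crosstab,
)

from conftest import make_table


def _table_from_scores(scores, n_judges=5, n_items=10):
    scores = np.asarray(scores, dtype=float)
    df = pd.DataFrame(
        {
            "n_judges": n_judges,
            "n_items": n_items,
            "replicate_id": np.arange(len(scores)),
            "seed": 0,
            "score1": scores,
            "score2": scores,
            "abs_score1": np.abs(scores),
            "abs_score2": np.abs(scores),
            "within_panel_sd": 0.3,
            "mean_accuracy": 0.8,
            "mean_stringency": 0.0,
            "mean_leadership": 0.0,
        }
    )
    return df


class TestComboSummary:
    def test_zero_variance_ci_collapses(self):
        out = combo_summary(_table_from_scores(np.full(100, 0.25)))
        row = out.iloc[0]
        assert row.mean_score == row.ci_low == row.ci_high == pytest.approx(0.25)

    def test_symmetric_scores_give_symmetric_ci(self):
        out = combo_summary(_table_from_scores([-1.0, 1.0]))
        row = out.iloc[0]
        assert row.mean_score == pytest.approx(0.0)
        assert row.ci_low == pytest.approx(-row.ci_high)

    def test_matches_hand_computed_t_interval(self, rng):
        scores = rng.standard_normal(100)
        out = combo_summary(_table_from_scores(scores)).iloc[0]
        crit = 1.9842  # t_{0.975, 99}
        half = crit * scores.std(ddof=1) / 10
        assert out.ci_low == pytest.approx(scores.mean() - half, abs=1e-4)
        assert out.ci_high == pytest.approx(scores.mean() + half, abs=1e-4)
        assert out.ci_low <= out.mean_score <= out.ci_high

    def test_single_panel_has_undefined_ci(self, caplog):
        out = combo_summary(_table_from_scores([0.1]))
        assert np.isnan(out.iloc[0].ci_low)


class TestPrecisionCurves:
    def test_single_combination(self):
        table = _table_from_scores([0.1, -0.3])
        out = precision_curves(table)
        r1 = out[out["round"] == 1]
        assert len(r1) == 1
        assert r1.iloc[0].mean_abs_score == pytest.approx(0.2)

    def test_all_zero_scores(self):
        out = precision_curves(_table_from_scores(np.zeros(10)))
        assert (out.mean_abs_score == 0).all()


class TestDeciles:
    def test_equal_groups_in_attribute_order(self, rng):
        table = make_table(20, rng)
        table["mean_stringency"] = np.arange(20.0)
        out = decile_analysis(table, "mean_stringency")
        assert (out.n_panels == 2).all()
        assert out.mean_attribute.is_monotonic_increasing
        assert out.n_panels.sum() == len(table)

    def test_monotone_score_yields_u_shape(self, rng):
        table = make_table(100, rng)
        table["mean_stringency"] = rng.normal(size=100)
        table["abs_score1"] = np.abs(table["mean_stringency"])
        out = decile_analysis(table, "mean_stringency")
        extremes = out[out.decile.isin([1, 10])].mean_abs_score.mean()
        middles = out[out.decile.isin([5, 6])].mean_abs_score.mean()
        assert extremes > middles

    def test_unknown_attribute_rejected(self, small_table):
        with pytest.raises(ValueError):
            decile_analysis(small_table, "n_judges")

    def test_crosstab_marginals_partition_table(self, rng):
        table = make_table(60, rng)
        out = stringency_accuracy_crosstab(table, 10, 3)
        assert out.n_panels.sum() == 60
        marg = out.groupby("stringency_bin").n_panels.sum()
        assert (marg == 6).all()


class TestPairedRounds:
    def test_identical_rounds(self):
        table = _table_from_scores([0.1, -0.2, 0.3])
        out = paired_round_comparison(table)
        assert out.t_statistic == 0.0
        assert out.cohens_d == 0.0
        assert out.p_value == 1.0

    def test_forced_arithmetic(self):
        table = _table_from_scores([1.0, 2.0, 3.0])
        table["abs_score2"] = 0.0  # diffs are {1, 2, 3}
        out = paired_round_comparison(table)
        assert out.cohens_d == pytest.approx(2.0)
        assert out.mean_abs_round1 - out.mean_abs_round2 == pytest.approx(2.0)

    def test_sign_convention(self, rng):
        """d < 0 exactly when round 2 deviates more than round 1."""
        table = make_table(200, rng)
        table["abs_score2"] = table["abs_score1"] + np.abs(rng.normal(size=200)) * 0.01
        out = paired_round_comparison(table)
        assert out.mean_abs_round1 < out.mean_abs_round2
        assert out.cohens_d < 0
        # scipy's paired t equals d * sqrt(n)
        assert out.t_statistic == pytest.approx(out.cohens_d * np.sqrt(out.n))


class TestPartialCorrelation:
    def test_perfect_correlation_with_constant_covariate(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4], "c": 1.0})
        out = partial_correlation(df, "x", "y", covariates=["c"])
        assert out.r == pytest.approx(1.0)

    def test_null_case(self, rng):
        n = 10_000
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "n_judges": rng.integers(5, 80, n),
                "n_items": rng.integers(5, 80, n),
            }
        )
        out = partial_correlation(df, "x", "y")
        assert abs(out.r) < 3 / np.sqrt(n)

    def test_matches_textbook_recursion(self, rng):
        """Two-covariate partialling equals the iterated closed-form recursion."""
        n = 6
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["x", "y", "z1", "z2"])

        def pearson(a, b):
            return np.corrcoef(df[a], df[b])[0, 1] if isinstance(a, str) else None

        def partial_r(rxy, rxz, ryz):
            return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))

        # first remove z1 from every pair, then remove z2.z1
        r = {p: np.corrcoef(df[p[0]], df[p[1]])[0, 1]
             for p in [("x", "y"), ("x", "z1"), ("y", "z1"),
                       ("x", "z2"), ("y", "z2"), ("z1", "z2")]}
        rxy_1 = partial_r(r[("x", "y")], r[("x", "z1")], r[("y", "z1")])
        rxz2_1 = partial_r(r[("x", "z2")], r[("x", "z1")], r[("z1", "z2")])
        ryz2_1 = partial_r(r[("y", "z2")], r[("y", "z1")], r[("z1", "z2")])
        expected = partial_r(rxy_1, rxz2_1, ryz2_1)

        out = partial_correlation(df, "x", "y", covariates=["z1", "z2"])
        assert out.r == pytest.approx(expected, rel=1e-9)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 200
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["x", "y", "a", "b"])
        df["y"] += 0.5 * df["x"] + 0.3 * df["a"]
        out = partial_correlation(df, "x", "y", covariates=["a", "b"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert out.r == pytest.approx(ref["r"].iloc[0], abs=1e-10)
        assert out.p_value == pytest.approx(ref["p_val"].iloc[0], abs=1e-8)

    def test_no_covariates_reduces_to_pearson(self, rng):
        n = 50
        df = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x", "y"])
        out = partial_correlation(df, "x", "y", covariates=[])
        r_ref, p_ref = stats.pearsonr(df["x"], df["y"])
        assert out.r == pytest.approx(r_ref, abs=1e-12)
        assert out.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_variance_explained_is_r_squared(self, small_table):
        out = partial_correlation(small_table, "within_panel_sd", "abs_score1")
        assert out.variance_explained == out.r**2

    def test_error_cases(self, small_table):
        with pytest.raises(KeyError):
            partial_correlation(small_table, "nope", "score1")
        with pytest.raises(ValueError):
            partial_correlation(small_table.head(4), "score1", "score2")
        const = small_table.copy()
        const["score1"] = 1.0
        with pytest.raises(ValueError, match="constant residuals"):
            partial_correlation(const, "score1", "score2", covariates=[])


class TestAttributeCorrelations:
    def test_constructed_dependence(self, rng):
        table = make_table(500, rng)
        table["score1"] = table["mean_stringency"]
        out = analysis.attribute_score_correlations(table)
        by_name = {c.x: c for c in out}
        assert by_name["mean_stringency"].r == pytest.approx(1.0, abs=1e-9)
        assert abs(by_name["mean_leadership"].r) < 0.2


class TestBuildReport:
    def test_report_counts_and_determinism(self, tmp_path, small_table):
        rep1 = analysis.build_report(small_table, tmp_path / "a", plots=False)
        rep2 = analysis.build_report(small_table, tmp_path / "b", plots=False)
        assert rep1 == rep2
        assert (tmp_path / "a" / "combo_summary.csv").read_bytes() == (
            tmp_path / "b" / "combo_summary.csv"
        ).read_bytes()
        assert rep1["n_panels"] == len(small_table)

    def test_small_table_skips_deciles(self, tmp_path, rng, caplog):
        import logging

        table = make_table(10, rng)
        with caplog.at_level(logging.WARNING):
            analysis.build_report(table, tmp_path, plots=False)
        assert not (tmp_path / "deciles_mean_stringency.csv").exists()
        assert any("skipped" in r.message for r in caplog.records)
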