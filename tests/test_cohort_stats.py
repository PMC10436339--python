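"""Cohort statistical battery: summaries, correlations, t-tests, screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ohp.cohort_stats import (
    ConstantInputError,
    bonferroni,
    item_summaries,
    item_total_correlations,
    mean_sd_correlation,
    screen_items,
    self_smell_correlations,
    sex_comparison,
    spearman_rho,
)
from ohp.io import attach_scores, item_column
from ohp.synthetic_data import CohortSpec, generate_cohort

from conftest import cohort_frame, random_halfstep_matrix


@pytest.fixture(scope="module")
def default_cohort() -> pd.DataFrame:
    return attach_scores(generate_cohort(CohortSpec(n=100, seed=77)))


class TestItemSummaries:
    def test_closed_form_two_respondents(self):
        rows = [[1.0] + [0.0] * 13, [3.0] + [0.0] * 13]
        s = item_summaries(cohort_frame(rows))
        assert s.loc[0, "mean"] == pytest.approx(2.0)
        assert s.loc[0, "sd"] == pytest.approx(np.sqrt(2.0))
        assert (s["n"] == 2).all()

    def test_identical_respondents_have_zero_sd(self):
        s = item_summaries(cohort_frame([[2.5] * 14] * 4))
        assert (s["sd"] == 0).all() and (s["mean"] == 2.5).all()

    def test_matches_two_pass_oracle_on_random_matrix(self):
        rng = np.random.default_rng(3)
        mat = random_halfstep_matrix(rng, 25)
        s = item_summaries(cohort_frame(mat.tolist()))
        for j in range(14):
            col = mat[:, j]
            mean = sum(col) / len(col)                     # independent two-pass
            sd = np.sqrt(sum((x - mean) ** 2 for x in col) / (len(col) - 1))
            assert s.loc[j, "mean"] == pytest.approx(mean)
            assert s.loc[j, "sd"] == pytest.approx(sd)

    def test_rejects_undersized_cohorts(self):
        with pytest.raises(ValueError):
            item_summaries(cohort_frame([[0.0] * 14]))


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        r = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)
        x = np.array([0.5, 1.5, 3.0, 7.0])
        assert spearman_rho(x, np.exp(-x)).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = rng.integers(5, 30)
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx = pd.Series(x).rank().to_numpy()
            ry = pd.Series(y).rank().to_numpy()
            expected = np.corrcoef(rx, ry)[0, 1]          # mid-ranks + Pearson
            assert spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = spearman_rho(x, y).rho
        assert spearman_rho(np.exp(x), y).rho == pytest.approx(base)
        assert spearman_rho(x, y ** 3).rho == pytest.approx(base)

    def test_p_value_uses_t_approximation(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = spearman_rho(x, y)
        t = r.rho * np.sqrt((30 - 2) / (1 - r.rho ** 2))
        assert r.p_raw == pytest.approx(2 * stats.t.sf(abs(t), 30 - 2), rel=1e-6)

    def test_constant_vector_and_short_input_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])

    def test_bonferroni_adjustment_properties(self):
        r = spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], family_size=10)
        assert r.p_adjusted == min(1.0, 10 * r.p_raw)
        assert r.p_adjusted >= r.p_raw
        assert bonferroni(0.2, 42) == 1.0
        with pytest.raises(ValueError):
            bonferroni(0.01, 0)


class TestItemTotalCorrelations:
    def test_shape_and_family(self, default_cohort):
        table = item_total_correlations(default_cohort)
        assert len(table) == 42
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        assert table["rho"].between(-1, 1).all()

    def test_dominant_item_correlates_positively_with_ts(self):
        # One item carries nearly all the variance of TS.
        rng = np.random.default_rng(21)
        big = rng.integers(0, 19, size=30) / 2.0
        rows = [[b] + list(rng.integers(-2, 3, size=13) / 2.0) for b in big]
        table = item_total_correlations(attach_scores(cohort_frame(rows)))
        row = table[(table["variable"] == "item01") & (table["total"] == "ts")]
        assert float(row["rho"].iloc[0]) > 0.5

    def test_bakery_item_signs_in_simulation(self):
        """The strongest pleasant item tracks T+ positively, T- negatively."""
        agree = 0
        for seed in range(30):
            df = attach_scores(generate_cohort(CohortSpec(n=100, seed=1000 + seed)))
            t = item_total_correlations(df)
            rho_tp = float(t[(t.variable == "item06") & (t.total == "t_plus")].rho.iloc[0])
            rho_tm = float(t[(t.variable == "item06") & (t.total == "t_minus")].rho.iloc[0])
            agree += (rho_tp > 0) and (rho_tm < 0)
        # Joint sign agreement holds in a majority of replicates (the T-
        # side is weak under item independence, so not near-certain).
        assert agree > 15

    def test_independent_noise_item_rarely_significant(self):
        """A pure-noise item seldom survives Bonferroni against totals it
        does not contribute to (leave-one-out null) at n=100."""
        from ohp.cohort_stats import spearman_rho

        nonsig = 0
        for seed in range(40):
            rng = np.random.default_rng(3000 + seed)
            df = generate_cohort(CohortSpec(n=100, seed=seed))
            noise = rng.integers(-18, 19, size=100) / 2.0
            others = df[[c for c in df.columns if c.startswith("item")
                         and c != item_column(5)]].to_numpy()
            totals = {
                "ts": np.abs(others).sum(axis=1),
                "t_plus": np.where(others > 0, others, 0).sum(axis=1),
                "t_minus": np.where(others < 0, others, 0).sum(axis=1),
            }
            sig = [spearman_rho(noise, tot, family_size=42).significant
                   for tot in totals.values()]
            nonsig += not any(sig)
        assert nonsig >= 36  # >= 90% of replicates


class TestMeanSdCorrelation:
    def test_sd_strictly_decreasing_in_abs_mean_gives_minus_one(self):
        # sd ordered strictly inversely to |mean|
        s = pd.DataFrame({"mean": [-6, -4, -2, 1, 3, 5],
                          "sd": [1.0, 2.0, 4.0, 5.0, 3.0, 1.5]})
        assert mean_sd_correlation(s).rho == pytest.approx(-1.0)

    def test_constant_sd_is_undefined(self):
        s = pd.DataFrame({"mean": [1.0, -2.0, 3.0], "sd": [2.0, 2.0, 2.0]})
        with pytest.raises(ConstantInputError):
            mean_sd_correlation(s)

    def test_needs_three_items(self):
        with pytest.raises(ValueError):
            mean_sd_correlation(pd.DataFrame({"mean": [1.0, 2.0], "sd": [1.0, 2.0]}))

    def test_default_cohort_reproduces_anticorrelation(self, default_cohort):
        r = mean_sd_correlation(item_summaries(default_cohort))
        assert r.rho < -0.5


class TestSexComparison:
    def test_identical_groups_give_zero_t_and_unit_p(self):
        # Mixed-valence rows so every variable (incl. T-) varies within group.
        rows = [[k] * 7 + [-k] * 6 + [k / 2] for k in (1.0, 2.0, 3.0)] * 2
        sexes = ["M", "M", "M", "F", "F", "F"]
        table = sex_comparison(cohort_frame(rows, sexes=sexes))
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p_raw"], 1.0)

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(31)
        rows_m = [list(np.zeros(14) + rng.normal(0, 0.1, 14).round() * 0.5)
                  for _ in range(6)]
        rows_f = [list(np.full(14, 5.0) + rng.integers(0, 2, 14) * 0.5)
                  for _ in range(6)]
        table = sex_comparison(cohort_frame(rows_m + rows_f,
                                            sexes=["M"] * 6 + ["F"] * 6))
        item_rows = table[table["variable"].str.startswith("item")]
        assert (item_rows["t"].abs() > 5).all()
        assert (item_rows["p_adjusted"] < 0.05).all()

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(32)
        rows = random_halfstep_matrix(rng, 12).tolist()
        sexes = ["M"] * 5 + ["F"] * 7
        table = sex_comparison(cohort_frame(rows, sexes=sexes))
        mat = np.array(rows)
        xm, xf = mat[:5], mat[5:]
        for j in range(14):
            a, b = xm[:, j], xf[:, j]
            sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
            expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
            assert table.loc[j, "t"] == pytest.approx(expected, rel=1e-10)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(33)
        rows = random_halfstep_matrix(rng, 10).tolist()
        t1 = sex_comparison(cohort_frame(rows, sexes=["M"] * 5 + ["F"] * 5))
        t2 = sex_comparison(cohort_frame(rows, sexes=["F"] * 5 + ["M"] * 5))
        assert np.allclose(t1["t"], -t2["t"])
        assert np.allclose(t1["p_raw"], t2["p_raw"])

    def test_t_sign_matches_mean_difference(self, default_cohort):
        table = sex_comparison(default_cohort)
        nonzero = table[table["t"] != 0]
        assert (np.sign(nonzero["t"]) == np.sign(nonzero["mean_m"] - nonzero["mean_f"])).all()

    def test_rejects_single_member_group(self):
        rows = [[0.0] * 14] * 3
        with pytest.raises(ValueError):
            sex_comparison(cohort_frame(rows, sexes=["M", "F", "F"]))


class TestSelfSmell:
    def test_self_smell_equal_to_ts_proxy_has_rho_one(self):
        rng = np.random.default_rng(41)
        rows = random_halfstep_matrix(rng, 20).tolist()
        df = attach_scores(cohort_frame(rows))
        # A self-rating that is a monotone (finely binned) transform of TS.
        df["self_smell"] = np.clip(np.round((df["ts"] - 60) / 4) * 0.5, -9, 9)
        table = self_smell_correlations(df)
        row = table[table["variable"] == "ts"]
        assert float(row["rho"].iloc[0]) > 0.9

    def test_missing_ratings_are_excluded_with_bookkeeping(self):
        rng = np.random.default_rng(42)
        rows = random_halfstep_matrix(rng, 10).tolist()
        ss = list(rng.integers(-4, 10, size=10) / 1.0)
        ss[3] = np.nan
        df = cohort_frame(rows, self_smell=ss)
        table = self_smell_correlations(attach_scores(df))
        assert (table["n"] == 9).all()
        assert (table["n_excluded"] == 1).all()

    def test_requires_three_rated_respondents(self):
        rows = [[1.0] * 14] * 5
        df = cohort_frame(rows, self_smell=[1.0, 2.0, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError):
            self_smell_correlations(attach_scores(df))

    def test_null_self_smell_rarely_significant(self):
        """Independent self-ratings stay non-significant after adjustment."""
        nonsig = 0
        for seed in range(40):
            df = attach_scores(generate_cohort(
                CohortSpec(n=100, seed=seed, self_smell_rho=0.0)))
            table = self_smell_correlations(df)
            nonsig += not table["significant"].any()
        assert nonsig >= 36


class TestScreenItems:
    @staticmethod
    def frames(scores_by_item: dict, flags_by_item: dict):
        return pd.DataFrame(scores_by_item), pd.DataFrame(flags_by_item)

    def test_never_experienced_rule_three_of_thirty(self):
        rng = np.random.default_rng(51)
        scores = np.round(rng.normal(0, 2, size=30) * 2) / 2
        s, f = self.frames({"swimming_pool": scores},
                           {"swimming_pool": [True] * 3 + [False] * 27})
        out = screen_items(s, f)
        assert not out.loc[0, "keep"]
        assert "never experienced by 3/30" in out.loc[0, "reason"]

    def test_two_of_thirty_is_tolerated(self):
        rng = np.random.default_rng(52)
        scores = np.clip(np.round(rng.normal(0, 2, size=30) * 2) / 2, -9, 9)
        s, f = self.frames({"ok": scores}, {"ok": [True] * 2 + [False] * 28})
        assert screen_items(s, f).loc[0, "keep"]

    def test_bimodal_item_fails_normality(self):
        scores = np.array([-9.0] * 15 + [9.0] * 15)
        s, f = self.frames({"cigarette": scores}, {"cigarette": [False] * 30})
        out = screen_items(s, f)
        assert not out.loc[0, "keep"]
        assert "non-normal" in out.loc[0, "reason"]

    def test_normalish_item_is_kept(self):
        rng = np.random.default_rng(53)
        scores = np.clip(np.round(rng.normal(1, 2.5, size=30) * 2) / 2, -9, 9)
        s, f = self.frames({"rain": scores}, {"rain": [False] * 30})
        assert screen_items(s, f).loc[0, "keep"]

    def test_mismatched_columns_and_tiny_n_rejected(self):
        s, f = self.frames({"a": [1.0, 2.0, 3.0]}, {"b": [False] * 3})
        with pytest.raises(ValueError):
            screen_items(s, f)
        s, f = self.frames({"a": [1.0, 2.0]}, {"a": [False, False]})
        with pytest.raises(ValueError):
            screen_items(s, f)
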