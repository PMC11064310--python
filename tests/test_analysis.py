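import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from minddiet import analysis
from minddiet.analysis import (
    ModelSpec,
    SeparationError,
    assign_score_groups,
    compare_categorical,
    compare_components,
    compare_continuous,
    correlate_score_cognition,
    describe_groups,
    fit_hierarchical_logistic,
    impute_missing,
    normality_check,
    pool_rubin,
)

from oracles import crossprod_or, mann_whitney_u


class TestAssignScoreGroups:
    def test_balanced_quartiles(self):
        res = assign_score_groups(list(range(1, 9)), k=4)
        assert res.sizes() == {"T1": 2, "T2": 2, "T3": 2, "T4": 2}

    def test_tie_rule_hand_enumeration(self):
        # scores (5,5,5,6,7,8,8,9), k=4; linear-interp quantiles q25=5,
        # q50=6.5, q75=8; ties-to-lower puts the three 5s in T1 and both
        # 8s (== q75) in T3: sizes 3,1,3,1.
        res = assign_score_groups([5, 5, 5, 6, 7, 8, 8, 9], k=4)
        assert res.boundaries == (5.0, 6.5, 8.0)
        assert res.sizes() == {"T1": 3, "T2": 1, "T3": 3, "T4": 1}

    def test_unequal_groups_are_acceptable(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(6.4, 1.6, 810) * 2) / 2
        res = assign_score_groups(scores, k=4)
        assert sum(res.sizes().values()) == 810

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            assign_score_groups([1, 1, 1, 2], k=4)

    def test_k_less_than_two(self):
        with pytest.raises(ValueError, match="k"):
            assign_score_groups([1, 2, 3], k=1)

    def test_partition_sums_to_n(self, cohort_810):
        res = assign_score_groups(cohort_810["diet_total"].to_numpy(), k=4)
        assert sum(res.sizes().values()) == len(cohort_810)

    def test_reproducible(self):
        scores = [5, 5, 5, 6, 7, 8, 8, 9]
        a = assign_score_groups(scores, k=4)
        b = assign_score_groups(scores, k=4)
        assert a.labels.tolist() == b.labels.tolist()


class TestDescribeGroups:
    def test_single_group_equals_overall(self, cohort_810):
        df = cohort_810.assign(all="All")
        out = describe_groups(df, "all", continuous=["age"], categorical=["sex"])
        row = out[(out.variable == "age")].iloc[0]
        assert row["mean"] == pytest.approx(cohort_810["age"].mean())
        assert row["n"] == 810

    def test_printed_group_sizes_give_prevalence(self):
        df = pd.DataFrame({"status": ["non"] * 565 + ["mci"] * 245, "g": "All"})
        out = describe_groups(df, "g", categorical=["status"])
        mci = out[(out.variable == "status") & (out.level == "mci")].iloc[0]
        assert round(float(mci["pct"]), 1) == 30.2

    def test_constant_variable_sd_zero(self):
        df = pd.DataFrame({"g": ["a"] * 5, "x": [2.0] * 5})
        out = describe_groups(df, "g", continuous=["x"])
        assert out.iloc[0]["sd"] == 0.0

    def test_missing_excluded_from_denominator(self):
        df = pd.DataFrame({"g": ["a"] * 4, "x": ["u", "v", None, "v"]})
        out = describe_groups(df, "g", categorical=["x"])
        v = out[(out.level == "v")].iloc[0]
        assert v["pct"] == pytest.approx(100 * 2 / 3)


class TestCompareContinuous:
    def test_anova_null_case(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "x": [1.0, 2, 3, 4] * 2})
        stat, p = compare_continuous(df, "g", "x", test="anova")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_anova_needs_two_obs_per_group(self):
        df = pd.DataFrame({"g": ["a", "b", "b"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_continuous(df, "g", "x", test="anova")

    def test_mann_whitney_complete_separation(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "x": [1.0, 2, 3, 10, 11, 12]})
        stat, _ = compare_continuous(df, "g", "x", test="mann_whitney")
        assert stat == 0.0

    def test_mann_whitney_small_matches_enumeration(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 3.0, 7.0]
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "x": a + b})
        stat, p = compare_continuous(df, "g", "x", test="mann_whitney")
        # stat is U of the first (sorted) group
        assert stat == mann_whitney_u(a, b)
        # exact p: proportion of the 20 equally likely rank splits at least
        # as extreme (two-sided)
        pooled = sorted(a + b)
        us = [
            mann_whitney_u(comb, [v for v in pooled if v not in comb])
            for comb in itertools.combinations(pooled, 3)
        ]
        mu = len(a) * len(b) / 2
        extreme = sum(abs(u - mu) >= abs(stat - mu) for u in us)
        assert p == pytest.approx(extreme / len(us))

    def test_mann_whitney_exhaustive_all_splits_of_8(self):
        values = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]  # includes a tie
        for k in range(1, 8):
            for idx in itertools.combinations(range(8), k):
                a = [values[i] for i in idx]
                b = [values[i] for i in range(8) if i not in idx]
                df = pd.DataFrame({"g": ["a"] * len(a) + ["b"] * len(b), "x": a + b})
                stat, _ = compare_continuous(df, "g", "x", test="mann_whitney")
                assert stat == mann_whitney_u(a, b), (a, b)

    def test_mann_whitney_requires_two_groups(self):
        df = pd.DataFrame({"g": ["a", "b", "c"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="exactly 2"):
            compare_continuous(df, "g", "x", test="mann_whitney")

    def test_unknown_test(self):
        df = pd.DataFrame({"g": ["a", "b"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unknown test"):
            compare_continuous(df, "g", "x", test="t")


class TestCompareCategorical:
    def test_identical_proportions_statistic_zero(self):
        df = pd.DataFrame({
            "g": ["a"] * 20 + ["b"] * 20,
            "x": (["y"] * 10 + ["n"] * 10) * 2,
        })
        stat, p = compare_categorical(df, "g", "x")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hypertension_2x2_strongly_significant(self):
        # non-MCI: 176 yes / 389 no; MCI: 126 yes / 119 no
        rows = (
            [("non", "yes")] * 176 + [("non", "no")] * 389
            + [("mci", "yes")] * 126 + [("mci", "no")] * 119
        )
        df = pd.DataFrame(rows, columns=["g", "x"])
        stat, p = compare_categorical(df, "g", "x")
        assert p < 0.001
        # Pearson chi-square closed form on the 2x2, no correction
        expected = stats.chi2_contingency(
            np.array([[176, 389], [126, 119]]), correction=False
        )[0]
        assert stat == pytest.approx(expected)

    def test_empty_margin_rejected(self):
        df = pd.DataFrame({"g": ["a", "a"], "x": ["y", "y"]})
        with pytest.raises(ValueError):
            compare_categorical(df, "g", "x")


class TestCorrelation:
    def test_perfect_positive(self):
        df = pd.DataFrame({"s": [1.0, 2, 3, 4, 5]})
        df["m"] = 2 * df["s"] + 1
        out = correlate_score_cognition(df, "s", ["m"])
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        df = pd.DataFrame({"s": [1.0, 2, 3, 4, 5]})
        df["m"] = -df["s"]
        out = correlate_score_cognition(df, "s", ["m"])
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_hand_example(self):
        # (1,2),(2,1),(3,4),(4,3),(5,5): sum dxdy=8, sum dx2=sum dy2=10 -> r=0.8
        df = pd.DataFrame({"s": [1.0, 2, 3, 4, 5], "m": [2.0, 1, 4, 3, 5]})
        out = correlate_score_cognition(df, "s", ["m"])
        assert out.iloc[0]["r"] == pytest.approx(0.8)
        t = 0.8 * math.sqrt(3 / (1 - 0.64))
        p_hand = 2 * stats.t.sf(t, df=3)
        assert out.iloc[0]["p"] == pytest.approx(p_hand)

    def test_constant_input_rejected(self):
        df = pd.DataFrame({"s": [1.0, 1, 1, 1], "m": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="constant"):
            correlate_score_cognition(df, "s", ["m"])

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"s": [1.0, 2], "m": [1.0, 2]})
        with pytest.raises(ValueError, match="3"):
            correlate_score_cognition(df, "s", ["m"])


def _binary_cohort(a, b, c, d):
    """y=1/x=1: a, y=1/x=0: b, y=0/x=1: c, y=0/x=0: d."""
    y = [1] * (a + b) + [0] * (c + d)
    x = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"y": y, "x": x})


class TestHierarchicalLogistic:
    def test_single_binary_matches_crossproduct(self):
        df = _binary_cohort(126, 119, 176, 389)
        res = fit_hierarchical_logistic(
            df, specs=[ModelSpec("M", ("x",))], outcome="y", group_col=None
        )
        fitted = res[0].term("x")["or_"]
        assert fitted == pytest.approx(crossprod_or(126, 119, 176, 389), abs=1e-6)

    def test_nesting_loglikelihood(self, cohort_810):
        blocks = fit_hierarchical_logistic(cohort_810)
        assert blocks[0].n == blocks[1].n == blocks[2].n
        assert blocks[2].llf >= blocks[1].llf >= blocks[0].llf

    def test_ci_and_or_consistency(self, cohort_810):
        for block in fit_hierarchical_logistic(cohort_810):
            t = block.table
            assert (t["ci_low"] <= t["or_"]).all()
            assert (t["or_"] <= t["ci_high"]).all()
            np.testing.assert_allclose(t["or_"], np.exp(t["coef"]))

    def test_null_outcome_ors_near_one(self):
        rng = np.random.default_rng(8)
        n = 20_000
        df = pd.DataFrame({
            "y": rng.random(n) < 0.3,
            "x1": rng.standard_normal(n),
            "x2": (rng.random(n) < 0.5).astype(float),
        })
        df["y"] = df["y"].astype(int)
        res = fit_hierarchical_logistic(
            df, specs=[ModelSpec("M", ("x1", "x2"))], outcome="y", group_col=None
        )
        for term in ("x1", "x2"):
            row = res[0].term(term)
            assert row["ci_low"] <= 1.0 <= row["ci_high"]
            assert row["or_"] == pytest.approx(1.0, abs=0.1)

    def test_non_nested_specs_rejected(self, cohort_810):
        specs = [ModelSpec("A", ("age",)), ModelSpec("B", ("bmi",))]
        with pytest.raises(ValueError, match="nested"):
            fit_hierarchical_logistic(cohort_810, specs=specs)

    def test_perfect_separation_detected(self):
        df = pd.DataFrame({"y": [0] * 30 + [1] * 30, "x": [0.0] * 30 + [1.0] * 30})
        with pytest.raises(SeparationError):
            fit_hierarchical_logistic(
                df, specs=[ModelSpec("M", ("x",))], outcome="y", group_col=None
            )

    def test_nonbinary_outcome_rejected(self, cohort_810):
        with pytest.raises(ValueError, match="binary"):
            fit_hierarchical_logistic(cohort_810, outcome="age")

    def test_complete_case_subsample_shared(self, cohort_810):
        df = cohort_810.copy()
        df.loc[df.index[:30], "bmi"] = np.nan
        blocks = fit_hierarchical_logistic(df)
        assert {b.n for b in blocks} == {len(df) - 30}


class TestCompareComponents:
    def test_table_shape_and_additivity(self, cohort_810, mymindd):
        out = compare_components(cohort_810, mymindd.component_ids)
        assert len(out) == 12  # 11 components + total
        assert out.iloc[-1]["component"] == "total"
        comp_mean_sum = out.iloc[:-1]["mean_all"].sum()
        assert comp_mean_sum == pytest.approx(out.iloc[-1]["mean_all"], abs=1e-9)

    def test_identical_groups_p_near_one(self):
        base = pd.DataFrame({
            "true_mci": [0, 1] * 20,
            "score_a": [0.5, 0.5, 1.0, 1.0] * 10,
            "diet_total": [3.0, 3.0, 4.0, 4.0] * 10,
        })
        out = compare_components(base, ["a"])
        assert (out["p"] > 0.9).all()


class TestImputation:
    def test_no_missing_identity(self, cohort_810):
        sub = cohort_810[["age", "bmi", "ravlt"]].copy()
        for method in ("complete_case", "single_mean_mode"):
            out = impute_missing(sub, method=method)
            pd.testing.assert_frame_equal(out, sub)
        multi = impute_missing(sub, method="multiple_imputation", m=2, seed=1)
        for d in multi:
            pd.testing.assert_frame_equal(d, sub)

    def test_complete_case_bookkeeping(self, cohort_810):
        df = cohort_810[["age", "bmi", "ravlt"]].copy()
        df.loc[df.index[:17], "bmi"] = np.nan
        df.loc[df.index[10:20], "age"] = np.nan
        out = impute_missing(df, method="complete_case")
        assert len(out) == len(df) - 20
        assert out.attrs["dropped_rows"] == 20

    def test_single_mean_mode(self):
        df = pd.DataFrame({"x": [1.0, 3.0, np.nan], "c": ["a", None, "a"]})
        out = impute_missing(df, method="single_mean_mode", variables=["x", "c"])
        assert out["x"].tolist() == [1.0, 3.0, 2.0]
        assert out["c"].tolist() == ["a", "a", "a"]

    def test_multiple_imputation_reproducible(self, cohort_810):
        df = cohort_810[["age", "bmi", "ravlt", "mmse"]].copy()
        rng = np.random.default_rng(3)
        df.loc[rng.choice(df.index, 40, replace=False), "bmi"] = np.nan
        a = impute_missing(df, method="multiple_imputation", m=3, seed=5)
        b = impute_missing(df, method="multiple_imputation", m=3, seed=5)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da, db)
        assert all(not d["bmi"].isna().any() for d in a)
        # imputations differ between draws
        assert not a[0]["bmi"].equals(a[1]["bmi"])

    def test_entirely_missing_variable_rejected(self):
        df = pd.DataFrame({"x": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely"):
            impute_missing(df, method="complete_case", variables=["x"])

    def test_unknown_method(self, cohort_810):
        with pytest.raises(ValueError, match="method"):
            impute_missing(cohort_810, method="magic")


class TestRubinPooling:
    def test_toy_hand_arithmetic(self):
        # m=3: estimates 1, 2, 3; variances 0.5, 0.5, 0.5
        # qbar = 2; W = 0.5; B = 1; T = 0.5 + (1 + 1/3) * 1 = 11/6
        out = pool_rubin([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        assert out["estimate"] == pytest.approx(2.0)
        assert out["within"] == pytest.approx(0.5)
        assert out["between"] == pytest.approx(1.0)
        assert out["variance"] == pytest.approx(11 / 6)

    def test_between_variance_nonnegative(self, cohort_810):
        df = cohort_810[["age", "bmi", "ravlt", "true_mci"]].copy()
        rng = np.random.default_rng(9)
        df.loc[rng.choice(df.index, 30, replace=False), "bmi"] = np.nan
        sets = impute_missing(df, method="multiple_imputation", m=5, seed=11)
        est, var = [], []
        for d in sets:
            res = fit_hierarchical_logistic(
                d, specs=[ModelSpec("M", ("age", "bmi"))], outcome="true_mci", group_col=None
            )
            row = res[0].term("bmi")
            est.append(row["coef"])
            var.append(row["se"] ** 2)
        pooled = pool_rubin(est, var)
        assert pooled["between"] >= 0
        assert pooled["variance"] >= pooled["within"]

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0], [0.5])


class TestNormalityCheck:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(13)
        stat, p = normality_check(rng.standard_normal(2_000))
        assert p > 0.05

    def test_five_point_ecdf_oracle(self):
        vals = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        stat, _ = normality_check(vals)
        mu, sd = vals.mean(), vals.std(ddof=1)
        cdf = stats.norm.cdf(np.sort(vals), mu, sd)
        n = len(vals)
        gaps = [
            max(abs((i + 1) / n - c), abs(i / n - c))
            for i, c in enumerate(cdf)
        ]
        assert stat == pytest.approx(max(gaps))

    def test_bimodal_fails(self):
        rng = np.random.default_rng(14)
        x = np.concatenate([rng.normal(-4, 0.3, 500), rng.normal(4, 0.3, 500)])
        _, p = normality_check(x)
        assert p < 1e-6

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check([3.0] * 10)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0, 3.0])
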