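"""Cohort statistics: scoring, exclusions, correlations, groups, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from seesaw.inference import (
    CohortTable,
    SubjectRecord,
    anova_2x2,
    apply_exclusions,
    assign_extreme_groups,
    bonferroni,
    cronbach_alpha,
    partial_correlation,
    pearson,
    score_scale,
    two_sample_t,
)


def make_cohort(n, rng):
    return CohortTable(
        [
            SubjectRecord(
                id=f"s{i:03d}",
                sas_score=float(rng.integers(20, 60)),
                sds_score=float(rng.integers(20, 60)),
                age=20.0,
                gender="F" if i % 2 else "M",
            )
            for i in range(n)
        ]
    )


class TestScoreScale:
    @pytest.mark.parametrize(
        "items,reverse,expected",
        [
            ([1] * 20, (), 20),
            ([4] * 20, (), 80),
            ([1] * 20, tuple(range(10)), 10 * 4 + 10 * 1),
        ],
    )
    def test_sums(self, items, reverse, expected):
        assert score_scale(items, reverse) == expected

    def test_out_of_range_names_item(self):
        items = [2] * 20
        items[7] = 5
        with pytest.raises(ValueError, match="item 7"):
            score_scale(items)


class TestExclusions:
    def test_strictly_above_rule(self, rng):
        cohort = make_cohort(4, rng)
        motion = {
            "s000": (2.5, 0.5),  # above translation limit -> excluded
            "s001": (2.0, 2.0),  # exactly at limits -> retained
            "s002": (0.5, 2.1),  # above rotation limit -> excluded
        }
        out = apply_exclusions(cohort, motion)
        assert [s.excluded for s in out.subjects] == [True, False, True, False]
        assert out.n_included == 2

    def test_planted_violators_counted(self, rng):
        n, k = 50, 7
        cohort = make_cohort(n, rng)
        motion = {f"s{i:03d}": (3.0, 0.1) for i in range(k)}
        assert apply_exclusions(cohort, motion).n_included == n - k

    def test_quality_flags(self, rng):
        cohort = make_cohort(3, rng)
        out = apply_exclusions(cohort, quality_flags={"s001": True})
        assert out.subjects[1].excluded
        assert out.subjects[1].exclusion_reason == "image quality"


class TestPearson:
    def test_perfect_and_orthogonal(self):
        assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson([1, -1, 1, -1], [1, 1, -1, -1]).r == pytest.approx(0.0)

    def test_matches_sum_formula_oracle(self, rng):
        x, y = rng.standard_normal((2, 50))
        n = 50
        sx, sy, sxy = x.sum(), y.sum(), (x * y).sum()
        sxx, syy = (x**2).sum(), (y**2).sum()
        r_oracle = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx**2) * (n * syy - sy**2)
        )
        res = pearson(x, y)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.df == 48

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.standard_normal((2, 40))
        a = pearson(x, y)
        b = partial_correlation(x, y, None)
        assert (a.r, a.t, a.df) == (b.r, b.t, b.df)

    def test_df_bookkeeping(self, rng):
        x, y = rng.standard_normal((2, 287))
        cov = rng.standard_normal((287, 2))
        assert partial_correlation(x, y, cov).df == 283

    def test_three_variable_closed_form(self, rng):
        x, y, z = rng.standard_normal((3, 100))
        rxy, rxz, ryz = (
            np.corrcoef(x, y)[0, 1],
            np.corrcoef(x, z)[0, 1],
            np.corrcoef(y, z)[0, 1],
        )
        oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        got = partial_correlation(x, y, z).r
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.standard_normal((2, 60))
        cov = rng.standard_normal((60, 3))
        df = pd.DataFrame(
            {"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1], "c3": cov[:, 2]}
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
        got = partial_correlation(x, y, cov)
        assert got.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert got.p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-10)

    def test_df_equals_residual_df_of_underlying_fit(self, rng):
        n, k = 75, 4
        x, y = rng.standard_normal((2, n))
        cov = rng.standard_normal((n, k))
        res = partial_correlation(x, y, cov)
        # least-squares fit of y on [1, cov, x] leaves n - k - 2 residual df
        assert res.df == n - 2 - k

    def test_rank_deficiency_is_error(self, rng):
        x, y = rng.standard_normal((2, 30))
        c = rng.standard_normal(30)
        with pytest.raises(ValueError):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestBonferroni:
    def test_doubling_and_cap(self):
        assert bonferroni([0.03], 2) == [0.06]
        assert bonferroni([0.9], 2) == [1.0]

    def test_family_smaller_than_tests_is_error(self):
        with pytest.raises(ValueError):
            bonferroni([0.01, 0.02, 0.03], 2)

    def test_invalid_p_is_error(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)


class TestExtremeGroups:
    def test_concordant_monotone_case(self):
        df = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(8)],
                "sas_score": np.arange(1, 9),
                "sds_score": np.arange(1, 9),
            }
        )
        groups = assign_extreme_groups(df, group_size=2)
        assert set(groups["HH"]) == {"s6", "s7"}
        assert set(groups["LL"]) == {"s0", "s1"}

    def test_discordant_subject_leads_lh(self):
        # s0: max SAS, min SDS -> first pick for LH (high anxious, low depressed)
        df = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(8)],
                "sas_score": [80, 30, 31, 32, 33, 34, 35, 36],
                "sds_score": [20, 40, 41, 42, 43, 44, 45, 46],
            }
        )
        groups = assign_extreme_groups(df, group_size=2)
        assert "s0" in groups["LH"]

    def test_disjoint_and_sized_on_random_cohort(self, rng):
        n = 287
        df = pd.DataFrame(
            {
                "id": [f"s{i:03d}" for i in range(n)],
                "sas_score": rng.integers(20, 80, n),
                "sds_score": rng.integers(20, 80, n),
            }
        )
        groups = assign_extreme_groups(df, group_size=33)
        all_ids = sum((groups[g] for g in ("HH", "LL", "LH", "HL")), [])
        assert len(all_ids) == 132
        assert len(set(all_ids)) == 132
        assert all(len(groups[g]) == 33 for g in groups)

    def test_insufficient_subjects_is_error(self, rng):
        df = pd.DataFrame(
            {"id": ["a", "b"], "sas_score": [1, 2], "sds_score": [1, 2]}
        )
        with pytest.raises(ValueError):
            assign_extreme_groups(df, group_size=1)


class TestAnova:
    def make_design(self, rng, per_cell=33):
        a = ["high"] * (2 * per_cell) + ["low"] * (2 * per_cell)
        b = (["high"] * per_cell + ["low"] * per_cell) * 2
        y = rng.standard_normal(4 * per_cell)
        return y, a, b

    def test_error_df_without_covariates(self, rng):
        y, a, b = self.make_design(rng)
        table = anova_2x2(y, a, b)
        assert (table["df_error"] == 128).all()

    def test_error_df_with_covariates(self, rng):
        y, a, b = self.make_design(rng)
        cov = pd.DataFrame(
            {"age": rng.normal(20, 1, 132), "gender01": rng.integers(0, 2, 132)}
        )
        table = anova_2x2(y, a, b, cov)
        assert (table["df_error"] == 126).all()

    def test_pure_factor_a_effect_is_orthogonal(self, rng):
        # balanced design: adding a pure A effect must leave B and A:B untouched
        noise, a, b = self.make_design(rng, per_cell=20)
        base = anova_2x2(noise, a, b)
        shifted = anova_2x2(
            noise + np.where(np.array(a) == "high", 1.0, -1.0), a, b
        )
        assert shifted.loc["A", "F"] > base.loc["A", "F"]
        for eff in ("B", "A:B"):
            assert shifted.loc[eff, "F"] == pytest.approx(
                base.loc[eff, "F"], rel=1e-8
            )

    def test_empty_cell_is_error(self, rng):
        y = rng.standard_normal(30)
        a = ["high"] * 30
        b = ["high"] * 15 + ["low"] * 15
        a[0] = "low"  # (low, low) cell stays empty
        with pytest.raises(ValueError):
            anova_2x2(y, a, b)


class TestTwoSampleT:
    def test_df_from_group_sizes(self, rng):
        a = rng.standard_normal(138)
        b = rng.standard_normal(149)
        _, df, _ = two_sample_t(a, b)
        assert df == 285

    def test_identical_groups_give_zero(self):
        t, _, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        t, df, _ = two_sample_t(a, b)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert df == 4

    def test_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.standard_normal((2, 30))
        t, _, p = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestCronbach:
    def test_parallel_items_alpha_one(self, rng):
        col = rng.integers(1, 5, 50).astype(float)
        items = np.tile(col[:, None], (1, 20))
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self, rng):
        items = rng.integers(1, 5, (5000, 20)).astype(float)
        assert abs(cronbach_alpha(items)) < 0.05

    def test_two_item_spearman_brown_closed_form(self, rng):
        x = rng.standard_normal(500)
        y = 0.5 * x + rng.standard_normal(500)
        items = np.column_stack([x, y])
        r = np.corrcoef(x, y)[0, 1]
        # standardized alpha equals Spearman-Brown only for equal variances;
        # raw-alpha closed form for k=2: 2*(1 - (v1+v2)/vt)
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        vt = (x + y).var(ddof=1)
        oracle = 2.0 * (1.0 - (v1 + v2) / vt)
        assert cronbach_alpha(items) == pytest.approx(oracle, abs=1e-10)
        del r

    def test_reverse_keys_recoded(self, rng):
        col = rng.integers(1, 5, 100).astype(float)
        items = np.column_stack([col, 5.0 - col])
        # without recoding the two items anticorrelate; recoding makes alpha 1
        assert cronbach_alpha(items, reverse_keys=[1]) == pytest.approx(1.0)
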