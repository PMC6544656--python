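"""Group-comparison statistics: ANOVA variants, chi-square, rank tests, ANCOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from revtranslate.clinical import (
    ancova,
    anova_from_summary,
    chi_square,
    group_comparison_table,
    kendall_tau,
    mann_whitney_u,
    one_way_anova,
    welch_anova,
    welch_anova_from_summary,
)
from revtranslate.synthetic import simulate_clinical_table, table4_clinical_config


class TestAnova:
    def test_identical_means_give_zero_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_matches_summary_based_computation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1.3, 9)
        raw = one_way_anova([x, y])
        summ = anova_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_infinite_f_flagged_when_msw_zero(self):
        res = anova_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert np.isinf(res.statistic)


class TestWelch:
    def test_equal_means_zero(self):
        res = welch_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)

    def test_summary_closed_form(self):
        res = welch_anova_from_summary(4.03, 3.33, 37, 3.15, 1.57, 13)
        assert res.statistic == pytest.approx(1.58, abs=0.005)
        assert res.df[1] == pytest.approx(43.6, abs=0.05)

    def test_equals_squared_welch_t(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 3, 8)
        res = welch_anova(x, y)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(t * t)
        assert res.p == pytest.approx(p)

    def test_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([1.0, 1.0], [2.0, 2.0])


class TestChiSquare:
    def test_language_counts(self):
        res = chi_square([[30, 7], [13, 0]])
        assert res.statistic == pytest.approx(2.86, abs=0.005)
        assert res.df == (1,)

    def test_handedness_counts(self):
        res = chi_square([[33, 4, 0], [11, 1, 1]])
        assert res.statistic == pytest.approx(2.96, abs=0.005)
        assert res.df == (2,)

    def test_equal_proportions_zero(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [1, 2]])

    def test_matches_permutation_null(self):
        # Monte-Carlo permutation null of a 2x2 table; mid-p handles the
        # point mass of the discrete permutation distribution
        observed = np.array([[45, 55], [55, 45]])
        res = chi_square(observed)
        rows = np.repeat([0, 1], observed.sum(axis=1))
        cols = np.concatenate(
            [np.repeat([0, 1], observed[i]) for i in range(2)]
        )
        rng = np.random.default_rng(2)
        greater = equal = 0
        n_perm = 10000
        for _ in range(n_perm):
            perm = rng.permutation(cols)
            table = np.array(
                [[np.sum((rows == i) & (perm == j)) for j in (0, 1)] for i in (0, 1)]
            )
            s = chi_square(table).statistic
            if s > res.statistic + 1e-9:
                greater += 1
            elif abs(s - res.statistic) <= 1e-9:
                equal += 1
        p_mc = (greater + equal / 2) / n_perm
        assert abs(p_mc - res.p) < 0.02  # ~3 sigma simulation error


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2], [3, 4]).statistic == 0

    def test_interleaved_pair_count(self):
        assert mann_whitney_u([1, 3], [2, 4]).statistic == 1

    def test_u_identity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=9)
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        u_x = res.statistic
        assert u_x + (len(x) * len(y) - u_x) == len(x) * len(y)
        assert mann_whitney_u(x, y).statistic == min(u_x, len(x) * len(y) - u_x)

    def test_exact_p_matches_enumeration(self):
        # brute force over all rank assignments for small n without ties
        rng = np.random.default_rng(4)
        for n_x, n_y in [(2, 3), (3, 3), (3, 4), (4, 4)]:
            x = rng.normal(size=n_x)
            y = rng.normal(size=n_y)
            res = mann_whitney_u(x, y)
            n = n_x + n_y
            combined = np.concatenate([x, y])
            ranks = stats.rankdata(combined)
            u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
            u_obs = min(u_obs, n_x * n_y - u_obs)
            count = total = 0
            for assignment in itertools.combinations(range(n), n_x):
                r = sum(ranks_all := [i + 1 for i in assignment])
                u = r - n_x * (n_x + 1) / 2
                u = min(u, n_x * n_y - u)
                total += 1
                if u <= u_obs + 1e-9:
                    count += 1
            assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_fully_tied_samples_give_p_one(self):
        res = mann_whitney_u([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p == pytest.approx(1.0)


class TestKendall:
    def test_identical_and_reversed_orderings(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_pair_enumeration_example(self):
        res = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(2.0 / 3.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestAncova:
    def test_constant_response_gives_zero_f(self):
        y = np.ones(16)
        group = np.repeat(["a", "b"], 8)
        cov = np.arange(16.0)
        f_group, f_cov = ancova(y, group, cov)
        assert f_group.statistic == pytest.approx(0.0)
        assert f_cov.statistic == pytest.approx(0.0)

    def test_pure_covariate_effect(self):
        rng = np.random.default_rng(5)
        cov = rng.normal(size=20)
        group = np.tile(["a", "b"], 10)
        y = cov + 1e-4 * rng.normal(size=20)
        f_group, f_cov = ancova(y, group, cov)
        assert f_cov.statistic > 1e6
        assert f_group.p > 0.05

    def test_null_group_effect_type_i_error(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            cov = rng.normal(size=16)
            y = 2.0 * cov + rng.normal(size=16)
            group = rng.permutation(np.repeat(["a", "b"], 8))
            f_group, _ = ancova(y, group, cov)
            rejections += f_group.p < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_collinear_covariate_rejected(self):
        group = np.repeat(["a", "b"], 5)
        cov = (group == "b").astype(float)
        with pytest.raises(ValueError):
            ancova(np.arange(10.0), group, cov)


class TestTypeIError:
    @pytest.mark.parametrize(
        "test_fn",
        [
            lambda x, y: one_way_anova([x, y]),
            welch_anova,
            mann_whitney_u,
        ],
    )
    def test_null_rejection_rate_at_alpha(self, test_fn):
        rng = np.random.default_rng(7)
        n_rep = 1000
        rejections = sum(
            test_fn(rng.normal(size=12), rng.normal(size=10)).p < 0.05
            for _ in range(n_rep)
        )
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.005

    def test_kendall_null_rate(self):
        rng = np.random.default_rng(8)
        n_rep = 1000
        rejections = sum(
            kendall_tau(rng.normal(size=20), rng.normal(size=20)).p < 0.05
            for _ in range(n_rep)
        )
        assert abs(rejections / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.005


class TestGroupComparisonTable:
    def test_schema_matches_published_row_set(self):
        clin = simulate_clinical_table(table4_clinical_config(), seed=9)
        positive = pd.Series(clin["group"] == "marker_positive", index=clin.index)
        report = group_comparison_table(clin, positive)
        assert set(report["covariate"]) == {
            "age",
            "duration_of_illness",
            "hospitalizations",
            "panss_total",
            "panss_positive",
            "panss_negative",
            "panss_general",
            "sex",
            "clozapine",
            "language",
            "handedness",
        }
        assert (report["p"] <= 1.0).all() and (report["p"] >= 0.0).all()

    def test_identical_covariates_give_trivial_pvalues(self):
        clin = pd.DataFrame(
            {
                "group": ["a"] * 6 + ["b"] * 6,
                "age": 30.0,
                "sex": "male",
            },
            index=[f"s{i}" for i in range(12)],
        )
        positive = pd.Series(clin["group"] == "b", index=clin.index)
        report = group_comparison_table(
            clin, positive, {"age": "anova", "sex": "chisq"}
        )
        assert (report["p"] >= 0.99).all()

    def test_deterministic_given_input(self):
        clin = simulate_clinical_table(table4_clinical_config(), seed=10)
        positive = pd.Series(clin["group"] == "marker_positive", index=clin.index)
        a = group_comparison_table(clin, positive)
        b = group_comparison_table(clin, positive)
        pd.testing.assert_frame_equal(a, b)
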