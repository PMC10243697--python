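import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from actisleep import ancova, chi2_independence, normality, ttest_from_summary, ttest_ind, ttest_rel


def moment_matched(mean, sd, n, seed=0):
    """A sample with exactly the requested mean and SD (ddof=1)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestIndependentT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ttest_ind(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_printed_age_comparison(self):
        """Group ages 30.3 +/- 8.7 (n=40) vs 25.8 +/- 5.6 (n=35): pooled
        t about 2.62 on 73 df, p about 0.011."""
        x = moment_matched(30.3, 8.7, 40, seed=1)
        y = moment_matched(25.8, 5.6, 35, seed=2)
        res = ttest_ind(x, y)
        if res.extra["equal_var"]:
            assert res.df == 73
            assert res.statistic == pytest.approx(2.62, abs=0.02)
            assert res.p == pytest.approx(0.011, abs=0.002)
        else:  # Levene on these realized samples chose Welch
            assert res.p < 0.05

    def test_matches_textbook_formula_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(0, 1, size=rng.integers(5, 30))
            y = rng.normal(0.3, 1, size=rng.integers(5, 30))
            res = ttest_ind(x, y)
            n1, n2 = len(x), len(y)
            if res.extra["equal_var"]:
                sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
                t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
                df = n1 + n2 - 2
            else:
                v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
                t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
                df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-8)
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), df), abs=1e-10)

    def test_swapping_groups_negates_t_preserves_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        a, b = ttest_ind(x, y), ttest_ind(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_constant_equal_samples(self):
        res = ttest_ind([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p == 1.0


class TestSummaryT:
    def test_printed_literature_comparison(self):
        """Published group (1.03 +/- 1.02, n=40) against a reference
        sample whose size is recovered from the printed df = 637."""
        res = ttest_from_summary(1.03, 1.02, 40, 1.33, 0.88, 599)
        assert res.df == 637
        assert res.statistic == pytest.approx(2.07, abs=0.01)
        assert res.se == pytest.approx(0.145, abs=0.002)
        assert res.p == pytest.approx(0.04, abs=0.005)

    def test_equal_means_zero_t(self):
        assert ttest_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12).statistic == 0.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.floats(-5, 5), st.floats(0.2, 3), st.integers(5, 40),
        st.floats(-5, 5), st.floats(0.2, 3), st.integers(5, 40),
        st.integers(0, 10_000),
    )
    def test_agrees_with_pooled_ttest_on_moment_matched_samples(self, m1, sd1, n1, m2, sd2, n2, seed):
        x = moment_matched(m1, sd1, n1, seed=seed)
        y = moment_matched(m2, sd2, n2, seed=seed + 1)
        summary = ttest_from_summary(m1, sd1, n1, m2, sd2, n2)
        pooled = sps.ttest_ind(y, x, equal_var=True)
        assert summary.statistic == pytest.approx(float(pooled.statistic), abs=1e-8)
        assert summary.p == pytest.approx(float(pooled.pvalue), abs=1e-10)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            ttest_from_summary(1, 1.0, 1, 2, 1.0, 10)


class TestPairedT:
    def test_zero_differences(self):
        x = np.array([1.0, 2.0, 3.0])
        res = ttest_rel(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_mean_difference_reported(self):
        # degenerate pairs carrying the group-mean rise times: the mean
        # weekday-weekend delta is 7:05 - 8:17 = -1.20 h
        workday = np.full(5, 7 + 5 / 60)
        weekend = np.full(5, 8 + 17 / 60)
        res = ttest_rel(workday + np.array([-0.01, 0.01, 0.0, -0.02, 0.02]), weekend)
        assert res.estimate == pytest.approx(-1.20, abs=1e-9)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 15), rng.normal(0.4, 1, 15)
        res = ttest_rel(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == len(d) - 1

    def test_incomplete_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0])
        y = np.array([1.5, 2.5, 3.0, 4.5])
        res = ttest_rel(x, y)
        assert res.extra["n_pairs"] == 3


def ancova_design_n8():
    """Small fixed design: 2x2 factors plus an age covariate."""
    return pd.DataFrame(
        {
            "outcome": [7.1, 7.9, 6.8, 8.3, 7.5, 6.9, 8.1, 7.2],
            "group": ["onsite", "onsite", "onsite", "onsite",
                      "home_office", "home_office", "home_office", "home_office"],
            "sex": ["male", "female", "male", "female"] * 2,
            "age": [30.0, 28.0, 35.0, 22.0, 26.0, 24.0, 29.0, 23.0],
        }
    )


class TestAncova:
    def test_group_f_matches_nested_rss_oracle(self):
        data = ancova_design_n8()
        res = ancova(data, "outcome")

        y = data["outcome"].to_numpy()
        g = np.where(data["group"] == "home_office", 1.0, -1.0)
        s = np.where(data["sex"] == "female", 1.0, -1.0)
        age = data["age"].to_numpy()
        X_full = np.column_stack([np.ones(8), g, s, age])
        X_red = np.column_stack([np.ones(8), s, age])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        f_oracle = (rss(X_red) - rss(X_full)) / 1.0 / (rss(X_full) / (8 - 4))
        assert res.statistic == pytest.approx(f_oracle, abs=1e-8)
        assert res.extra["df_num"] == 1
        assert res.df == 4

    def test_no_adjustment_identity(self):
        """With a balanced design and an age coefficient of exactly zero,
        the EMMs equal the raw group means."""
        data = ancova_design_n8().copy()
        # outcome exactly linear in group and sex: the unique least-squares
        # fit has a zero age coefficient, so EMMs are unadjusted
        g = (data["group"] == "onsite").astype(float)
        s = (data["sex"] == "female").astype(float)
        data["outcome"] = 7.0 + 0.5 * g + 0.2 * s
        res = ancova(data, "outcome")
        raw = data.groupby("group")["outcome"].mean()
        for grp in ("onsite", "home_office"):
            assert res.emms[grp]["mean"] == pytest.approx(raw[grp], abs=1e-8)

    def test_adjustment_beats_raw_difference_under_confounding(self):
        """With a known group effect confounded by age, the EMM difference
        is closer to the truth than the raw mean difference."""
        rng = np.random.default_rng(21)
        n = 120
        group = np.repeat(["onsite", "home_office"], n // 2)
        age = np.where(group == "onsite", 31.0, 25.0) + rng.normal(0, 4, n)
        true_effect = 0.5
        y = 5.0 + 0.08 * age + np.where(group == "home_office", true_effect, 0.0) + rng.normal(0, 0.3, n)
        data = pd.DataFrame({"outcome": y, "group": group, "age": age,
                             "sex": np.tile(["male", "female"], n // 2)})
        res = ancova(data, "outcome")
        raw_diff = data.loc[group == "home_office", "outcome"].mean() - data.loc[group == "onsite", "outcome"].mean()
        emm_diff = res.emms["home_office"]["mean"] - res.emms["onsite"]["mean"]
        assert abs(emm_diff - true_effect) < abs(raw_diff - true_effect)

    def test_f_reduces_to_anova_without_age_signal(self):
        data = ancova_design_n8().copy()
        data["age"] = 27.0  # constant covariate would be aliased
        with pytest.raises(ValueError, match="rank|aliased"):
            ancova(data, "outcome")


class TestChi2:
    def test_proportional_table_zero_statistic(self):
        res = chi2_independence([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_sex_table_hand_computation(self):
        """2x2 sex-by-group counts [[15,25],[9,26]]: Pearson statistic by
        direct expected-count arithmetic is about 1.19 on 1 df."""
        table = np.array([[15, 25], [9, 26]], dtype=float)
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        hand = float(((table - expected) ** 2 / expected).sum())
        res = chi2_independence(table)
        assert res.statistic == pytest.approx(hand, abs=1e-12)
        assert res.statistic == pytest.approx(1.19, abs=0.02)
        assert res.df == 1

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            table = rng.integers(1, 40, size=(2, rng.integers(2, 5))).astype(float)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            hand = float(((table - expected) ** 2 / expected).sum())
            res = chi2_independence(table)
            assert res.statistic == pytest.approx(hand, abs=1e-10)
            assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_independence([[0, 0], [5, 5]])


class TestNormality:
    def test_normal_sample_passes_both(self):
        rng = np.random.default_rng(2)
        ks, sw = normality(rng.standard_normal(300))
        assert ks.p > 0.05 and sw.p > 0.05
        assert ks.extra["estimated_params"] is True

    def test_bimodal_sample_fails_shapiro(self):
        rng = np.random.default_rng(4)
        sample = np.concatenate([rng.normal(-4, 0.3, 150), rng.normal(4, 0.3, 150)])
        _, sw = normality(sample)
        assert sw.p < 0.05

    def test_deterministic_fixture_matches_scipy_oracle(self):
        sample = np.array([4.1, 3.9, 5.0, 4.4, 3.6, 4.8, 4.2, 4.0, 4.6, 3.8])
        _, sw = normality(sample)
        stat, p = sps.shapiro(sample)
        assert sw.statistic == pytest.approx(float(stat), abs=1e-12)
        assert sw.p == pytest.approx(float(p), abs=1e-12)

    def test_constant_sample_degenerate(self):
        ks, sw = normality([3.0] * 10)
        assert ks.extra["degenerate"] and sw.extra["degenerate"]
        assert np.isnan(sw.p)
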