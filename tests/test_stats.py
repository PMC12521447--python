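import numpy as np
import pandas as pd
import pytest

from ldaep_lab import stats as st
from ldaep_lab.cohort import CohortSpec, generate_cohort


def moment_sample(mean, sd, n, seed=0):
    """Sample with exactly the requested first two moments."""
    x = np.random.default_rng(seed).standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestNormalityScreen:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(10)
        passes = sum(st.ks_normality(rng.standard_normal(500))[1] > 0.05
                     for _ in range(200))
        assert passes >= 180

    def test_exponential_samples_usually_fail(self):
        rng = np.random.default_rng(11)
        fails = sum(st.ks_normality(rng.exponential(size=500))[1] < 0.05
                    for _ in range(200))
        assert fails >= 180

    def test_constant_input_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            stat, p = st.ks_normality(np.full(10, 3.0))
        assert np.isnan(stat)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            st.ks_normality(np.array([1.0, 2.0, 3.0]))


class TestOneWayAnova:
    def test_hand_computed_six_numbers(self):
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        groups = np.array(list("aaabbb"))
        a = st.one_way_anova(vals, groups)
        assert a.F == pytest.approx(13.5, abs=1e-10)
        assert (a.df1, a.df2) == (1, 4)

    def test_identical_means_give_zero_f(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        a = st.one_way_anova(vals, np.array(list("aaabbb")))
        assert a.F == pytest.approx(0.0, abs=1e-12)
        assert a.partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 9)
        a = st.one_way_anova(np.r_[x, y], np.r_[["x"] * 12, ["y"] * 9])
        t = st.two_sample_t_and_d(x, y)
        assert a.F == pytest.approx(t["t"] ** 2, abs=1e-10)
        assert a.mean_diff == pytest.approx(t["mean_diff"], abs=1e-12)
        assert a.mean_diff_ci[0] == pytest.approx(t["ci"][0], abs=1e-12)

    def test_eta_identity_for_every_reported_f(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            vals = rng.normal(size=20)
            g = rng.choice(list("abc"), size=20)
            if min(np.sum(g == c) for c in "abc") < 2:
                continue
            a = st.one_way_anova(vals, g)
            assert a.partial_eta_sq == pytest.approx(
                a.F * a.df1 / (a.F * a.df1 + a.df2), abs=1e-12)
            assert 0.0 <= a.eta_ci[0] <= a.partial_eta_sq
            assert a.eta_ci[1] == 1.0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            st.one_way_anova(np.arange(4.0), np.array(["a", "a", "a", "b"]))


def brute_force_type2(df, outcome, terms):
    """Independent Type-II oracle: SS by explicit model-comparison refits
    using plain numpy least squares on dummy-coded designs."""

    def design(cols):
        mats = [np.ones((len(df), 1))]
        for c in cols:
            v = df[c]
            if v.dtype == object or str(v.dtype) == "category":
                levels = sorted(v.unique())[1:]
                mats.append(np.column_stack([(v == l).astype(float) for l in levels]))
            else:
                mats.append(v.to_numpy(float)[:, None])
        return np.hstack(mats)

    def sse(cols):
        X = design(cols)
        y = df[outcome].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full = sse(terms)
    return {t: sse([u for u in terms if u != t]) - full for t in terms}, full


class TestAncovaType2:
    def make_cohort_df(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "group2": rng.choice(["a", "b"], size=n),
            "age": rng.normal(25, 4, n),
            "bdi_cognitive": rng.poisson(5, n).astype(float),
            "bdi_somatic_affective": rng.poisson(5, n).astype(float),
        })
        df["y"] = (rng.normal(size=n) + 0.5 * (df.group2 == "b")
                   + 0.02 * df.age + 0.03 * df.bdi_cognitive)
        return df

    def test_matches_brute_force_oracle(self):
        for seed in range(8):
            df = self.make_cohort_df(n=25, seed=seed)
            res = st.ancova_type2(df, "y", "group2")
            terms = ["group2", "age", "bdi_cognitive", "bdi_somatic_affective"]
            oracle, sse_full = brute_force_type2(df, "y", terms)
            got = dict(zip(
                ["group2", "age", "bdi_cognitive", "bdi_somatic_affective"],
                [res.table.loc["C(group2)", "sum_sq"],
                 res.table.loc["age", "sum_sq"],
                 res.table.loc["bdi_cognitive", "sum_sq"],
                 res.table.loc["bdi_somatic_affective", "sum_sq"]]))
            for t in terms:
                assert got[t] == pytest.approx(oracle[t], abs=1e-8)

    def test_orthogonal_design_type2_equals_type1(self):
        rng = np.random.default_rng(3)
        n = 40
        g = np.repeat(["a", "b"], n // 2)
        cov = np.tile([-1.0, 1.0], n // 2)  # orthogonal to the balanced group
        df = pd.DataFrame({"group2": g, "age": cov,
                           "bdi_cognitive": np.zeros(n) + np.tile([-1.0, 1.0], n // 2)[::-1],
                           "bdi_somatic_affective": rng.normal(size=n)})
        df["y"] = rng.normal(size=n)
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        model = ols("y ~ C(group2) + age", data=df).fit()
        t1 = anova_lm(model, typ=1)
        t2 = anova_lm(model, typ=2)
        assert t1.loc["C(group2)", "sum_sq"] == pytest.approx(
            t2.loc["C(group2)", "sum_sq"], abs=1e-10)

    def test_group_f_close_to_anova_with_uncorrelated_covariates(self):
        rng = np.random.default_rng(4)
        n = 5000
        g = rng.choice(["a", "b"], size=n)
        df = pd.DataFrame({
            "group2": g,
            "age": rng.normal(25, 4, n),
            "bdi_cognitive": rng.normal(5, 2, n),
            "bdi_somatic_affective": rng.normal(5, 2, n),
            "y": rng.normal(size=n) + 0.1 * (g == "b"),
        })
        anc = st.ancova_type2(df, "y", "group2")
        av = st.one_way_anova(df["y"].to_numpy(), g)
        f_anc = float(anc.table.loc["C(group2)", "F"])
        assert f_anc == pytest.approx(av.F, rel=0.05)

    def test_emm_vif_r2_contracts(self):
        df = self.make_cohort_df(n=60, seed=9)
        res = st.ancova_type2(df, "y", "group2")
        assert all(v >= 1.0 for v in res.vif.values())
        assert res.r2_adj <= res.r2
        # EMM difference equals the group coefficient
        emm_diff = res.emmeans["b"][0] - res.emmeans["a"][0]
        from statsmodels.formula.api import ols

        model = ols("y ~ C(group2) + age + bdi_cognitive + bdi_somatic_affective",
                    data=df).fit()
        assert emm_diff == pytest.approx(model.params["C(group2)[T.b]"], abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        df = self.make_cohort_df(n=30, seed=5)
        df["bdi_somatic_affective"] = df["bdi_cognitive"]  # collinear
        with pytest.raises(ValueError):
            st.ancova_type2(df, "y", "group2")

    def test_missing_columns_listed(self):
        df = pd.DataFrame({"y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="age"):
            st.ancova_type2(df, "y", "group2")


def fisher_enumeration(table):
    """Exhaustive two-sided Fisher p: sum hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


class TestRankAndExactTests:
    def test_phase_by_group_contingency(self):
        counts = np.array([[8, 4, 2], [6, 4, 1], [6, 6, 3]])
        chi2, p = st.rank_and_exact_tests("chi_square", counts=counts)
        assert chi2 == pytest.approx(1.28, abs=0.005)
        assert p == pytest.approx(0.865, abs=0.001)

    def test_independent_2x2(self):
        counts = np.array([[5, 5], [5, 5]])
        chi2, _ = st.rank_and_exact_tests("chi_square", counts=counts)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        _, p = st.rank_and_exact_tests("fisher", counts=counts)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[13, 10], [14, 3]], [[1, 9], [11, 3]], [[5, 0], [1, 4]], [[2, 2], [2, 2]],
    ])
    def test_fisher_matches_enumeration_oracle(self, table):
        _, p = st.rank_and_exact_tests("fisher", counts=np.array(table))
        assert p == pytest.approx(fisher_enumeration(table), abs=1e-10)

    def test_chi_square_additivity_of_cell_contributions(self):
        counts = np.array([[10.0, 20], [30, 15]])
        chi2, _ = st.rank_and_exact_tests("chi_square", counts=counts)
        row = counts.sum(axis=1, keepdims=True)
        col = counts.sum(axis=0, keepdims=True)
        expected = row * col / counts.sum()
        assert chi2 == pytest.approx(((counts - expected) ** 2 / expected).sum())

    def test_wilcoxon_shift_detected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(1.0, 1, 30)
        y = rng.normal(0.0, 1, 25)
        w, p = st.rank_and_exact_tests("wilcoxon", x=x, y=y)
        assert p < 0.01
        assert 0 <= w <= 30 * 25

    def test_wilcoxon_handles_ties(self):
        x = np.array([1, 1, 2, 2, 3, 3, 4])
        y = np.array([1, 2, 2, 3, 3, 4, 4])
        w, p = st.rank_and_exact_tests("wilcoxon", x=x, y=y)
        assert 0 < p <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            st.rank_and_exact_tests("chi_square", counts=np.array([[1, -2], [3, 4]]))


class TestTTestAndD:
    def test_identical_samples_null(self):
        x = np.array([1.0, 2, 3, 4])
        r = st.two_sample_t_and_d(x, x.copy())
        assert r["t"] == pytest.approx(0.0, abs=1e-12)
        assert r["d"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_four_numbers(self):
        r = st.two_sample_t_and_d(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        assert r["mean_diff"] == pytest.approx(-1.0)
        assert r["d"] == pytest.approx(-1.414, abs=5e-4)

    def test_group_summary_moments_reproduce_reported_difference(self):
        """Exact-moment samples at the published group summaries give the
        published mean difference and its 95% CI."""
        x = moment_sample(-0.080, 0.033, 30, seed=1)
        y = moment_sample(-0.052, 0.040, 24, seed=2)
        r = st.two_sample_t_and_d(x, y)
        assert r["mean_diff"] == pytest.approx(-0.028, abs=1e-9)
        assert r["ci"][0] == pytest.approx(-0.048, abs=5e-4)
        assert r["ci"][1] == pytest.approx(-0.008, abs=5e-4)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            st.two_sample_t_and_d(np.ones(3), np.ones(4))

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.5, 10)
        y = rng.normal(0, 3.0, 40)
        pooled = st.two_sample_t_and_d(x, y, pooled=True)
        welch = st.two_sample_t_and_d(x, y, pooled=False)
        assert welch["df"] < pooled["df"]


class TestPower:
    def test_saturated_effect_needs_minimum_n(self):
        n, pw = st.power_two_sample_t(st.PowerSpec(d=1000.0))
        assert n == 4
        assert pw > 0.999

    def test_bracketing_self_consistency(self):
        spec = st.PowerSpec(d=0.77, alpha=0.05, power=0.80, tails=2)
        n, pw = st.power_two_sample_t(spec)
        assert pw >= 0.80
        assert st.power_at_n(n // 2 - 1, n // 2 - 1, 0.77) < 0.80

    def test_monte_carlo_oracle(self):
        """Achieved power agrees with direct simulation of the pooled t-test."""
        n1 = n2 = 27
        d = 0.77
        reps = 50_000
        rng = np.random.default_rng(12345)
        x = rng.standard_normal((reps, n1)) + d
        y = rng.standard_normal((reps, n2))
        v1 = x.var(axis=1, ddof=1)
        v2 = y.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        from scipy.stats import t as tdist

        tcrit = tdist.ppf(0.975, n1 + n2 - 2)
        mc = np.mean(np.abs(t) > tcrit)
        assert st.power_at_n(n1, n2, d) == pytest.approx(mc, abs=0.01)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            st.power_two_sample_t(st.PowerSpec(d=0.0))

    def test_unreachable_power_capped(self):
        with pytest.raises(ValueError, match="unreachable"):
            st.power_two_sample_t(st.PowerSpec(d=1e-4, n_cap=500))


class TestGroupAnalysis:
    @pytest.fixture(scope="class")
    def cohort_with_slopes(self):
        _, table = generate_cohort(CohortSpec(seed=8))
        df = table.copy()
        df["n1_slope"] = df["true_n1_slope"]
        df["p2_slope"] = df["true_p2_slope"]
        df["n1p2_slope"] = df["true_n1p2_slope"]
        return df

    def test_report_shape(self, cohort_with_slopes):
        tabs = st.run_group_analysis(cohort_with_slopes)
        assert len(tabs["anova"]) == 3
        assert len(tabs["ancova"]) == 3
        assert set(tabs["anova"]["outcome"]) == {"n1_slope", "p2_slope", "n1p2_slope"}
        assert {"F", "p", "partial_eta_sq", "mean_diff"} <= set(tabs["anova"].columns)

    def test_group_merge(self, cohort_with_slopes):
        df = st.merge_groups(cohort_with_slopes)
        assert set(df["group2"]) == {"current_user", "non_user"}
        assert (df.loc[df.group == "past_user", "group2"] == "non_user").all()

    def test_single_group_cohort_skips_between_group_analyses(self, cohort_with_slopes):
        users_only = cohort_with_slopes[
            cohort_with_slopes["group"] == "current_user"].copy()
        tabs = st.run_group_analysis(users_only)
        assert len(tabs["anova"]) == 0
        assert any("between-group" in n for n in tabs["notices"]["notice"])

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="missing required columns"):
            st.run_group_analysis(pd.DataFrame({"group": ["current_user"]}))

    def test_null_cohorts_type_i_error_calibrated(self):
        """ANOVA on cohorts where both groups share one distribution rejects
        at ~alpha."""
        rng = np.random.default_rng(99)
        reps = 400
        rej = 0
        g = np.r_[["u"] * 30, ["n"] * 24]
        for _ in range(reps):
            vals = rng.normal(-0.052, 0.040, 54)
            a = st.one_way_anova(vals, g)
            rej += a.p < 0.05
        assert 0.02 <= rej / reps <= 0.09
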