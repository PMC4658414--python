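import numpy as np
import pandas as pd
import pytest

from motordcm.stats import (
    ancova_f,
    ancova_per_connection,
    bonferroni_threshold,
    build_design,
    pairwise_posthoc,
    partial_correlation,
)


def toy_table(seed=0, n_per_group=3, noise=0.0, effect=(0.0, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    rows = []
    for g, (label, eff) in enumerate(zip(("HC", "earlyHD", "preHD"), effect)):
        for k in range(n_per_group):
            age = 30 + 5 * g + 2 * k
            rows.append({
                "group": label,
                "age": age,
                "y": eff + 0.02 * age + noise * rng.standard_normal(),
            })
    return pd.DataFrame(rows)


class TestAncova:
    def test_identical_group_means_give_zero_f(self):
        table = toy_table(effect=(0.0, 0.0, 0.0))
        G, X0, _ = build_design(table, covariates=("age",))
        F, df, p = ancova_f(table.y.to_numpy(), G, X0)
        assert F == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels_extra_ss(self):
        """9 subjects, 3 groups, 1 covariate: F and p to 1e-8 against an
        independently fitted nested-model comparison."""
        import statsmodels.formula.api as smf

        table = toy_table(seed=1, noise=0.3, effect=(0.0, 0.4, -0.2))
        G, X0, _ = build_design(table, covariates=("age",))
        F, df, p = ancova_f(table.y.to_numpy(), G, X0)
        full = smf.ols("y ~ C(group) + age", data=table).fit()
        red = smf.ols("y ~ age", data=table).fit()
        F_sm, p_sm, df_sm = full.compare_f_test(red)
        assert F == pytest.approx(F_sm, abs=1e-8)
        assert p == pytest.approx(p_sm, abs=1e-8)
        assert df == (int(df_sm), int(full.df_resid))

    def test_type_one_error_calibrated(self):
        """Null simulation: rejection rate at alpha=0.05 within (0.03, 0.07)."""
        rng = np.random.default_rng(42)
        n, reps = 150, 1000
        groups = np.repeat(["a", "b", "c"], 50)
        age = rng.normal(45, 9, n)
        gender = rng.choice(["F", "M"], n)
        rejections = 0
        base = pd.DataFrame({"group": groups, "age": age, "gender": gender})
        G, X0, _ = build_design(base, covariates=("age", "gender"))
        from scipy.stats import f as fdist
        for _ in range(reps):
            y = rng.standard_normal(n)
            F, df, p = ancova_f(y, G, X0)
            rejections += p < 0.05
        assert 0.03 < rejections / reps < 0.07

    def test_invariant_to_covariate_rescaling(self):
        table = toy_table(seed=2, noise=0.5, effect=(0, 0.3, 0.6))
        G, X0, _ = build_design(table, covariates=("age",))
        F1, _, _ = ancova_f(table.y.to_numpy(), G, X0)
        table2 = table.assign(age=table.age * 13.7 + 100)
        G2, X02, _ = build_design(table2, covariates=("age",))
        F2, _, _ = ancova_f(table2.y.to_numpy(), G2, X02)
        assert F1 == pytest.approx(F2, rel=1e-10)

    def test_invariant_to_row_permutation(self):
        table = toy_table(seed=3, noise=0.5, effect=(0, 0.3, 0.6), n_per_group=6)
        perm = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        for t in (table, perm):
            G, X0, _ = build_design(t, covariates=("age",))
            t.attrs["F"] = ancova_f(t.y.to_numpy(), G, X0)[0]
        assert table.attrs["F"] == pytest.approx(perm.attrs["F"], rel=1e-10)

    def test_orthogonal_covariates_reduce_to_anova_on_residuals(self):
        """Covariate orthogonal to group: ANCOVA F equals one-way ANOVA F of
        the covariate-residualised response."""
        from scipy.stats import f_oneway

        rng = np.random.default_rng(6)
        n_per = 20
        groups = np.repeat(["a", "b", "c"], n_per)
        cov = np.tile(rng.standard_normal(n_per), 3)  # identical per group
        cov = cov - cov.mean()
        y = np.repeat([0.0, 0.5, 1.0], n_per) + 0.8 * cov + rng.standard_normal(3 * n_per)
        table = pd.DataFrame({"group": groups, "age": cov, "y": y})
        G, X0, _ = build_design(table, covariates=("age",))
        F, _, _ = ancova_f(y, G, X0)
        Z = np.column_stack([np.ones(len(y)), cov])
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        F_ref = f_oneway(*[resid[groups == g] for g in ("a", "b", "c")]).statistic
        # the residualised ANOVA loses one denominator df; rescale
        df2_ancova = len(y) - 2 - 2
        df2_anova = len(y) - 3
        assert F == pytest.approx(F_ref * df2_ancova / df2_anova, rel=1e-8)

    def test_rank_deficient_design_raises(self):
        table = toy_table()
        table["age2"] = table.age  # collinear copy
        with pytest.raises(ValueError, match="rank-deficient"):
            G, X0, _ = build_design(table, covariates=("age", "age2"))
            ancova_f(table.y.to_numpy(), G, X0)

    def test_per_connection_bonferroni_flags(self):
        rng = np.random.default_rng(8)
        n = 60
        table = pd.DataFrame({
            "group": np.repeat(["HC", "preHD", "earlyHD"], n // 3),
            "age": rng.normal(45, 8, n),
            "gender": rng.choice(["F", "M"], n),
            "site": rng.choice(list("ABCD"), n),
            "education": rng.normal(13, 3, n),
            "null_conn": rng.standard_normal(n),
            "strong_conn": np.repeat([0.0, 0.0, 2.0], n // 3) + 0.1 * rng.standard_normal(n),
        })
        results = ancova_per_connection(table, ["null_conn", "strong_conn"], n_tests=47)
        by_name = {r.connection: r for r in results}
        assert by_name["strong_conn"].significant_bonferroni
        assert not by_name["null_conn"].significant_bonferroni


class TestBonferroni:
    def test_connection_family_of_47(self):
        assert bonferroni_threshold(47, 0.05) == pytest.approx(0.0010638, abs=1e-7)

    def test_single_test(self):
        assert bonferroni_threshold(1, 0.05) == 0.05

    def test_three_group_posthoc_family(self):
        assert bonferroni_threshold(3, 0.05) == pytest.approx(0.016667, abs=1e-6)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestPairwisePosthoc:
    def three_group_table(self):
        return pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "y": [1.0, 2, 3, 4, 5, 6, 7, 8, 9],
        })

    def test_pooled_t_closed_form(self):
        """(1,2,3) vs (4,5,6) with pooled within-group variance 1:
        t = -3/sqrt(2/3) = -3.674, df from the pooled model, p tripled."""
        res = pairwise_posthoc(self.three_group_table(), "y", covariates=())
        ab = [r for r in res if (r.group_a, r.group_b) == ("a", "b")][0]
        assert ab.t == pytest.approx(-3.6742346, abs=1e-6)
        assert ab.p_adjusted == pytest.approx(min(1.0, 3 * ab.p_raw))

    def test_identical_pair_distributions(self):
        table = pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "y": [1.0, 2, 3, 1, 2, 3, 9, 10, 11],
        })
        res = pairwise_posthoc(table, "y", covariates=())
        ab = [r for r in res if (r.group_a, r.group_b) == ("a", "b")][0]
        assert ab.t == pytest.approx(0.0, abs=1e-12)
        assert ab.p_adjusted == 1.0

    def test_adjusted_p_capped_at_one(self):
        res = pairwise_posthoc(self.three_group_table(), "y", covariates=())
        assert all(r.p_adjusted <= 1.0 for r in res)

    def test_small_group_untestable(self):
        table = pd.DataFrame({
            "group": ["a"] * 4 + ["b"] * 4 + ["c"],
            "y": np.arange(9.0),
        })
        res = pairwise_posthoc(table, "y", covariates=())
        flags = {(r.group_a, r.group_b): r.untestable for r in res}
        assert flags[("a", "c")] and flags[("b", "c")]
        assert not flags[("a", "b")]

    def test_welch_variant_runs(self):
        res = pairwise_posthoc(self.three_group_table(), "y", covariates=(),
                               welch=True)
        assert len(res) == 3
        assert all(np.isfinite(r.t) for r in res)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 50))
        r, p, n = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert n == 50

    def test_identical_variables(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        z = rng.standard_normal(30)
        r, p, _ = partial_correlation(x, x.copy(), z)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_first_order_formula(self):
        """Matches the inverse-correlation-matrix (textbook) expression."""
        rng = np.random.default_rng(2)
        z = rng.standard_normal(200)
        x = 0.6 * z + rng.standard_normal(200)
        y = -0.4 * z + 0.3 * x + rng.standard_normal(200)
        r, p, n = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_constant_residual_raises(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(2 * z + 1, np.random.default_rng(0).standard_normal(10), z)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            partial_correlation(np.ones(3), np.ones(3), np.ones((3, 2)))
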