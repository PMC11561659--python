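"""Cohort statistics: partial correlation, FDR, ANCOVA, Fisher z, trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sandimri.stats import (
    assign_age_group,
    build_results_table,
    compare_groups_ancova,
    fdr_adjust,
    fisher_z_compare,
    ks_normality,
    partial_pearson,
    polynomial_age_fit,
)


def brute_force_bh(p):
    """Step-up threshold search: adj p_i = min_{j: p_j >= p_i} p_(j) m / rank."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = p[order] * m / (np.arange(m) + 1)
    # step-up: running minimum from the largest p downwards
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj_sorted, 0, 1)
    return out


class TestPartialPearson:
    def test_identity_gives_r_one(self):
        x = np.arange(6.0)
        res = partial_pearson(x, x)
        assert res.r == pytest.approx(1.0)

    def test_matches_residualize_then_correlate_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        z = np.array([0.0, 0, 0, 1, 1, 1])
        res = partial_pearson(x, y, z)
        # independent oracle: explicit residuals then plain Pearson
        def resid(v):
            d = np.column_stack([np.ones(6), z])
            beta = np.linalg.lstsq(d, v, rcond=None)[0]
            return v - d @ beta
        oracle_r = sps.pearsonr(resid(x), resid(y))[0]
        assert res.r == pytest.approx(oracle_r, abs=1e-12)

    def test_no_covariates_equals_plain_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_pearson(x, y)
        r, p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_collinear_covariate_rejected(self):
        x = np.arange(10.0)
        y = np.random.default_rng(1).normal(size=10)
        with pytest.raises(ValueError, match="residual variance"):
            partial_pearson(x, y, 2 * x)

    def test_sex_coding_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(size=40)
        sex = rng.integers(0, 2, 40).astype(float)
        a = partial_pearson(x, y, sex)
        b = partial_pearson(x, y, 1.0 - sex)  # swap the binary coding
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)


class TestFDR:
    def test_worked_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_and_dominates_raw(self, p):
        p = np.array(p)
        adj = fdr_adjust(p)
        assert np.allclose(adj, brute_force_bh(p), atol=1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        assert np.allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


def _group_table(young, middle, older, rng):
    frames = []
    for name, vals in (("young", young), ("middle", middle), ("older", older)):
        frames.append(pd.DataFrame({
            "group": name, "value": vals,
            "sex_code": rng.integers(0, 2, len(vals)).astype(float)}))
    return pd.concat(frames, ignore_index=True)


class TestANCOVA:
    def test_identical_groups_give_zero_f(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=12)
        t = _group_table(base, base, base, np.random.default_rng(0))
        # exact copies: same sex pattern in every group as well
        t["sex_code"] = np.tile(np.array([0.0, 1.0] * 6), 3)
        res = compare_groups_ancova(t, "value")
        assert res.f_stat == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_f_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        t = _group_table(rng.normal(0, 1, 33), rng.normal(0.2, 1, 21),
                         rng.normal(1.0, 1, 18), rng)
        res = compare_groups_ancova(t, "value")
        model = smf.ols("value ~ C(group) + sex_code", data=t).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        assert res.f_stat == pytest.approx(anova.loc["C(group)", "F"],
                                           abs=1e-10)
        assert res.p == pytest.approx(anova.loc["C(group)", "PR(>F)"],
                                      abs=1e-12)

    def test_power_for_one_sd_shift(self):
        # older group shifted by one pooled SD at the study's group sizes:
        # noncentrality sum n_i (mu_i - mu_bar)^2 = 13.5 puts the F(2, 68)
        # power near 0.89, so detection should happen in most seeds
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t = _group_table(rng.normal(0, 1, 33), rng.normal(0, 1, 21),
                             rng.normal(1.0, 1, 18), rng)
            res = compare_groups_ancova(t, "value")
            fdr = fdr_adjust([res.p])[0]
            hits += fdr < 0.05
        assert hits / n_seeds >= 0.85

    def test_three_pairwise_posthoc_with_fdr(self):
        rng = np.random.default_rng(6)
        t = _group_table(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                         rng.normal(2, 1, 10), rng)
        res = compare_groups_ancova(t, "value")
        assert len(res.pairwise) == 3
        for _, (tstat, raw, adj) in res.pairwise.items():
            assert adj >= raw - 1e-12


class TestFisherZ:
    def test_occipital_worked_example(self):
        # published inputs: r1 = -0.69, r2 = -0.31, both n = 72
        z, p = fisher_z_compare(-0.69, 72, -0.31, 72)
        assert round(z, 2) == 3.10
        assert p == pytest.approx(0.002, abs=5e-4)

    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.4, 50, 0.4, 80)
        assert z == 0.0
        assert p == 1.0

    def test_antisymmetry(self):
        z1, _ = fisher_z_compare(-0.7, 60, -0.3, 60)
        z2, _ = fisher_z_compare(-0.3, 60, -0.7, 60)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.3, 50)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.3, 50)


class TestAgeTrends:
    def test_exact_vertex_recovery(self):
        age = np.linspace(19, 85, 72)
        y = -((age - 55.0) ** 2)
        fit = polynomial_age_fit(age, y)
        assert fit.peak_age == pytest.approx(55.0, abs=1e-9)
        assert fit.r2_quadratic == pytest.approx(1.0, abs=1e-12)
        assert fit.concave

    @given(st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_nested_r2_ordering(self, seed):
        rng = np.random.default_rng(seed)
        age = rng.uniform(19, 85, 30)
        y = rng.normal(size=30)
        fit = polynomial_age_fit(age, y)
        assert fit.r2_quadratic >= fit.r2_linear - 1e-12

    def test_peak_only_for_concave_in_range(self):
        age = np.linspace(19, 85, 50)
        fit = polynomial_age_fit(age, (age - 55.0) ** 2)  # convex
        assert fit.peak_age is None and not fit.concave

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            polynomial_age_fit(np.full(10, 40.0), np.arange(10.0))


class TestKSNormality:
    def test_d_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.normal(2.0, 3.0, 40)
        d, _ = ks_normality(v)
        s = np.sort(v)
        cdf = sps.norm.cdf(s, v.mean(), v.std(ddof=1))
        n = len(s)
        oracle = max(np.max(cdf - np.arange(n) / n),
                     np.max((np.arange(n) + 1) / n - cdf))
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_near_normal_sample_passes(self):
        q = sps.norm.ppf((np.arange(50) + 0.5) / 50)
        d, p = ks_normality(q)
        assert p > 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))


class TestResultsTable:
    @staticmethod
    def _cohort(seed, planted_r=-0.75):
        rng = np.random.default_rng(seed)
        n = 72
        age = rng.uniform(19, 85, n)
        sex = rng.integers(0, 2, n).astype(float)
        slope = -0.0015
        sd = abs(slope) * age.std(ddof=1) * np.sqrt(1 / planted_r**2 - 1)
        return pd.DataFrame({
            "region": "cortex", "age": age, "sex_code": sex,
            "f_is": 0.3 + slope * age + rng.normal(0, sd, n),
            "nullm": rng.normal(0.5, 0.1, n),
        })

    def test_planted_correlation_recovered(self):
        hits = 0
        for seed in range(30):
            t = self._cohort(seed)
            out = build_results_table(t, ["f_is"], targets=("age",))
            if -0.85 <= out["r"].iloc[0] <= -0.65:
                hits += 1
        assert hits >= 27  # ~sampling distribution of r at n=72

    def test_null_metric_type_i_control(self):
        sig = 0
        for seed in range(40):
            t = self._cohort(seed)
            out = build_results_table(t, ["f_is", "nullm"], targets=("age",))
            row = out[out["metric"] == "nullm"].iloc[0]
            sig += row["fdr_p"] < 0.05
        assert sig <= 4  # >= 90% of seeds stay non-significant

    def test_schema(self):
        t = self._cohort(0)
        t["volume"] = 0.3 - 0.001 * t["age"]
        out = build_results_table(t, ["f_is"], targets=("age", "volume"))
        assert list(out.columns) == ["metric", "region", "target", "r", "p",
                                     "n", "fdr_p"]
        assert set(out["target"]) == {"age", "volume"}
        assert np.all(out["fdr_p"] >= out["p"] - 1e-12)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            build_results_table(self._cohort(0), ["absent"], targets=("age",))


def test_age_group_assignment_cut_points():
    got = assign_age_group([19, 34, 34.5, 35, 54, 55, 85])
    assert list(got) == ["young", "young", "middle", "middle", "middle",
                         "older", "older"]
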