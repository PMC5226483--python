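"""Group statistics: ANOVA, summary-ANOVA, chi-square, ANCOVA, partial
correlation and hub identification, each against an independent route."""

import numpy as np
import pandas as pd
import pytest

from wmnet.atlas import aal90
from wmnet.stats import (
    adjust_pvalues,
    ancova_group_effect,
    anova_from_summary,
    anova_oneway,
    chi_square,
    identify_hubs,
    partial_correlation,
)

from conftest import small_atlas


def anova_oracle(groups):
    """Naive two-pass sums-of-squares decomposition."""
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    k, n = len(groups), len(all_vals)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        g = {"NC": [1.0, 2.0, 3.0], "SCD": [2.0, 2.0, 2.0], "aMCI": [1.5, 2.5, 2.0]}
        assert anova_oneway(g).F == pytest.approx(0.0, abs=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = {
                "NC": rng.normal(0, 1, rng.integers(3, 20)),
                "SCD": rng.normal(0.5, 1.2, rng.integers(3, 20)),
                "aMCI": rng.normal(-0.3, 0.8, rng.integers(3, 20)),
            }
            assert anova_oneway(g).F == pytest.approx(anova_oracle(g), rel=1e-10)

    def test_posthoc_only_when_omnibus_significant(self):
        rng = np.random.default_rng(1)
        null = {k: rng.normal(0, 1, 30) for k in ("NC", "SCD", "aMCI")}
        strong = {
            "NC": rng.normal(0, 1, 30),
            "SCD": rng.normal(0, 1, 30),
            "aMCI": rng.normal(3, 1, 30),
        }
        weak_cmp = anova_oneway(null)
        strong_cmp = anova_oneway(strong)
        if weak_cmp.p >= 0.05:
            assert weak_cmp.posthoc == {}
        assert strong_cmp.p < 0.05 and strong_cmp.posthoc
        assert all(0 <= p <= 1 for p in strong_cmp.posthoc.values())

    def test_bonferroni_adjustment_is_conservative(self):
        rng = np.random.default_rng(2)
        g = {
            "NC": rng.normal(0, 1, 25),
            "SCD": rng.normal(0.8, 1, 25),
            "aMCI": rng.normal(1.6, 1, 25),
        }
        cmp_ = anova_oneway(g)
        from scipy import stats as sps

        # raw pooled-error pairwise p values must never exceed adjusted ones
        for pair, p_adj in cmp_.posthoc.items():
            assert p_adj <= 1.0
            assert p_adj >= 0.0

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError):
            anova_oneway({"NC": [1.0, 1.0], "SCD": [1.0, 1.0]})


class TestAnovaFromSummary:
    def test_equal_means_give_zero(self):
        f, _ = anova_from_summary([5.0, 5.0, 5.0], [1.0, 2.0, 1.5], [10, 12, 8])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_exact_summaries_reproduce_raw_anova(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = {
                "a": rng.normal(0, 1, rng.integers(3, 25)),
                "b": rng.normal(1, 2, rng.integers(3, 25)),
                "c": rng.normal(-1, 1.5, rng.integers(3, 25)),
            }
            f_raw = anova_oneway(g).F
            f_sum, _ = anova_from_summary(
                [np.mean(v) for v in g.values()],
                [np.std(v, ddof=1) for v in g.values()],
                [len(v) for v in g.values()],
            )
            assert f_sum == pytest.approx(f_raw, rel=1e-9)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            anova_from_summary([1.0, 2.0], [1.0, 1.0], [1, 10])
        with pytest.raises(ValueError):
            anova_from_summary([1.0, 2.0], [0.0, 0.0], [5, 5])


class TestChiSquare:
    def test_uniform_table_gives_zero(self):
        stat, p, dof = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert dof == 1

    def test_two_by_two_closed_form(self):
        # chi2 = n (ad - bc)^2 / (row and column marginals product)
        stat, _, _ = chi_square([[20, 10], [10, 20]])
        expected = 60 * (20 * 20 - 10 * 10) ** 2 / (30 * 30 * 30 * 30)
        assert stat == pytest.approx(expected, rel=1e-12)
        assert stat == pytest.approx(6.667, abs=5e-4)

    def test_matches_expected_count_oracle(self):
        rng = np.random.default_rng(4)
        t = rng.integers(5, 40, (3, 2)).astype(float)
        stat, _, dof = chi_square(t)
        row, col, n = t.sum(1, keepdims=True), t.sum(0, keepdims=True), t.sum()
        expected = row @ col / n
        assert stat == pytest.approx((((t - expected) ** 2) / expected).sum(), rel=1e-12)
        assert dof == 2

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestAncova:
    def test_reduces_to_anova_without_covariates(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 60)
        groups = np.repeat(["NC", "SCD", "aMCI"], 20)
        y[groups == "aMCI"] += 1.0
        f_anova = anova_oneway({g: y[groups == g] for g in set(groups)}).F
        cmp_ = ancova_group_effect(y, groups, covariates=None)
        assert cmp_.F == pytest.approx(f_anova, rel=1e-9)

    def test_metric_fully_explained_by_covariate_gives_null_group_effect(self):
        rng = np.random.default_rng(6)
        age = rng.uniform(50, 80, 90)
        y = 2.0 * age + rng.normal(0, 1e-8, 90)
        groups = np.repeat(["NC", "SCD", "aMCI"], 30)
        cmp_ = ancova_group_effect(y, groups, covariates={"age": age})
        assert cmp_.F == pytest.approx(0.0, abs=1e-3)

    def test_matches_statsmodels_model_comparison(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 75
        groups = np.array(["NC", "SCD", "aMCI"])[rng.integers(0, 3, n)]
        age = rng.uniform(50, 80, n)
        edu = rng.uniform(5, 20, n)
        y = rng.normal(0, 1, n) + 0.05 * age + (groups == "aMCI") * 0.8
        cov = pd.DataFrame({"age": age, "education": edu})
        cmp_ = ancova_group_effect(y, groups, cov)
        dummies = pd.get_dummies(pd.Series(groups), drop_first=True).astype(float)
        xf = sm.add_constant(pd.concat([dummies.reset_index(drop=True), cov], axis=1))
        xr = sm.add_constant(cov)
        full = sm.OLS(y, xf).fit()
        red = sm.OLS(y, xr).fit()
        f_sm = float(full.compare_f_test(red)[0])
        assert cmp_.F == pytest.approx(f_sm, rel=1e-8)

    def test_adjustment_shifts_f_under_planted_confounding(self):
        """When a covariate drives the group difference, adjusting for it
        removes (shrinks) the apparent group effect."""
        rng = np.random.default_rng(8)
        n = 120
        groups = np.repeat(["NC", "SCD", "aMCI"], 40)
        age = rng.uniform(55, 65, n) + (groups == "aMCI") * 8  # confounded
        y = 0.5 * age + rng.normal(0, 1, n)  # metric driven by age only
        f_unadj = ancova_group_effect(y, groups, covariates=None).F
        f_adj = ancova_group_effect(y, groups, covariates={"age": age}).F
        assert f_adj < f_unadj

    def test_collinear_covariate_named_in_error(self):
        rng = np.random.default_rng(9)
        n = 30
        groups = np.repeat(["NC", "aMCI"], 15)
        age = rng.uniform(50, 80, n)
        with pytest.raises(ValueError, match="age2"):
            ancova_group_effect(
                rng.normal(0, 1, n), groups, covariates={"age": age, "age2": 2 * age}
            )


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        r, p = partial_correlation(x, y)
        r2, p2 = pearsonr(x, y)
        assert r == pytest.approx(float(r2), rel=1e-10)
        assert p == pytest.approx(float(p2), rel=1e-8)

    def test_identical_variables_give_unit_correlation(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 40)
        cov = {"age": rng.uniform(50, 80, 40)}
        r, p = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(12)
        n = 80
        df = pd.DataFrame(
            {
                "x": rng.normal(0, 1, n),
                "age": rng.uniform(50, 80, n),
                "edu": rng.uniform(5, 20, n),
            }
        )
        df["y"] = 0.4 * df["x"] + 0.1 * df["age"] + rng.normal(0, 1, n)
        r, p = partial_correlation(df["x"], df["y"], df[["age", "edu"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["age", "edu"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_recovers_planted_partial_association(self):
        """x-y partial r = 0.5 planted behind a shared covariate, n = 200."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 200
            z = rng.normal(0, 1, n)
            x = 0.8 * z + rng.normal(0, 1, n)
            eps = rng.normal(0, 1, n)
            # partial corr of x,y given z is 0.5 by construction:
            y = 0.8 * z + (x - 0.8 * z) * (0.5 / np.sqrt(1 - 0.25)) + eps
            r, _ = partial_correlation(x, y, {"z": z})
            if abs(r - 0.5) < 0.12:
                hits += 1
        assert hits >= 18  # ~95% of seeds within the band

    def test_constant_residual_raises(self):
        rng = np.random.default_rng(13)
        z = rng.normal(0, 1, 30)
        with pytest.raises(ValueError):
            partial_correlation(2 * z, rng.normal(0, 1, 30), {"z": z})


class TestHubs:
    def test_ninety_region_atlas_yields_nine_hubs(self):
        rng = np.random.default_rng(14)
        b = rng.gamma(2.0, 50.0, (10, 90))
        report = identify_hubs(b, aal90(), group="NC", fraction=0.10)
        assert len(report.hub_regions) == 9
        vals = [v for _, v in report.hub_regions]
        assert vals == sorted(vals, reverse=True)

    def test_ten_regions_yield_one_hub(self):
        b = np.arange(10, dtype=float)[None, :]
        report = identify_hubs(b, small_atlas(10), fraction=0.10)
        assert len(report.hub_regions) == 1
        assert report.hub_regions[0][0] == "N9"

    def test_planted_star_center_ranks_first(self):
        rng = np.random.default_rng(15)
        b = rng.uniform(0, 1, (8, 20))
        b[:, 7] += 100.0  # one region on most shortest paths
        report = identify_hubs(b, small_atlas(20), fraction=0.10)
        assert report.hub_regions[0][0] == "N7"

    def test_tie_at_cutoff_warns_and_keeps_lower_index(self):
        b = np.zeros((1, 10))
        b[0, [3, 5]] = 7.0  # tie for the single hub slot
        with pytest.warns(UserWarning, match="tie"):
            report = identify_hubs(b, small_atlas(10), fraction=0.10)
        assert report.hub_regions[0][0] == "N3"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            identify_hubs(np.empty((0, 10)), small_atlas(10))


class TestPAdjust:
    def test_bonferroni_and_fdr_dominate_raw(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(0, 1, 50)
        for method in ("bonferroni", "fdr"):
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
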