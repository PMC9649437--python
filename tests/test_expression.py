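"""Regional PGS-expression association, permutation null, DE contrast."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from sptdt.expression import (
    consistency_stat,
    cross_effect_correlation,
    filter_expressed,
    mean_region_assoc,
    per_gene_assoc,
    permutation_mean_t,
    permute_within_cohort,
    region_de_contrast,
    scale_within_cohort,
)
from sptdt.annotation import density_correlation


def make_dataset(rng, n_donors=120, n_genes=30, beta=0.0, cohorts=("a", "b", "c")):
    """Three cohorts as in the combined design: single-cell European, bulk
    European and bulk African-ancestry donors (two cohorts would make the
    assay and ancestry indicators sum to the intercept)."""
    donors = [f"d{i}" for i in range(n_donors)]
    labels = [cohorts[i % len(cohorts)] for i in range(n_donors)]
    cohort = pd.Series(sorted(labels), index=donors, name="cohort_id")
    covars = pd.DataFrame(
        {
            "cohort_id": cohort,
            "diagnosis": rng.binomial(1, 0.5, n_donors),
            "african_ancestry": (cohort == cohorts[-1]).astype(int),
            "single_cell": (cohort == cohorts[0]).astype(int),
        },
        index=donors,
    )
    pgs = pd.Series(rng.standard_normal(n_donors), index=donors, name="pgs")
    expr = pd.DataFrame(
        beta * pgs.to_numpy()[None, :] + rng.standard_normal((n_genes, n_donors)),
        index=[f"g{j}" for j in range(n_genes)],
        columns=donors,
    )
    return expr, covars, pgs


class TestFilterExpressed:
    def test_distinct_means_keep_half(self, rng):
        expr = pd.DataFrame(
            np.arange(10)[:, None] + rng.normal(0, 0.01, size=(10, 6)),
            index=[f"g{j}" for j in range(10)],
        )
        assert len(filter_expressed(expr)) == 5

    def test_all_equal_keeps_nothing(self):
        expr = pd.DataFrame(np.ones((4, 5)), index=list("abcd"))
        with pytest.warns(UserWarning, match="median"):
            assert filter_expressed(expr) == set()

    def test_matches_sort_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(41, 7)), index=[f"g{j}" for j in range(41)])
        means = expr.mean(axis=1)
        expected = set(means.sort_values(ascending=False).index[: (41 - 1) // 2 + (0 if 41 % 2 else 0)])
        got = filter_expressed(expr)
        # strict above-median rule: exactly the top 20 of 41 distinct means
        assert got == set(means.sort_values(ascending=False).index[:20])


class TestScaleWithinCohort:
    def test_single_cohort_is_global_standardization(self, rng):
        vals = pd.DataFrame(rng.normal(2, 3, size=(4, 50)), columns=[f"d{i}" for i in range(50)])
        cohort = pd.Series(["x"] * 50, index=vals.columns)
        out = scale_within_cohort(vals, cohort)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, rtol=1e-12)

    def test_per_cohort_moments(self, rng):
        vals = pd.DataFrame(
            np.concatenate([rng.normal(5, 1, (3, 30)), rng.normal(-2, 4, (3, 20))], axis=1),
            columns=[f"d{i}" for i in range(50)],
        )
        cohort = pd.Series(["a"] * 30 + ["b"] * 20, index=vals.columns)
        out = scale_within_cohort(vals, cohort)
        for label in ("a", "b"):
            block = out.loc[:, cohort == label]
            np.testing.assert_allclose(block.mean(axis=1), 0, atol=1e-12)
            np.testing.assert_allclose(block.std(axis=1, ddof=1), 1, rtol=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        vals = pd.DataFrame(rng.normal(size=(2, 40)), columns=[f"d{i}" for i in range(40)])
        cohort = pd.Series(["a"] * 25 + ["b"] * 15, index=vals.columns)
        out = scale_within_cohort(vals, cohort)
        for label, cols in [("a", vals.columns[:25]), ("b", vals.columns[25:])]:
            block = vals.loc[:, cols].to_numpy()
            expected = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, ddof=1, keepdims=True)
            np.testing.assert_allclose(out.loc[:, cols].to_numpy(), expected, rtol=1e-12)

    def test_constant_feature_errors(self):
        vals = pd.DataFrame(np.ones((1, 4)), columns=list("wxyz"), index=["flat"])
        cohort = pd.Series(["a"] * 4, index=vals.columns)
        with pytest.raises(ValueError, match="flat"):
            scale_within_cohort(vals, cohort)


class TestPerGeneAssoc:
    def test_constant_pgs_errors(self, rng):
        expr, covars, pgs = make_dataset(rng)
        with pytest.raises(ValueError, match="pgs"):
            per_gene_assoc(expr, covars, pd.Series(1.0, index=pgs.index))

    def test_recovers_planted_effect(self, rng):
        expr, covars, pgs = make_dataset(rng, n_donors=200, n_genes=1, beta=-0.3)
        out = per_gene_assoc(expr, covars, pgs)
        X = sm.add_constant(
            pd.DataFrame({"pgs": pgs, **{c: covars[c] for c in ("diagnosis", "african_ancestry", "single_cell")}})
        )
        se = sm.OLS(expr.iloc[0], X).fit().bse["pgs"]
        assert abs(out["beta"].iloc[0] - (-0.3)) < 3 * se

    def test_matches_statsmodels_oracle(self, rng):
        expr, covars, pgs = make_dataset(rng, n_genes=5)
        out = per_gene_assoc(expr, covars, pgs)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "pgs": pgs,
                    "diagnosis": covars["diagnosis"],
                    "african_ancestry": covars["african_ancestry"],
                    "single_cell": covars["single_cell"],
                }
            )
        )
        for g in expr.index:
            fit = sm.OLS(expr.loc[g].to_numpy(), X.to_numpy()).fit()
            assert out.loc[g, "beta"] == pytest.approx(fit.params[1], rel=1e-8)
            assert out.loc[g, "t"] == pytest.approx(fit.tvalues[1], rel=1e-8)

    def test_t_invariant_to_within_cohort_rescaling(self, rng):
        expr, covars, pgs = make_dataset(rng)
        cohort = covars["cohort_id"]
        rescaled = expr.copy()
        rescaled.loc[:, cohort == "a"] *= 7.0
        rescaled.loc[:, cohort == "b"] = rescaled.loc[:, cohort == "b"] * 0.3 + 2.0
        a = per_gene_assoc(scale_within_cohort(expr, cohort), covars, pgs)
        b = per_gene_assoc(scale_within_cohort(rescaled, cohort), covars, pgs)
        np.testing.assert_allclose(a["t"], b["t"], atol=1e-8)


class TestMeanRegionAssoc:
    def test_single_gene_set_consistency(self, rng):
        expr, covars, pgs = make_dataset(rng, n_genes=4)
        per = per_gene_assoc(expr, covars, pgs)
        mean = mean_region_assoc(expr, covars, pgs, ["g2"])
        assert mean["beta"] == pytest.approx(per.loc["g2", "beta"], rel=1e-10)
        assert mean["t"] == pytest.approx(per.loc["g2", "t"], rel=1e-10)

    def test_equals_fit_on_averaged_matrix(self, rng):
        expr, covars, pgs = make_dataset(rng, n_genes=10)
        gene_set = ["g0", "g3", "g7"]
        out = mean_region_assoc(expr, covars, pgs, gene_set)
        y = expr.loc[gene_set].mean(axis=0)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "pgs": pgs,
                    "diagnosis": covars["diagnosis"],
                    "african_ancestry": covars["african_ancestry"],
                    "single_cell": covars["single_cell"],
                }
            )
        )
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        assert out["beta"] == pytest.approx(fit.params[1], rel=1e-10)
        assert out["se"] == pytest.approx(fit.bse[1], rel=1e-10)

    def test_planted_negative_shift_sign_recovery(self, rng):
        hits = 0
        for _ in range(100):
            expr, covars, pgs = make_dataset(rng, n_donors=200, n_genes=10, beta=-0.3)
            out = mean_region_assoc(expr, covars, pgs, list(expr.index))
            hits += out["beta"] < 0
        assert hits >= 95

    def test_empty_gene_set_errors(self, rng):
        expr, covars, pgs = make_dataset(rng)
        with pytest.raises(ValueError, match="empty gene set"):
            mean_region_assoc(expr, covars, pgs, ["absent"])


class TestPermutation:
    def test_extreme_observation_hits_add_one_floor(self, rng):
        expr, covars, pgs = make_dataset(rng, n_donors=100, n_genes=8, beta=-2.0)
        out = permutation_mean_t(expr, covars, pgs, list(expr.index), n_perm=1000, seed=3)
        assert out["empirical_p"] == pytest.approx(1 / 1001)

    def test_seeded_determinism(self, rng):
        expr, covars, pgs = make_dataset(rng, n_genes=5)
        a = permutation_mean_t(expr, covars, pgs, list(expr.index), n_perm=50, seed=11)
        b = permutation_mean_t(expr, covars, pgs, list(expr.index), n_perm=50, seed=11)
        assert a == b

    def test_shuffle_preserves_within_cohort_multiset(self, rng):
        expr, covars, pgs = make_dataset(rng)
        cohort = covars["cohort_id"]
        for _ in range(20):
            perm = permute_within_cohort(pgs, cohort, rng)
            for label in cohort.unique():
                assert sorted(perm[cohort == label]) == sorted(pgs[cohort == label])

    def test_invalid_n_perm(self, rng):
        expr, covars, pgs = make_dataset(rng)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_mean_t(expr, covars, pgs, list(expr.index), n_perm=0)


class TestConsistencyStat:
    def test_most_positive_coefficient(self):
        assert consistency_stat([-0.1, -0.05, -0.2]) == pytest.approx(-0.05)
        assert consistency_stat([-0.4]) == pytest.approx(-0.4)

    def test_matches_max_oracle(self, rng):
        betas = list(rng.normal(size=10))
        assert consistency_stat(betas) == max(betas)


def make_de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "log2fc", "t"])


class TestRegionDeContrast:
    def test_exclusion_window_boundary(self):
        # deletion window [1.0, 2.0] Mb: a gene starting 50 kb beyond the end
        # still overlaps the +-100 kb buffer and is excluded
        de = make_de(
            [
                ("near", "chr16", 2_050_000, 2_060_000, -0.5, -2.0),
                ("far", "chr16", 2_150_000, 2_160_000, -0.1, -0.5),
                ("bg1", "chr16", 9_000_000, 9_010_000, 0.0, 0.1),
                ("bg2", "chr16", 9_500_000, 9_510_000, 0.0, -0.1),
            ]
        )
        out = region_de_contrast(de, ["near", "far"], ("chr16", 1_000_000, 2_000_000))
        assert out["n_region"] == 1  # only "far" survives
        assert out["mean_t_region"] == pytest.approx(-0.5)

    def test_identical_groups_are_null(self):
        de = make_de(
            [(f"r{i}", "chr1", i * 1000, i * 1000 + 10, 0.0, t) for i, t in enumerate([-1.0, 0.0, 1.0])]
            + [(f"b{i}", "chr2", i * 1000, i * 1000 + 10, 0.0, t) for i, t in enumerate([-1.0, 0.0, 1.0])]
        )
        out = region_de_contrast(de, ["r0", "r1", "r2"], None)
        assert out["two_sample_p"] == pytest.approx(1.0)
        assert out["mean_t_region"] == pytest.approx(0.0)

    def test_no_window_reduces_to_plain_group_contrast(self, rng):
        t = rng.normal(size=50)
        de = make_de(
            [(f"g{i}", "chr1", i * 1000, i * 1000 + 10, 0.1 * t[i], t[i]) for i in range(50)]
        )
        region = [f"g{i}" for i in range(15)]
        out = region_de_contrast(de, region, None, exclusion=0)
        expected = stats.ttest_ind(t[:15], t[15:])
        assert out["two_sample_p"] == pytest.approx(expected.pvalue, rel=1e-10)

    def test_power_for_planted_regional_shift(self, rng):
        hits = 0
        for _ in range(100):
            t_region = rng.normal(-0.2, 1.0, size=200)
            t_bg = rng.normal(0.0, 1.0, size=8000)
            p = stats.ttest_ind(t_region, t_bg).pvalue
            hits += (p < 0.05) and (t_region.mean() < 0)
        assert hits > 50  # the design detects a -0.2 s.d. shift most of the time

    def test_empty_region_after_exclusion_errors(self):
        de = make_de([("g", "chr16", 1_000_000, 1_010_000, 0.0, 0.0)])
        with pytest.raises(ValueError, match="region genes"):
            region_de_contrast(de, ["g"], ("chr16", 900_000, 1_100_000))


class TestCrossEffectCorrelation:
    def test_identical_vectors(self, rng):
        t = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        out = cross_effect_correlation(t, t)
        assert out["r"] == pytest.approx(1.0)

    def test_agrees_with_density_correlation(self, rng):
        idx = [f"g{i}" for i in range(30)]
        a = pd.Series(rng.normal(size=30), index=idx)
        b = pd.Series(rng.normal(size=30), index=idx)
        out = cross_effect_correlation(a, b)
        ref = density_correlation(a.to_numpy(), b.to_numpy())
        assert out["r"] == pytest.approx(ref["r"], rel=1e-12)
        assert out["p"] == pytest.approx(ref["two_sided_p"], rel=1e-10)

    def test_subset_intersection_and_minimum(self, rng):
        a = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        b = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(5, 15)])
        out = cross_effect_correlation(a, b)
        assert out["n_genes"] == 5
        with pytest.raises(ValueError, match="shared genes"):
            cross_effect_correlation(a, pd.Series([1.0, 2.0], index=["g0", "g1"]))
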