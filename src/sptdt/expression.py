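"""Regional PGS-expression association with a donor-shuffling permutation
null, cross-cohort combination, and the CNV regional differential-expression
contrast.

The combined per-gene model is

    expression ~ regional PGS + diagnosis + ancestry + single_cell

fit by OLS after within-cohort standardization of per-gene expression and
per-partition PGS; the reported statistic is the PGS coefficient and its t.
Significance of the mean per-gene t over a regional gene set comes from a
permutation null built by shuffling the PGS-to-donor assignment
independently within each cohort, keeping expression and covariates fixed.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._ols import batch_ols_t

__all__ = [
    "COVARIATE_COLUMNS",
    "filter_expressed",
    "scale_within_cohort",
    "per_gene_assoc",
    "mean_region_assoc",
    "permute_within_cohort",
    "permutation_mean_t",
    "consistency_stat",
    "region_de_contrast",
    "cross_effect_correlation",
]

COVARIATE_COLUMNS = ("diagnosis", "african_ancestry", "single_cell")
"""Binary donor covariates of the combined association model."""


def filter_expressed(expr: pd.DataFrame) -> set[str]:
    """Genes whose mean expression across donors strictly exceeds the
    across-gene median of those means (the 'above-median' expressed set).

    With an even gene count and distinct means this keeps exactly half; an
    all-equal matrix keeps nothing (strict inequality) with a warning.
    """
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    means = expr.mean(axis=1)
    kept = set(means.index[means > means.median()])
    if not kept:
        warnings.warn("no gene exceeds the median mean expression", stacklevel=2)
    return kept


def scale_within_cohort(values: pd.DataFrame, cohorts: pd.Series) -> pd.DataFrame:
    """Standardize each row to mean 0 / s.d. 1 (ddof=1) within each cohort.

    ``values`` has features in rows and donors in columns; ``cohorts`` maps
    donor -> cohort label.  Applied identically to per-gene expression and
    per-partition PGS before cross-cohort concatenation.  A feature constant
    within a cohort raises (its scale is undefined).
    """
    out = values.copy().astype(float)
    cohorts = cohorts.loc[values.columns]
    for label in cohorts.unique():
        cols = cohorts.index[cohorts == label]
        if len(cols) < 2:
            raise ValueError(f"cohort {label!r} has < 2 donors")
        block = out.loc[:, cols]
        sd = block.std(axis=1, ddof=1)
        if (sd == 0).any():
            bad = sd.index[sd == 0][0]
            raise ValueError(f"feature {bad!r} constant within cohort {label!r}")
        out.loc[:, cols] = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)
    return out


def _design(covars: pd.DataFrame, pgs: pd.Series) -> tuple[np.ndarray, list[str]]:
    cols = ["const", "pgs"] + [c for c in COVARIATE_COLUMNS if c in covars.columns]
    X = np.column_stack(
        [np.ones(len(pgs)), pgs.to_numpy(dtype=float)]
        + [covars[c].to_numpy(dtype=float) for c in cols[2:]]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j, name in enumerate(cols):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, cols


def per_gene_assoc(
    expr: pd.DataFrame, covars: pd.DataFrame, pgs: pd.Series
) -> pd.DataFrame:
    """Per-gene OLS of expression on the regional PGS plus donor covariates.

    ``expr`` is genes x donors (already within-cohort scaled), ``covars``
    is donors x covariates, ``pgs`` the (scaled) per-donor regional score.
    Returns per-gene ``beta`` and ``t`` for the PGS coefficient.  Fits all
    genes against the shared design in one pass.
    """
    donors = list(expr.columns)
    covars = covars.loc[donors]
    pgs = pgs.loc[donors]
    X, _ = _design(covars, pgs)
    beta, t = batch_ols_t(X, expr.to_numpy(dtype=float).T, coef=1)
    return pd.DataFrame({"beta": beta, "t": t}, index=expr.index)


def mean_region_assoc(
    expr: pd.DataFrame,
    covars: pd.DataFrame,
    pgs: pd.Series,
    gene_set: Sequence[str],
) -> dict[str, float]:
    """Regression of average regional gene expression on the regional PGS.

    Averages the (scaled) expression of the gene set per donor, then fits
    the same covariate model; returns the PGS coefficient, its s.e., t and
    two-sided p.
    """
    gene_set = [g for g in gene_set if g in expr.index]
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    donors = list(expr.columns)
    covars = covars.loc[donors]
    pgs = pgs.loc[donors]
    y = expr.loc[gene_set].mean(axis=0).to_numpy(dtype=float)
    X, cols = _design(covars, pgs)
    fit = sm.OLS(y, X).fit()
    j = cols.index("pgs")
    return {
        "beta": float(fit.params[j]),
        "se": float(fit.bse[j]),
        "t": float(fit.tvalues[j]),
        "p": float(fit.pvalues[j]),
        "n_genes": len(gene_set),
    }


def permute_within_cohort(
    values: pd.Series, cohorts: pd.Series, rng: np.random.Generator
) -> pd.Series:
    """Shuffle a per-donor vector independently within each cohort.

    Preserves the within-cohort multiset of values exactly; the donor index
    is unchanged.
    """
    vals = values.to_numpy(dtype=float).copy()
    cohorts = cohorts.loc[values.index]
    for c in cohorts.unique():
        idx = np.flatnonzero((cohorts == c).to_numpy())
        vals[idx] = vals[idx][rng.permutation(idx.size)]
    return pd.Series(vals, index=values.index, name=values.name)


def permutation_mean_t(
    expr: pd.DataFrame,
    covars: pd.DataFrame,
    pgs: pd.Series,
    gene_set: Sequence[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Permutation test of the mean per-gene PGS t over a regional gene set.

    The observed statistic is the mean t from :func:`per_gene_assoc` over
    the gene set.  The null shuffles the PGS-to-donor assignment
    independently within each cohort (column ``cohort_id`` of ``covars``),
    keeping expression and covariates fixed.  The one-sided empirical p
    uses the add-one convention

        p = (1 + #{null mean t <= observed}) / (1 + n_perm)

    so a never-matched observation at n_perm = 1000 yields p = 1/1001.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_set = [g for g in gene_set if g in expr.index]
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    donors = list(expr.columns)
    covars = covars.loc[donors]
    pgs = pgs.loc[donors]
    Y = expr.loc[gene_set, donors].to_numpy(dtype=float).T

    def mean_t(p_vec: pd.Series) -> float:
        X, _ = _design(covars, p_vec)
        _, t = batch_ols_t(X, Y, coef=1)
        return float(t.mean())

    observed = mean_t(pgs)
    cohort = covars["cohort_id"]
    hits = 0
    for _ in range(n_perm):
        null = mean_t(permute_within_cohort(pgs, cohort, rng))
        if null <= observed:
            hits += 1
    return {
        "observed_mean_t": observed,
        "empirical_p": (1 + hits) / (1 + n_perm),
        "n_perm": n_perm,
    }


def consistency_stat(betas: Sequence[float]) -> float:
    """Most positive per-cohort regional coefficient (a region is
    'consistently negative' exactly when this maximum is negative)."""
    if len(betas) == 0:
        raise ValueError("need >= 1 cohort beta")
    return float(max(betas))


def region_de_contrast(
    de: pd.DataFrame,
    region_genes: Sequence[str],
    cnv_window: tuple[str, int, int] | None = None,
    exclusion: int = 100_000,
) -> dict[str, float]:
    """Regional differential-expression contrast around a CNV deletion.

    ``de`` has one row per gene with columns gene_id, chrom, start, end,
    log2fc, t.  Genes whose body overlaps ``cnv_window`` widened by
    ``exclusion`` bp on both sides are dropped (their cis-regulatory
    context may be perturbed by the deletion itself).  Reports the region
    genes' mean t with a one-sample two-sided t-test against 0, the mean
    log2 fold-change likewise, and a two-sided two-sample t-test of region
    versus all remaining (background) genes.
    """
    df = de.reset_index(drop=True)
    if cnv_window is not None:
        chrom, w_start, w_end = cnv_window
        lo, hi = w_start - exclusion, w_end + exclusion
        drop = (df["chrom"] == chrom) & (df["start"] < hi) & (df["end"] > lo)
        df = df[~drop]
    region_mask = df["gene_id"].isin(set(region_genes))
    region = df[region_mask]
    background = df[~region_mask]
    if len(region) == 0:
        raise ValueError("no region genes remain after CNV exclusion")
    t_region = region["t"].to_numpy(dtype=float)
    t_bg = background["t"].to_numpy(dtype=float)
    lfc_region = region["log2fc"].to_numpy(dtype=float)
    out = {
        "mean_t_region": float(t_region.mean()),
        "mean_t_background": float(t_bg.mean()) if len(background) else np.nan,
        "mean_log2fc_region": float(lfc_region.mean()),
        "n_region": int(len(region)),
        "n_background": int(len(background)),
    }
    out["one_sample_p"] = float(stats.ttest_1samp(t_region, 0.0).pvalue)
    out["one_sample_p_log2fc"] = float(stats.ttest_1samp(lfc_region, 0.0).pvalue)
    if len(background) >= 2:
        out["two_sample_p"] = float(stats.ttest_ind(t_region, t_bg).pvalue)
    else:
        out["two_sample_p"] = np.nan
    return out


def cross_effect_correlation(tA: pd.Series, tB: pd.Series) -> dict[str, float]:
    """Pearson correlation of two per-gene effect vectors over their shared
    genes (e.g. PGS-expression t versus deletion differential-expression t)."""
    shared = tA.index.intersection(tB.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    r, p = stats.pearsonr(tA.loc[shared].to_numpy(float), tB.loc[shared].to_numpy(float))
    return {"r": float(r), "p": float(p), "n_genes": int(len(shared))}
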