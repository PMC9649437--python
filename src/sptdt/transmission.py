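"""Transmission statistics: pTDT, the stratified S-pTDT scan, residual
z-scores, quadrant enrichment and block-removal decay.

For one family with child stratified score ``PGS_S,C`` and midparent score
``PGS_S,MP = (mother + father)/2``, the S-pTDT deviation is

    (PGS_S,C - PGS_S,MP) / sd(PGS_S,MP)

where the s.d. is taken over the analyzed families (ddof=1).  A cohort's
S-pTDT estimate is the mean deviation, tested against 0 with a one-sample
two-sided Student's t-test.  Positive mean deviation ("over-transmission")
means ascertained children carry more score than midparent expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import residual_z
from .partitions import Partition, chrom_sort_key
from .scoring import PedigreeTable

__all__ = [
    "TrioScoreSet",
    "PtdtResult",
    "trio_scores",
    "ptdt_deviations",
    "ptdt_test",
    "sptdt_scan",
    "residual_zscores",
    "quadrant_enrichment",
    "block_removal_decay",
    "exclude_carrier_families",
]


class TrioScoreSet:
    """Per-family child/mother/father scores for one (stratified) PGS."""

    REQUIRED = ("family_id", "child_score", "mother_score", "father_score")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"TrioScoreSet missing columns: {missing}")
        df = table.reset_index(drop=True)
        vals = df[["child_score", "mother_score", "father_score"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("scores must be finite")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class PtdtResult:
    """One-sample t-test summary of a deviation vector."""

    mean_deviation: float
    se: float
    t_statistic: float
    p_value: float
    n_families: int
    ci95: tuple[float, float]


def trio_scores(scores: pd.Series, ped: PedigreeTable, role: str = "proband") -> TrioScoreSet:
    """Join a per-sample score vector with a pedigree into trio score rows."""
    t = ped.table[ped.table["role"] == role]
    missing = [
        s
        for s in pd.unique(t[["child_id", "mother_id", "father_id"]].to_numpy().ravel())
        if s not in scores.index
    ]
    if missing:
        raise KeyError(f"samples missing from score vector: {missing[:5]}")
    return TrioScoreSet(
        pd.DataFrame(
            {
                "family_id": t["family_id"].to_numpy(),
                "child_score": scores.loc[t["child_id"]].to_numpy(),
                "mother_score": scores.loc[t["mother_id"]].to_numpy(),
                "father_score": scores.loc[t["father_id"]].to_numpy(),
            }
        )
    )


def ptdt_deviations(t: TrioScoreSet) -> np.ndarray:
    """Per-family normalized transmission deviations.

    Raises if fewer than 2 families or if the midparent scores are constant
    (the normalizer is then undefined).
    """
    if len(t) < 2:
        raise ValueError("need >= 2 families")
    child = t.table["child_score"].to_numpy(dtype=float)
    midparent = (
        t.table["mother_score"].to_numpy(dtype=float) + t.table["father_score"].to_numpy(dtype=float)
    ) / 2.0
    sd = midparent.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(midparent).max())):
        raise ValueError("midparent scores are constant; deviation normalizer undefined")
    return (child - midparent) / sd


def ptdt_test(deviations: np.ndarray) -> PtdtResult:
    """One-sample two-sided Student's t-test of mean deviation against 0."""
    dev = np.asarray(deviations, dtype=float)
    n = dev.size
    if n < 2:
        raise ValueError("need >= 2 deviations")
    sd = dev.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(dev).max())):
        raise ValueError("deviations are constant; t-test undefined")
    res = stats.ttest_1samp(dev, 0.0)
    se = sd / np.sqrt(n)
    half = stats.t.ppf(0.975, n - 1) * se
    mean = float(dev.mean())
    return PtdtResult(
        mean_deviation=mean,
        se=float(se),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_families=n,
        ci95=(mean - float(half), mean + float(half)),
    )


def sptdt_scan(
    strat_scores: pd.DataFrame,
    ped: PedigreeTable,
    partitions: Sequence[Partition],
    role: str = "proband",
) -> pd.DataFrame:
    """S-pTDT on every partition's stratified scores.

    ``strat_scores`` is the partition x sample table from
    :func:`~sptdt.scoring.stratified_scores`.  The deviation normalizer is
    recomputed per partition.  Partitions failing the pTDT preconditions
    (e.g. zero midparent variance) are flagged (``error=True``) and carry
    NaN statistics; downstream residual modelling drops them.

    Returns a frame with columns partition_id, estimate, se, t, p,
    n_families, n_snps, length, effective_length, error.
    """
    rows = []
    for p in partitions:
        row = {
            "partition_id": p.partition_id,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "n_snps": p.n_snps,
            "length": p.length,
            "effective_length": p.effective_length if p.effective_length is not None else p.length,
        }
        try:
            scores = strat_scores.loc[p.partition_id]
            dev = ptdt_deviations(trio_scores(scores, ped, role=role))
            res = ptdt_test(dev)
            row.update(
                estimate=res.mean_deviation,
                se=res.se,
                t=res.t_statistic,
                p=res.p_value,
                n_families=res.n_families,
                error=False,
            )
        except ValueError as exc:
            warnings.warn(f"partition {p.partition_id} excluded: {exc}", stacklevel=2)
            row.update(estimate=np.nan, se=np.nan, t=np.nan, p=np.nan, n_families=0, error=True)
        rows.append(row)
    return pd.DataFrame(rows)


def residual_zscores(
    table: pd.DataFrame,
    covariates: Sequence[str] = ("n_snps", "effective_length"),
) -> pd.DataFrame:
    """Regress the per-partition estimate on size covariates and standardize
    the residuals.

    Fits OLS with intercept of ``estimate`` on the named covariates (the
    gap-capped effective length is the intended length covariate; for
    equal-length windows pass ``("n_snps",)`` only).  ``residual_z`` is the
    residual divided by the residual sample s.d.; flagged/error rows are
    excluded from the fit and carry NaN.
    """
    df = table.copy()
    ok = ~df.get("error", pd.Series(False, index=df.index)).astype(bool)
    ok &= df["estimate"].notna()
    fit_df = df.loc[ok]
    covariates = list(covariates)
    if len(fit_df) < len(covariates) + 1:
        raise ValueError("too few partitions for the residual model")
    X = fit_df[covariates].astype(float)
    # drop covariates that add no rank (e.g. length collinear with n_snps)
    Xc = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in covariates])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        warnings.warn(
            "collinear covariates in residual model; dropping "
            f"{covariates[-1]!r}",
            stacklevel=2,
        )
        covariates = covariates[:-1]
        X = fit_df[covariates].astype(float)
    z = residual_z(fit_df["estimate"].to_numpy(), X)
    df["residual_z"] = np.nan
    df.loc[ok, "residual_z"] = z
    return df


def quadrant_enrichment(
    zA: np.ndarray, zB: np.ndarray, flags: np.ndarray
) -> dict[str, float]:
    """Enrichment of flagged partitions in the (zA > 0, zB > 0) quadrant.

    The baseline fraction is the overall fraction of partitions in that
    quadrant; expected = n_flagged x baseline.  The p-value is a one-sided
    (greater) exact binomial tail at the baseline fraction.
    """
    zA = np.asarray(zA, dtype=float)
    zB = np.asarray(zB, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if not (zA.shape == zB.shape == flags.shape):
        raise ValueError("zA, zB and flags must share one partition set")
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        raise ValueError("no flagged partitions")
    in_quadrant = (zA > 0) & (zB > 0)
    baseline = in_quadrant.mean()
    observed = int((in_quadrant & flags).sum())
    p = stats.binomtest(observed, n_flagged, baseline, alternative="greater").pvalue
    return {
        "observed": observed,
        "expected": n_flagged * float(baseline),
        "baseline_fraction": float(baseline),
        "n_flagged": n_flagged,
        "p": float(p),
    }


def block_removal_decay(
    blocks: Sequence[Partition],
    strat_scores: pd.DataFrame,
    ped: PedigreeTable,
    role: str = "proband",
) -> pd.DataFrame:
    """Signal decay under successive removal of the most over-transmitted
    remaining block.

    Step 0 tests the stratified score summed over all blocks; each later
    step removes the remaining block with the largest per-block mean
    deviation (ties broken by genomic order) and re-tests the union.  The
    curve has one row per block.
    """
    if len(blocks) == 0:
        raise ValueError("need >= 1 block")
    order = {p.partition_id: i for i, p in enumerate(sorted(blocks, key=lambda p: (chrom_sort_key(p.chrom), p.start)))}
    per_block = {}
    for p in blocks:
        dev = ptdt_deviations(trio_scores(strat_scores.loc[p.partition_id], ped, role=role))
        per_block[p.partition_id] = dev.mean()
    remaining = [p.partition_id for p in blocks]
    rows = []
    for step in range(len(blocks)):
        union = strat_scores.loc[remaining].sum(axis=0)
        res = ptdt_test(ptdt_deviations(trio_scores(union, ped, role=role)))
        rows.append(
            {
                "n_removed": step,
                "n_blocks_remaining": len(remaining),
                "estimate": res.mean_deviation,
                "se": res.se,
                "p": res.p_value,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
            }
        )
        if len(remaining) > 1:
            top = max(remaining, key=lambda b: (per_block[b], -order[b]))
            remaining.remove(top)
            rows[-1]["removed_next"] = top
    return pd.DataFrame(rows)


def exclude_carrier_families(ped: PedigreeTable, carriers: Sequence[str]) -> PedigreeTable:
    """Drop families whose listed child (e.g. a CNV carrier proband) appears
    in ``carriers``; warns on ids not present in the pedigree."""
    known = set(ped.table["child_id"])
    unknown = [c for c in carriers if c not in known]
    if unknown:
        warnings.warn(f"{len(unknown)} carrier id(s) not in pedigree", stacklevel=2)
    drop_fams = set(ped.table.loc[ped.table["child_id"].isin(set(carriers)), "family_id"])
    return PedigreeTable(ped.table[~ped.table["family_id"].isin(drop_fams)])
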