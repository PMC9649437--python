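"""Structural and gene-composition annotation of genome partitions.

Covers segmental-duplication coverage, tissue-specific gene sets, gene
density residual tests, 2x2 chi-square enrichment and histone-peak density
z-scores.  Interval inputs are 0-based half-open frames with columns
chrom/start/end.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from ._ols import residual_z
from .partitions import GeneTable, Partition

__all__ = [
    "merge_intervals",
    "segdup_fraction",
    "brain_specific_set",
    "density_residual_test",
    "density_correlation",
    "enrichment_chi2",
    "peak_density_z",
]


def _to_pyranges(intervals: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": intervals["chrom"].astype(str),
                "Start": intervals["start"].astype(np.int64),
                "End": intervals["end"].astype(np.int64),
            }
        )
    )


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    if len(intervals) == 0:
        return intervals.loc[:, ["chrom", "start", "end"]].copy()
    merged = _to_pyranges(intervals).merge().df
    return pd.DataFrame(
        {"chrom": merged["Chromosome"].astype(str), "start": merged["Start"], "end": merged["End"]}
    )


def segdup_fraction(p: Partition, segdups: pd.DataFrame) -> float:
    """Fraction of partition bases covered by the union of the intervals.

    Intervals are merged first, so the result is invariant to splitting an
    interval into abutting pieces and to input order.
    """
    if len(segdups) == 0:
        return 0.0
    merged = merge_intervals(segdups)
    sub = merged[merged["chrom"] == p.chrom]
    starts = np.maximum(sub["start"].to_numpy(np.int64), p.start)
    ends = np.minimum(sub["end"].to_numpy(np.int64), p.end)
    covered = np.clip(ends - starts, 0, None).sum()
    return float(covered) / p.length


def brain_specific_set(genes: GeneTable, top_fraction: float = 0.10) -> GeneTable:
    """Flag the genes in the top decile (by default) of tissue-specific
    expression.

    Flags ``ceil(top_fraction * n)`` genes with the highest
    ``specificity_t``; ties at the cutoff are broken by gene_id order so
    the flagged set is deterministic.  Returns a new table with a
    ``brain_specific`` boolean column.
    """
    df = genes.table.copy()
    if "specificity_t" not in df.columns or df["specificity_t"].isna().any():
        raise ValueError("specificity_t must be present and non-missing")
    k = math.ceil(top_fraction * len(df))
    ranked = df.sort_values(["specificity_t", "gene_id"], ascending=[False, True], kind="mergesort")
    flagged = set(ranked["gene_id"].head(k))
    df["brain_specific"] = df["gene_id"].isin(flagged)
    return GeneTable(df)


def density_residual_test(
    specific_counts: np.ndarray, total_counts: np.ndarray
) -> pd.DataFrame:
    """Excess of special genes relative to total gene density.

    OLS with intercept of the specific count on the total count; residuals
    are standardized across partitions and two-sided normal-tail p-values
    are reported per partition.
    """
    specific = np.asarray(specific_counts, dtype=float)
    total = np.asarray(total_counts, dtype=float)
    if specific.size != total.size or specific.size < 3:
        raise ValueError("need >= 3 matched partition counts")
    if np.ptp(total) == 0:
        raise ValueError("total counts are constant; density model undefined")
    z = residual_z(specific, pd.DataFrame({"total": total}))
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"residual_z": z, "two_sided_p": p})


def density_correlation(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "two_sided_p": float(p)}


def enrichment_chi2(
    region_hits: int, region_total: int, genome_hits: int, genome_total: int
) -> dict[str, float]:
    """2x2 chi-square (no continuity correction) for hit enrichment in a
    region: (in-region x hit) against their complements.

    ``expected_hits = genome_hits * region_total / genome_total``.  A
    warning recommends an exact test when any expected cell is below 5.
    """
    if region_total > genome_total or region_hits > min(region_total, genome_hits):
        raise ValueError("inconsistent counts")
    table = np.array(
        [
            [region_hits, region_total - region_hits],
            [genome_hits - region_hits, (genome_total - region_total) - (genome_hits - region_hits)],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        warnings.warn("expected cell count < 5; consider an exact test", stacklevel=2)
    return {
        "chi2": float(chi2),
        "p": float(p),
        "expected_hits": genome_hits * region_total / genome_total,
    }


def peak_density_z(
    peak_replicates: Sequence[pd.DataFrame], partitions: Sequence[Partition]
) -> pd.Series:
    """Replicate-averaged standardized peak counts per partition.

    Within each replicate, peaks are assigned to the partition containing
    their midpoint, counts are standardized to mean 0 / s.d. 1 (ddof=1)
    across partitions, and the z-scores are averaged across replicates.
    """
    if len(peak_replicates) < 1:
        raise ValueError("need >= 1 replicate")
    if len(partitions) < 2:
        raise ValueError("need >= 2 partitions to standardize counts")
    zs = []
    for peaks in peak_replicates:
        mid = (peaks["start"].to_numpy(np.int64) + peaks["end"].to_numpy(np.int64)) // 2
        chrom = peaks["chrom"].to_numpy()
        counts = np.array(
            [
                int(((chrom == p.chrom) & (mid >= p.start) & (mid < p.end)).sum())
                for p in partitions
            ],
            dtype=float,
        )
        sd = counts.std(ddof=1)
        if sd == 0:
            raise ValueError("peak counts constant across partitions")
        zs.append((counts - counts.mean()) / sd)
    avg = np.mean(zs, axis=0)
    return pd.Series(avg, index=pd.Index([p.partition_id for p in partitions], name="partition_id"), name="peak_density_z")
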