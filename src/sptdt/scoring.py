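"""Polygenic scoring: genome-wide and partition-stratified linear scores.

Scores use the sum form

    score_i = sum_j dosage_ij * weight_j

rather than the per-allele average some tools default to; the S-pTDT
normalization cancels any positive rescaling of the score, so the simpler
dialect is used and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .partitions import Partition, SnpMap

__all__ = [
    "DosageMatrix",
    "PedigreeTable",
    "score_samples",
    "stratified_scores",
    "harmonize_snps",
    "orient_dosages",
]


@dataclass
class DosageMatrix:
    """Samples x SNPs effect-allele dosages in [0, 2]; NaN marks missing.

    Column order must match the owning :class:`~sptdt.partitions.SnpMap`'s
    global SNP order.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise ValueError("dosages must lie in [0, 2] or be missing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def check_aligned(self, snps: SnpMap) -> None:
        if list(self.snp_ids) != list(snps.snp_ids):
            raise ValueError("DosageMatrix SNP order does not match SnpMap")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def from_tsv(cls, path) -> "DosageMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


class PedigreeTable:
    """Trio records: family_id, child_id, father_id, mother_id, role.

    ``role`` is ``'proband'`` or ``'sibling'``; one child per record.
    """

    REQUIRED = ("family_id", "child_id", "father_id", "mother_id", "role")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"PedigreeTable missing columns: {missing}")
        df = table.loc[:, list(self.REQUIRED)].copy().reset_index(drop=True)
        bad = set(df["role"]) - {"proband", "sibling"}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        if df["child_id"].duplicated().any():
            raise ValueError("child_id values must be unique")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def subset_role(self, role: str) -> "PedigreeTable":
        return PedigreeTable(self.table[self.table["role"] == role])

    def member_ids(self) -> list[str]:
        t = self.table
        return list(
            dict.fromkeys(list(t["child_id"]) + list(t["father_id"]) + list(t["mother_id"]))
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PedigreeTable":
        return cls(pd.read_csv(path, sep="\t"))


def _fill_missing(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Impute missing dosages to 2 x effect-allele frequency estimated from
    the non-missing samples (i.e. the column mean).  Columns with no
    observed dosage are flagged for exclusion."""
    filled = d.copy()
    missing = np.isnan(d)
    all_missing = missing.all(axis=0)
    if missing.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(d, axis=0)
        col_mean[all_missing] = 0.0
        idx = np.where(missing)
        filled[idx] = col_mean[idx[1]]
    return filled, all_missing


def score_samples(
    d: DosageMatrix,
    snps: SnpMap,
    subset: tuple[int, int] | None = None,
) -> pd.Series:
    """Linear score over a SNP index range (default: all SNPs).

    Missing dosages are imputed to twice the effect-allele frequency of the
    non-missing samples; SNPs missing in every sample are excluded with a
    warning.
    """
    d.check_aligned(snps)
    lo, hi = (0, len(snps)) if subset is None else subset
    if lo < 0 or hi > len(snps) or lo > hi:
        raise ValueError(f"subset {subset} outside SnpMap of size {len(snps)}")
    block = d.dosages[:, lo:hi]
    filled, all_missing = _fill_missing(block)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} SNP(s) missing in all samples excluded from scoring",
            stacklevel=2,
        )
        filled = filled[:, ~all_missing]
        w = snps.weights[lo:hi][~all_missing]
    else:
        w = snps.weights[lo:hi]
    return pd.Series(filled @ w, index=pd.Index(d.sample_ids, name="sample_id"), name="score")


def stratified_scores(
    d: DosageMatrix,
    snps: SnpMap,
    partitions: Sequence[Partition],
) -> pd.DataFrame:
    """Partition x sample table of stratified scores.

    Row ``p`` equals :func:`score_samples` restricted to partition ``p``'s
    SNPs; stratified scores over a disjoint cover of the SNPs therefore sum
    column-wise to the genome-wide score, exactly.
    """
    rows = {}
    for p in partitions:
        if p.snp_index_range is None or p.n_snps == 0:
            warnings.warn(f"partition {p.partition_id} has no SNPs; scores set to 0", stacklevel=2)
            rows[p.partition_id] = np.zeros(d.n_samples)
        else:
            rows[p.partition_id] = score_samples(d, snps, p.snp_index_range).to_numpy()
    out = pd.DataFrame(rows, index=pd.Index(d.sample_ids, name="sample_id")).T
    out.index.name = "partition_id"
    return out


def harmonize_snps(maps: Sequence[SnpMap], reference: int = 0) -> SnpMap:
    """Intersect SNP maps by snp_id, keeping the reference map's weights.

    Positions must agree across maps for shared ids.  Effect-allele
    disagreements are permitted here (strand-consistent allele swaps) and
    are resolved at scoring time by :func:`orient_dosages`.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to harmonize")
    ref = maps[reference]
    shared = set(ref.snp_ids)
    for m in maps:
        shared &= set(m.snp_ids)
    pos_by_id = {}
    for m in maps:
        t = m.table[m.table["snp_id"].isin(shared)]
        for sid, chrom, pos in zip(t["snp_id"], t["chrom"], t["pos"]):
            prev = pos_by_id.setdefault(sid, (chrom, pos))
            if prev != (chrom, pos):
                raise ValueError(f"conflicting position for {sid!r}: {prev} vs {(chrom, pos)}")
    return SnpMap(ref.table[ref.table["snp_id"].isin(shared)])


def orient_dosages(d: DosageMatrix, cohort_map: SnpMap, harmonized: SnpMap) -> DosageMatrix:
    """Re-express a cohort's dosages on the harmonized map's effect alleles.

    Columns are subset/reordered to the harmonized map; where the cohort's
    effect allele differs from the harmonized one the dosage is flipped to
    ``2 - dosage`` (missing stays missing).
    """
    cohort = cohort_map.table.set_index("snp_id")
    cols = {sid: j for j, sid in enumerate(d.snp_ids)}
    idx, flip = [], []
    for sid, allele in zip(harmonized.snp_ids, harmonized.table["effect_allele"]):
        if sid not in cols:
            raise ValueError(f"SNP {sid!r} absent from dosage matrix")
        idx.append(cols[sid])
        flip.append(cohort.loc[sid, "effect_allele"] != allele)
    sub = d.dosages[:, idx].copy()
    flip = np.asarray(flip)
    sub[:, flip] = 2.0 - sub[:, flip]
    return DosageMatrix(sub, d.sample_ids, list(harmonized.snp_ids))
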