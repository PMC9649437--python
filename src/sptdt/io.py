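"""Readers and writers for the plain-text interchange formats.

Most domain containers also expose ``to_tsv``/``from_tsv`` classmethods;
this module adds BED interval sets, long-format stratified scores and VCF
dosage extraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .partitions import Partition, partitions_to_frame
from .scoring import DosageMatrix

__all__ = [
    "read_bed",
    "write_bed",
    "write_partitions_bed",
    "read_partitions_bed",
    "write_stratified_scores",
    "read_stratified_scores",
    "dosages_from_vcf",
]


def read_bed(path) -> pd.DataFrame:
    """3+ column BED (0-based half-open) into a chrom/start/end frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_partitions_bed(partitions, path) -> None:
    """BED with partition_id, n_snps and effective_length extra columns."""
    partitions_to_frame(partitions).to_csv(path, sep="\t", header=True, index=False)


def read_partitions_bed(path) -> list[Partition]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        eff = None if row.effective_length < 0 else int(row.effective_length)
        out.append(
            Partition(
                partition_id=str(row.partition_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                effective_length=eff,
                stored_n_snps=int(row.n_snps),
            )
        )
    return out


def write_stratified_scores(strat: pd.DataFrame, path) -> None:
    """Partition x sample score table as long-format TSV
    (partition_id, sample_id, score)."""
    long = strat.stack().rename("score").reset_index()
    long.columns = ["partition_id", "sample_id", "score"]
    long.to_csv(path, sep="\t", index=False)


def read_stratified_scores(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="partition_id", columns="sample_id", values="score")
    wide.columns.name = "sample_id"
    return wide


def dosages_from_vcf(path, snp_ids: list[str], field: str = "GT") -> DosageMatrix:
    """Effect-allele (ALT) dosages from a VCF, ordered to ``snp_ids``.

    ``field='GT'`` counts ALT alleles from hard genotypes (missing calls
    become NaN); ``field='DS'`` reads the dosage FORMAT field.  Requires
    cyvcf2 (optional dependency).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    by_id: dict[str, np.ndarray] = {}
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if field == "GT":
            # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
            arr = np.asarray(var.gt_types, dtype=float)
            arr[arr == 3] = np.nan
        elif field == "DS":
            arr = np.asarray(var.format("DS"), dtype=float).ravel()
        else:
            raise ValueError(f"unknown dosage field: {field}")
        by_id[vid] = arr
    missing = [s for s in snp_ids if s not in by_id]
    if missing:
        raise KeyError(f"SNPs absent from VCF: {missing[:5]}")
    mat = np.column_stack([by_id[s] for s in snp_ids])
    return DosageMatrix(mat, samples, list(snp_ids))
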