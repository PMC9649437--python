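"""Genome partitioning: SNP-count blocks, fixed-length windows and annotations.

Coordinate conventions used throughout the package:

* SNP positions are 1-based (VCF convention).
* Interval coordinates (partitions, genes, BED-style interval sets) are
  0-based, half-open ``[start, end)``.

A SNP at 1-based position ``p`` occupies the 0-based interval ``[p-1, p)``
and therefore belongs to a partition ``[start, end)`` iff
``start <= p - 1 < end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "Partition",
    "GenomeBounds",
    "GeneTable",
    "chrom_sort_key",
    "make_snp_count_partitions",
    "make_fixed_length_partitions",
    "effective_length",
    "attach_snps",
    "assign_genes",
    "filter_partitions_by_intervals",
    "partitions_to_frame",
]

DEFAULT_GAP_CAP = 1_000_000
"""Cap, in bp, on the contribution of a single inter-SNP gap to the
effective length of a partition.  Accounts for decay of linkage
disequilibrium across large SNP deserts."""


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key for chromosome labels: chr2 < chr10 < chrX."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


class SnpMap:
    """Ordered table of PGS SNPs with per-effect-allele-dose weights.

    Parameters
    ----------
    table
        DataFrame with columns ``snp_id, chrom, pos, effect_allele, weight``.
        Positions are 1-based.  Rows are sorted by (chromosome, position) on
        construction; the resulting row order defines the global SNP index
        used by :class:`Partition` and by dosage matrices.
    """

    REQUIRED = ("snp_id", "chrom", "pos", "effect_allele", "weight")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"SnpMap table missing columns: {missing}")
        df = table.loc[:, list(self.REQUIRED)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["weight"] = df["weight"].astype(float)
        order = sorted(range(len(df)), key=lambda i: (chrom_sort_key(df["chrom"].iat[i]), df["pos"].iat[i]))
        df = df.iloc[order].reset_index(drop=True)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id in SnpMap: {dup!r}")
        if not np.all(np.isfinite(df["weight"].to_numpy())):
            raise ValueError("SnpMap weights must be finite")
        for chrom, sub in df.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return f"SnpMap({len(self)} SNPs, {len(self.chromosomes())} chromosomes)"

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def chrom_index_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global index range of the SNPs on one chromosome."""
        mask = (self.table["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return (0, 0)
        return int(idx[0]), int(idx[-1]) + 1

    def subset(self, index_range: tuple[int, int]) -> pd.DataFrame:
        lo, hi = index_range
        return self.table.iloc[lo:hi]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnpMap":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class Partition:
    """A contiguous genomic block over which regional statistics are computed.

    ``start``/``end`` are 0-based half-open.  ``snp_index_range`` is a
    half-open range into the owning :class:`SnpMap`'s global order, or
    ``None`` when no SNPs are attached.
    """

    partition_id: str
    chrom: str
    start: int
    end: int
    snp_index_range: tuple[int, int] | None = None
    effective_length: int | None = None
    stored_n_snps: int | None = None  # SNP count read back from disk

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.partition_id}: start must be < end")
        if self.snp_index_range is not None:
            lo, hi = self.snp_index_range
            if lo > hi:
                raise ValueError(f"{self.partition_id}: bad snp_index_range")

    @property
    def n_snps(self) -> int:
        if self.snp_index_range is None:
            return self.stored_n_snps or 0
        lo, hi = self.snp_index_range
        return hi - lo

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class GenomeBounds:
    """Per-chromosome analyzable extent, 0-based half-open."""

    bounds: Mapping[str, tuple[int, int]]

    def __post_init__(self):
        for chrom, (s, e) in self.bounds.items():
            if e <= s:
                raise ValueError(f"{chrom}: end must exceed start")

    def chromosomes(self) -> list[str]:
        return sorted(self.bounds, key=chrom_sort_key)


class GeneTable:
    """Genes with 0-based half-open bodies and optional per-gene statistics.

    Optional columns: ``specificity_t`` plus boolean flags such as
    ``brain_specific``, ``constrained``, ``exome_implicated``,
    ``differentially_expressed``.
    """

    REQUIRED = ("gene_id", "chrom", "start", "end")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"GeneTable missing columns: {missing}")
        df = table.copy().reset_index(drop=True)
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        if (df["end"] <= df["start"]).any():
            raise ValueError("gene end must exceed start")
        df["midpoint"] = (df["start"].astype(np.int64) + df["end"].astype(np.int64)) // 2
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneTable":
        return cls(pd.read_csv(path, sep="\t"))


def make_snp_count_partitions(
    snps: SnpMap,
    block_size: int,
    anchor: Literal["start", "end"] = "start",
) -> list[Partition]:
    """Divide each chromosome's SNPs into consecutive blocks of fixed count.

    Blocks of exactly ``block_size`` SNPs are laid down from the chromosome
    start (``anchor='start'``) or from the chromosome end backwards
    (``anchor='end'``); the final leftover run of fewer than ``block_size``
    SNPs at the non-anchor end is not assigned to any partition.  A
    partition's span covers its first through last member SNP, and its
    effective length is gap-capped at :data:`DEFAULT_GAP_CAP`.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    out: list[Partition] = []
    for chrom in snps.chromosomes():
        lo, hi = snps.chrom_index_range(chrom)
        n = hi - lo
        n_blocks = n // block_size
        for k in range(n_blocks):
            if anchor == "start":
                a = lo + k * block_size
            else:
                a = hi - (n_blocks - k) * block_size
            b = a + block_size
            pos = snps.positions[a:b]
            part = Partition(
                partition_id=f"{chrom}:snp{block_size}:{anchor}:{k}",
                chrom=chrom,
                start=int(pos[0]) - 1,
                end=int(pos[-1]),
                snp_index_range=(a, b),
            )
            part.effective_length = effective_length(part, snps)
            out.append(part)
    return out


def make_fixed_length_partitions(bounds: GenomeBounds, length: int) -> list[Partition]:
    """Adjacent disjoint windows of exactly ``length`` bp from each
    chromosome start; a trailing remainder shorter than ``length`` is
    discarded (chromosomes shorter than ``length`` contribute nothing)."""
    if length <= 0:
        raise ValueError("length must be positive")
    out: list[Partition] = []
    for chrom in bounds.chromosomes():
        s, e = bounds.bounds[chrom]
        n_windows = (e - s) // length
        for k in range(n_windows):
            out.append(
                Partition(
                    partition_id=f"{chrom}:win{k}",
                    chrom=chrom,
                    start=s + k * length,
                    end=s + (k + 1) * length,
                )
            )
    return out


def effective_length(p: Partition, snps: SnpMap, gap_cap: int = DEFAULT_GAP_CAP) -> int:
    """Sum of consecutive member-SNP gaps, each capped at ``gap_cap`` bp.

    Only inter-SNP gaps contribute; leading/trailing flank does not.  A
    single-SNP partition has effective length 0.
    """
    if p.snp_index_range is None or p.n_snps == 0:
        raise ValueError(f"{p.partition_id}: effective length undefined with no member SNPs")
    lo, hi = p.snp_index_range
    pos = snps.positions[lo:hi]
    if pos.size == 1:
        return 0
    gaps = np.diff(pos)
    return int(np.minimum(gaps, gap_cap).sum())


def attach_snps(
    partitions: Sequence[Partition], snps: SnpMap, gap_cap: int = DEFAULT_GAP_CAP
) -> list[Partition]:
    """Attach to each partition the contiguous run of SNPs whose (0-based)
    positions fall inside ``[start, end)``, and compute effective length.

    Used to build stratified scores for coordinate-defined partitions such
    as 33-Mb windows.  Partitions containing no SNPs get an empty range and
    effective length 0.
    """
    out = []
    for p in partitions:
        lo, hi = snps.chrom_index_range(p.chrom)
        pos = snps.positions[lo:hi]
        # SNP 1-based pos q lies in [start, end) iff start <= q-1 < end
        a = lo + int(np.searchsorted(pos, p.start + 1, side="left"))
        b = lo + int(np.searchsorted(pos, p.end, side="right"))
        q = replace(p, snp_index_range=(a, b))
        q.effective_length = effective_length(q, snps, gap_cap) if b > a else 0
        out.append(q)
    return out


def assign_genes(
    genes: GeneTable,
    partitions: Sequence[Partition],
    allow_multi: bool = False,
) -> dict[str, set[str]]:
    """Map each partition to the genes whose body midpoint it contains.

    With non-overlapping partitions every gene lands in at most one
    partition; overlapping partitions raise unless ``allow_multi`` is set,
    in which case a gene may appear under several partitions.
    """
    if not allow_multi:
        by_chrom: dict[str, list[Partition]] = {}
        for p in partitions:
            by_chrom.setdefault(p.chrom, []).append(p)
        for plist in by_chrom.values():
            plist = sorted(plist, key=lambda p: p.start)
            for a, b in zip(plist, plist[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping partitions {a.partition_id}/{b.partition_id}; "
                        "pass allow_multi=True for multi-assignment"
                    )
    result: dict[str, set[str]] = {p.partition_id: set() for p in partitions}
    g = genes.table
    for p in partitions:
        mask = (g["chrom"] == p.chrom) & (g["midpoint"] >= p.start) & (g["midpoint"] < p.end)
        result[p.partition_id].update(g.loc[mask, "gene_id"])
    return result


def filter_partitions_by_intervals(
    partitions: Sequence[Partition],
    intervals: pd.DataFrame,
    mode: Literal["drop_overlapping"] = "drop_overlapping",
) -> list[Partition]:
    """Remove partitions overlapping any interval (e.g. centromeres),
    preserving input order.  ``intervals`` has columns chrom/start/end,
    0-based half-open."""
    if mode != "drop_overlapping":
        raise ValueError(f"unknown mode: {mode}")
    if len(intervals) == 0:
        return list(partitions)
    kept = []
    for p in partitions:
        sub = intervals[intervals["chrom"] == p.chrom]
        hit = ((sub["start"] < p.end) & (sub["end"] > p.start)).any()
        if not hit:
            kept.append(p)
    return kept


def partitions_to_frame(partitions: Sequence[Partition]) -> pd.DataFrame:
    """BED-like frame (chrom, start, end, partition_id, n_snps,
    effective_length) for writing partitions to disk."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in partitions],
            "start": [p.start for p in partitions],
            "end": [p.end for p in partitions],
            "partition_id": [p.partition_id for p in partitions],
            "n_snps": [p.n_snps for p in partitions],
            "effective_length": [p.effective_length if p.effective_length is not None else -1 for p in partitions],
        }
    )
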