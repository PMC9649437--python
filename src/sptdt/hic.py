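"""Region-level Hi-C contact scoring and the distal rectangle enrichment
test.

All analyses are intra-chromosomal.  A :class:`ContactMatrix` holds a
symmetric bins x bins matrix at a stated resolution; partitions are snapped
to the nearest bin boundaries before scoring.  Distances between bin pairs
are measured between bin start coordinates, and the distance-matched
control band is inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import residual_z
from .partitions import Partition

__all__ = [
    "ContactMatrix",
    "snap_partition_to_bins",
    "snap_region_to_bins",
    "within_region_contact",
    "contact_residual_z",
    "rectangle_distance_range",
    "distal_enrichment",
]


@dataclass
class ContactMatrix:
    """Binned symmetric contact matrix for one chromosome.

    ``zero_is_missing`` records whether zero entries denote masked bins
    (e.g. zeroed-out segmental-duplication-rich rows) rather than true
    absence of contact.
    """

    matrix: np.ndarray
    resolution: int
    chrom: str
    zero_is_missing: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not np.allclose(self.matrix, self.matrix.T, rtol=1e-6, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def to_coo_tsv(self, path) -> None:
        """Upper-triangle triplet text (bin_i, bin_j, value), non-zero only."""
        iu = np.triu_indices(self.n_bins)
        vals = self.matrix[iu]
        keep = vals != 0
        pd.DataFrame(
            {"bin_i": iu[0][keep], "bin_j": iu[1][keep], "value": vals[keep]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_coo_tsv(cls, path, resolution: int, chrom: str, n_bins: int | None = None, **kw) -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t")
        n = n_bins if n_bins is not None else int(max(df["bin_i"].max(), df["bin_j"].max())) + 1
        m = np.zeros((n, n))
        m[df["bin_i"], df["bin_j"]] = df["value"]
        m[df["bin_j"], df["bin_i"]] = df["value"]
        return cls(m, resolution, chrom, **kw)

    @classmethod
    def from_dense_tsv(cls, path, resolution: int, chrom: str, **kw) -> "ContactMatrix":
        return cls(pd.read_csv(path, sep="\t", header=None).to_numpy(float), resolution, chrom, **kw)


def snap_region_to_bins(start: int, end: int, m: ContactMatrix) -> tuple[int, int]:
    """Round bp bounds to the nearest bin boundaries; at least one bin."""
    b0 = int(round(start / m.resolution))
    b1 = int(round(end / m.resolution))
    if b1 <= b0:
        b1 = b0 + 1
    if b0 < 0 or b1 > m.n_bins:
        raise ValueError(f"region [{start}, {end}) outside matrix extent")
    return b0, b1


def snap_partition_to_bins(p: Partition, m: ContactMatrix) -> tuple[int, int]:
    """Bin index range of a partition on the matrix's chromosome."""
    if p.chrom != m.chrom:
        raise ValueError(f"partition on {p.chrom}, matrix on {m.chrom}")
    return snap_region_to_bins(p.start, p.end, m)


def within_region_contact(
    m: ContactMatrix,
    bins: tuple[int, int],
    mode: Literal["off_diagonal", "all_elements"] = "off_diagonal",
) -> float:
    """Mean contact of the square sub-matrix over a bin range.

    ``off_diagonal`` excludes the diagonal (raw count matrices, where the
    diagonal dominates); ``all_elements`` includes it (matrices whose
    diagonal was already zeroed out upstream).
    """
    b0, b1 = bins
    n = b1 - b0
    if n < 1:
        raise ValueError("empty bin range")
    sub = m.matrix[b0:b1, b0:b1]
    if mode == "all_elements":
        return float(sub.mean())
    if mode == "off_diagonal":
        if n < 2:
            raise ValueError("off_diagonal mode needs >= 2 bins")
        total = sub.sum() - np.trace(sub)
        return float(total / (n * n - n))
    raise ValueError(f"unknown mode: {mode}")


def contact_residual_z(
    contacts: np.ndarray, gene_counts: np.ndarray, segdup_fractions: np.ndarray
) -> np.ndarray:
    """Within-partition contact corrected for genomic composition.

    OLS with intercept of mean contact on gene count and segmental
    duplication coverage; residuals standardized to unit s.d. across
    partitions (shared machinery with the transmission residual model).
    """
    contacts = np.asarray(contacts, dtype=float)
    if contacts.size < 4:
        raise ValueError("need >= 4 partitions")
    X = pd.DataFrame(
        {"gene_count": np.asarray(gene_counts, float), "segdup": np.asarray(segdup_fractions, float)}
    )
    Xc = np.column_stack([np.ones(len(X)), X["gene_count"], X["segdup"]])
    if np.linalg.matrix_rank(Xc) < 3:
        raise ValueError("collinear contact-model covariates")
    return residual_z(contacts, X)


def rectangle_distance_range(
    regionA: tuple[int, int], regionB: tuple[int, int]
) -> dict[str, int]:
    """Minimum (nearest-edge) and maximum (farthest-edge) separation in bp
    spanned by the rectangle of contacts between two disjoint intervals on
    one chromosome."""
    a0, a1 = regionA
    b0, b1 = regionB
    if a0 < b1 and b0 < a1:
        raise ValueError("regions overlap; rectangle distances undefined")
    if a0 >= b1:
        return {"min_distance": a0 - b1, "max_distance": a1 - b0}
    return {"min_distance": b0 - a1, "max_distance": b1 - a0}


def distal_enrichment(
    m: ContactMatrix,
    regionA: tuple[int, int],
    regionB: tuple[int, int],
    zero_policy: Literal["exclude", "include"] = "exclude",
) -> dict[str, float]:
    """Contact enrichment of the A x B rectangle over distance-matched
    controls.

    Target contacts are the bin pairs of the A x B rectangle.  Control
    contacts are all other same-chromosome bin pairs whose separation
    (between bin starts, in bp) lies inside the rectangle's
    [min_distance, max_distance] band, both ends inclusive.  With
    ``zero_policy='exclude'`` (the default, appropriate when zero entries
    are masked bins) zero entries are dropped from both sets.  Reports
    fold = mean(target) / mean(control) and a two-sided two-sample
    Student's t-test.
    """
    dist = rectangle_distance_range(regionA, regionB)
    a0, a1 = snap_region_to_bins(*regionA, m)
    b0, b1 = snap_region_to_bins(*regionB, m)

    in_rect = np.zeros((m.n_bins, m.n_bins), dtype=bool)
    in_rect[a0:a1, b0:b1] = True
    in_rect |= in_rect.T

    i, j = np.triu_indices(m.n_bins, k=1)
    sep = (j - i) * m.resolution
    band = (sep >= dist["min_distance"]) & (sep <= dist["max_distance"])
    rect_mask = in_rect[i, j]
    target = m.matrix[i, j][rect_mask]
    control = m.matrix[i, j][band & ~rect_mask]
    if zero_policy == "exclude":
        target = target[target != 0]
        control = control[control != 0]
    elif zero_policy != "include":
        raise ValueError(f"unknown zero_policy: {zero_policy}")
    if control.size == 0:
        raise ValueError("empty control set")
    if control.mean() == 0:
        raise ValueError("control mean is 0; fold undefined")
    res = stats.ttest_ind(target, control)
    return {
        "fold": float(target.mean() / control.mean()),
        "target_n": int(target.size),
        "control_n": int(control.size),
        "target_mean": float(target.mean()),
        "control_mean": float(control.mean()),
        "two_sample_p": float(res.pvalue),
    }
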