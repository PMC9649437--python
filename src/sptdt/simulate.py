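"""Synthetic data with the statistical structure the regional analyses
assume: Mendelian trio transmission under liability-threshold proband
ascertainment, a designated region with concentrated score weight, gene and
interval annotations, expression with a regional PGS effect plus cohort
covariates, and distance-decay Hi-C matrices with planted boosts.

Every generator is a pure function of (config, rng/seed) and reproduces
byte-identically under a fixed seed.  Ascertainment works through a
liability threshold rather than by injecting a deviation directly, so score
over-transmission in probands is emergent and can be checked against
theory-free Monte-Carlo baselines; unascertained siblings from the same
families provide a built-in null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic import ContactMatrix
from .partitions import GeneTable, GenomeBounds, SnpMap
from .scoring import DosageMatrix, PedigreeTable

__all__ = [
    "SimulationConfig",
    "simulate_snp_map",
    "simulate_trios",
    "simulate_expression",
    "simulate_contact_matrix",
    "simulate_annotations",
    "genome_bounds",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome, trios, expression and Hi-C.

    Defaults describe a desk-scale genome of three 99-Mb chromosomes with a
    33-Mb region of concentrated PGS weight on chr16 (emulating 16p), trios
    ascertained at the top 2% of a liability with a 30% PGS share, and an
    expression study of three cohorts sized like the contributing brain
    cohorts (122 single-cell European, 229 bulk European, 193 bulk African
    ancestry donors).
    """

    seed: int = 0

    # genome / SNP map
    chromosomes: tuple[str, ...] = ("chr1", "chr2", "chr16")
    chrom_length: int = 99_000_000
    n_snps_per_chrom: int = 600
    freq_range: tuple[float, float] = (0.05, 0.5)
    weight_sd: float = 1.0
    effect_region: tuple[str, int, int] = ("chr16", 0, 33_000_000)
    effect_multiplier: float = 3.0

    # trios
    n_families: int = 500
    pgs_liability_share: float = 0.30  # h^2 share of liability carried by the PGS
    ascertainment_quantile: float = 0.98  # probands exceed this liability quantile
    max_batches: int = 500

    # expression
    n_region_genes: int = 40
    n_background_genes: int = 260
    regional_beta: float = -0.3
    expression_noise_sd: float = 1.0
    diagnosis_effect: float = 0.5
    cohort_sizes: tuple[int, ...] = (122, 229, 193)
    cohort_single_cell: tuple[int, ...] = (1, 0, 0)
    cohort_african: tuple[int, ...] = (0, 0, 1)
    cohort_expr_shift: tuple[float, ...] = (0.0, 1.0, -0.5)
    cohort_expr_scale: tuple[float, ...] = (1.0, 1.6, 0.8)

    # Hi-C
    hic_n_bins: int = 330
    hic_resolution: int = 100_000
    hic_decay: float = 1.0
    hic_scale: float = 100.0
    hic_noise_sd: float = 0.1  # lognormal sigma
    hic_block: tuple[int, int] | None = None  # bin range boosted by block_boost
    hic_block_boost: float = 1.0
    hic_rect: tuple[tuple[int, int], tuple[int, int]] = ((295, 302), (0, 52))
    hic_rectangle_boost: float = 1.0

    # annotations
    gene_density_per_mb: float = 2.0
    gene_density_window: int = 33_000_000  # density redrawn per window of this size
    gene_density_log_sd: float = 0.5  # between-window spread of log density
    region_density_multiplier: float = 1.8  # ~433 vs ~242 genes per 33-Mb window
    specificity_region_shift: float = 0.0
    n_segdups: int = 60
    segdup_length: tuple[int, int] = (20_000, 400_000)
    centromere_fraction: float = 0.5  # centromere placed at this relative position
    centromere_halfwidth: int = 1_500_000
    de_region_shift: float = 0.0  # planted mean shift of region DE t-statistics

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def __post_init__(self):
        if not 0.0 <= self.pgs_liability_share <= 1.0:
            raise ValueError("pgs_liability_share must lie in [0, 1]")
        if not 0.0 <= self.ascertainment_quantile < 1.0:
            raise ValueError("ascertainment_quantile must lie in [0, 1)")


def genome_bounds(cfg: SimulationConfig) -> GenomeBounds:
    return GenomeBounds({c: (0, cfg.chrom_length) for c in cfg.chromosomes})


def simulate_snp_map(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SnpMap:
    """Sorted SNP positions (uniform over each chromosome, so occasional
    >1-Mb gaps arise naturally and exercise gap capping) with normal
    weights, inflated by ``effect_multiplier`` inside the effect region."""
    rng = cfg.rng() if rng is None else rng
    frames = []
    for chrom in cfg.chromosomes:
        pos = np.unique(rng.integers(1, cfg.chrom_length + 1, size=cfg.n_snps_per_chrom))
        while pos.size < cfg.n_snps_per_chrom:  # rare duplicate top-up
            extra = rng.integers(1, cfg.chrom_length + 1, size=cfg.n_snps_per_chrom - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        w = rng.normal(0.0, cfg.weight_sd, size=cfg.n_snps_per_chrom)
        ec, es, ee = cfg.effect_region
        if chrom == ec:
            in_region = (pos - 1 >= es) & (pos - 1 < ee)
            w[in_region] *= cfg.effect_multiplier
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"{chrom}:{p}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "effect_allele": rng.choice(list("ACGT"), size=cfg.n_snps_per_chrom),
                    "weight": w,
                }
            )
        )
    return SnpMap(pd.concat(frames, ignore_index=True))


def _transmit(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One fair Mendelian allele draw per parent genotype (0/1/2)."""
    return rng.binomial(1, parent_geno / 2.0)


def simulate_trios(
    cfg: SimulationConfig,
    snps: SnpMap,
    rng: np.random.Generator | None = None,
    with_siblings: bool = False,
) -> tuple[DosageMatrix, PedigreeTable]:
    """Trio genotypes with liability-threshold proband ascertainment.

    Parent genotypes are Binomial(2, f) per SNP; children receive one fair
    Mendelian allele draw per parent.  Proband liability is

        L = z(PGS) * sqrt(h2) + eps * sqrt(1 - h2)

    with the child PGS standardized by its analytic population moments;
    families are kept when L exceeds the ``ascertainment_quantile`` normal
    quantile (quantile 0 keeps everyone — unascertained trios).  Candidate
    families are drawn in batches until ``n_families`` probands accrue;
    generation aborts after ``max_batches`` batches.  With
    ``with_siblings`` each kept family also gets an unascertained sibling.
    """
    from scipy import stats

    rng = cfg.rng() if rng is None else rng
    n_snps = len(snps)
    freqs = rng.uniform(*cfg.freq_range, size=n_snps)
    w = snps.weights
    mu = float((2.0 * freqs * w).sum())
    var = float((2.0 * freqs * (1.0 - freqs) * w**2).sum())
    sd = np.sqrt(var) if var > 0 else 1.0
    h2 = cfg.pgs_liability_share
    thresh = (
        -np.inf
        if cfg.ascertainment_quantile == 0.0
        else stats.norm.ppf(cfg.ascertainment_quantile)
    )

    kept_father, kept_mother, kept_child = [], [], []
    accept_rate = max(1.0 - cfg.ascertainment_quantile, 1e-3)
    # bounded batch keeps peak memory modest at extreme thresholds
    batch = min(max(int(np.ceil(cfg.n_families / accept_rate / 4)), cfg.n_families), 20_000)
    n_kept = 0
    for _ in range(cfg.max_batches):
        if n_kept >= cfg.n_families:
            break
        gf = rng.binomial(2, freqs, size=(batch, n_snps))
        gm = rng.binomial(2, freqs, size=(batch, n_snps))
        gc = _transmit(gf, rng) + _transmit(gm, rng)
        z = (gc @ w - mu) / sd
        liab = np.sqrt(h2) * z + np.sqrt(1.0 - h2) * rng.standard_normal(batch)
        keep = np.flatnonzero(liab > thresh)
        if keep.size:
            kept_father.append(gf[keep])
            kept_mother.append(gm[keep])
            kept_child.append(gc[keep])
            n_kept += keep.size
    if n_kept < cfg.n_families:
        raise RuntimeError(
            f"ascertainment stalled: {n_kept}/{cfg.n_families} probands after "
            f"{cfg.max_batches} batches"
        )
    gf = np.concatenate(kept_father)[: cfg.n_families]
    gm = np.concatenate(kept_mother)[: cfg.n_families]
    gc = np.concatenate(kept_child)[: cfg.n_families]

    blocks = [gc, gm, gf]
    sample_ids = (
        [f"fam{i}_child" for i in range(cfg.n_families)]
        + [f"fam{i}_mother" for i in range(cfg.n_families)]
        + [f"fam{i}_father" for i in range(cfg.n_families)]
    )
    ped_rows = [
        {
            "family_id": f"fam{i}",
            "child_id": f"fam{i}_child",
            "father_id": f"fam{i}_father",
            "mother_id": f"fam{i}_mother",
            "role": "proband",
        }
        for i in range(cfg.n_families)
    ]
    if with_siblings:
        gs = _transmit(gf, rng) + _transmit(gm, rng)
        blocks.append(gs)
        sample_ids += [f"fam{i}_sib" for i in range(cfg.n_families)]
        ped_rows += [
            {
                "family_id": f"fam{i}",
                "child_id": f"fam{i}_sib",
                "father_id": f"fam{i}_father",
                "mother_id": f"fam{i}_mother",
                "role": "sibling",
            }
            for i in range(cfg.n_families)
        ]
    dosages = np.concatenate(blocks, axis=0).astype(float)
    return (
        DosageMatrix(dosages, sample_ids, list(snps.snp_ids)),
        PedigreeTable(pd.DataFrame(ped_rows)),
    )


def simulate_annotations(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, object]:
    """Gene table, interval sets and a per-gene DE statistic table.

    Genes are placed with ``region_density_multiplier``-fold density inside
    the effect region and carry a ``specificity_t`` statistic whose region
    mean is shifted by ``specificity_region_shift``.  Segdup intervals are
    random; one centromere interval per chromosome sits at
    ``centromere_fraction`` of its length.  DE t-statistics are standard
    normal with a planted ``de_region_shift`` on region genes and
    ``log2fc = 0.1 t`` plus noise.
    """
    rng = cfg.rng() if rng is None else rng
    ec, es, ee = cfg.effect_region
    genes = []
    for chrom in cfg.chromosomes:
        # gene density varies between large windows (real 33-Mb windows span
        # a wide gene-count range); the effect region gets a fixed multiplier
        starts_list = []
        for w0 in range(0, cfg.chrom_length, cfg.gene_density_window):
            w1 = min(w0 + cfg.gene_density_window, cfg.chrom_length)
            mult = rng.lognormal(0.0, cfg.gene_density_log_sd)
            if chrom == ec and w0 >= es and w1 <= ee:
                mult = cfg.region_density_multiplier
            lam = cfg.gene_density_per_mb * (w1 - w0) / 1e6 * mult
            n = rng.poisson(lam)
            starts_list.append(rng.integers(w0, max(w1 - 100_000, w0 + 1), size=n))
        starts = np.sort(np.concatenate(starts_list))
        lengths = rng.integers(5_000, 100_000, size=starts.size)
        for k, (s, L) in enumerate(zip(starts, lengths)):
            genes.append({"gene_id": f"{chrom}_g{k}", "chrom": chrom, "start": int(s), "end": int(s + L)})
    gdf = pd.DataFrame(genes)
    mid = (gdf["start"] + gdf["end"]) // 2
    in_region = (gdf["chrom"] == ec) & (mid >= es) & (mid < ee)
    gdf["specificity_t"] = rng.standard_normal(len(gdf)) + np.where(in_region, cfg.specificity_region_shift, 0.0)
    gdf["in_effect_region"] = in_region.to_numpy()

    seg = []
    for chrom in cfg.chromosomes:
        lengths = rng.integers(*cfg.segdup_length, size=cfg.n_segdups)
        starts = rng.integers(0, cfg.chrom_length - cfg.segdup_length[1], size=cfg.n_segdups)
        seg.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lengths}))
    segdups = pd.concat(seg, ignore_index=True)

    cen_mid = int(cfg.centromere_fraction * cfg.chrom_length)
    centromeres = pd.DataFrame(
        {
            "chrom": list(cfg.chromosomes),
            "start": cen_mid - cfg.centromere_halfwidth,
            "end": cen_mid + cfg.centromere_halfwidth,
        }
    )

    t = rng.standard_normal(len(gdf)) + np.where(in_region, cfg.de_region_shift, 0.0)
    de_stats = pd.DataFrame(
        {
            "gene_id": gdf["gene_id"],
            "chrom": gdf["chrom"],
            "start": gdf["start"],
            "end": gdf["end"],
            "log2fc": 0.1 * t + 0.02 * rng.standard_normal(len(gdf)),
            "t": t,
        }
    )
    return {
        "genes": GeneTable(gdf),
        "segdups": segdups,
        "centromeres": centromeres,
        "de_stats": de_stats,
    }


def simulate_expression(
    cfg: SimulationConfig,
    donor_pgs: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneTable]:
    """Expression with a regional PGS effect plus cohort/diagnosis structure.

    ``donor_pgs`` is the per-donor regional PGS driving the region genes.
    Region genes get ``regional_beta * z(PGS)`` plus diagnosis and noise;
    background genes omit the PGS term.  Donors are split into cohorts of
    ``cohort_sizes`` with distinct expression means/scales (exercising the
    within-cohort scaling step) and the stated binary covariates.

    Returns (genes x donors expression, donor covariate table, gene table
    with an ``in_effect_region`` flag).
    """
    rng = cfg.rng() if rng is None else rng
    donors = list(donor_pgs.index)
    if len(donors) != sum(cfg.cohort_sizes):
        raise ValueError(
            f"donor_pgs has {len(donors)} donors; cohort_sizes sum to {sum(cfg.cohort_sizes)}"
        )
    cohort_id = np.repeat([f"cohort{k}" for k in range(len(cfg.cohort_sizes))], cfg.cohort_sizes)
    single_cell = np.repeat(cfg.cohort_single_cell, cfg.cohort_sizes).astype(int)
    african = np.repeat(cfg.cohort_african, cfg.cohort_sizes).astype(int)
    shift = np.repeat(cfg.cohort_expr_shift, cfg.cohort_sizes)
    scale = np.repeat(cfg.cohort_expr_scale, cfg.cohort_sizes)
    diagnosis = rng.binomial(1, 0.5, size=len(donors))

    pgs = donor_pgs.to_numpy(dtype=float)
    z = (pgs - pgs.mean()) / pgs.std(ddof=1)

    n_genes = cfg.n_region_genes + cfg.n_background_genes
    ec, es, ee = cfg.effect_region
    region_starts = rng.integers(es, ee - 100_000, size=cfg.n_region_genes)
    bg_starts = rng.integers(ee, cfg.chrom_length - 100_000, size=cfg.n_background_genes)
    gdf = pd.DataFrame(
        {
            "gene_id": [f"rg{k}" for k in range(cfg.n_region_genes)]
            + [f"bg{k}" for k in range(cfg.n_background_genes)],
            "chrom": ec,
            "start": np.concatenate([region_starts, bg_starts]),
        }
    )
    gdf["end"] = gdf["start"] + 50_000
    gdf["in_effect_region"] = [True] * cfg.n_region_genes + [False] * cfg.n_background_genes

    signal = np.where(gdf["in_effect_region"].to_numpy()[:, None], cfg.regional_beta * z[None, :], 0.0)
    expr = (
        signal
        + cfg.diagnosis_effect * diagnosis[None, :]
        + shift[None, :]
        + scale[None, :] * cfg.expression_noise_sd * rng.standard_normal((n_genes, len(donors)))
    )
    expr = pd.DataFrame(expr, index=gdf["gene_id"].to_numpy(), columns=donors)
    covars = pd.DataFrame(
        {
            "cohort_id": cohort_id,
            "diagnosis": diagnosis,
            "african_ancestry": african,
            "single_cell": single_cell,
        },
        index=pd.Index(donors, name="donor_id"),
    )
    return expr, covars, GeneTable(gdf)


def simulate_contact_matrix(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> ContactMatrix:
    """Symmetric distance-decay contact matrix with optional planted boosts.

    Entry (i, j) is ``scale * (|i-j| * resolution)^(-decay)`` times
    multiplicative lognormal noise; the diagonal carries the one-bin value.
    A designated bin block is multiplied by ``hic_block_boost`` and the
    designated off-diagonal rectangle by ``hic_rectangle_boost``.
    """
    rng = cfg.rng() if rng is None else rng
    if cfg.hic_decay <= 0:
        raise ValueError("decay exponent must be positive")
    n = cfg.hic_n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    np.fill_diagonal(d, 1.0)  # diagonal scored as one-bin separation
    base = cfg.hic_scale * (d * cfg.hic_resolution) ** (-cfg.hic_decay)
    if cfg.hic_noise_sd > 0:
        noise = rng.lognormal(0.0, cfg.hic_noise_sd, size=(n, n))
        noise = np.sqrt(noise * noise.T)  # symmetric multiplicative noise
    else:
        noise = 1.0
    m = base * noise
    if cfg.hic_block is not None and cfg.hic_block_boost != 1.0:
        b0, b1 = cfg.hic_block
        m[b0:b1, b0:b1] *= cfg.hic_block_boost
    if cfg.hic_rectangle_boost != 1.0:
        (a0, a1), (b0, b1) = cfg.hic_rect
        m[a0:a1, b0:b1] *= cfg.hic_rectangle_boost
        m[b0:b1, a0:a1] *= cfg.hic_rectangle_boost
    return ContactMatrix(m, cfg.hic_resolution, cfg.effect_region[0])
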