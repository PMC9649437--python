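import numpy as np
import pandas as pd
import pytest

from sptdt.partitions import GenomeBounds, SnpMap
from sptdt.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_snp_map(rng, chroms=("chr1", "chr2", "chr3"), n_per_chrom=200, span=50_000_000):
    frames = []
    for chrom in chroms:
        pos = np.unique(rng.integers(1, span, size=n_per_chrom))
        while pos.size < n_per_chrom:
            pos = np.unique(
                np.concatenate([pos, rng.integers(1, span, size=n_per_chrom - pos.size)])
            )
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"{chrom}_s{i}" for i in range(n_per_chrom)],
                    "chrom": chrom,
                    "pos": pos,
                    "effect_allele": rng.choice(list("ACGT"), size=n_per_chrom),
                    "weight": rng.normal(size=n_per_chrom),
                }
            )
        )
    return SnpMap(pd.concat(frames, ignore_index=True))


@pytest.fixture
def snp_map(rng):
    return random_snp_map(rng)


@pytest.fixture
def small_trio_cfg():
    """Fast unascertained trio setup: few SNPs, modest family count."""
    return SimulationConfig(
        seed=7,
        chromosomes=("chr1", "chr2", "chr16"),
        n_snps_per_chrom=100,
        n_families=200,
        ascertainment_quantile=0.0,
    )


@pytest.fixture
def hg19_like_bounds():
    """22-autosome bounds with lengths in the human range (synthetic)."""
    lengths = np.linspace(249_000_000, 48_000_000, 22).astype(int)
    return GenomeBounds({f"chr{i+1}": (0, int(L)) for i, L in enumerate(lengths)})
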