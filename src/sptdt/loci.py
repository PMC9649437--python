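"""Canonical chromosome 16 regions used throughout the regional analyses.

All intervals are 0-based half-open (chrom, start, end) in hg19-style
coordinates.
"""

CHR16P = ("chr16", 0, 33_000_000)
"""The ~33-Mb short arm of chromosome 16."""

LOCUS_16P11_2 = ("chr16", 29_500_000, 30_200_000)
"""The recurrent proximal 16p11.2 CNV locus (0.7 Mb)."""

TELOMERIC_16P = ("chr16", 0, 5_200_000)
"""Gene-dense distal/telomeric segment at the start of chromosome 16."""


def region_width(region: tuple[str, int, int]) -> int:
    """Width of a (chrom, start, end) region in bp."""
    return region[2] - region[1]
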