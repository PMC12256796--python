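"""Genome-region classification for chrX-aware GWAS tables.

Variants are classed as autosomal, chrX pseudoautosomal (PAR, analyzed as
diploid in both sexes) or chrX non-pseudoautosomal (non-PAR, hemizygous in
males and coded {0,2}).  Default PAR boundaries are GRCh37.
"""

from __future__ import annotations

AUTOSOME = "autosome"
CHRX_PAR = "chrX_PAR"
CHRX_NONPAR = "chrX_nonPAR"

REGION_CLASSES = (AUTOSOME, CHRX_PAR, CHRX_NONPAR)

# GRCh37 chrX pseudoautosomal boundaries (1-based, inclusive).
PAR1_END = 2_699_520
PAR2_START = 154_931_044

# MHC exclusion window on chr6 (GRCh37, generous bounds).
MHC_CHROM = "6"
MHC_START = 25_000_000
MHC_END = 34_000_000

_X_LABELS = {"X", "23", "chrX", "chr23"}


def is_chrx(chrom: str | int) -> bool:
    return str(chrom) in _X_LABELS


def classify_region(chrom: str | int, position: int,
                    par1_end: int = PAR1_END,
                    par2_start: int = PAR2_START) -> str:
    """Region class of a variant from chromosome label and 1-based position."""
    if not is_chrx(chrom):
        return AUTOSOME
    if position <= par1_end or position >= par2_start:
        return CHRX_PAR
    return CHRX_NONPAR


def in_mhc(chrom: str | int, position: int) -> bool:
    return str(chrom) == MHC_CHROM and MHC_START <= position <= MHC_END
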