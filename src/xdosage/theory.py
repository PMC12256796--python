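"""Closed-form expectations under X-chromosome dosage compensation.

Under the standard GWAS coding ({0,1,2} genotypes in females everywhere,
{0,2} in males in the non-pseudoautosomal region of chrX), full X
inactivation (XCI) with equal active-allele effects makes the per-locus
trait variance explained twice as large in males as in females, while
escape from XCI attenuates the male advantage and absent XCI reverses it.
This module collects the resulting algebraic expectations: the X influence
statistic XI = hX²/hA² under the X = A / X = AA scenarios, male:female
chrX-heritability ratios under XCI scenarios, chrX:autosome per-SNP
heritability ratios for an upregulation factor u, and the sex power bias.

Strata are "male", "female" or "combined", where combined quantities are
between-sex means (autosomal heritability is assumed sex-symmetric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

STRATA = ("male", "female", "combined")

#: Ratio of heritability-contributing variant counts chrX:autosomes from
#: common-variant counts (MAF >= 0.01) in Europeans.
PHI_COMMON_VARIANTS = 0.034

# Expected XI as a multiple of phi, per scenario and stratum.  Under X = AA
# one active X carries the effect of an autosome pair (active-allele effects
# doubled); under X = A it matches a single autosome copy.
_XI_FACTORS = {
    "X_eq_AA": {"male": 2.0, "female": 1.0, "combined": 1.5},
    "X_eq_A": {"male": 0.5, "female": 0.25, "combined": 0.375},
}


def expected_xi(scenario: str, stratum: str, phi: float) -> float:
    """Expected XI (= hX²/hA²) for a variant-count ratio ``phi``.

    ``scenario`` is ``"X_eq_AA"`` (2-fold active-allele effects in chrX) or
    ``"X_eq_A"`` (equal active-allele effects); ``stratum`` is ``"male"``,
    ``"female"`` or ``"combined"`` (between-sex mean).
    """
    if scenario not in _XI_FACTORS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return _XI_FACTORS[scenario][stratum] * phi


def variant_count_ratio(count_x: float, count_auto: float) -> float:
    """phi: ratio of contributing variant (or LD-block) counts chrX:autosomes."""
    if count_auto <= 0:
        raise ValueError("autosomal count must be positive")
    if count_x < 0:
        raise ValueError("chrX count must be non-negative")
    return count_x / count_auto


#: Same ratio derived from semi-independent LD-block counts, (71+5)/2479.
PHI_LD_BLOCKS = variant_count_ratio(71 + 5, 2479)


def escape_h2_ratio(escape_fraction: float, female_male_effect_ratio: float) -> float:
    """Male:female chrX h² ratio when a fraction of loci escape XCI.

    Non-escape loci contribute a per-locus male:female variance ratio of 2;
    a locus where the female effect is ``r`` times the male effect contributes
    2/r².  The chromosome-wide ratio is the locus-fraction-weighted mean
    2(1-p) + (2/r²)p, e.g. 1.75 for p = 0.25, r = sqrt(2).
    """
    p, r = escape_fraction, female_male_effect_ratio
    if not 0.0 <= p <= 1.0:
        raise ValueError("escape_fraction must be in [0, 1]")
    if r < 1.0:
        raise ValueError("female:male effect ratio below 1 is outside the escape model")
    return 2.0 * (1.0 - p) + (2.0 / r**2) * p


def per_snp_h2_ratio(u: float, stratum: str) -> float:
    """chrX:autosome per-SNP-h² ratio under full XCI for upregulation ``u``.

    ``u`` is the chrX:autosome active-allele effect ratio (u = 1 is X = A,
    u = 2 is X = AA).  Ratios are u²/2 in males, u²/4 in females and the
    between-sex mean 3u²/8 combined; u = sqrt(8/3) ≈ 1.6 balances the
    combined ratio at 1.
    """
    if u < 0:
        raise ValueError("u must be >= 0")
    if stratum == "male":
        return u**2 / 2.0
    if stratum == "female":
        return u**2 / 4.0
    if stratum == "combined":
        return 3.0 * u**2 / 8.0
    raise ValueError(f"unknown stratum {stratum!r}")


def balancing_upregulation() -> float:
    """u that equalizes the sex-combined per-SNP h² of chrX and autosomes."""
    return math.sqrt(8.0 / 3.0)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a single-locus association power calculation."""

    n: float
    maf: float
    active_effect: float
    alpha: float = 5e-8
    residual_variance: float = 1.0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.residual_variance <= 0:
            raise ValueError("residual variance must be positive")


def coded_genotype_variance(maf: float, sex: str, region: str) -> float:
    """Variance of the coded genotype: 2f(1-f) diploid, 4f(1-f) male non-PAR."""
    base = 2.0 * maf * (1.0 - maf)
    if sex == "male" and region == "chrX_nonPAR":
        return 2.0 * base
    return base


def detection_power(spec: PowerSpec, sex: str, region: str) -> float:
    """Power of the 1-df association chi-square test at one locus.

    The fitted coded-genotype effect is half the active-allele effect for
    chrX under the {0,1,2}/{0,2} scheme (a/2 in both sexes under full XCI),
    and the full allele effect on autosomes.  The non-centrality parameter is
    n·β²·var(G_coded)/var(residual); at equal a, f and n the male non-PAR NCP
    is twice the female one, which is the source of the male power bias.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    if region == "autosome":
        beta = spec.active_effect
    elif region in ("chrX_nonPAR", "chrX_PAR"):
        beta = spec.active_effect / 2.0
    else:
        raise ValueError(f"unknown region {region!r}")
    var_g = coded_genotype_variance(spec.maf, sex, region)
    ncp = spec.n * beta**2 * var_g / spec.residual_variance
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    if ncp == 0.0:
        return spec.alpha
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))
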