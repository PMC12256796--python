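"""Synthetic sex-stratified GWAS data under explicit XCI/upregulation scenarios.

The generative model follows the {0,1,2} female / {0,2} male non-PAR coding.
Writing a for the active-allele effect and λ ∈ [0,1] for the activity of the
inactive-X allele (λ = 0 full XCI, λ = 1 no XCI), the coded-genotype effects
at a chrX locus are

    male:   β_m = a / 2          (coding {0,2} halves the per-allele effect)
    female: β_f = (1 + λ) a / 2  (heterozygote functional dosage (1+λ)/2)

so the per-locus variance explained (β²·var(G_coded)) is β_m²·4f(1−f) in
males and β_f²·2f(1−f) in females: a male:female ratio of 2/(1+λ)², i.e. 2
under full XCI, 1 at λ = √2−1 and 0.5 with no XCI.  chrX active-allele
effects are u times autosomal ones (u = 1 is X = A, u = 2 is X = AA).

Causal variants carry equal expected variance explained (active-allele
effects scaled by 1/sqrt(2f(1−f))), the assumption behind the downstream
effect-size mixture.  Escape loci keep the *female* per-locus variance in
line with non-escape loci (the male effect is attenuated relative to the
female one, β_m = β_f/(1+λ)), which makes the chromosome-wide male:female
h² ratio equal the locus-weighted mean 2(1−p) + p·2/(1+λ)² — 1.75 at
p = 0.25, λ = √2−1 — matching :func:`xdosage.theory.escape_h2_ratio`.

Two generation paths share one parameterization: :func:`simulate_cohort` +
:func:`run_sex_specific_gwas` produce individual-level genotypes and run the
per-variant OLS, and :func:`simulate_sumstats_direct` draws β̂ around the
same true effects with SE² = var(y)/(n·var(G_coded)).  Every generated
quantity has a closed-form oracle in :func:`true_summaries`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .regions import AUTOSOME, CHRX_NONPAR

SQRT2 = math.sqrt(2.0)

_XCI_MODES = ("full", "escape", "none")


@dataclass(frozen=True)
class DosageScenario:
    """Generative parameters for dosage compensation on chrX.

    xci_mode: "full" (λ forced to 0), "escape" (a fraction of chrX causal
    loci keep inactive-allele activity λ) or "none" (λ forced to 1).
    upregulation: u, chrX:autosome active-allele effect ratio.
    phi: optional variant-count ratio chrX:autosomes used by theory
    comparisons; defaults to the simulated m_x/m_auto when unset.
    """

    xci_mode: str = "full"
    escape_fraction: float = 0.25
    inactive_activity: float = SQRT2 - 1.0
    upregulation: float = 1.0
    phi: float | None = None

    def __post_init__(self):
        if self.xci_mode not in _XCI_MODES:
            raise ValueError(f"unknown xci_mode {self.xci_mode!r}")
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ValueError("escape_fraction must be in [0, 1]")
        if not 0.0 <= self.inactive_activity <= 1.0:
            raise ValueError("inactive_activity (lambda) must be in [0, 1]")
        if self.upregulation <= 0:
            raise ValueError("upregulation u must be > 0")
        if self.phi is not None and self.phi < 0:
            raise ValueError("phi must be >= 0")

    @property
    def effective_lambda(self) -> float:
        """λ at escape loci after applying the mode override."""
        if self.xci_mode == "full":
            return 0.0
        if self.xci_mode == "none":
            return 1.0
        return self.inactive_activity

    @property
    def effective_escape_fraction(self) -> float:
        if self.xci_mode == "full":
            return 0.0
        if self.xci_mode == "none":
            return 1.0
        return self.escape_fraction

    @classmethod
    def full_xci(cls, upregulation: float = 1.0) -> "DosageScenario":
        return cls(xci_mode="full", upregulation=upregulation)

    @classmethod
    def escape_xci(cls, escape_fraction: float = 0.25,
                   inactive_activity: float = SQRT2 - 1.0,
                   upregulation: float = 1.0) -> "DosageScenario":
        return cls(xci_mode="escape", escape_fraction=escape_fraction,
                   inactive_activity=inactive_activity, upregulation=upregulation)

    @classmethod
    def no_xci(cls, upregulation: float = 1.0) -> "DosageScenario":
        return cls(xci_mode="none", upregulation=upregulation)


@dataclass(frozen=True)
class SimConfig:
    """Cohort sizes, variant counts and heritability targets for a run.

    ``h2_x`` is the *female* chrX heritability target (the male value follows
    from the scenario's male:female ratio); pass ``None`` to imply it from
    ``h2_auto`` via the variant-count ratio and upregulation (female chrX h²
    = h2_auto · (m_x/m_auto) · u²/4, the X-scenario algebra).  ``h2_auto``
    applies to both sexes.
    """

    n_males: int = 20_000
    n_females: int = 20_000
    m_auto: int = 0
    m_x: int = 2_000
    causal_fraction_auto: float = 0.1
    causal_fraction_x: float = 0.1
    h2_auto: float = 0.0
    h2_x: float | None = 0.03
    maf_range: tuple[float, float] = (0.05, 0.5)
    scenario: DosageScenario = field(default_factory=DosageScenario)
    seed: int = 0
    lambda_jitter: float = 0.0

    def __post_init__(self):
        if self.n_males <= 0 or self.n_females <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.m_auto < 0 or self.m_x < 0 or self.m_auto + self.m_x == 0:
            raise ValueError("variant counts must be non-negative and not all zero")
        for pi in (self.causal_fraction_auto, self.causal_fraction_x):
            if not 0.0 < pi <= 1.0:
                raise ValueError("causal fractions must be in (0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not 0.0 <= self.h2_auto < 1.0:
            raise ValueError("h2_auto must be in [0, 1)")
        if self.h2_x is not None and not 0.0 <= self.h2_x < 1.0:
            raise ValueError("h2_x must be in [0, 1)")
        if self.m_auto == 0 and self.h2_auto > 0:
            raise ValueError("h2_auto > 0 with no autosomal variants")
        if self.m_x == 0 and (self.h2_x or 0) > 0:
            raise ValueError("h2_x > 0 with no chrX variants")
        if self.h2_x is None and self.m_auto == 0:
            raise ValueError("implied h2_x needs autosomal variants")

    # -- derived generative quantities (closed form) ------------------------

    @property
    def h2_x_female(self) -> float:
        if self.h2_x is not None:
            return self.h2_x
        u = self.scenario.upregulation
        return self.h2_auto * (self.m_x / self.m_auto) * u**2 / 4.0

    @property
    def male_female_x_ratio(self) -> float:
        """True male:female chrX h² ratio implied by the scenario."""
        s = self.scenario
        p, lam = s.effective_escape_fraction, s.effective_lambda
        return 2.0 * (1.0 - p) + p * 2.0 / (1.0 + lam) ** 2

    @property
    def h2_x_male(self) -> float:
        return self.h2_x_female * self.male_female_x_ratio

    def h2_total(self, sex: str) -> float:
        hx = self.h2_x_male if sex == "male" else self.h2_x_female
        return self.h2_auto + hx

    def validate_feasible(self) -> None:
        for sex in ("male", "female"):
            if self.h2_total(sex) >= 1.0:
                raise ValueError(f"total {sex} h2 {self.h2_total(sex):.3f} >= 1")
        if self.h2_auto > 0 and round(self.causal_fraction_auto * self.m_auto) == 0:
            raise ValueError("zero autosomal causal variants with h2_auto > 0")
        if self.h2_x_female > 0 and round(self.causal_fraction_x * self.m_x) == 0:
            raise ValueError("zero chrX causal variants with h2_x > 0")


@dataclass
class SyntheticCohort:
    """Individual-level cohort with coded genotypes and per-variant truth."""

    config: SimConfig
    variants: pd.DataFrame        # metadata incl. true coded effects per sex
    geno_f: np.ndarray            # n_females x m, coded {0,1,2}
    geno_m: np.ndarray            # n_males x m, {0,1,2} autosomes, {0,2} non-PAR
    pheno_f: np.ndarray
    pheno_m: np.ndarray

    @property
    def n_males(self) -> int:
        return self.geno_m.shape[0]

    @property
    def n_females(self) -> int:
        return self.geno_f.shape[0]


def _draw_variant_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant metadata with true coded effects per sex, one row per variant."""
    s = config.scenario
    m = config.m_auto + config.m_x
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    is_x = np.arange(m) >= config.m_auto
    chrom = np.where(is_x, "X", "1")
    # 10 kb spacing; chrX positions inside the GRCh37 non-PAR interval.
    bp = np.empty(m, dtype=np.int64)
    bp[~is_x] = 1_000_000 + 10_000 * np.arange((~is_x).sum())
    bp[is_x] = 3_000_000 + 10_000 * np.arange(is_x.sum())
    region = np.where(is_x, CHRX_NONPAR, AUTOSOME)

    causal = np.zeros(m, bool)
    for sel, m_reg, pi in ((~is_x, config.m_auto, config.causal_fraction_auto),
                           (is_x, config.m_x, config.causal_fraction_x)):
        n_causal = int(round(pi * m_reg))
        if m_reg:
            idx = np.flatnonzero(sel)
            causal[rng.choice(idx, size=n_causal, replace=False)] = True

    escape = np.zeros(m, bool)
    lam = np.zeros(m)
    if s.xci_mode != "full":
        cx = causal & is_x
        if s.xci_mode == "none":
            escape[cx] = True
        else:
            escape[cx] = rng.random(cx.sum()) < s.escape_fraction
        lam_val = s.effective_lambda
        lam[escape] = lam_val
        if config.lambda_jitter > 0 and s.xci_mode == "escape":
            lam[escape] = np.clip(
                lam[escape] + rng.uniform(-config.lambda_jitter,
                                          config.lambda_jitter, escape.sum()),
                0.0, 1.0)

    # Per-causal-variant variance explained (constant within region):
    # autosomes s_A² per sex; chrX females u²s_A²/4 (or the explicit target).
    beta_f = np.zeros(m)
    beta_m = np.zeros(m)
    z = rng.standard_normal(m)
    var_g_dip = 2.0 * maf * (1.0 - maf)

    mc_a = int(round(config.causal_fraction_auto * config.m_auto))
    if mc_a and config.h2_auto > 0:
        s2_a = config.h2_auto / mc_a
        sel = causal & ~is_x
        b = z[sel] * np.sqrt(s2_a / var_g_dip[sel])
        beta_f[sel] = b
        beta_m[sel] = b

    mc_x = int(round(config.causal_fraction_x * config.m_x))
    if mc_x and config.h2_x_female > 0:
        v_f = config.h2_x_female / mc_x    # female per-causal variance explained
        sel = causal & is_x
        bf = z[sel] * np.sqrt(v_f / var_g_dip[sel])
        beta_f[sel] = bf
        beta_m[sel] = bf / (1.0 + lam[sel])

    return pd.DataFrame({
        "SNP": [f"{'x' if x else 'a'}_{i:06d}" for i, x in enumerate(is_x)],
        "CHR": chrom, "BP": bp, "A1": "A", "A2": "G",
        "A1FREQ": maf, "REGION": region,
        "CAUSAL": causal, "ESCAPE": escape, "LAMBDA": lam,
        "BETA_TRUE_F": beta_f, "BETA_TRUE_M": beta_m,
    })


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw coded genotypes and phenotypes for both sexes.

    Phenotypes are genetic value plus Gaussian noise with the noise variance
    set per sex so the phenotype has unit expected variance (traits are
    normalized per sex upstream of a GWAS).
    """
    config.validate_feasible()
    rng = np.random.default_rng(config.seed)
    variants = _draw_variant_frame(config, rng)
    maf = variants["A1FREQ"].to_numpy()
    is_x = (variants["REGION"] == CHRX_NONPAR).to_numpy()
    m = len(variants)

    geno_f = rng.binomial(2, maf, size=(config.n_females, m)).astype(np.int8)
    geno_m = np.empty((config.n_males, m), dtype=np.int8)
    geno_m[:, ~is_x] = rng.binomial(2, maf[~is_x], size=(config.n_males, (~is_x).sum()))
    geno_m[:, is_x] = 2 * rng.binomial(1, maf[is_x], size=(config.n_males, is_x.sum()))

    beta_f = variants["BETA_TRUE_F"].to_numpy()
    beta_m = variants["BETA_TRUE_M"].to_numpy()
    g_f = geno_f @ beta_f
    g_m = geno_m @ beta_m
    noise_f = math.sqrt(max(1.0 - config.h2_total("female"), 1e-6))
    noise_m = math.sqrt(max(1.0 - config.h2_total("male"), 1e-6))
    pheno_f = g_f - g_f.mean() + noise_f * rng.standard_normal(config.n_females)
    pheno_m = g_m - g_m.mean() + noise_m * rng.standard_normal(config.n_males)
    return SyntheticCohort(config=config, variants=variants,
                           geno_f=geno_f, geno_m=geno_m,
                           pheno_f=pheno_f, pheno_m=pheno_m)


def _ols_per_variant(G: np.ndarray, y: np.ndarray):
    """Vectorized simple linear regression of y on each genotype column."""
    n = G.shape[0]
    Gc = G - G.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    ssg = (Gc**2).sum(axis=0)
    mono = ssg == 0
    ssg_safe = np.where(mono, np.nan, ssg)
    beta = (Gc * yc[:, None]).sum(axis=0) / ssg_safe
    rss = (yc**2).sum() - beta**2 * ssg_safe
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / ssg_safe)
    return beta, se, mono


def run_sex_specific_gwas(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-variant OLS of phenotype on coded genotype, separately per sex.

    Monomorphic variants (no genotype variance in a sex) are flagged and
    excluded with a log entry.  Output follows the native sumstats layout
    plus the generator's truth columns and QC fields (MISS per sex, female
    Hardy-Weinberg chi-square p).
    """
    import logging
    log = logging.getLogger(__name__)
    cfg = cohort.config
    if cfg.n_males < 30 or cfg.n_females < 30:
        raise ValueError("need at least 30 individuals per sex")
    out = cohort.variants.copy()
    bf, sef, mono_f = _ols_per_variant(cohort.geno_f.astype(np.float64), cohort.pheno_f)
    bm, sem, mono_m = _ols_per_variant(cohort.geno_m.astype(np.float64), cohort.pheno_m)
    out["BETA_F"], out["SE_F"] = bf, sef
    out["BETA_M"], out["SE_M"] = bm, sem
    out["P_F"] = stats.chi2.sf((bf / sef) ** 2, df=1)
    out["P_M"] = stats.chi2.sf((bm / sem) ** 2, df=1)
    out["N_F"], out["N_M"] = cfg.n_females, cfg.n_males
    out["MISS_F"] = 0.0
    out["MISS_M"] = 0.0
    out["HWE_P"] = _female_hwe_p(cohort.geno_f)
    bad = mono_f | mono_m
    for snp in out.loc[bad, "SNP"]:
        log.warning("monomorphic variant excluded from GWAS output: %s", snp)
    return out.loc[~bad].reset_index(drop=True)


def _female_hwe_p(geno_f: np.ndarray) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg test on female genotype counts."""
    n = geno_f.shape[0]
    n_aa = (geno_f == 2).sum(axis=0)
    n_ab = (geno_f == 1).sum(axis=0)
    f = (2 * n_aa + n_ab) / (2 * n)
    exp = np.stack([n * (1 - f) ** 2, 2 * n * f * (1 - f), n * f**2])
    obs = np.stack([n - n_aa - n_ab, n_ab, n_aa])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    return stats.chi2.sf(chi2, df=1)


def simulate_sumstats_direct(config: SimConfig) -> pd.DataFrame:
    """Draw summary statistics directly around the true coded effects.

    β̂ = β_true + N(0, SE²) with SE² = var(y)/(n·var(G_coded)) and unit
    phenotype variance; moment-matched to :func:`run_sex_specific_gwas` and
    orders of magnitude faster.  QC columns are emitted at their ideal
    values (no missingness, uniform Hardy-Weinberg p) since no genotypes
    are realized on this path.
    """
    config.validate_feasible()
    rng = np.random.default_rng(config.seed)
    out = _draw_variant_frame(config, rng)
    maf = out["A1FREQ"].to_numpy()
    is_x = (out["REGION"] == CHRX_NONPAR).to_numpy()
    var_g_f = 2.0 * maf * (1.0 - maf)
    var_g_m = np.where(is_x, 4.0 * maf * (1.0 - maf), var_g_f)
    se_f = np.sqrt(1.0 / (config.n_females * var_g_f))
    se_m = np.sqrt(1.0 / (config.n_males * var_g_m))
    out["BETA_F"] = out["BETA_TRUE_F"] + se_f * rng.standard_normal(len(out))
    out["BETA_M"] = out["BETA_TRUE_M"] + se_m * rng.standard_normal(len(out))
    out["SE_F"], out["SE_M"] = se_f, se_m
    out["P_F"] = stats.chi2.sf((out["BETA_F"] / se_f) ** 2, df=1)
    out["P_M"] = stats.chi2.sf((out["BETA_M"] / se_m) ** 2, df=1)
    out["N_F"], out["N_M"] = config.n_females, config.n_males
    out["MISS_F"] = 0.0
    out["MISS_M"] = 0.0
    out["HWE_P"] = rng.uniform(size=len(out))
    return out


@dataclass(frozen=True)
class TrueSummaries:
    """Closed-form ground truth implied by a SimConfig."""

    h2: dict            # (sex, region) -> h²
    xi: dict            # stratum -> hX²/hA² (nan when h2_auto == 0)
    male_female_x_ratio: float
    mixture_proportions: dict   # chrX component shares under alpha=2 labels
    phi: float


def true_summaries(config: SimConfig) -> TrueSummaries:
    """Oracle record used as ground truth in recovery tests.

    The mixture proportions classify chrX causal loci by their female:male
    coded-effect ratio: 1 -> equal (M2), 2 -> female-biased at α = 2 (M1);
    escape loci with intermediate attenuation (e.g. √2) are counted as
    female_biased with the caveat that their ratio is below α.
    """
    s = config.scenario
    h2 = {
        ("male", "autosomes"): config.h2_auto,
        ("female", "autosomes"): config.h2_auto,
        ("male", "chrX"): config.h2_x_male,
        ("female", "chrX"): config.h2_x_female,
    }
    h2[("combined", "chrX")] = (h2[("male", "chrX")] + h2[("female", "chrX")]) / 2
    h2[("combined", "autosomes")] = config.h2_auto
    xi = {}
    for stratum in ("male", "female", "combined"):
        ha = h2[(stratum, "autosomes")]
        xi[stratum] = h2[(stratum, "chrX")] / ha if ha > 0 else float("nan")
    pi_c = config.causal_fraction_x
    p_esc = s.effective_escape_fraction
    props = {
        "null": 1.0 - pi_c,
        "female_biased": pi_c * p_esc,
        "equal": pi_c * (1.0 - p_esc),
        "male_biased": 0.0,
    }
    phi = s.phi if s.phi is not None else (
        config.m_x / config.m_auto if config.m_auto else float("nan"))
    return TrueSummaries(h2=h2, xi=xi,
                         male_female_x_ratio=config.male_female_x_ratio,
                         mixture_proportions=props, phi=phi)


def scenario_config(scenario: DosageScenario, **overrides) -> SimConfig:
    """Convenience constructor binding a scenario into a SimConfig."""
    return replace(SimConfig(scenario=scenario), **overrides)
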