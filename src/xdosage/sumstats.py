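"""Sex-stratified GWAS summary-statistic tables: schema, I/O and utilities.

The in-memory container is a pandas DataFrame in the *native* layout, one
row per variant with both sexes side by side:

    SNP CHR BP A1 A2 A1FREQ REGION
    BETA_F SE_F P_F N_F  BETA_M SE_M P_M N_M

A1 is the effect allele; after reading, frequencies are folded so A1FREQ is
the minor-allele frequency (effect signs flip accordingly).  REGION is one
of ``autosome``, ``chrX_PAR``, ``chrX_nonPAR`` and is derived from CHR/BP
when absent.  Extra columns (true effects, QC fields emitted by the
synthetic generator) ride along untouched.

Also here: the phenotype-preparation utilities used upstream of a GWAS
(6-SD outlier removal + rank-based inverse-normal transform, blood-pressure
medication offsets, statin correction) and the post-GWAS operations shared
by the analyses (lead-variant region calling, non-PAR active-allele
rescaling, male power equalization, bootstrap CI of a median).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import classify_region

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "A1FREQ",
    "BETA_F", "SE_F", "P_F", "N_F",
    "BETA_M", "SE_M", "P_M", "N_M",
]

#: Column maps for external single-sex dialects -> native per-sex names.
DIALECTS = {
    "native": None,
    "bolt-like": {
        "SNP": "SNP", "CHR": "CHR", "BP": "BP",
        "ALLELE1": "A1", "ALLELE0": "A2", "A1FREQ": "A1FREQ",
        "BETA": "BETA", "SE": "SE", "P_BOLT_LMM": "P", "N": "N",
    },
    "regenie-like": {
        "ID": "SNP", "CHROM": "CHR", "GENPOS": "BP",
        "ALLELE1": "A1", "ALLELE0": "A2", "A1FREQ": "A1FREQ",
        "BETA": "BETA", "SE": "SE", "P": "P", "N": "N",
    },
}


class SumStatError(ValueError):
    pass


def _ensure_region(df: pd.DataFrame) -> pd.DataFrame:
    if "REGION" not in df.columns:
        df = df.copy()
        df["REGION"] = [classify_region(c, int(b)) for c, b in zip(df["CHR"], df["BP"])]
    return df


def fold_to_minor(df: pd.DataFrame) -> pd.DataFrame:
    """Fold A1FREQ to the minor allele, flipping effect signs and alleles."""
    df = df.copy()
    flip = df["A1FREQ"].to_numpy(float) > 0.5
    if flip.any():
        for b in ("BETA_F", "BETA_M"):
            if b in df.columns:
                df.loc[flip, b] = -df.loc[flip, b]
        a1 = df.loc[flip, "A1"].copy()
        df.loc[flip, "A1"] = df.loc[flip, "A2"]
        df.loc[flip, "A2"] = a1
        df.loc[flip, "A1FREQ"] = 1.0 - df.loc[flip, "A1FREQ"]
    return df


def validate_sumstats(df: pd.DataFrame, sexes: tuple[str, ...] = ("F", "M")) -> pd.DataFrame:
    """Drop malformed rows (non-positive SE, p outside (0,1], bad MAF), logging each."""
    keep = np.ones(len(df), bool)
    reasons = []
    freq = df["A1FREQ"].to_numpy(float)
    bad = ~((freq > 0.0) & (freq < 1.0))
    for s in sexes:
        se = df[f"SE_{s}"].to_numpy(float)
        p = df[f"P_{s}"].to_numpy(float)
        bad |= ~(se > 0.0) | ~((p > 0.0) & (p <= 1.0))
    for i in np.flatnonzero(bad):
        reasons.append(f"line {i + 2}: invalid SE/P/A1FREQ for {df['SNP'].iat[i]}")
    keep &= ~bad
    for r in reasons:
        logger.warning("rejected sumstat row: %s", r)
    out = df.loc[keep].reset_index(drop=True)
    return out


def read_sumstats(path, dialect: str = "native", sex: str | None = None) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file into the native layout.

    ``dialect="native"`` expects both-sex columns; the single-sex dialects
    (``bolt-like``, ``regenie-like``) require ``sex`` ("F" or "M") and
    produce a frame with that sex's columns only (merge with
    :func:`merge_sex_tables`).
    """
    if dialect not in DIALECTS:
        raise SumStatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    if dialect == "native":
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SumStatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = validate_sumstats(df)
    else:
        if sex not in ("F", "M"):
            raise SumStatError("single-sex dialects require sex='F' or 'M'")
        cmap = dict(DIALECTS[dialect])
        missing = [c for c in cmap if c not in df.columns]
        if missing:
            raise SumStatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.rename(columns=cmap)
        df = df.rename(columns={k: f"{k}_{sex}" for k in ("BETA", "SE", "P", "N")})
        df = validate_sumstats(df, sexes=(sex,))
    df = _ensure_region(df)
    return fold_to_minor(df)


def merge_sex_tables(female: pd.DataFrame, male: pd.DataFrame) -> pd.DataFrame:
    """Join single-sex frames on variant identity into the native layout."""
    keys = ["SNP", "CHR", "BP", "A1", "A2", "REGION"]
    out = female.merge(male.drop(columns=["A1FREQ"]), on=keys, how="inner")
    return out


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype preparation


def inverse_normal_transform(values, outlier_sd: float = 6.0) -> np.ndarray:
    """Rank-based inverse-normal transform with prior 6-SD outlier removal.

    Points farther than ``outlier_sd`` standard deviations from the mean are
    set to NaN before ranking; remaining values are mapped through
    Phi^{-1}((rank - 0.5)/n).  Rank order is preserved; output has mean ~0
    and SD ~1.  NaNs propagate.
    """
    x = np.asarray(values, float).copy()
    ok = np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    mu, sd = x[ok].mean(), x[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("all values identical; ranks undefined")
    x[ok & (np.abs(x - mu) > outlier_sd * sd)] = np.nan
    ok = np.isfinite(x)
    n = ok.sum()
    out = np.full_like(x, np.nan)
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def adjust_blood_pressure(values, trait: str, on_medication) -> np.ndarray:
    """Add the medication offset (+15 systolic / +10 diastolic mmHg) to flagged rows."""
    offsets = {"systolic": 15.0, "diastolic": 10.0}
    if trait not in offsets:
        raise ValueError(f"unknown blood-pressure trait {trait!r}")
    x = np.asarray(values, float).copy()
    flags = np.asarray(on_medication, bool)
    if flags.shape != x.shape:
        raise ValueError("medication flags must align with values")
    x[flags] += offsets[trait]
    return x


@dataclass(frozen=True)
class StatinAdjustment:
    values: np.ndarray
    factor: float
    p_value: float
    applied: bool


def statin_adjust(pre_values, on_values, population_values, statin_user,
                  alpha: float = 0.05) -> StatinAdjustment:
    """Statin correction for a biomarker.

    The factor is the mean on-statin/pre-statin ratio over paired individuals;
    statin users' population values are divided by it only when the paired
    signed-rank test finds a significant pre/on difference (p < ``alpha``).
    """
    pre = np.asarray(pre_values, float)
    on = np.asarray(on_values, float)
    if pre.size == 0 or pre.size != on.size:
        raise ValueError("need matched, non-empty pre/on pairs")
    if pre.size < 2:
        raise ValueError("need at least 2 pre/on pairs")
    if np.any(pre == 0):
        raise ValueError("pre-statin value of 0 makes the ratio undefined")
    factor = float(np.mean(on / pre))
    diff = on - pre
    if np.all(diff == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(on, pre).pvalue)
    x = np.asarray(population_values, float).copy()
    flags = np.asarray(statin_user, bool)
    applied = p < alpha
    if applied:
        x[flags] = x[flags] / factor
    return StatinAdjustment(values=x, factor=factor, p_value=p, applied=applied)


# ---------------------------------------------------------------------------
# Lead variants and effect rescaling


@dataclass(frozen=True)
class AssociationRegion:
    chromosome: str
    start: int
    end: int
    lead_snp: str
    lead_bp: int
    lead_p: float


def identify_lead_variants(df: pd.DataFrame, sex: str = "F",
                           p_threshold: float = 5e-8,
                           region_span: int = 500_000) -> list[AssociationRegion]:
    """Call merged association regions around genome-wide significant variants.

    Every variant with p below threshold seeds a window of total width
    ``region_span`` centered on it; overlapping windows on a chromosome merge
    transitively; each merged region's lead is its smallest-p variant (ties:
    smallest position, then id).
    """
    half = region_span // 2
    p = df[f"P_{sex}"].to_numpy(float)
    sig = df.loc[p < p_threshold, ["SNP", "CHR", "BP"]].copy()
    sig["P"] = p[p < p_threshold]
    regions: list[AssociationRegion] = []
    for chrom, grp in sig.groupby("CHR", sort=True):
        grp = grp.sort_values(["BP", "SNP"]).reset_index(drop=True)
        start = end = None
        members = []

        def flush():
            m = pd.DataFrame(members)
            m = m.sort_values(["P", "BP", "SNP"]).iloc[0]
            regions.append(AssociationRegion(str(chrom), int(start), int(end),
                                             str(m["SNP"]), int(m["BP"]), float(m["P"])))

        for _, row in grp.iterrows():
            lo, hi = int(row["BP"]) - half, int(row["BP"]) + half
            if start is None:
                start, end, members = lo, hi, [row]
            elif lo <= end:
                end = max(end, hi)
                members.append(row)
            else:
                flush()
                start, end, members = lo, hi, [row]
        if start is not None:
            flush()
    regions.sort(key=lambda r: (r.chromosome, r.start))
    return regions


def active_allele_scale(df: pd.DataFrame) -> pd.DataFrame:
    """Rescale non-PAR effects to the active-allele scale (beta and SE x2).

    Under {0,2} male / {0,1,2} female coding with full XCI the fitted
    coefficient is half the active-allele effect, so doubling recovers a in
    both sexes.  PAR and autosomal rows, p-values and z-scores are untouched.
    A provenance column ``ACTIVE_SCALED`` guards against double application.
    """
    if "ACTIVE_SCALED" in df.columns and df["ACTIVE_SCALED"].any():
        raise ValueError("table already on the active-allele scale")
    df = df.copy()
    mask = df["REGION"] == "chrX_nonPAR"
    for s in ("F", "M"):
        for col in (f"BETA_{s}", f"SE_{s}"):
            if col in df.columns:
                df.loc[mask, col] = 2.0 * df.loc[mask, col]
    df["ACTIVE_SCALED"] = mask
    return df


def equalize_power_males(df: pd.DataFrame = None, mode: str = "se-inflate",
                         cohort=None, seed: int = 0):
    """Equalize male non-PAR association power with the autosomal analysis.

    The {0,2} coding doubles the male non-PAR variance explained; halving the
    effective male sample removes the bias.  ``mode="se-inflate"`` operates on
    summary statistics (SE x sqrt(2), N halved, p recomputed from the new z);
    ``mode="individual-downsample"`` returns a seeded half-sample of male
    indices for a cohort re-analysis.
    """
    if mode == "individual-downsample":
        if cohort is None:
            raise ValueError("individual-downsample mode requires cohort data")
        n_m = cohort.n_males
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(n_m, size=n_m // 2, replace=False))
    if mode != "se-inflate":
        raise ValueError(f"unknown mode {mode!r}")
    out = df.copy()
    mask = out["REGION"] == "chrX_nonPAR"
    out.loc[mask, "SE_M"] = out.loc[mask, "SE_M"] * np.sqrt(2.0)
    out.loc[mask, "N_M"] = out.loc[mask, "N_M"] / 2.0
    z = out.loc[mask, "BETA_M"] / out.loc[mask, "SE_M"]
    out.loc[mask, "P_M"] = stats.chi2.sf(z**2, df=1)
    return out


def bootstrap_median_ci(values, n_boot: int = 2000, level: float = 0.95,
                        seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the median; seeded and reproducible."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile CIs")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    lo, hi = np.quantile(meds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(np.median(x)), float(lo), float(hi)
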