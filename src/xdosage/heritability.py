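"""SNP-heritability estimation from sex-stratified summary statistics.

Works on approximately independent variants (the synthetic default, or
post-pruning data).  Effects are first standardized to the variance-explained
scale, u_j = β̂_j·sqrt(var(G_coded,j)), so that u_j² is the phenotypic
variance explained by variant j for a unit-variance trait and the sampling
SD of u_j is SE_j·sqrt(var(G_coded,j)) ≈ 1/sqrt(n).  On that scale the
two-component effect-size mixture

    u_j ~ (1 - πc)·N(0, s_j²) + πc·N(0, σ² + s_j²)

is fit by EM, giving the polygenicity πc (proportion of non-null variants),
the heritability per causal variant σ², and h² = M·πc·σ².  The X influence
XI = hX²/hA² carries a delta-method SE, hX² = 0 is tested with
T = (ĥ²/SE)² ~ χ²₁, and multiple traits are FDR-controlled by
Benjamini-Hochberg.  LD scores (tagging r² > 0.1 within 1 Mb, small-sample
adjusted) are computed from a genotype-like reference for LD-aware inputs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import CHRX_NONPAR

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class H2Estimate:
    """A (trait, stratum, region) SNP heritability with its decomposition."""

    trait: str
    stratum: str            # male | female | combined
    region: str             # chrX | autosomes
    h2: float
    se: float
    pi_c: float = float("nan")
    sigma2: float = float("nan")
    M: int = 0
    method: str = "mixture"

    def __post_init__(self):
        if self.M and np.isfinite(self.pi_c) and np.isfinite(self.sigma2):
            assert abs(self.h2 - self.M * self.pi_c * self.sigma2) < 1e-8 + 1e-6 * abs(self.h2)


@dataclass
class XIEstimate:
    trait: str
    stratum: str
    xi: float
    se: float


def _standardized(df: pd.DataFrame, stratum: str, region: str):
    """(u, s) on the variance-explained scale for one sex and genome region."""
    if region == "chrX":
        sel = df["REGION"].isin(["chrX_PAR", "chrX_nonPAR"])
    elif region == "autosomes":
        sel = df["REGION"] == "autosome"
    else:
        raise ValueError(f"unknown region {region!r}")
    sub = df.loc[sel]
    sex = {"male": "M", "female": "F"}[stratum]
    f = sub["A1FREQ"].to_numpy(float)
    var_g = 2.0 * f * (1.0 - f)
    if stratum == "male":
        var_g = np.where(sub["REGION"] == CHRX_NONPAR, 2.0 * var_g, var_g)
    w = np.sqrt(var_g)
    u = sub[f"BETA_{sex}"].to_numpy(float) * w
    s = sub[f"SE_{sex}"].to_numpy(float) * w
    return u, s, sub


def _mixture_loglik(u, s2, pi_c, sigma2):
    l0 = stats.norm.logpdf(u, scale=np.sqrt(s2))
    l1 = stats.norm.logpdf(u, scale=np.sqrt(sigma2 + s2))
    a = np.log1p(-pi_c) + l0 if pi_c < 1 else np.full_like(l0, -np.inf)
    b = np.log(pi_c) + l1 if pi_c > 0 else np.full_like(l1, -np.inf)
    mx = np.maximum(a, b)
    return float(np.sum(mx + np.log(np.exp(a - mx) + np.exp(b - mx))))


def _sigma2_mstep(u, s2, r, v0):
    """Weighted-likelihood update of sigma2 by damped Newton (v >= 0)."""
    v = max(v0, 1e-12)
    for _ in range(60):
        t = v + s2
        g = 0.5 * np.sum(r * (u**2 - t) / t**2)
        h = np.sum(r * (0.5 / t**2 - u**2 / t**3))
        if h >= 0:   # fall back to a gradient step when not concave
            step = 0.5 * g * v / (abs(g) * v + 1e-12) * v
        else:
            step = -g / h
        v_new = v + step
        if not np.isfinite(v_new) or v_new <= 0:
            v_new = v / 2 if g < 0 else v * 2
        if abs(v_new - v) < 1e-14 + 1e-10 * v:
            v = v_new
            break
        v = v_new
    return max(v, 0.0)


def _em_fit(u, s2, pi0, v0, fix_pi_c, max_iter, tol):
    pi_c, v = pi0, max(v0, 1e-10)
    trace = []
    ll_old = -np.inf
    for it in range(max_iter):
        if fix_pi_c is not None:
            pi_c = fix_pi_c
        if 0 < pi_c < 1:
            a = np.log1p(-pi_c) + stats.norm.logpdf(u, scale=np.sqrt(s2))
            b = np.log(pi_c) + stats.norm.logpdf(u, scale=np.sqrt(v + s2))
            mx = np.maximum(a, b)
            r = np.exp(b - mx) / (np.exp(a - mx) + np.exp(b - mx))
        else:
            r = np.full_like(u, float(pi_c))
        if fix_pi_c is None:
            pi_c = float(np.clip(r.mean(), 1e-6, 1.0))
        v = _sigma2_mstep(u, s2, r, v)
        ll = _mixture_loglik(u, s2, pi_c, v)
        trace.append(ll)
        if it > 0 and abs(ll - ll_old) < tol * (abs(ll_old) + 1e-3):
            return pi_c, v, ll, trace, True
        ll_old = ll
    return pi_c, v, ll_old, trace, False


def fit_effect_mixture(df: pd.DataFrame, stratum: str, region: str,
                       trait: str = "trait", M: int | None = None,
                       fix_pi_c: float | None = None,
                       n_restarts: int = 10, max_iter: int = 3000,
                       tol: float = 1e-8,
                       se_method: str = "bootstrap", n_boot: int = 200,
                       seed: int = 0) -> H2Estimate:
    """Fit the two-component effect-size mixture and return h² = M·πc·σ².

    σ² is initialized by method of moments on the top 1% |z| variants and
    πc at 0.01; seeded random restarts guard against local optima.  SEs come
    from a seeded nonparametric bootstrap over variants (``se_method=
    "bootstrap"``), a numerical observed-information approximation
    (``"info"``), or are skipped (``"none"``).  ``fix_pi_c=1`` reduces the
    model to the method-of-moments estimator mean(u² − s²).
    """
    u, s, _ = _standardized(df, stratum, region)
    mobs = u.size
    if M is None:
        M = mobs
    if M < 50:
        warnings.warn("fewer than 50 variants; mixture h2 will be unstable")
    s2 = s**2
    z2 = (u / s) ** 2
    top = z2 >= np.quantile(z2, 0.99)
    mom_top = float(np.mean(u[top] ** 2 - s2[top]))
    if mom_top <= 0:
        warnings.warn("negative method-of-moments variance clipped at 0")
        mom_top = float(np.mean(s2)) * 0.1
    rng = np.random.default_rng(seed)
    starts = [(0.01 if fix_pi_c is None else fix_pi_c, mom_top)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append((float(rng.uniform(0.005, 0.5)) if fix_pi_c is None else fix_pi_c,
                       mom_top * float(rng.uniform(0.1, 3.0))))
    best = None
    for pi0, v0 in starts:
        pi_c, v, ll, trace, conv = _em_fit(u, s2, pi0, v0, fix_pi_c, max_iter, tol)
        if best is None or ll > best[2]:
            best = (pi_c, v, ll, trace, conv)
    pi_c, v, ll, trace, conv = best
    if not conv:
        raise ConvergenceError(f"EM did not converge in {max_iter} iterations", trace)
    h2 = M * pi_c * v

    if se_method == "none":
        se = float("nan")
    elif se_method == "info":
        se = _h2_se_info(u, s2, pi_c, v, M, fix_pi_c)
    elif se_method == "bootstrap":
        draws = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, mobs, size=mobs)
            pb, vb, *_ = _em_fit(u[idx], s2[idx], pi_c, v, fix_pi_c,
                                 max_iter, tol)
            draws[b] = M * pb * vb
        se = float(draws.std(ddof=1))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return H2Estimate(trait=trait, stratum=stratum, region=region,
                      h2=float(h2), se=se, pi_c=float(pi_c), sigma2=float(v),
                      M=int(M), method="mixture")


def _h2_se_info(u, s2, pi_c, v, M, fix_pi_c):
    """Delta-method SE of h² from a finite-difference observed information."""
    free_pi = fix_pi_c is None and 0 < pi_c < 1

    def ll(theta):
        p = float(np.clip(theta[0], 1e-8, 1 - 1e-8)) if free_pi else pi_c
        vv = max(theta[-1], 1e-12)
        return _mixture_loglik(u, s2, p, vv)

    theta = np.array([pi_c, v]) if free_pi else np.array([v])
    eps = np.maximum(1e-5 * np.abs(theta), 1e-9)
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * eps[i]
            ej = np.eye(k)[j] * eps[j]
            H[i, j] = H[j, i] = (
                ll(theta + ei + ej) - ll(theta + ei - ej)
                - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4 * eps[i] * eps[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return float("nan")
    grad = np.array([M * v, M * pi_c]) if free_pi else np.array([M * pi_c])
    var = float(grad @ cov @ grad)
    return math.sqrt(var) if var > 0 else float("nan")


def chi2_h2(df: pd.DataFrame, stratum: str, region: str,
            trait: str = "trait", M: int | None = None) -> H2Estimate:
    """Moment estimator h² = M·(mean χ² − 1)/n̄ for independent variants.

    The SE follows from the sampling variance of the mean χ² statistic.
    Negative estimates are clipped at 0 with a warning.
    """
    sex = {"male": "M", "female": "F"}[stratum]
    u, s, sub = _standardized(df, stratum, region)
    if f"N_{sex}" not in sub.columns or sub[f"N_{sex}"].isna().any():
        raise ValueError("per-variant sample size N is required")
    m_obs = u.size
    if M is None:
        M = m_obs
    chi2 = (u / s) ** 2
    nbar = float(sub[f"N_{sex}"].mean())
    h2 = M * (float(chi2.mean()) - 1.0) / nbar
    se = M * float(chi2.std(ddof=1)) / (math.sqrt(m_obs) * nbar)
    if h2 < 0:
        warnings.warn("chi-square h2 estimate below 0; clipped")
        h2 = 0.0
    return H2Estimate(trait=trait, stratum=stratum, region=region,
                      h2=h2, se=se, M=int(M), method="chi2")


def xi(h2_x: H2Estimate, h2_a: H2Estimate) -> XIEstimate:
    """X influence XI = hX²/hA² with the delta-method SE

    SE(XI) = XI · sqrt(SE²(hX²)/hX²·² + SE²(hA²)/hA²·²).
    """
    if h2_a.h2 <= 0:
        raise ValueError("autosomal h2 must be positive")
    if h2_x.h2 < 0:
        raise ValueError("chrX h2 must be non-negative")
    val = h2_x.h2 / h2_a.h2
    if h2_x.h2 == 0:
        se = float("nan")
    else:
        se = val * math.sqrt((h2_x.se / h2_x.h2) ** 2 + (h2_a.se / h2_a.h2) ** 2)
    return XIEstimate(trait=h2_x.trait, stratum=h2_x.stratum, xi=val, se=se)


def combined_estimate(male: H2Estimate, female: H2Estimate) -> H2Estimate:
    """Sex-combined h² as the mean of the sex-specific estimates.

    Male and female strata are disjoint samples, so the SE of the average is
    sqrt(se_m² + se_f²)/2.
    """
    if male.trait != female.trait or male.region != female.region:
        raise ValueError("estimates must share trait and region")
    return H2Estimate(trait=male.trait, stratum="combined", region=male.region,
                      h2=(male.h2 + female.h2) / 2.0,
                      se=math.sqrt(male.se**2 + female.se**2) / 2.0,
                      M=male.M, method=male.method)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] / (np.arange(1, n + 1) / n)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def test_h2_zero(estimates: list[H2Estimate]) -> pd.DataFrame:
    """Test h² = 0 per trait with T = (ĥ²/SE)² ~ χ²₁ and BH FDR over the set."""
    for e in estimates:
        if not e.se > 0:
            raise ValueError(f"non-positive SE for trait {e.trait}")
    T = np.array([(e.h2 / e.se) ** 2 for e in estimates])
    p = stats.chi2.sf(T, df=1)
    return pd.DataFrame({
        "trait": [e.trait for e in estimates],
        "stratum": [e.stratum for e in estimates],
        "region": [e.region for e in estimates],
        "h2": [e.h2 for e in estimates],
        "se": [e.se for e in estimates],
        "T": T, "p": p, "q": bh_qvalues(p),
    })


def ld_scores(reference: np.ndarray, positions, window: float = 1_000_000,
              tag_r2: float = 0.1, adjust: bool = True) -> np.ndarray:
    """Per-variant LD scores from a genotype-like reference matrix.

    A variant tags a GWAS marker when its raw r² exceeds ``tag_r2`` and it
    lies within ``window`` bp; the score sums the small-sample adjusted
    r̃² = r² − (1 − r²)/(n_ref − 2) over tagging variants (self included);
    ``adjust=False`` sums the raw r², which overstates scores by roughly
    (m − 1)/n_ref for unlinked variants.  Monomorphic reference variants
    get NaN and a log entry.
    """
    R = np.asarray(reference, float)
    n_ref, m = R.shape
    if n_ref < 3:
        raise ValueError("reference needs at least 3 samples")
    pos = np.asarray(positions, float)
    sd = R.std(axis=0)
    mono = sd == 0
    for j in np.flatnonzero(mono):
        logger.warning("monomorphic reference variant excluded from LD scores: %d", j)
    Z = np.zeros_like(R)
    Z[:, ~mono] = (R[:, ~mono] - R[:, ~mono].mean(axis=0)) / sd[~mono]
    scores = np.full(m, np.nan)
    order = np.argsort(pos, kind="mergesort")
    for jj, j in enumerate(order):
        if mono[j]:
            continue
        lo = np.searchsorted(pos[order], pos[j] - window)
        hi = np.searchsorted(pos[order], pos[j] + window, side="right")
        nb = order[lo:hi]
        nb = nb[~mono[nb]]
        r = (Z[:, nb].T @ Z[:, j]) / n_ref
        r2 = r**2
        tag = r2 > tag_r2
        vals = r2[tag]
        if adjust:
            vals = vals - (1.0 - vals) / (n_ref - 2)
        scores[j] = float(vals.sum())
    return scores
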