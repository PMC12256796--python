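"""Four-component mixture model of sex-specific genetic effects.

Scaled sex-specific effect estimates (β̂_f, β̂_m) for approximately
independent variants are modeled as a mixture of four zero-mean bivariate
Gaussians: M0 null, M1 female-biased (β_f = α·β_m), M2 equal, M3
male-biased (β_m = α·β_f), with a shared non-null effect variance σ² and
perfect within-variant cross-sex effect correlation:

    [β̂_f, β̂_m] ~ N(0, diag(SE_f², SE_m²) + σ²·Σ_k),
    Σ0 = 0,  Σ1 = [[α², α], [α, 1]],  Σ2 = [[1, 1], [1, 1]],
    Σ3 = [[1, α], [α, α²]],  α = 2 by default.

Priors are Dirichlet(1/4, 1/4, 1/4, 1/4) on the proportions π and
Uniform(0,1) on σ².  The default inference is MAP by EM with seeded
restarts (posterior maximized in an unconstrained parameterization, with
Wald/normal posterior draws for CIs); ``mode="mcmc"`` samples the same
posterior with an affine-invariant ensemble sampler and a split-Rhat
convergence check.  Fits whose restarts (or chains) disagree are rejected.

Effect standardization multiplies β̂ and SE by sqrt(2f(1−f)) so the scaled
β̂² is the per-variant phenotypic variance explained and, a priori, every
variant carries similar weight; a flag restores the literal 2f(1−f)
multiplier.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .regions import in_mhc

logger = logging.getLogger(__name__)

COMPONENTS = ("M0", "M1", "M2", "M3")


class MixtureDiagnosticError(RuntimeError):
    """Restart or chain disagreement; the fit is rejected, not returned."""


def component_covariances(alpha: float) -> np.ndarray:
    """Stacked Σ_k matrices, k = 0..3, in (female, male) coordinate order."""
    a = alpha
    return np.array([
        [[0.0, 0.0], [0.0, 0.0]],
        [[a * a, a], [a, 1.0]],
        [[1.0, 1.0], [1.0, 1.0]],
        [[1.0, a], [a, a * a]],
    ])


@dataclass
class MixtureFit:
    pi: np.ndarray
    sigma2: float
    alpha: float
    loglik: float
    mode: str
    n_variants: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    pi_ci: np.ndarray | None = None       # (4, 2) lower/upper
    sigma2_ci: tuple | None = None
    draws: np.ndarray | None = None       # posterior draws, columns pi0..pi3, sigma2


# ---------------------------------------------------------------------------
# Variant preparation


def scale_effects(df: pd.DataFrame, literal: bool = False) -> pd.DataFrame:
    """Multiply β̂ and SE per sex by sqrt(2f(1-f)) (or 2f(1-f) if literal)."""
    out = df.copy()
    f = out["A1FREQ"].to_numpy(float)
    w = 2.0 * f * (1.0 - f)
    if not literal:
        w = np.sqrt(w)
    for s in ("F", "M"):
        out[f"BETA_{s}"] = out[f"BETA_{s}"] * w
        out[f"SE_{s}"] = out[f"SE_{s}"] * w
    out["SCALE_W"] = w
    return out


def ld_prune(reference: np.ndarray, window: int = 50, step: int = 5,
             r2_max: float = 0.1) -> np.ndarray:
    """Greedy sliding-window pairwise pruning (PLINK --indep-pairwise style).

    Within each window of ``window`` variants (advanced by ``step``), pairs
    of retained variants with r² > ``r2_max`` in the reference lose the
    later-index member.  Returns a boolean keep mask over columns.
    """
    R = np.asarray(reference, float)
    m = R.shape[1]
    keep = np.ones(m, bool)
    sd = R.std(axis=0)
    keep &= sd > 0
    start = 0
    while start < m:
        idx = np.flatnonzero(keep[start:start + window]) + start
        if idx.size > 1:
            changed = True
            while changed:
                changed = False
                idx = idx[keep[idx]]
                if idx.size < 2:
                    break
                sub = R[:, idx]
                c = np.corrcoef(sub, rowvar=False)
                r2 = c**2
                np.fill_diagonal(r2, 0.0)
                ii, jj = np.nonzero(np.triu(r2 > r2_max))
                if ii.size:
                    keep[idx[jj[0]]] = False   # drop the later of the first pair
                    changed = True
        start += step
    return keep


def prepare_variants(df: pd.DataFrame, maf_min: float = 0.01,
                     missingness_max: float = 0.01, hwe_p_min: float = 1e-7,
                     prune_r2: float = 0.1, prune_window: int = 50,
                     prune_step: int = 5, reference: np.ndarray | None = None,
                     mhc_exclude: bool = True,
                     literal_scaling: bool = False) -> pd.DataFrame:
    """QC-filter and scale a sumstats table into mixture-ready effect pairs.

    Filters, in order: MHC exclusion, missingness > ``missingness_max`` in
    either sex, MAF < ``maf_min``, Hardy-Weinberg p < ``hwe_p_min``, then
    greedy LD pruning when a genotype ``reference`` (columns aligned to the
    rows of ``df``) is supplied.
    """
    out = df.copy()
    if mhc_exclude:
        mhc = np.array([in_mhc(c, int(b)) for c, b in zip(out["CHR"], out["BP"])])
        out = out.loc[~mhc]
    if {"MISS_F", "MISS_M"} <= set(out.columns):
        miss = np.maximum(out["MISS_F"].to_numpy(float), out["MISS_M"].to_numpy(float))
        out = out.loc[miss <= missingness_max]
    out = out.loc[out["A1FREQ"].to_numpy(float) >= maf_min]
    if "HWE_P" in out.columns:
        out = out.loc[out["HWE_P"].to_numpy(float) >= hwe_p_min]
    if reference is not None:
        ref = np.asarray(reference, float)[:, out.index.to_numpy()]
        keep = ld_prune(ref, window=prune_window, step=prune_step, r2_max=prune_r2)
        out = out.loc[out.index.to_numpy()[keep]]
    if len(out) == 0:
        raise ValueError("no variants survive QC filtering")
    return scale_effects(out.reset_index(drop=True), literal=literal_scaling)


def subsample_autosomes(df: pd.DataFrame, group_col: str = "LD_GROUP",
                        per_group: int = 6, seed: int = 0) -> pd.DataFrame:
    """Seeded uniform sample of up to ``per_group`` variants per LD group."""
    rng = np.random.default_rng(seed)
    taken = []
    for _, grp in df.groupby(group_col, sort=True):
        if len(grp) <= per_group:
            taken.append(grp)
        else:
            taken.append(grp.iloc[np.sort(rng.choice(len(grp), per_group, replace=False))])
    return pd.concat(taken).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Likelihood and posterior


def _component_logliks(bf, bm, sf2, sm2, sigma2, sigmas):
    """(n, 4) matrix of per-variant log densities under each component."""
    n = bf.size
    L = np.empty((n, 4))
    for k in range(4):
        a = sf2 + sigma2 * sigmas[k, 0, 0]
        b = sigma2 * sigmas[k, 0, 1]
        d = sm2 + sigma2 * sigmas[k, 1, 1]
        det = a * d - b * b
        quad = (d * bf**2 - 2.0 * b * bf * bm + a * bm**2) / det
        L[:, k] = -math.log(2 * math.pi) - 0.5 * np.log(det) - 0.5 * quad
    return L


def _theta_to_params(theta):
    """theta = (eta1, eta2, eta3, zeta) -> (pi[4], sigma2)."""
    eta = np.concatenate([[0.0], theta[:3]])
    pi = np.exp(eta - special.logsumexp(eta))
    sigma2 = float(special.expit(theta[3]))
    return pi, sigma2


def _params_to_theta(pi, sigma2):
    pi = np.clip(np.asarray(pi, float), 1e-10, None)
    pi = pi / pi.sum()
    eta = np.log(pi) - np.log(pi[0])
    s = min(max(sigma2, 1e-10), 1 - 1e-10)
    return np.array([eta[1], eta[2], eta[3], special.logit(s)])


def _log_posterior(theta, bf, bm, sf2, sm2, sigmas, dirichlet_a=0.25):
    pi, sigma2 = _theta_to_params(theta)
    if sigma2 <= 0 or sigma2 >= 1:
        return -np.inf
    L = _component_logliks(bf, bm, sf2, sm2, sigma2, sigmas)
    a = L + np.log(pi)
    mx = a.max(axis=1)
    ll = float(np.sum(mx + np.log(np.exp(a - mx[:, None]).sum(axis=1))))
    # Dirichlet(1/4) prior + softmax Jacobian; Uniform(0,1) prior + logit Jacobian.
    lp = (dirichlet_a - 1.0) * np.log(pi).sum() + np.log(pi).sum()
    lp += math.log(sigma2 * (1.0 - sigma2))
    return ll + lp


def _em_map(bf, bm, sf2, sm2, sigmas, pi0, s0, max_iter, tol):
    """EM on the MAP objective (Dirichlet(1/4)+Jacobian => counts + 1/4)."""
    pi, sigma2 = np.asarray(pi0, float), float(s0)
    obj_old = -np.inf
    for _ in range(max_iter):
        L = _component_logliks(bf, bm, sf2, sm2, sigma2, sigmas)
        a = L + np.log(np.clip(pi, 1e-300, None))
        a -= a.max(axis=1, keepdims=True)
        r = np.exp(a)
        r /= r.sum(axis=1, keepdims=True)
        pi = (r.sum(axis=0) + 0.25) / (r.shape[0] + 1.0)

        def nobj(ls):
            s = math.exp(ls)
            if s >= 1.0:
                return np.inf
            Ls = _component_logliks(bf, bm, sf2, sm2, s, sigmas)
            return -(float(np.sum(r * Ls)) + math.log(s * (1.0 - s)))

        res = optimize.minimize_scalar(nobj, bounds=(math.log(1e-8), -1e-9),
                                       method="bounded", options={"xatol": 1e-12})
        sigma2 = math.exp(res.x)
        theta = _params_to_theta(pi, sigma2)
        obj = _log_posterior(theta, bf, bm, sf2, sm2, sigmas)
        if abs(obj - obj_old) < tol * (abs(obj_old) + 1.0):
            return pi, sigma2, obj, True
        obj_old = obj
    return pi, sigma2, obj_old, False


def fit_mixture(pairs: pd.DataFrame, alpha: float = 2.0, mode: str = "map",
                seed: int = 0, n_restarts: int = 8, max_iter: int = 500,
                tol: float = 1e-9, ci_level: float = 0.95,
                n_ci_draws: int = 2000, mcmc_steps: int = 4000,
                mcmc_warmup: int = 2000, n_walkers: int = 16,
                rhat_max: float = 1.01, restart_spread_max: float = 0.1,
                check_diagnostics: bool = True,
                min_variants: int = 200) -> MixtureFit:
    """Fit the four-component sex-bias mixture to scaled effect pairs.

    ``pairs`` must carry scaled BETA_F/BETA_M/SE_F/SE_M columns (see
    :func:`prepare_variants`).  MAP mode runs EM from ``n_restarts`` seeded
    starting points and rejects fits whose near-optimal restarts disagree in
    π by more than ``restart_spread_max``; CIs come from normal posterior
    draws around the MAP (columns π0..π3, σ² in ``draws``).  MCMC mode
    samples the same posterior with emcee and rejects on split-Rhat >
    ``rhat_max``.
    """
    if alpha <= 1.0:
        raise ValueError("alpha must be > 1")
    if len(pairs) < min_variants:
        raise ValueError(f"need at least {min_variants} variant pairs")
    bf = pairs["BETA_F"].to_numpy(float)
    bm = pairs["BETA_M"].to_numpy(float)
    sf2 = pairs["SE_F"].to_numpy(float) ** 2
    sm2 = pairs["SE_M"].to_numpy(float) ** 2
    if np.any(sf2 <= 0) or np.any(sm2 <= 0):
        raise ValueError("SEs must be positive")
    sigmas = component_covariances(alpha)
    rng = np.random.default_rng(seed)

    results = []
    for rs in range(n_restarts):
        if rs == 0:
            pi0 = np.array([0.7, 0.1, 0.1, 0.1])
            s0 = float(np.clip(np.mean(np.maximum(bf**2 - sf2, 0.0)), 1e-6, 0.5))
        else:
            pi0 = rng.dirichlet(np.ones(4))
            s0 = float(10 ** rng.uniform(-5, -0.5))
        pi, sigma2, obj, conv = _em_map(bf, bm, sf2, sm2, sigmas, pi0, s0,
                                        max_iter, tol)
        if conv:
            results.append((obj, pi, sigma2))
    if not results:
        raise MixtureDiagnosticError("no EM restart converged")
    results.sort(key=lambda t: -t[0])
    obj_best, pi_best, s_best = results[0]
    near = [r for r in results if r[0] > obj_best - 0.5]
    spread = max(float(np.abs(r[1] - pi_best).max()) for r in near)
    diagnostics = {"n_restarts_converged": len(results),
                   "restart_pi_spread": spread}
    if check_diagnostics and spread > restart_spread_max:
        raise MixtureDiagnosticError(
            f"restart disagreement: pi spread {spread:.3f} > {restart_spread_max}")

    # Polish the MAP in the unconstrained parameterization.
    theta0 = _params_to_theta(pi_best, s_best)
    neg = lambda th: -_log_posterior(th, bf, bm, sf2, sm2, sigmas)
    res = optimize.minimize(neg, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    theta_map = res.x if -res.fun >= obj_best - 1e-6 else theta0
    pi_map, s_map = _theta_to_params(theta_map)
    obj_map = _log_posterior(theta_map, bf, bm, sf2, sm2, sigmas)

    if mode == "map":
        draws = _wald_draws(theta_map, bf, bm, sf2, sm2, sigmas, n_ci_draws, rng)
        converged = True
    elif mode == "mcmc":
        draws, rhat = _mcmc_draws(theta_map, bf, bm, sf2, sm2, sigmas,
                                  n_walkers, mcmc_steps, mcmc_warmup, rng)
        diagnostics["rhat"] = rhat
        converged = bool(np.all(rhat <= rhat_max))
        if check_diagnostics and not converged:
            raise MixtureDiagnosticError(
                f"chain disagreement: max split-Rhat {np.max(rhat):.4f} > {rhat_max}")
        pi_map = draws[:, :4].mean(axis=0)
        s_map = float(draws[:, 4].mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    qlo, qhi = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    pi_ci = np.quantile(draws[:, :4], [qlo, qhi], axis=0).T
    s_ci = tuple(np.quantile(draws[:, 4], [qlo, qhi]))
    if alpha < 1.2:
        diagnostics["alpha_near_one"] = True
        warnings.warn("alpha close to 1: sex-biased components nearly coalesce")
    return MixtureFit(pi=np.asarray(pi_map), sigma2=float(s_map), alpha=alpha,
                      loglik=float(obj_map), mode=mode, n_variants=bf.size,
                      converged=converged, diagnostics=diagnostics,
                      pi_ci=pi_ci, sigma2_ci=s_ci, draws=draws)


def _wald_draws(theta_map, bf, bm, sf2, sm2, sigmas, n_draws, rng):
    """Normal posterior draws from the finite-difference observed information."""
    k = theta_map.size
    eps = 1e-4 * np.maximum(np.abs(theta_map), 1.0)
    H = np.zeros((k, k))
    f0 = _log_posterior(theta_map, bf, bm, sf2, sm2, sigmas)

    def f(th):
        return _log_posterior(th, bf, bm, sf2, sm2, sigmas)

    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * eps[i]
            ej = np.eye(k)[j] * eps[j]
            if i == j:
                H[i, i] = (f(theta_map + ei) - 2 * f0 + f(theta_map - ei)) / eps[i] ** 2
            else:
                H[i, j] = H[j, i] = (f(theta_map + ei + ej) - f(theta_map + ei - ej)
                                     - f(theta_map - ei + ej) + f(theta_map - ei - ej)
                                     ) / (4 * eps[i] * eps[j])
    cov = -H
    try:
        cov = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(cov)
    # enforce symmetry / PSD for sampling
    cov = (cov + cov.T) / 2
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 1e-12, None)
    A = V @ np.diag(np.sqrt(w))
    thetas = theta_map + rng.standard_normal((n_draws, k)) @ A.T
    out = np.empty((n_draws, 5))
    for i, th in enumerate(thetas):
        pi, s = _theta_to_params(th)
        out[i, :4] = pi
        out[i, 4] = s
    return out


def _mcmc_draws(theta_map, bf, bm, sf2, sm2, sigmas, n_walkers, steps, warmup, rng):
    import emcee

    ndim = 4

    def logp(th):
        return _log_posterior(th, bf, bm, sf2, sm2, sigmas)

    p0 = theta_map + 0.05 * rng.standard_normal((n_walkers, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, logp, moves=moves)
    init = emcee.State(p0, random_state=np.random.RandomState(
        int(rng.integers(2**31 - 1))))
    state = sampler.run_mcmc(init, warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, steps - warmup, progress=False)
    chain = sampler.get_chain()            # (nsteps, nwalkers, ndim)
    rhat = _split_rhat(chain)
    flat = chain.reshape(-1, ndim)
    out = np.empty((flat.shape[0], 5))
    for i, th in enumerate(flat):
        pi, s = _theta_to_params(th)
        out[i, :4] = pi
        out[i, 4] = s
    return out, rhat


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter; walkers as chains, each split in half."""
    nsteps, nwalk, ndim = chain.shape
    half = nsteps // 2
    segs = np.concatenate([chain[:half], chain[half:2 * half]], axis=1)
    m = segs.shape[1]
    n = segs.shape[0]
    means = segs.mean(axis=0)              # (m, ndim)
    vars_ = segs.var(axis=0, ddof=1)       # (m, ndim)
    W = vars_.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return np.sqrt(var_hat / W)


# ---------------------------------------------------------------------------
# Posterior assignment and summaries


def assign_components(fit: MixtureFit, pairs: pd.DataFrame,
                      threshold: float = 0.8) -> pd.DataFrame:
    """Per-variant posterior component probabilities and hard labels.

    p_{i,k} ∝ π̂_k · N(β̂_i; 0, Ŝ_i + σ̂²Σ_k); a variant is labeled M_k only
    when p_{i,k} > ``threshold``, otherwise "uncategorized".
    """
    bf = pairs["BETA_F"].to_numpy(float)
    bm = pairs["BETA_M"].to_numpy(float)
    sf2 = pairs["SE_F"].to_numpy(float) ** 2
    sm2 = pairs["SE_M"].to_numpy(float) ** 2
    sigmas = component_covariances(fit.alpha)
    L = _component_logliks(bf, bm, sf2, sm2, fit.sigma2, sigmas)
    a = L + np.log(np.clip(fit.pi, 1e-300, None))
    a -= a.max(axis=1, keepdims=True)
    post = np.exp(a)
    post /= post.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)
    labels = np.where(post.max(axis=1) > threshold,
                      np.array(COMPONENTS)[best], "uncategorized")
    out = pd.DataFrame(post, columns=[f"p_{c}" for c in COMPONENTS])
    if "SNP" in pairs.columns:
        out.insert(0, "SNP", pairs["SNP"].to_numpy())
    out["label"] = labels
    return out


def nonnull_proportions(fit: MixtureFit, ci_level: float = 0.95) -> pd.DataFrame:
    """Shares of female-biased/equal/male-biased among non-null variants."""
    nonnull = fit.pi[1:]
    tot = nonnull.sum()
    if tot <= 0 or fit.pi[0] >= 1.0:
        raise ValueError("no non-null mass: pi0 = 1")
    shares = nonnull / tot
    rows = {"component": ["female_biased", "equal", "male_biased"],
            "share": shares}
    if fit.draws is not None:
        d = fit.draws[:, 1:4]
        s = d / np.clip(d.sum(axis=1, keepdims=True), 1e-12, None)
        qlo, qhi = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
        lo, hi = np.quantile(s, [qlo, qhi], axis=0)
        rows["ci_low"], rows["ci_high"] = lo, hi
    return pd.DataFrame(rows)
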