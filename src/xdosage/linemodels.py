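"""Bayesian line-model clustering of (female h², male h²) estimate pairs.

Each XCI scenario is a zero-mean bivariate Gaussian whose major axis is a
line of slope b in the (hf², hm²) plane: full XCI predicts hm² = 2·hf²
(slope 2 on chrX, 1 on autosomes), 25%-escape 1.75 (0.875), and no XCI 0.5
(0.25).  A trait's pair of estimates, with independent per-sex SEs (the
samples are disjoint), is evaluated under

    (hf², hm²) ~ N(0, diag(SE_f², SE_m²) + τ²·R(b, r)),
    R(b, r) = [[1, r·b], [r·b, b²]] / (1 + b²),

so the prior variance along the line direction approaches τ² as the
concentration r → 1 (fixed at 0.999 by default).  Scale parameters τ are
optimized in two stages (shared τ first, then freed per model) by EM with a
derivative-free bounded search in log τ, and traits are assigned to the
model with the highest equal-prior posterior when it exceeds 0.80.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

CHRX_SLOPES = {"F-XCI": 2.0, "E-XCI": 1.75, "N-XCI": 0.5}


@dataclass(frozen=True)
class LineModel:
    label: str
    slope: float
    corr: float = 0.999
    tau: float | None = None

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 < self.corr < 1.0:
            raise ValueError("correlation must be in (0, 1)")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be >= 0")

    def prior_cov(self, tau: float | None = None) -> np.ndarray:
        t = self.tau if tau is None else tau
        b, r = self.slope, self.corr
        R = np.array([[1.0, r * b], [r * b, b * b]]) / (1.0 + b * b)
        return t * t * R


@dataclass(frozen=True)
class ClusterResult:
    trait: str
    posteriors: dict           # label -> probability (sums to 1)
    label: str                 # assigned label or "unassigned"
    threshold: float


def default_models(region: str) -> list[LineModel]:
    """The three XCI line models; autosomal slopes are the chrX slopes / 2."""
    if region == "chrX":
        div = 1.0
    elif region == "autosomes":
        div = 2.0
    else:
        raise ValueError(f"unknown region {region!r}")
    return [LineModel(label=k, slope=v / div) for k, v in CHRX_SLOPES.items()]


def model_loglik(pair, ses, model: LineModel, tau: float | None = None) -> float:
    """Log marginal density of an estimate pair under one line model."""
    se_f, se_m = ses
    if se_f < 0 or se_m < 0:
        raise ValueError("SEs must be >= 0")
    C = np.diag([se_f**2, se_m**2]) + model.prior_cov(tau)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("covariance not positive definite")
    x = np.asarray(pair, float)
    quad = float(x @ np.linalg.solve(C, x))
    return -math.log(2 * math.pi) - 0.5 * logdet - 0.5 * quad

def _loglik_matrix(pairs, ses, models, taus):
    n = len(pairs)
    L = np.empty((n, len(models)))
    for k, (mod, t) in enumerate(zip(models, taus)):
        for i in range(n):
            L[i, k] = model_loglik(pairs[i], ses[i], mod, tau=t)
    return L


def _mixture_ll(L, weights):
    a = L + np.log(weights)
    mx = a.max(axis=1, keepdims=True)
    return float(np.sum(mx.ravel() + np.log(np.exp(a - mx).sum(axis=1))))


def _responsibilities(L, weights):
    a = L + np.log(weights)
    a -= a.max(axis=1, keepdims=True)
    r = np.exp(a)
    return r / r.sum(axis=1, keepdims=True)


def initial_tau(pairs) -> float:
    """Starting scale: the larger across-trait SD of the two h² estimate sets."""
    arr = np.asarray(pairs, float)
    return float(max(arr[:, 0].std(ddof=1), arr[:, 1].std(ddof=1)))


def optimize_scales(pairs, ses, models: list[LineModel],
                    stage: str = "both", weights=None,
                    max_iter: int = 200, tol: float = 1e-10):
    """Two-stage scale optimization of the line-model mixture.

    Stage 1 maximizes the mixture likelihood with one shared τ (equal
    initial proportions); stage 2 starts from the stage-1 optimum and frees
    per-model τ.  Returns (fitted models with τ set, mixture proportions).
    Deterministic: fixed starting point, bounded scalar searches in log τ.
    """
    pairs = np.asarray(pairs, float)
    ses = np.asarray(ses, float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 trait pairs")
    K = len(models)
    tau0 = initial_tau(pairs)
    if tau0 <= 0:
        raise ValueError("degenerate pairs: zero across-trait variance")
    lo, hi = math.log(tau0) - 10.0, math.log(tau0) + 5.0

    def em(taus, weights, shared):
        taus = list(taus)
        weights = np.asarray(weights, float)
        ll_old = -np.inf
        for _ in range(max_iter):
            L = _loglik_matrix(pairs, ses, models, taus)
            r = _responsibilities(L, weights)
            weights = r.mean(axis=0)
            weights = np.clip(weights, 1e-12, None)
            weights /= weights.sum()
            if shared:
                def nobj(lt):
                    Lt = _loglik_matrix(pairs, ses, models, [math.exp(lt)] * K)
                    return -float(np.sum(r * Lt))
                res = optimize.minimize_scalar(nobj, bounds=(lo, hi), method="bounded",
                                               options={"xatol": 1e-10})
                taus = [math.exp(res.x)] * K
            else:
                for k in range(K):
                    def nobj_k(lt, k=k):
                        col = np.array([model_loglik(pairs[i], ses[i], models[k],
                                                     tau=math.exp(lt))
                                        for i in range(len(pairs))])
                        return -float(r[:, k] @ col)
                    res = optimize.minimize_scalar(nobj_k, bounds=(lo, hi),
                                                   method="bounded",
                                                   options={"xatol": 1e-10})
                    taus[k] = math.exp(res.x)
            L = _loglik_matrix(pairs, ses, models, taus)
            ll = _mixture_ll(L, weights)
            if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
                break
            ll_old = ll
        return taus, weights

    w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
    taus = [tau0] * K
    if stage in ("both", "stage1"):
        taus, w = em(taus, w, shared=True)
    if stage in ("both", "stage2"):
        taus, w = em(taus, w, shared=False)
    for t in taus:
        if t <= math.exp(lo) * 1.01:
            warnings.warn("fitted tau at the lower boundary")
    fitted = [replace(mod, tau=t) for mod, t in zip(models, taus)]
    return fitted, w


def posterior_membership(pair, ses, models: list[LineModel], prior=None,
                         threshold: float = 0.80, trait: str = "trait") -> ClusterResult:
    """Equal-prior posterior over fitted models; assign only above threshold."""
    K = len(models)
    prior = np.full(K, 1.0 / K) if prior is None else np.asarray(prior, float)
    logp = np.array([model_loglik(pair, ses, mod) for mod in models]) + np.log(prior)
    logp -= logp.max()
    post = np.exp(logp)
    post /= post.sum()
    posteriors = {mod.label: float(p) for mod, p in zip(models, post)}
    best = int(np.argmax(post))
    label = models[best].label if post[best] > threshold else "unassigned"
    return ClusterResult(trait=trait, posteriors=posteriors, label=label,
                         threshold=threshold)


def cluster_traits(h2_pairs: pd.DataFrame, region: str = "chrX",
                   threshold: float = 0.80) -> pd.DataFrame:
    """Fit scales on a table of per-trait (h2_f, se_f, h2_m, se_m) and assign.

    Returns one row per trait with per-model posteriors and the assignment.
    """
    pairs = h2_pairs[["h2_f", "h2_m"]].to_numpy(float)
    ses = h2_pairs[["se_f", "se_m"]].to_numpy(float)
    models = default_models(region)
    fitted, _ = optimize_scales(pairs, ses, models)
    rows = []
    for i, trait in enumerate(h2_pairs["trait"]):
        res = posterior_membership(pairs[i], ses[i], fitted, threshold=threshold,
                                   trait=str(trait))
        row = {"trait": res.trait, "label": res.label}
        row.update({f"post_{k}": v for k, v in res.posteriors.items()})
        rows.append(row)
    return pd.DataFrame(rows)
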