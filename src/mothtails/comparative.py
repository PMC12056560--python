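"""Continuous-trait comparative methods on species means.

Model selection among Brownian motion (BM, random walk), Ornstein-Uhlenbeck
(OU, pull toward an optimum) and early burst (EB, exponentially decaying
rate) by maximum likelihood; Blomberg's K with a tip-shuffling permutation
p-value; and maximum-likelihood (GLS) ancestral state reconstruction under
BM.

All three evolution models are Gaussian on the tip vector with mean z0 * 1
and a covariance determined by the tree and the shape parameter:

    BM:  Cov_ij = sigma2 * t_mrca(i,j)
    OU:  Cov_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_mrca))
    EB:  Cov_ij = sigma2 * (exp(r t_mrca) - 1) / r       (r <= 0; r -> 0 is BM)

with d_ij the patristic distance and t_mrca the root-to-MRCA time.  The OU
form is the fixed-root, single-optimum (theta = z0) parameterization.  z0 and
sigma2 are profiled in closed form; alpha and r are optimized on a grid with
local refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .trees import Phylogeny

__all__ = [
    "EvoModelFit",
    "KResult",
    "vcv_from_tree",
    "bm_covariance",
    "ou_covariance",
    "eb_covariance",
    "model_loglik",
    "fit_evolution_model",
    "compare_evolution_models",
    "blomberg_k",
    "asr_bm",
]


def vcv_from_tree(tree: Phylogeny, normalize: str = "raw") -> tuple:
    """Brownian-motion tip covariance: root-to-MRCA shared path lengths.

    Returns ``(C, tip_labels)``; ``normalize="unit_height"`` divides by the
    tree height so an ultrametric tree has a unit diagonal.
    """
    return tree.vcv(normalize)


@dataclass
class EvoModelFit:
    """One fitted trait-evolution model; AIC = 2k - 2 logLik (k=2 for BM,
    3 for OU and EB)."""

    model: str
    z0: float
    sigma2: float
    logLik: float
    aic: float
    alpha: float | None = None  # OU pull, 1/time
    r: float | None = None  # EB exponent, 1/time, <= 0


@dataclass
class KResult:
    """Blomberg's K and its tip-permutation p-value."""

    K: float
    p: float
    n_perm: int
    seed: int


# ------------------------------------------------------------- covariances
def bm_covariance(tree: Phylogeny) -> np.ndarray:
    C, _ = tree.vcv("raw")
    return C


def ou_covariance(tree: Phylogeny, alpha: float) -> np.ndarray:
    """Fixed-root OU covariance (unit sigma2)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    Ta, _ = tree.vcv("raw")
    D = tree.patristic_matrix()
    # -expm1 keeps precision as alpha -> 0, where this tends to BM's Ta
    return np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * Ta)) / (2.0 * alpha)


def eb_covariance(tree: Phylogeny, r: float) -> np.ndarray:
    """Early-burst covariance (unit sigma2); r = 0 is the BM limit."""
    if r > 0:
        raise ValueError("EB exponent r must be <= 0")
    Ta, _ = tree.vcv("raw")
    if r == 0.0:
        return Ta
    return np.expm1(r * Ta) / r


def _shape_matrix(tree, model, alpha=None, r=None) -> np.ndarray:
    if model == "BM":
        return bm_covariance(tree)
    if model == "OU":
        if alpha is None:
            raise ValueError("OU requires alpha")
        return ou_covariance(tree, alpha)
    if model == "EB":
        if r is None:
            raise ValueError("EB requires r")
        return eb_covariance(tree, r)
    raise ValueError(f"unknown model {model!r}")


def _profiled_loglik(M: np.ndarray, y: np.ndarray):
    """ML of N(z0*1, sigma2*M) with z0 and sigma2 profiled out.

    Returns ``(loglik, z0_hat, sigma2_hat)`` or None when M is not positive
    definite.
    """
    n = len(y)
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return None
    from scipy.linalg import solve_triangular

    ones = np.ones(n)
    wy = solve_triangular(L, y, lower=True)
    w1 = solve_triangular(L, ones, lower=True)
    z0 = float(w1 @ wy) / float(w1 @ w1)
    res = wy - z0 * w1
    q = float(res @ res)
    if q <= 0:
        return None
    s2 = q / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * math.log(2.0 * math.pi * s2) + logdet + n)
    return ll, z0, s2


def model_loglik(
    tree: Phylogeny,
    traits: dict,
    model: str,
    alpha: float | None = None,
    r: float | None = None,
):
    """Profiled log-likelihood of one model at a given shape parameter.

    z0 and sigma2 are maximized in closed form; returns
    ``(loglik, z0_hat, sigma2_hat)``.
    """
    y = _trait_vector(tree, traits)
    M = _shape_matrix(tree, model, alpha=alpha, r=r)
    out = _profiled_loglik(M, y)
    if out is None:
        raise np.linalg.LinAlgError(
            f"{model} covariance not positive definite at the given parameters"
        )
    return out


def _trait_vector(tree: Phylogeny, traits: dict) -> np.ndarray:
    labels = tree.tip_labels()
    missing = [lab for lab in labels if lab not in traits]
    if missing:
        raise KeyError(f"traits missing for tips: {missing}")
    return np.array([float(traits[lab]) for lab in labels])


# ----------------------------------------------------------------- fitting
def fit_evolution_model(tree: Phylogeny, traits: dict, model: str) -> EvoModelFit:
    """Maximum-likelihood fit of BM, OU or EB to species-level traits.

    Shape parameters are searched on a grid spanning the identifiable range
    (alpha * height in [1e-4, 100]; r in [-10/height, 0]) and refined with a
    bounded scalar optimizer; non-positive-definite proposals are rejected,
    not fatal.
    """
    model = model.upper()
    y = _trait_vector(tree, traits)
    n = len(y)
    if n < 2 or (model in ("OU", "EB") and n < 4):
        raise ValueError(f"too few tips ({n}) to fit {model}")
    h = tree.height

    if model == "BM":
        out = _profiled_loglik(bm_covariance(tree), y)
        if out is None:
            raise np.linalg.LinAlgError("BM covariance not positive definite")
        ll, z0, s2 = out
        return EvoModelFit("BM", z0, s2, ll, 2 * 2 - 2 * ll)

    if model == "OU":
        def neg(log_alpha):
            res = _profiled_loglik(ou_covariance(tree, math.exp(log_alpha)), y)
            return math.inf if res is None else -res[0]

        lo, hi = math.log(1e-4 / h), math.log(100.0 / h)
        grid = np.linspace(lo, hi, 30)
        vals = [neg(g) for g in grid]
        k = int(np.argmin(vals))
        a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(neg, bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-8})
        log_alpha = res.x if res.fun <= vals[k] else grid[k]
        alpha = math.exp(log_alpha)
        ll, z0, s2 = _profiled_loglik(ou_covariance(tree, alpha), y)
        return EvoModelFit("OU", z0, s2, ll, 2 * 3 - 2 * ll, alpha=alpha)

    if model == "EB":
        def neg(r):
            res = _profiled_loglik(eb_covariance(tree, min(r, 0.0)), y)
            return math.inf if res is None else -res[0]

        grid = np.linspace(-10.0 / h, 0.0, 30)
        vals = [neg(g) for g in grid]
        k = int(np.argmin(vals))
        a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(neg, bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-10})
        r = min(res.x, 0.0) if res.fun <= vals[k] else grid[k]
        ll, z0, s2 = _profiled_loglik(eb_covariance(tree, r), y)
        return EvoModelFit("EB", z0, s2, ll, 2 * 3 - 2 * ll, r=r)

    raise ValueError(f"unknown model {model!r}")


def compare_evolution_models(
    tree: Phylogeny, traits: dict, models: tuple = ("BM", "OU", "EB")
) -> list:
    """Fit each model and return the fits sorted by AIC (best first)."""
    fits = [fit_evolution_model(tree, traits, m) for m in models]
    return sorted(fits, key=lambda f: f.aic)


# -------------------------------------------------------------- Blomberg K
def _k_ratios(Ci: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Observed MSE0/MSE ratio of Blomberg's K for each column of Y."""
    c1 = Ci @ np.ones(Ci.shape[0])
    s1 = float(c1.sum())
    a = (c1 @ Y) / s1  # phylogenetic mean per column
    R = Y - a[None, :]
    num = (R * R).sum(axis=0)
    den = (R * (Ci @ R)).sum(axis=0)
    return num / den


def blomberg_k(
    tree: Phylogeny, traits: dict, n_perm: int = 1000, seed: int = 0
) -> KResult:
    """Blomberg's K with a tip-label permutation test.

    K is the ratio of the observed mean squared error around the phylogenetic
    mean to its expectation under BM on the given tree (K near 1 under BM,
    below 1 when relatives resemble each other less than BM predicts).  The
    p-value counts permutations whose observed ratio is at least the actual
    one, with the +1 correction so p is never 0.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y = _trait_vector(tree, traits)
    n = len(y)
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if np.allclose(y, y[0]):
        raise ValueError("constant traits: K undefined")
    C = bm_covariance(tree)
    Ci = np.linalg.inv(C)
    c1 = Ci @ np.ones(n)
    s1 = float(c1.sum())
    expected = (float(np.trace(C)) - n / s1) / (n - 1)
    obs_ratio = float(_k_ratios(Ci, y[:, None])[0])
    # the 1/(n-1) in numerator and denominator of the observed ratio cancels
    K = obs_ratio / expected

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    ratios = _k_ratios(Ci, y[perms].T)
    p = (1 + int((ratios >= obs_ratio - 1e-12).sum())) / (n_perm + 1)
    return KResult(K=float(K), p=float(p), n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------- ASR
@dataclass
class ASRResult:
    """BM ancestral states: node index -> ML state, plus fitted z0, sigma2."""

    states: dict
    z0: float
    sigma2: float


def asr_bm(tree: Phylogeny, traits: dict) -> ASRResult:
    """Joint maximum-likelihood ancestral states under Brownian motion.

    Equivalently the conditional expectation of internal-node states given
    the tips: a + Cov(internal, tips) C^-1 (y - a), with a the GLS
    phylogenetic mean (which is exactly the root state).  A 1e-12 diagonal
    tolerance absorbs zero-length terminal branches.
    """
    y = _trait_vector(tree, traits)
    n = len(y)
    if n < 2:
        raise ValueError("ancestral state reconstruction needs at least 2 tips")
    M = tree.mrca_depth_matrix()
    tips = tree.tip_indices()
    internal = np.array([i for i in range(tree.n_nodes) if i not in set(tips)])
    Ctt = M[np.ix_(tips, tips)].copy()
    np.fill_diagonal(Ctt, np.diag(Ctt) + 1e-12)
    Cit = M[np.ix_(internal, tips)]
    Ci = np.linalg.inv(Ctt)
    c1 = Ci @ np.ones(n)
    a = float(c1 @ y) / float(c1.sum())
    resid = y - a
    states_vec = a + Cit @ (Ci @ resid)
    s2 = float(resid @ (Ci @ resid)) / n
    states = {int(node): float(v) for node, v in zip(internal, states_vec)}
    return ASRResult(states=states, z0=a, sigma2=s2)
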