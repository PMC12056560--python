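"""Phylogenetic generalized linear mixed models (Gaussian response).

The model for observation-level adjusted wing length is

    y ~ N(X beta, V),   V = s2_phy Z C* Z' + s2_sp Z Z' + s2_e I

where Z maps observations to species, C* is the Brownian-motion correlation
matrix of the phylogeny scaled to unit height, the species random effect
absorbs repeated observations per species, and the fixed effects act on
centred-and-scaled covariates.  Variance components are estimated by REML
(default) or ML over log variance ratios with multiple starts; beta is the
GLS solution at the optimum with Wald 95% intervals.  A random-walk
Metropolis sampler reproduces Bayesian outputs (equal-tailed credible
intervals and the DIC on the marginal, random-effects-integrated deviance).

Likelihood evaluations use the Woodbury identity so the per-iteration cost is
cubic in the number of species, not observations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "PGLMMFit",
    "PosteriorResult",
    "ZeroVarianceError",
    "center_scale",
    "vif",
    "build_covariance",
    "fit_pglmm",
    "marginal_loglik",
    "sample_pglmm_posterior",
    "compare_models",
    "r2_components",
]

_LOG2PI = math.log(2.0 * math.pi)


class ZeroVarianceError(ValueError):
    """A covariate (or the response) is constant and cannot be scaled."""


# ------------------------------------------------------------------- scaling
def center_scale(x) -> np.ndarray:
    """Subtract the mean and divide by the sample (n-1) standard deviation."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("center_scale expects a 1-D vector")
    finite = x[np.isfinite(x)]
    if np.unique(finite).size < 2:
        raise ZeroVarianceError("vector has fewer than 2 distinct finite values")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ZeroVarianceError("zero variance")
    return (x - x.mean()) / sd


def vif(X, names=None) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) from regressing
    covariate j on all the others plus an intercept.

    Exactly collinear covariates are reported as ``inf`` (and logged).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 covariates")
    n, k = X.shape
    if n <= k:
        raise ValueError("need more rows than covariates")
    if names is None:
        names = [f"x{j}" for j in range(k)]
    out = {}
    for j in range(k):
        yj = X[:, j]
        Xj = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        sst = float(((yj - yj.mean()) ** 2).sum())
        if sst == 0:
            raise ZeroVarianceError(f"covariate {names[j]!r} is constant")
        r2 = 1.0 - float((resid**2).sum()) / sst
        if 1.0 - r2 < 1e-12:
            logger.warning("vif: covariate %r is exactly collinear", names[j])
            out[names[j]] = math.inf
        else:
            out[names[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out)


# ------------------------------------------------------------------- surface
@dataclass
class ModelSpec:
    """Fixed-effect structure of one candidate model.

    Interaction terms are named ``"a:b"`` and built as the elementwise
    product of the scaled parents, itself re-scaled.
    """

    response: str
    fixed: tuple = ()
    include_phylo: bool = True
    include_species: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        self.fixed = tuple(self.fixed)
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("fixed covariate names must be unique")
        if self.response in self.fixed:
            raise ValueError("response cannot appear among the fixed effects")
        if not self.name:
            self.name = "+".join(self.fixed) if self.fixed else "null"


@dataclass
class PGLMMFit:
    """Estimates from one PGLMM fit.

    ``beta`` is a DataFrame indexed by coefficient name with columns
    ``estimate, se, ci_low, ci_high`` (Wald 95%).  Variance components are on
    the response scale (mm^2).  ``aic`` uses the ML log-likelihood with
    k = p + number of free variance components.
    """

    beta: pd.DataFrame
    sigma2_phy: float
    sigma2_sp: float
    sigma2_e: float
    logLik_ml: float
    logLik_reml: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_species: int
    method: str
    dic: float | None = None
    spec: ModelSpec | None = None
    _ctx: "_Context" = field(default=None, repr=False, compare=False)


@dataclass
class _Context:
    """Precomputed sufficient statistics for fast marginal likelihoods."""

    y: np.ndarray
    X: np.ndarray
    names: list
    sp_idx: np.ndarray
    Cstar: np.ndarray
    include_phylo: bool
    include_species: bool

    def __post_init__(self) -> None:
        m = self.Cstar.shape[0]
        n, p = self.X.shape
        self.n, self.p, self.m = n, p, m
        self.D = np.bincount(self.sp_idx, minlength=m).astype(float)
        self.Zty = np.zeros(m)
        np.add.at(self.Zty, self.sp_idx, self.y)
        self.ZtX = np.zeros((m, p))
        np.add.at(self.ZtX, self.sp_idx, self.X)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _species_cov(self, rp: float, rs: float) -> np.ndarray:
        m = self.m
        A = np.zeros((m, m))
        if self.include_phylo and rp > 0:
            A += rp * self.Cstar
        if self.include_species and rs > 0:
            A += rs * np.eye(m)
        return A

    def whitened_forms(self, rp: float, rs: float):
        """Quadratic forms under W = I + Z A Z' (V = s2_e * W).

        Returns ``(XtWiX, XtWiy, ytWiy, logdetW)`` using the Woodbury
        identity W^-1 = I - Z A (I + D A)^-1 Z' with D = Z'Z diagonal.
        """
        A = self._species_cov(rp, rs)
        M = np.eye(self.m) + self.D[:, None] * A
        sign, logdetW = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        S = np.linalg.solve(M.T, A.T).T  # S = A (I + D A)^-1
        SU = S @ self.ZtX
        Sv = S @ self.Zty
        XtWiX = self.XtX - self.ZtX.T @ SU
        XtWiy = self.Xty - self.ZtX.T @ Sv
        ytWiy = self.yty - float(self.Zty @ Sv)
        return XtWiX, XtWiy, ytWiy, float(logdetW)

    def profiled(self, rp: float, rs: float, reml: bool):
        """GLS fit with the error variance profiled out.

        Returns ``(loglik, beta, s2_e, cov_unscaled)`` where ``cov_unscaled``
        is (X' W^-1 X)^-1 (multiply by s2_e for the beta covariance).
        """
        forms = self.whitened_forms(rp, rs)
        if forms is None:
            return None
        XtWiX, XtWiy, ytWiy, logdetW = forms
        try:
            cF = np.linalg.cholesky(XtWiX)
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(XtWiX, XtWiy)
        q = max(ytWiy - float(XtWiy @ beta), 1e-300)
        n, p = self.n, self.p
        if reml:
            s = q / (n - p)
            logdet_xtx = 2.0 * float(np.log(np.diag(cF)).sum())
            ll = -0.5 * (
                (n - p) * math.log(s)
                + logdetW
                + logdet_xtx
                + (n - p)
                + (n - p) * _LOG2PI
            )
        else:
            s = q / n
            ll = -0.5 * (n * math.log(s) + logdetW + n + n * _LOG2PI)
        cov_unscaled = np.linalg.inv(XtWiX)
        return ll, beta, s, cov_unscaled

    def loglik_at(self, beta: np.ndarray, s2p: float, s2s: float, s2e: float) -> float:
        """Marginal Gaussian log-likelihood at fully specified parameters."""
        if s2e <= 0:
            return -math.inf
        rp, rs = s2p / s2e, s2s / s2e
        A = self._species_cov(rp, rs)
        M = np.eye(self.m) + self.D[:, None] * A
        sign, logdetW = np.linalg.slogdet(M)
        if sign <= 0:
            return -math.inf
        S = np.linalg.solve(M.T, A.T).T
        r = self.y - self.X @ beta
        Ztr = np.zeros(self.m)
        np.add.at(Ztr, self.sp_idx, r)
        q = float(r @ r) - float(Ztr @ (S @ Ztr))
        n = self.n
        return -0.5 * (n * math.log(s2e) + float(logdetW) + q / s2e + n * _LOG2PI)


# ----------------------------------------------------------------- design
def _build_design(obs: pd.DataFrame, spec: ModelSpec, rescale: bool):
    n = len(obs)
    cols = [np.ones(n)]
    names = ["intercept"]
    scaled_cache: dict = {}

    def scaled(name: str) -> np.ndarray:
        if name not in scaled_cache:
            if name not in obs.columns:
                raise KeyError(f"covariate column {name!r} not in observation table")
            v = obs[name].to_numpy(dtype=float)
            scaled_cache[name] = center_scale(v) if rescale else v
        return scaled_cache[name]

    for term in spec.fixed:
        if ":" in term:
            a, b = term.split(":", 1)
            prod = scaled(a) * scaled(b)
            cols.append(center_scale(prod) if rescale else prod)
        else:
            cols.append(scaled(term))
        names.append(term)
    return np.column_stack(cols), names


def build_covariance(
    tree: Phylogeny,
    species_of_rows,
    sigma2_phy: float,
    sigma2_sp: float,
    sigma2_e: float,
) -> np.ndarray:
    """Dense observation-level covariance V = s2_phy Z C* Z' + s2_sp Z Z' + s2_e I.

    C* is the unit-height BM correlation matrix of the tree.  This dense form
    is the reference object; fitting uses an algebraically identical
    reduced-rank path.
    """
    Cstar, _ = tree.vcv("unit_height")
    idx = tree.tip_index_of(list(species_of_rows))
    n = len(idx)
    V = sigma2_phy * Cstar[np.ix_(idx, idx)]
    V = V + sigma2_sp * (idx[:, None] == idx[None, :])
    V = V + sigma2_e * np.eye(n)
    return V


def _make_context(obs, tree, spec, rescale) -> _Context:
    y = obs[spec.response].to_numpy(dtype=float)
    X, names = _build_design(obs, spec, rescale)
    Cstar, _ = tree.vcv("unit_height")
    sp_idx = tree.tip_index_of(obs["species"].tolist())
    return _Context(
        y=y,
        X=X,
        names=names,
        sp_idx=sp_idx,
        Cstar=Cstar,
        include_phylo=spec.include_phylo,
        include_species=spec.include_species,
    )


# ------------------------------------------------------------------- fitting
_STARTS = [(-2.3, -2.3), (0.7, -1.6), (-4.6, 0.0), (0.0, 0.7), (-8.0, -8.0)]


def _optimize_ratios(ctx: _Context, reml: bool):
    """Maximize the profiled (RE)ML over active log variance ratios."""
    active = []
    if ctx.include_phylo:
        active.append("phy")
    if ctx.include_species:
        active.append("sp")

    def unpack(x):
        vals = {"phy": 0.0, "sp": 0.0}
        for name, xi in zip(active, x):
            vals[name] = math.exp(min(xi, 30.0))
        return vals["phy"], vals["sp"]

    def neg(x):
        rp, rs = unpack(x)
        res = ctx.profiled(rp, rs, reml)
        return math.inf if res is None else -res[0]

    if not active:
        return 0.0, 0.0
    best_x, best_f = None, math.inf
    starts = [_x[: len(active)] for _x in _STARTS]
    for x0 in starts:
        r = optimize.minimize(
            neg, np.asarray(x0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
        )
        if r.fun < best_f:
            best_f, best_x = r.fun, r.x
    # boundary candidates: drop each component to (numerically) zero
    rp, rs = unpack(best_x)
    candidates = [(rp, rs), (0.0, rs), (rp, 0.0), (0.0, 0.0)]
    best = None
    for cand in candidates:
        res = ctx.profiled(cand[0], cand[1], reml)
        if res is not None and (best is None or res[0] > best[1][0]):
            best = (cand, res)
    return best[0]


def fit_pglmm(
    obs: pd.DataFrame,
    tree: Phylogeny,
    spec: ModelSpec,
    method: str = "reml",
    rescale: bool = True,
    fixed_variances: tuple | None = None,
) -> PGLMMFit:
    """Fit the phylogenetic mixed model.

    ``method`` selects the objective for the variance components ("reml",
    the default, or "ml"); beta and its Wald interval come from GLS at the
    optimum.  ``rescale=True`` centre-scales every fixed covariate (and
    interaction product) before fitting.  ``fixed_variances=(s2_phy, s2_sp,
    s2_e)`` skips optimization and fits GLS under that known covariance.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    ctx = _make_context(obs, tree, spec, rescale)
    if ctx.n <= ctx.p:
        raise ValueError("more coefficients than observations")
    singles = int((ctx.D == 1).sum())
    if singles and ctx.include_species:
        logger.warning(
            "%d species have a single observation; sigma2_sp and sigma2_e "
            "are weakly identified",
            singles,
        )

    if fixed_variances is not None:
        s2p, s2s, s2e = (float(v) for v in fixed_variances)
        if s2e <= 0:
            raise ValueError("sigma2_e must be > 0")
        rp, rs = s2p / s2e, s2s / s2e
        res = ctx.profiled(rp, rs, reml=True)
        if res is None:
            raise np.linalg.LinAlgError("singular X' V^-1 X")
        _, beta, _, cov_unscaled = res
        ll_ml = ctx.loglik_at(beta, s2p, s2s, s2e)
        ll_reml = ll_ml  # variances are not estimated here
        cov_beta = s2e * cov_unscaled
        k_var = 0
    else:
        rp_r, rs_r = _optimize_ratios(ctx, reml=True)
        rp_m, rs_m = _optimize_ratios(ctx, reml=False)
        res_reml = ctx.profiled(rp_r, rs_r, reml=True)
        res_ml = ctx.profiled(rp_m, rs_m, reml=False)
        if res_reml is None or res_ml is None:
            raise np.linalg.LinAlgError("non-finite likelihood at the optimum")
        ll_reml = res_reml[0]
        ll_ml = res_ml[0]
        if method == "reml":
            _, beta, s2e, cov_unscaled = res_reml
            rp, rs = rp_r, rs_r
        else:
            _, beta, s2e, cov_unscaled = res_ml
            rp, rs = rp_m, rs_m
        s2p, s2s = rp * s2e, rs * s2e
        cov_beta = s2e * cov_unscaled
        k_var = 1 + int(ctx.include_phylo) + int(ctx.include_species)

    se = np.sqrt(np.diag(cov_beta))
    table = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
        },
        index=ctx.names,
    )
    aic = 2.0 * (ctx.p + k_var) - 2.0 * ll_ml
    r2m, r2c = _r2_from_parts(ctx.X @ beta, s2p, s2s, s2e)
    return PGLMMFit(
        beta=table,
        sigma2_phy=s2p if ctx.include_phylo else 0.0,
        sigma2_sp=s2s if ctx.include_species else 0.0,
        sigma2_e=s2e,
        logLik_ml=ll_ml,
        logLik_reml=ll_reml,
        aic=aic,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=ctx.n,
        n_species=int(np.unique(ctx.sp_idx).size),
        method=method,
        spec=spec,
        _ctx=ctx,
    )


def marginal_loglik(
    obs: pd.DataFrame,
    tree: Phylogeny,
    spec: ModelSpec,
    beta,
    sigma2_phy: float,
    sigma2_sp: float,
    sigma2_e: float,
    rescale: bool = True,
) -> float:
    """Evaluate log N(y; X beta, V(sigma2_phy, sigma2_sp, sigma2_e)).

    The marginal (random-effects-integrated) log-likelihood at fully
    specified parameters; used for deviance computations and as a check
    against dense multivariate-normal references.
    """
    ctx = _make_context(obs, tree, spec, rescale)
    return ctx.loglik_at(np.asarray(beta, dtype=float), sigma2_phy, sigma2_sp, sigma2_e)


# ----------------------------------------------------------------------- r2
def _r2_from_parts(fitted, s2p, s2s, s2e):
    var_fixed = float(np.var(fitted, ddof=1)) if len(fitted) > 1 else 0.0
    denom = var_fixed + s2p + s2s + s2e
    if denom <= 0:
        raise ZeroVarianceError("zero total variance; r2 undefined")
    return var_fixed / denom, (var_fixed + s2p + s2s) / denom


def r2_components(fit: PGLMMFit, X: np.ndarray | None = None) -> tuple:
    """Nakagawa-style marginal and conditional r-squared.

    marginal = var(X beta) / (var(X beta) + s2_phy + s2_sp + s2_e);
    conditional additionally credits both random effects.
    """
    if X is None:
        X = fit._ctx.X
    fitted = X @ fit.beta["estimate"].to_numpy()
    return _r2_from_parts(fitted, fit.sigma2_phy, fit.sigma2_sp, fit.sigma2_e)


# -------------------------------------------------------------------- MCMC
@dataclass
class PosteriorResult:
    """Posterior summaries from the random-walk Metropolis sampler."""

    beta: pd.DataFrame  # mean, sd, ci_low, ci_high per coefficient
    sigma: pd.DataFrame  # posterior summaries of the standard deviations
    dic: float
    acceptance_rate: float
    n_iter: int
    burn_in: int
    seed: int


def sample_pglmm_posterior(
    fit: PGLMMFit,
    n_iter: int = 4000,
    burn_in: int = 1000,
    seed: int = 0,
    sample_variances: bool = True,
) -> PosteriorResult:
    """Random-walk Metropolis on (beta, log sd components).

    Priors: flat on beta; half-normal on each standard deviation with scale
    five times the REML estimate (floored at 5% of sd(y) so a boundary REML
    estimate of zero does not degenerate the prior).  The proposal is an
    independent Gaussian per coordinate, adapted toward a 30% acceptance rate
    during burn-in only.  DIC uses the marginal deviance
    D = -2 log N(y; X beta, V): DIC = 2 mean(D) - D(posterior mean).

    ``sample_variances=False`` holds the variance components fixed at the
    fit's values and samples beta alone; with a flat prior the exact
    posterior is then N(beta_GLS, (X' V^-1 X)^-1).
    """
    ctx = fit._ctx
    rng = np.random.default_rng(seed)
    p = ctx.p
    comp_names = ["sigma_e"]
    if ctx.include_phylo:
        comp_names.append("sigma_phy")
    if ctx.include_species:
        comp_names.append("sigma_sp")
    reml_sd = {
        "sigma_e": math.sqrt(fit.sigma2_e),
        "sigma_phy": math.sqrt(fit.sigma2_phy),
        "sigma_sp": math.sqrt(fit.sigma2_sp),
    }
    sd_y = float(np.std(ctx.y, ddof=1))
    prior_scale = np.array(
        [5.0 * max(reml_sd[c], 0.05 * sd_y) for c in comp_names]
    )

    def log_post(beta, log_sd):
        sd = np.exp(log_sd)
        comp = dict(zip(comp_names, sd))
        ll = ctx.loglik_at(
            beta,
            comp.get("sigma_phy", 0.0) ** 2,
            comp.get("sigma_sp", 0.0) ** 2,
            comp["sigma_e"] ** 2,
        )
        if not np.isfinite(ll):
            return -math.inf
        # half-normal prior on sd plus the log-parameterization Jacobian
        lp = float(np.sum(-0.5 * (sd / prior_scale) ** 2 + log_sd))
        return ll + lp

    beta = fit.beta["estimate"].to_numpy().copy()
    log_sd = np.log(
        np.array([max(reml_sd[c], 1e-4 * sd_y) for c in comp_names])
    )
    n_comp = len(comp_names)
    # correlated beta proposal from the Wald covariance so collinear
    # covariates mix well; one global scale is adapted during burn-in
    res = ctx.profiled(
        fit.sigma2_phy / fit.sigma2_e, fit.sigma2_sp / fit.sigma2_e, True
    )
    cov_beta = fit.sigma2_e * res[3]
    try:
        L_beta = np.linalg.cholesky(cov_beta)
    except np.linalg.LinAlgError:
        L_beta = np.diag(np.maximum(fit.beta["se"].to_numpy(), 1e-8 * max(sd_y, 1.0)))
    sd_step = 0.6 if sample_variances else 0.0
    n_free = p + (n_comp if sample_variances else 0)
    scale = 2.4 / math.sqrt(max(n_free, 1))
    cur_lp = log_post(beta, log_sd)
    draws_beta = np.empty((n_iter, p))
    draws_sd = np.empty((n_iter, n_comp))
    deviance = np.empty(n_iter)
    accepted_post = 0
    accept_window = 0
    for it in range(burn_in + n_iter):
        z = rng.standard_normal(p + n_comp)
        prop_beta = beta + scale * (L_beta @ z[:p])
        prop_sd = log_sd + scale * sd_step * z[p:]
        lp = log_post(prop_beta, prop_sd)
        if math.log(rng.random()) < lp - cur_lp:
            beta, log_sd, cur_lp = prop_beta, prop_sd, lp
            accept_window += 1
            if it >= burn_in:
                accepted_post += 1
        if it < burn_in and (it + 1) % 50 == 0:
            rate = accept_window / 50.0
            scale *= math.exp(0.6 * (rate - 0.3))
            accept_window = 0
        elif it == burn_in - 1:
            accept_window = 0
        if it >= burn_in:
            k = it - burn_in
            draws_beta[k] = beta
            draws_sd[k] = np.exp(log_sd)
            comp = dict(zip(comp_names, np.exp(log_sd)))
            deviance[k] = -2.0 * ctx.loglik_at(
                beta,
                comp.get("sigma_phy", 0.0) ** 2,
                comp.get("sigma_sp", 0.0) ** 2,
                comp["sigma_e"] ** 2,
            )

    rate = accepted_post / n_iter
    if not (0.05 <= rate <= 0.7):
        warnings.warn(
            f"Metropolis acceptance rate {rate:.3f} outside [0.05, 0.7]; "
            "inspect mixing",
            stacklevel=2,
        )
    beta_mean = draws_beta.mean(axis=0)
    sd_mean = draws_sd.mean(axis=0)
    comp = dict(zip(comp_names, sd_mean))
    d_at_mean = -2.0 * ctx.loglik_at(
        beta_mean,
        comp.get("sigma_phy", 0.0) ** 2,
        comp.get("sigma_sp", 0.0) ** 2,
        comp["sigma_e"] ** 2,
    )
    dic = 2.0 * float(deviance.mean()) - d_at_mean

    beta_tab = pd.DataFrame(
        {
            "mean": beta_mean,
            "sd": draws_beta.std(axis=0, ddof=1),
            "ci_low": np.percentile(draws_beta, 2.5, axis=0),
            "ci_high": np.percentile(draws_beta, 97.5, axis=0),
        },
        index=ctx.names,
    )
    sigma_tab = pd.DataFrame(
        {
            "mean": sd_mean,
            "sd": draws_sd.std(axis=0, ddof=1),
            "ci_low": np.percentile(draws_sd, 2.5, axis=0),
            "ci_high": np.percentile(draws_sd, 97.5, axis=0),
        },
        index=comp_names,
    )
    return PosteriorResult(
        beta=beta_tab,
        sigma=sigma_tab,
        dic=dic,
        acceptance_rate=rate,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
    )


# -------------------------------------------------------------- comparison
def compare_models(
    obs: pd.DataFrame,
    tree: Phylogeny,
    specs: list,
    method: str = "reml",
    mcmc_iter: int = 0,
    burn_in: int | None = None,
    seed: int = 0,
    rescale: bool = True,
) -> pd.DataFrame:
    """Fit each candidate model and tabulate AIC (and DIC when sampling).

    Rows are sorted by DIC when ``mcmc_iter > 0``, else by AIC.  Models that
    fail to fit are reported with their error message, never silently
    dropped.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    rows = []
    fits = {}
    for i, spec in enumerate(specs):
        row = {"name": spec.name, "aic": math.nan, "dic": math.nan,
               "r2_marginal": math.nan, "r2_conditional": math.nan, "error": ""}
        try:
            fit = fit_pglmm(obs, tree, spec, method=method, rescale=rescale)
            row["aic"] = fit.aic
            row["r2_marginal"] = fit.r2_marginal
            row["r2_conditional"] = fit.r2_conditional
            if mcmc_iter > 0:
                post = sample_pglmm_posterior(
                    fit,
                    n_iter=mcmc_iter,
                    burn_in=burn_in if burn_in is not None else mcmc_iter // 4,
                    seed=seed + i,
                )
                fit.dic = post.dic
                row["dic"] = post.dic
            fits[spec.name] = fit
        except Exception as exc:  # report, don't drop
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    sort_col = "dic" if mcmc_iter > 0 else "aic"
    table = table.sort_values(sort_col, na_position="last").reset_index(drop=True)
    table.attrs["fits"] = fits
    return table
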