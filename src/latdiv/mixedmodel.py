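"""Maximum-likelihood random-intercept linear mixed models and OLS fits.

The mixed model is y = X beta + a_g + eps with one normal intercept offset
a_g ~ N(0, sigma2_alpha) per group (species) and residuals
eps ~ N(0, sigma2_eps).  Everything is fitted by plain ML (not REML) so that
models with different fixed-effect structures are comparable by AIC.

Fitting profiles beta and sigma2_eps out analytically: for a fixed variance
ratio lambda = sigma2_alpha / sigma2_eps the GLS estimate of beta and the ML
residual variance have closed forms (the marginal covariance is block
compound-symmetric, so each group's inverse and log-determinant are O(1) via
the Sherman-Morrison identity).  Nelder-Mead then minimises the remaining
one-dimensional profiled deviance in t = log(lambda), run from three starts
(lambda = 0.01, 1, 100); t below -30 is clamped to the sigma2_alpha = 0
boundary, which is an admissible (singular) fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

_T_CLAMP = 30.0
_SIGMA2_FLOOR = 1e-12


@dataclass
class StandardScale:
    """Parameters of a z-scoring transform, retained for back-mapping."""

    mean: float
    sd: float

    def transform(self, v):
        return (np.asarray(v, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


@dataclass
class DesignSpec:
    """Response, fixed-effects matrix and group labels for one model fit."""

    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.groups = np.asarray(self.groups)
        if not (len(self.y) == len(self.X) == len(self.groups)):
            raise ValueError("y, X and groups must have equal row counts")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effects matrix X is rank deficient")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]


@dataclass
class LMMFit:
    beta: np.ndarray
    se_beta: np.ndarray
    t_values: np.ndarray
    sigma2_alpha: float
    sigma2_eps: float
    loglik: float
    k: int
    N: int
    converged: bool
    names: list[str]
    singular: bool = False
    cov_beta: np.ndarray | None = None


@dataclass
class OLSFit:
    beta: np.ndarray
    se_beta: np.ndarray
    p_values: np.ndarray
    sigma2: float
    loglik: float
    k: int
    N: int
    r2: float
    adj_r2: float
    names: list[str]
    cov_beta: np.ndarray | None = None


@dataclass
class BootstrapSummary:
    B: int
    seed: int
    names: list[str]
    bias: np.ndarray
    se: np.ndarray
    n_failed: int
    unreliable: bool


def zscore(v) -> tuple[np.ndarray, StandardScale]:
    """Center to mean 0 and scale to sample standard deviation 1 (ddof=1)."""
    arr = np.asarray(v, dtype=float)
    if arr.size < 2 or np.ptp(arr) == 0:
        raise ValueError("cannot z-score a constant (or singleton) vector")
    scale = StandardScale(mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
    return scale.transform(arr), scale


def polynomial_design(z, order: int) -> np.ndarray:
    """Raw-power design [1, z, z^2, ..., z^order] of a z-scored predictor.

    Raw powers (not orthogonal polynomials) are used: centering and scaling
    the predictor already curbs the collinearity among its powers, and raw
    powers keep coefficients directly interpretable.
    """
    if not 0 <= order <= 4:
        raise ValueError("polynomial order must be in 0..4")
    z = np.asarray(z, dtype=float)
    X = np.column_stack([z**j for j in range(order + 1)])
    if np.linalg.matrix_rank(X) < order + 1:
        raise ValueError(
            f"design of order {order} is rank deficient "
            f"({len(np.unique(z))} distinct predictor values)"
        )
    return X


class _Profile:
    """Closed-form GLS/profiled-likelihood pieces for a fixed variance ratio."""

    def __init__(self, y, X, groups):
        self.y = y
        self.X = X
        self.N, self.p = X.shape
        _, self.idx = np.unique(groups, return_inverse=True)
        self.G = int(self.idx.max()) + 1
        self.n_g = np.bincount(self.idx).astype(float)
        self.sx = np.zeros((self.G, self.p))
        np.add.at(self.sx, self.idx, X)
        self.sy = np.bincount(self.idx, weights=y)
        self.Sxx = X.T @ X
        self.Sxy = X.T @ y
        self.Syy = float(y @ y)

    def solve(self, lam: float):
        c = lam / (1.0 + lam * self.n_g)
        A = self.Sxx - (self.sx * c[:, None]).T @ self.sx
        b = self.Sxy - self.sx.T @ (c * self.sy)
        beta = np.linalg.solve(A, b)
        resid_g = self.sy - self.sx @ beta
        Q = (self.Syy - 2.0 * beta @ self.Sxy + beta @ self.Sxx @ beta
             - float(np.sum(c * resid_g**2)))
        sigma2_eps = max(Q / self.N, _SIGMA2_FLOOR)
        logdet = float(np.sum(np.log1p(lam * self.n_g)))
        loglik = -0.5 * (self.N * math.log(2.0 * math.pi * sigma2_eps)
                         + logdet + self.N)
        return beta, sigma2_eps, loglik, A

    def deviance(self, t: float) -> float:
        lam = 0.0 if t <= -_T_CLAMP else math.exp(min(t, _T_CLAMP))
        _, _, ll, _ = self.solve(lam)
        return -2.0 * ll


def fit_lmm_ml(
    spec: DesignSpec,
    starts: tuple[float, ...] = (0.01, 1.0, 100.0),
    xatol: float = 1e-8,
    fatol: float = 1e-10,
) -> LMMFit:
    """Fit the random-intercept model by ML over the profiled deviance.

    The parameter count ``k`` is the number of fixed effects plus two
    variance components, matching the df convention of lme4-style summaries
    (an intercept-only mixed model has k = 3).  A boundary solution
    sigma2_alpha = 0 is retained and flagged ``singular``.
    """
    prof = _Profile(spec.y, spec.X, spec.groups)
    best_t, best_dev, any_ok = None, np.inf, False
    for lam0 in starts:
        res = optimize.minimize(
            lambda t: prof.deviance(float(t[0])),
            x0=[math.log(lam0)],
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 500},
        )
        any_ok = any_ok or bool(res.success)
        if res.fun < best_dev:
            best_dev, best_t = float(res.fun), float(res.x[0])
    converged = any_ok and best_t is not None and np.isfinite(best_dev)
    lam = 0.0 if best_t is None or best_t <= -_T_CLAMP else math.exp(min(best_t, _T_CLAMP))
    beta, sigma2_eps, loglik, A = prof.solve(lam)
    cov_beta = sigma2_eps * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > 0, beta / se, np.nan)
    return LMMFit(
        beta=beta,
        se_beta=se,
        t_values=t_vals,
        sigma2_alpha=lam * sigma2_eps,
        sigma2_eps=sigma2_eps,
        loglik=loglik,
        k=spec.X.shape[1] + 2,
        N=prof.N,
        converged=bool(converged),
        names=list(spec.names),
        singular=lam == 0.0,
        cov_beta=cov_beta,
    )


def information_criteria(loglik: float, k: int, N: int) -> dict[str, float]:
    """AIC = -2 loglik + 2k and its small-sample correction AICc.

    ``k`` counts fixed effects plus 2 variance parameters for mixed fits, or
    plus 1 residual variance for OLS.
    """
    aic = -2.0 * loglik + 2.0 * k
    if N <= k + 1:
        raise ValueError(f"AICc undefined: N={N} <= k+1={k + 1}")
    aicc = aic + 2.0 * k * (k + 1.0) / (N - k - 1.0)
    return {"AIC": aic, "AICc": aicc}


def r2_nakagawa(fit: LMMFit, X: np.ndarray) -> dict[str, float]:
    """Marginal and conditional R^2 for a random-intercept model.

    sigma2_f is the population variance (N denominator) of the fixed-effect
    predictions X beta; marginal R^2 is the fixed-effect share of
    sigma2_f + sigma2_alpha + sigma2_eps, conditional R^2 additionally
    credits the random intercepts.
    """
    yhat = np.asarray(X, dtype=float) @ fit.beta
    sigma2_f = float(np.var(yhat))
    total = sigma2_f + fit.sigma2_alpha + fit.sigma2_eps
    if total <= 0:
        raise ValueError("total variance is zero; R^2 undefined")
    return {
        "R2m": sigma2_f / total,
        "R2c": (sigma2_f + fit.sigma2_alpha) / total,
    }


def parametric_bootstrap(
    fit: LMMFit,
    spec: DesignSpec,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """Full parametric bootstrap of the fixed effects.

    Each replicate resimulates both the species intercepts and the residuals
    from the fitted variances, refits, and records the fixed-effect
    estimates; bias is the mean replicate estimate minus the point estimate
    and SE the standard deviation across replicates.  Replicates that fail to
    converge are excluded and counted; more than 20% failures flags the
    summary unreliable.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    rng = np.random.default_rng(seed)
    _, idx = np.unique(spec.groups, return_inverse=True)
    G = int(idx.max()) + 1
    mu = spec.X @ fit.beta
    sd_a = math.sqrt(max(fit.sigma2_alpha, 0.0))
    sd_e = math.sqrt(max(fit.sigma2_eps, 0.0))
    estimates, n_failed = [], 0
    for _ in range(B):
        a = rng.normal(0.0, sd_a, size=G)
        y_star = mu + a[idx] + rng.normal(0.0, sd_e, size=len(mu))
        rep = fit_lmm_ml(DesignSpec(y_star, spec.X, spec.groups, list(spec.names)))
        if rep.converged:
            estimates.append(rep.beta)
        else:
            n_failed += 1
    if not estimates:
        raise ValueError("all bootstrap replicates failed")
    est = np.asarray(estimates)
    bias = est.mean(axis=0) - fit.beta
    se = est.std(axis=0, ddof=1) if len(est) > 1 else np.full(est.shape[1], np.nan)
    return BootstrapSummary(
        B=B,
        seed=seed,
        names=list(fit.names),
        bias=bias,
        se=se,
        n_failed=n_failed,
        unreliable=n_failed > 0.2 * B,
    )


def fit_ols(y, X, names: list[str] | None = None) -> OLSFit:
    """Ordinary least squares with Gaussian ML log-likelihood.

    loglik uses the ML variance (SSE/N); k = coefficients + 1 residual
    variance; adjusted R^2 = 1 - (1 - R^2)(N - 1)/(N - p - 1) with p the
    non-intercept term count.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    N, ncol = X.shape
    if N <= ncol:
        raise ValueError(f"need N > number of coefficients ({N} <= {ncol})")
    if np.linalg.matrix_rank(X) < ncol:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sigma2_ml = max(sse / N, _SIGMA2_FLOOR)
    loglik = -0.5 * N * (math.log(2.0 * math.pi * sigma2_ml) + 1.0)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - sse / tss
    p = ncol - 1
    adj_r2 = r2 if N - p - 1 <= 0 else 1.0 - (1.0 - r2) * (N - 1.0) / (N - p - 1.0)
    dof = N - ncol
    if dof > 0:
        s2 = sse / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(t_stat), dof)
    else:
        cov = None
        se = np.full(ncol, np.nan)
        pvals = np.full(ncol, np.nan)
    return OLSFit(
        beta=beta,
        se_beta=se,
        p_values=pvals,
        sigma2=sigma2_ml,
        loglik=loglik,
        k=ncol + 1,
        N=N,
        r2=r2,
        adj_r2=adj_r2,
        names=list(names) if names else [f"x{j}" for j in range(ncol)],
        cov_beta=cov,
    )
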