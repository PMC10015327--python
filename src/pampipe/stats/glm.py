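"""Logistic occurrence models.

Maximum-likelihood fits by IRLS with explicit complete-separation detection,
Firth-type bias-reduced fits (Jeffreys penalty) that stay finite under
separation, Wald pairwise contrasts with Bonferroni correction, response
prediction with delta-method confidence bands, and empirical tipping-point
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "ModelFit",
    "ContrastResult",
    "TippingPoint",
    "fit_logistic",
    "fit_firth",
    "pairwise_contrasts",
    "predict_response",
    "tipping_point",
    "design_from_factor",
]

#: |standardised coefficient| beyond which separation is suspected
SEPARATION_BETA = 15.0
MAX_ITER = 100
GRAD_TOL = 1e-8


@dataclass
class ModelFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    null_loglik: float
    fitted: np.ndarray
    residuals: np.ndarray  # response residuals y - p
    converged: bool
    method: str  # {"ML", "bias-reduced"}
    names: list[str] = field(default_factory=list)
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    separation: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = self.coef / se
        p = 2 * sps.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": self.names, "estimate": self.coef, "se": se, "z": z, "p": p}
        )


def _loglik(X, y, beta):
    eta = X @ beta
    # log p = -log(1+exp(-eta)); log(1-p) = -log(1+exp(eta))
    return float(-np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))


def _null_loglik(y):
    n, k = len(y), int(np.sum(y))
    if k in (0, n):
        return 0.0
    p = k / n
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def _prepare(X, y, names, allow_single_class: bool = False):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    if not allow_single_class and len(np.unique(y)) < 2:
        raise ValueError("response must contain both classes")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    return X, y, list(names)


def _standardised_scale(X):
    """Column scales for the separation check (intercept-like columns -> 1)."""
    sd = X.std(axis=0)
    return np.where(sd > 0, sd, 1.0)


def fit_logistic(X, y, names=None, max_iter: int = MAX_ITER, tol: float = GRAD_TOL) -> ModelFit:
    """ML logistic regression by IRLS (Newton scoring).

    Diverging coefficients (|beta| > 15 on standardised covariates) or
    non-convergence within ``max_iter`` steps flag suspected complete
    separation; the fit is returned non-converged with the advice to use the
    bias-reduced path.
    """
    X, y, names = _prepare(X, y, names)
    n, p = X.shape
    beta = np.zeros(p)
    scale = _standardised_scale(X)
    converged = False
    separation = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.any(np.abs(beta * scale) > SEPARATION_BETA):
            separation = True
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    if separation:
        converged = False
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(info)
    return ModelFit(
        coef=beta,
        cov=cov,
        loglik=_loglik(X, y, beta),
        null_loglik=_null_loglik(y),
        fitted=mu,
        residuals=y - mu,
        converged=converged,
        method="ML",
        names=names,
        X=X,
        y=y,
        separation=separation,
    )


def fit_firth(X, y, names=None, max_iter: int = 200, tol: float = GRAD_TOL) -> ModelFit:
    """Bias-reduced logistic regression (Jeffreys penalty, Firth scoring).

    Maximises l(beta) + 0.5 log|I(beta)|; estimates stay finite under
    complete separation. The modified score is X'(y - p + h(0.5 - p)) with h
    the hat-matrix diagonal. Single-class responses are allowed (the penalty
    keeps the intercept finite).
    """
    X, y, names = _prepare(X, y, names, allow_single_class=True)
    n, p = X.shape
    beta = np.zeros(p)

    def penalised_ll(b):
        eta = X @ b
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        return _loglik(X, y, b) + 0.5 * logdet

    ll = penalised_ll(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        Xw = X * w[:, None]
        info = Xw.T @ X
        info_inv = np.linalg.pinv(info)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X, info_inv, Xw)
        score = X.T @ (y - mu + h * (0.5 - mu))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        # step-halving on the penalised likelihood
        new_ll = penalised_ll(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_ll = penalised_ll(beta + step)
            halvings += 1
        beta = beta + step
        ll = new_ll
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(info)
    return ModelFit(
        coef=beta,
        cov=cov,
        loglik=_loglik(X, y, beta),
        null_loglik=_null_loglik(y),
        fitted=mu,
        residuals=y - mu,
        converged=converged,
        method="bias-reduced",
        names=names,
        X=X,
        y=y,
    )


def design_from_factor(levels: list[str] | np.ndarray) -> tuple[np.ndarray, list[str], list[str]]:
    """Dummy-coded design (intercept + k-1 indicators, reference = first
    sorted level). Returns (X, column names, sorted levels)."""
    levels = np.asarray(levels)
    uniq = sorted(np.unique(levels).tolist())
    X = np.ones((len(levels), len(uniq)))
    for j, lv in enumerate(uniq[1:], start=1):
        X[:, j] = (levels == lv).astype(float)
    names = ["(Intercept)"] + [f"level[{lv}]" for lv in uniq[1:]]
    return X, names, uniq


@dataclass(frozen=True)
class ContrastResult:
    level_a: str
    level_b: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float


def pairwise_contrasts(
    fit: ModelFit, levels: list[str], m: int | None = None
) -> list[ContrastResult]:
    """Wald contrasts between all pairs of factor levels with Bonferroni
    adjustment: p_adj = min(1, m * p_raw), m = number of comparisons.

    ``fit`` must come from a :func:`design_from_factor` design over
    ``levels`` (sorted unique levels, first = reference).
    """
    if len(levels) < 2:
        raise ValueError("need a factor with >= 2 levels")
    pairs = list(combinations(range(len(levels)), 2))
    if m is None:
        m = len(pairs)
    k = len(fit.coef)
    out = []
    for a, b in pairs:
        c = np.zeros(k)
        # effect of level j relative to reference sits in coef[j] (j >= 1)
        if a >= 1:
            c[a] -= 1.0
        if b >= 1:
            c[b] += 1.0
        est = float(c @ fit.coef)
        var = float(c @ fit.cov @ c)
        if var <= 0:
            raise ValueError(f"rank-deficient contrast {levels[a]} vs {levels[b]}")
        se = np.sqrt(var)
        z = est / se
        p = float(2 * sps.norm.sf(abs(z)))
        out.append(
            ContrastResult(
                level_a=levels[a],
                level_b=levels[b],
                estimate=est,
                se=se,
                p_raw=p,
                p_adjusted=min(1.0, m * p),
            )
        )
    return out


def predict_response(
    fit: ModelFit, X_new, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fitted probabilities with delta-method CI built on the logit scale
    (endpoints therefore always inside (0, 1))."""
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    if X_new.shape[1] != len(fit.coef):
        raise ValueError(
            f"design has {X_new.shape[1]} columns, fit has {len(fit.coef)} coefficients"
        )
    eta = X_new @ fit.coef
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X_new, fit.cov, X_new))
    z = sps.norm.ppf(0.5 + level / 2)
    return expit(eta), expit(eta - z * se_eta), expit(eta + z * se_eta)


@dataclass(frozen=True)
class TippingPoint:
    covariate: str
    direction: str  # {"presence-above", "presence-below"}
    boundary: float
    n_absences_beyond: int


def tipping_point(y, covariate, direction: str, name: str = "covariate") -> TippingPoint:
    """Empirical data boundary: min (presence-above) or max (presence-below)
    covariate value among presences, with the count of absences on the
    presence side of the boundary."""
    y = np.asarray(y, dtype=int)
    x = np.asarray(covariate, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("need both presences and absences")
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate (constant)")
    pres = x[y == 1]
    abs_ = x[y == 0]
    if direction == "presence-above":
        boundary = float(pres.min())
        beyond = int(np.sum(abs_ >= boundary))
    elif direction == "presence-below":
        boundary = float(pres.max())
        beyond = int(np.sum(abs_ <= boundary))
    else:
        raise ValueError("direction must be 'presence-above' or 'presence-below'")
    return TippingPoint(
        covariate=name, direction=direction, boundary=boundary, n_absences_beyond=beyond
    )
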