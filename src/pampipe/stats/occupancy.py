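"""Constant-psi, constant-p null occupancy model on 7-day detection histories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from ..review import DetectionHistory, N_DAYS

__all__ = ["OccupancyFit", "null_occupancy_mle", "occupancy_loglik"]


@dataclass(frozen=True)
class OccupancyFit:
    psi: float  # occupancy probability
    p: float  # daily detection probability given occupancy
    se_psi: float  # delta-method SEs (from the logit-scale Hessian)
    se_p: float
    loglik: float
    n_sites: int
    n_days: int


def _histories_to_counts(histories) -> tuple[np.ndarray, int]:
    if isinstance(histories, np.ndarray):
        mat = histories
    else:
        first = histories[0]
        if isinstance(first, DetectionHistory):
            mat = np.array([h.days for h in histories])
        else:
            mat = np.asarray(histories)
    if mat.ndim != 2:
        raise ValueError("histories must be a (sites x days) binary matrix")
    return mat.sum(axis=1), mat.shape[1]


def occupancy_loglik(psi: float, p: float, detections: np.ndarray, n_days: int) -> float:
    """Zero-inflated binomial log-likelihood of per-site detection counts."""
    d = np.asarray(detections, dtype=np.float64)
    det = d > 0
    ll = np.sum(
        np.log(psi) + d[det] * np.log(p) + (n_days - d[det]) * np.log(1 - p)
    )
    ll += np.sum(det == False) * np.log(psi * (1 - p) ** n_days + (1 - psi))  # noqa: E712
    return float(ll)


def null_occupancy_mle(histories) -> OccupancyFit:
    """MLE of (psi, p), optimised on the logit scale (L-BFGS).

    ``histories`` is a list of :class:`DetectionHistory` or a binary
    (sites x days) array. All-zero histories leave psi unidentifiable and
    raise; the estimate satisfies psi_hat >= naive occupancy.
    """
    d, J = _histories_to_counts(histories)
    n = len(d)
    if n < 1 or J < 1:
        raise ValueError("need >= 1 site and >= 1 survey")
    if np.all(d == 0):
        raise ValueError("no detections anywhere: psi is unidentifiable")

    naive = float(np.mean(d > 0))
    mean_rate = float(d[d > 0].mean() / J)

    def nll(theta):
        psi, p = expit(theta)
        psi = min(max(psi, 1e-12), 1 - 1e-12)
        p = min(max(p, 1e-12), 1 - 1e-12)
        return -occupancy_loglik(psi, p, d, J)

    x0 = logit(np.clip([min(naive * 1.05, 0.99), mean_rate], 0.01, 0.99))
    opts = {"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000}
    res = minimize(nll, x0, method="L-BFGS-B", options=opts)
    # fall back to a second start if the first stalled
    res2 = minimize(nll, logit([0.5, 0.5]), method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    if res2.fun < res.fun:
        res = res2
    theta = res.x
    psi_hat, p_hat = expit(theta)

    # numerical Hessian on the logit scale -> delta method to probabilities
    eps = 1e-5
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            tpp = theta.copy(); tpp[i] += eps; tpp[j] += eps
            tpm = theta.copy(); tpm[i] += eps; tpm[j] -= eps
            tmp = theta.copy(); tmp[i] -= eps; tmp[j] += eps
            tmm = theta.copy(); tmm[i] -= eps; tmm[j] -= eps
            H[i, j] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (4 * eps**2)
    try:
        cov_logit = np.linalg.inv(H)
        grad = np.array([psi_hat * (1 - psi_hat), p_hat * (1 - p_hat)])
        var = grad**2 * np.diag(cov_logit)
        se_psi, se_p = np.sqrt(np.clip(var, 0, None))
    except np.linalg.LinAlgError:
        se_psi = se_p = np.nan
    return OccupancyFit(
        psi=float(psi_hat),
        p=float(p_hat),
        se_psi=float(se_psi),
        se_p=float(se_p),
        loglik=float(-res.fun),
        n_sites=n,
        n_days=J,
    )
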