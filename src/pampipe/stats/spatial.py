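"""Spatial diagnostics and correction: Moran's I on residuals, the empirical
variogram, and the distance-weighted autocovariate predictor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist

__all__ = ["SpatialWeights", "MoranResult", "morans_i", "autocovariate", "empirical_variogram"]


@dataclass
class SpatialWeights:
    """Inverse-distance weights w_ij >= 0 with zero diagonal.

    ``cutoff_m``: neighbourhood radius (None = global); ``row_standardize``
    divides each row by its sum.
    """

    matrix: np.ndarray
    scheme: str = "inverse-distance"
    cutoff_m: float | None = None
    row_standardized: bool = False

    @classmethod
    def inverse_distance(
        cls,
        coords: np.ndarray,
        cutoff_m: float | None = None,
        row_standardize: bool = False,
        power: float = 1.0,
    ) -> "SpatialWeights":
        coords = np.asarray(coords, dtype=np.float64)
        d = cdist(coords, coords)
        n = len(coords)
        off = ~np.eye(n, dtype=bool)
        if np.any(d[off] == 0):
            raise ValueError("coincident sites (zero distance)")
        w = np.zeros_like(d)
        w[off] = 1.0 / d[off] ** power
        if cutoff_m is not None:
            w[d > cutoff_m] = 0.0
        if np.any(w.sum(axis=1) == 0):
            raise ValueError("every site needs >= 1 neighbour (increase cutoff)")
        if row_standardize:
            w = w / w.sum(axis=1, keepdims=True)
        return cls(
            matrix=w, cutoff_m=cutoff_m, row_standardized=row_standardize
        )


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float  # exactly -1/(n-1)
    variance: float
    z: float
    p: float  # two-sided, normal approximation


def morans_i(values, coords=None, weights: SpatialWeights | None = None) -> MoranResult:
    """Global Moran's I with expectation, normality variance and two-sided p.

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i²), z centred values.
    """
    x = np.asarray(values, dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if weights is None:
        if coords is None:
            raise ValueError("provide coords or weights")
        weights = SpatialWeights.inverse_distance(np.asarray(coords))
    w = weights.matrix
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero-variance values")
    s0 = float(w.sum())
    num = float(z @ w @ z)
    I = (n / s0) * (num / denom)
    expected = -1.0 / (n - 1)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - expected**2
    zscore = (I - expected) / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(zscore)))
    return MoranResult(I=float(I), expected=expected, variance=float(var), z=float(zscore), p=p)


def autocovariate(y, coords, min_neighbour_dist: float = 210.0) -> np.ndarray:
    """Distance-weighted average of neighbouring responses.

    A_i = sum_j w_ij y_j / sum_j w_ij with w_ij = 1/d_ij over neighbours
    within radius_i = max(min_neighbour_dist, nearest-neighbour distance of
    i), so no site is left neighbourless. Invariant to rescaling distances.
    """
    y = np.asarray(y, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.float64)
    d = cdist(coords, coords)
    n = len(y)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident sites (zero distance)")
    nearest = np.where(np.eye(n, dtype=bool), np.inf, d).min(axis=1)
    out = np.empty(n)
    for i in range(n):
        radius = max(min_neighbour_dist, nearest[i])
        nbr = (d[i] <= radius + 1e-9) & off[i]
        w = 1.0 / d[i, nbr]
        out[i] = float(w @ y[nbr] / w.sum())
    return out


def empirical_variogram(values, coords, n_bins: int = 10, max_dist: float | None = None) -> pd.DataFrame:
    """Semivariance gamma(h) = mean of 0.5 (z_i - z_j)² over distance bins.

    Empty bins are reported with count 0 (gamma NaN). Columns: lag_mid,
    semivariance, n_pairs.
    """
    z = np.asarray(values, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.float64)
    n = len(z)
    if n < 2:
        raise ValueError("need n >= 2")
    iu = np.triu_indices(n, k=1)
    d = cdist(coords, coords)[iu]
    g = 0.5 * (z[:, None] - z[None, :])[iu] ** 2
    if max_dist is None:
        max_dist = float(d.max())
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    keep = d <= max_dist
    rows = []
    for b in range(n_bins):
        m = keep & (idx == b)
        cnt = int(m.sum())
        rows.append(
            {
                "lag_mid": 0.5 * (edges[b] + edges[b + 1]),
                "semivariance": float(g[m].mean()) if cnt else np.nan,
                "n_pairs": cnt,
            }
        )
    return pd.DataFrame(rows)
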