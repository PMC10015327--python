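"""Hierarchical (all-subsets) variance partitioning of logistic goodness of
fit into independent and joint contributions per predictor."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .glm import fit_logistic, fit_firth
from .scale import pseudo_r2

__all__ = ["PartitionResult", "hier_partition"]

MAX_PREDICTORS = 6


@dataclass
class PartitionResult:
    predictors: list[str]
    independent: dict  # name -> gof units
    joint: dict  # name -> marginal - independent
    total_gof: float  # full-model gof

    @property
    def percent(self) -> dict:
        return {k: 100.0 * v / self.total_gof for k, v in self.independent.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "independent": [self.independent[p] for p in self.predictors],
                "joint": [self.joint[p] for p in self.predictors],
                "percent_of_total": [self.percent[p] for p in self.predictors],
            }
        )


def _as_matrix(col) -> np.ndarray:
    a = np.asarray(col, dtype=np.float64)
    return a[:, None] if a.ndim == 1 else a


def hier_partition(
    y,
    predictors: dict[str, np.ndarray],
    gof_kind: str = "mcfadden",
    method: str = "auto",
) -> PartitionResult:
    """Chevan–Sutherland hierarchical partitioning over all 2^k subsets.

    The independent contribution of x is the hierarchy-weighted average gain
    in goodness of fit from adding x to subsets lacking it (the Shapley
    value of the gof game); joint = marginal single-predictor gof minus
    independent. Predictors may be multi-column groups. With
    ``method='auto'`` any subset showing separation switches the whole run
    to bias-reduced fits so all gofs stay comparable.
    """
    names = list(predictors)
    k = len(names)
    if k > MAX_PREDICTORS:
        raise ValueError(f"refusing k={k} > {MAX_PREDICTORS} predictors (2^k subset fits)")
    y = np.asarray(y, dtype=int)
    mats = {nm: _as_matrix(predictors[nm]) for nm in names}
    n = len(y)

    def design(subset: tuple[str, ...]) -> np.ndarray:
        cols = [np.ones((n, 1))]
        cols += [mats[nm] for nm in subset]
        return np.hstack(cols)

    subsets = [tuple(c) for r in range(k + 1) for c in combinations(names, r)]

    def fit_all(use_firth: bool) -> tuple[dict, bool]:
        gof = {}
        saw_sep = False
        for s in subsets:
            if not s:
                gof[s] = 0.0
                continue
            X = design(s)
            fit = fit_firth(X, y) if use_firth else fit_logistic(X, y)
            if not use_firth and (fit.separation or not fit.converged):
                saw_sep = True
            gof[s] = pseudo_r2(fit, gof_kind)
        return gof, saw_sep

    if method == "firth":
        gof, _ = fit_all(True)
    elif method == "ml":
        gof, _ = fit_all(False)
    else:
        gof, saw_sep = fit_all(False)
        if saw_sep:
            gof, _ = fit_all(True)

    independent = {}
    for x in names:
        others = [nm for nm in names if nm != x]
        total = 0.0
        for r in range(k):
            for s in combinations(others, r):
                w = factorial(r) * factorial(k - r - 1) / factorial(k)
                total += w * (gof[tuple(sorted(s + (x,), key=names.index))] - gof[tuple(s)])
        independent[x] = total
    joint = {x: gof[(x,)] - independent[x] for x in names}
    return PartitionResult(
        predictors=names,
        independent=independent,
        joint=joint,
        total_gof=gof[tuple(names)],
    )
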