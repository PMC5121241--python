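"""Permutation inference for dyadic and nodal network data.

Observations on dyads of a network are not independent, so ordinary regression
p-values are invalid. The procedures here build null distributions by permuting node
identities:

* :func:`mrqap_dsp` — multiple regression across dyadic matrices with
  double-semi-partialling QAP permutations: each predictor is residualized on the
  remaining predictors, the residual *matrix* is permuted by relabeling nodes (rows
  and columns jointly, preserving the dyadic dependence structure), substituted back
  into the design, and the model refit; the per-predictor pivot is the t-like
  standardized coefficient, compared two-tailed by absolute value. Point estimates are
  exactly ordinary least squares on the vectorized off-diagonal dyads — the
  permutation machinery affects p-values only.
* :func:`node_regression` — OLS on per-node quantities with significance from
  permuting the outcome vector across nodes.
* :func:`gearys_c` — network autocorrelation between a node attribute and a weight
  matrix; 1.0 under no association, below 1.0 when tied nodes have similar values.

All p-values use the add-one convention ``(b + 1) / (n_perm + 1)`` so they are never
exactly zero, and every result is bit-reproducible given (data, n_perm, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DyadMatrix

__all__ = [
    "PermRegressionResult",
    "GearyResult",
    "qap_permute",
    "mrqap_dsp",
    "node_regression",
    "gearys_c",
    "CollinearityError",
]


class CollinearityError(ValueError):
    """The predictor set is rank-deficient; the message names the predictors."""


@dataclass
class PermRegressionResult:
    """Coefficients and permutation p-values of one permutation regression."""

    predictors: list[str]
    beta: np.ndarray  # per predictor, intercept excluded
    std_beta: np.ndarray
    t_stat: np.ndarray
    p_perm: np.ndarray
    intercept: float
    r_squared: float
    n_perm: int
    seed: int
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "beta": self.beta,
                "std_beta": self.std_beta,
                "t": self.t_stat,
                "p_perm": self.p_perm,
                "r_squared": self.r_squared,
                "n_perm": self.n_perm,
                "seed": self.seed,
                "n_obs": self.n_obs,
            }
        )

    def bonferroni(self) -> np.ndarray:
        """Optional family-wise correction (off by default everywhere)."""
        return np.minimum(1.0, self.p_perm * len(self.predictors))


@dataclass
class GearyResult:
    """Geary's C autocorrelation between a node attribute and network weights."""

    c: float
    n_perm: int = 0
    seed: int = 0
    p_perm: float | None = None
    null_mean: float | None = None

    @property
    def direction(self) -> str:
        if self.c < 1.0:
            return "positive"
        if self.c > 1.0:
            return "negative"
        return "none"


def _as_permutation(m: DyadMatrix, permutation) -> np.ndarray:
    """Normalize a permutation given as index array or id->id mapping."""
    if isinstance(permutation, dict):
        if sorted(permutation) != sorted(m.ids) or sorted(
            permutation.values()
        ) != sorted(m.ids):
            raise ValueError("permutation must be a bijection on the node labels")
        pos = {label: i for i, label in enumerate(m.ids)}
        return np.array([pos[permutation[label]] for label in m.ids])
    idx = np.asarray(permutation, dtype=int)
    if sorted(idx.tolist()) != list(range(m.n)):
        raise ValueError("permutation must be a bijection on node indices")
    return idx


def qap_permute(m: DyadMatrix, permutation) -> DyadMatrix:
    """Relabel nodes: rows and columns permuted simultaneously, mask included."""
    idx = _as_permutation(m, permutation)
    return DyadMatrix(list(m.ids), m.values[np.ix_(idx, idx)], m.label, m.directed)


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS fit; returns (coef, t-stats, r_squared). Degenerate SEs give t = 0."""
    n, p = design.shape
    xtx = design.T @ design
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = max(n - p, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(xtx)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef, t, min(max(r2, 0.0), 1.0)


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            "rank-deficient design among predictors: " + ", ".join(names)
        )


def mrqap_dsp(
    y: DyadMatrix, predictors: list[DyadMatrix], n_perm: int = 2000, seed: int = 0
) -> PermRegressionResult:
    """Double-semi-partialling MRQAP regression of one dyadic matrix on others.

    Dyads with a missing value in the outcome or any predictor are dropped listwise.
    Permutations relabel nodes on each predictor's residual matrix, then re-extract
    the originally observed dyads; a permutation that moves a missing cell into the
    observed set drops that dyad for that permutation only.
    """
    if not predictors:
        raise ValueError("need at least one predictor matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    ids = list(y.ids)
    for x in predictors:
        if list(x.ids) != ids:
            raise ValueError("all matrices must share the same id list")
    n = y.n
    names = [x.label or f"X{i+1}" for i, x in enumerate(predictors)]

    mask = y.present_mask()
    for x in predictors:
        mask &= x.present_mask()
    if mask.sum() < len(predictors) + 2:
        raise ValueError("too few complete dyads for regression")
    yv = y.values[mask]
    Xv = np.column_stack([x.values[mask] for x in predictors])
    design = np.column_stack([np.ones(len(yv)), Xv])
    _check_rank(design, names)

    coef, t_obs, r2 = _ols(design, yv)
    beta = coef[1:]
    sy = yv.std()
    std_beta = beta * (Xv.std(axis=0) / sy if sy > 0 else 0.0)

    rng = np.random.default_rng(seed)
    p = len(predictors)
    exceed = np.zeros(p, dtype=int)
    # residual matrices: X_k residualized cellwise on the other predictors
    for k in range(p):
        others = np.delete(Xv, k, axis=1)
        d_other = np.column_stack([np.ones(len(yv)), others])
        g, *_ = np.linalg.lstsq(d_other, Xv[:, k], rcond=None)
        resid = Xv[:, k] - d_other @ g
        emat = np.full((n, n), np.nan)
        emat[mask] = resid
        for _ in range(n_perm):
            idx = rng.permutation(n)
            ev = emat[np.ix_(idx, idx)][mask]
            keep = ~np.isnan(ev)
            d_star = np.column_stack(
                [np.ones(keep.sum()), others[keep], ev[keep]]
            )
            _, t_star, _ = _ols(d_star, yv[keep])
            if abs(t_star[-1]) >= abs(t_obs[k + 1]):
                exceed[k] += 1
    p_perm = (exceed + 1) / (n_perm + 1)

    return PermRegressionResult(
        predictors=names,
        beta=beta,
        std_beta=std_beta,
        t_stat=t_obs[1:],
        p_perm=p_perm,
        intercept=float(coef[0]),
        r_squared=r2,
        n_perm=n_perm,
        seed=seed,
        n_obs=int(mask.sum()),
    )


def node_regression(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermRegressionResult:
    """Node-level OLS with significance from permuting the outcome across nodes."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    df = pd.concat([outcome.rename("_y"), predictors], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete nodes")
    yv = df["_y"].to_numpy(float)
    names = list(predictors.columns)
    Xv = df[names].to_numpy(float)
    design = np.column_stack([np.ones(len(yv)), Xv])
    _check_rank(design, names)
    coef, t_obs, r2 = _ols(design, yv)
    beta = coef[1:]
    sy = yv.std()
    std_beta = beta * (Xv.std(axis=0) / sy if sy > 0 else 0.0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names), dtype=int)
    for _ in range(n_perm):
        yp = yv[rng.permutation(len(yv))]
        _, t_star, _ = _ols(design, yp)
        exceed += (np.abs(t_star[1:]) >= np.abs(t_obs[1:])).astype(int)
    p_perm = (exceed + 1) / (n_perm + 1)

    return PermRegressionResult(
        predictors=names,
        beta=beta,
        std_beta=std_beta,
        t_stat=t_obs[1:],
        p_perm=p_perm,
        intercept=float(coef[0]),
        r_squared=r2,
        n_perm=n_perm,
        seed=seed,
        n_obs=len(yv),
    )


def gearys_c(
    attribute: pd.Series | np.ndarray,
    weights: DyadMatrix,
    *,
    binary: bool = False,
    n_perm: int = 0,
    seed: int = 0,
) -> GearyResult:
    """Geary's C autocorrelation of a node attribute over network weights.

    ``C = [(n-1) * sum_ij w_ij (x_i - x_j)^2] / [2 * (sum_ij w_ij) * sum_i (x_i - xbar)^2]``

    Missing weight cells contribute zero. With ``binary=True`` the weights are
    dichotomized first (tie/no tie). With ``n_perm > 0``, the attribute is randomly
    permuted over nodes to form a null distribution; the result then carries the null
    mean of C and a one-tailed add-one p-value in the observed direction.
    """
    if isinstance(attribute, pd.Series):
        x = attribute.reindex(weights.ids).to_numpy(float)
        if np.any(np.isnan(x)):
            raise ValueError("attribute missing for some network nodes")
    else:
        x = np.asarray(attribute, float)
        if x.shape != (weights.n,):
            raise ValueError("attribute length must match the number of nodes")
    w = np.nan_to_num(weights.values, nan=0.0)
    np.fill_diagonal(w, 0.0)
    if binary:
        w = (w > 0).astype(float)
    w_sum = w.sum()
    if w_sum <= 0:
        raise ValueError("all weights are zero")
    var = np.sum((x - x.mean()) ** 2)
    if var <= 0:
        raise ValueError("attribute has zero variance; C undefined")
    n = len(x)

    def _c(xv: np.ndarray) -> float:
        diff2 = (xv[:, None] - xv[None, :]) ** 2
        return float((n - 1) * np.sum(w * diff2) / (2.0 * w_sum * np.sum((xv - xv.mean()) ** 2)))

    c_obs = _c(x)
    result = GearyResult(c=c_obs, n_perm=n_perm, seed=seed)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.array([_c(x[rng.permutation(n)]) for _ in range(n_perm)])
        result.null_mean = float(null.mean())
        if c_obs <= 1.0:
            b = int(np.sum(null <= c_obs))
        else:
            b = int(np.sum(null >= c_obs))
        result.p_perm = (b + 1) / (n_perm + 1)
    return result
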