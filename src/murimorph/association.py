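"""Association between tooth shape and external variables.

Two-block partial least squares extracts paired axes of maximal covariation
between the shape-variable block and an external block (the VD grazing
index, or log centroid size) by singular value decomposition of the
between-block correlation matrix (default; cross-covariance available).
The RV coefficient summarizes overall association as a multivariate
analogue of the squared correlation, and permutation tests (rows of the
second block shuffled) give exact-style p-values with the (1+exceed)/(1+n)
convention.  Allometry is assessed by multivariate regression of the shape
variables on log centroid size, reporting Wilks' lambda with its F
approximation and the percentage of total shape variation predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

from .tps_shape import ShapeScores

__all__ = [
    "AssociationResult",
    "RegressionResult",
    "two_block_pls",
    "rv_coefficient",
    "permutation_test",
    "shape_size_regression",
]


def _as_matrix(block) -> np.ndarray:
    if isinstance(block, ShapeScores):
        block = block.matrix
    arr = np.asarray(block, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


@dataclass
class AssociationResult:
    """PLS axes and association statistics between two blocks."""

    singular_values: np.ndarray  # non-increasing
    percent_covariation: np.ndarray  # squared singular values, % of their sum
    axis_scores_1: np.ndarray  # (n, n_axes)
    axis_scores_2: np.ndarray  # (n, n_axes)
    axis_correlation: np.ndarray  # Pearson r per axis pair
    left_vectors: np.ndarray  # (p1, n_axes)
    right_vectors: np.ndarray  # (p2, n_axes)
    mode: str = "correlation"
    rv: float | None = None
    p_perm_r: float | None = None
    p_perm_rv: float | None = None
    n_perm: int = 0


def two_block_pls(block1, block2, mode: str = "correlation") -> AssociationResult:
    """Two-block PLS by SVD of the between-block correlation (or covariance) matrix.

    Blocks are centered; in correlation mode both are additionally
    standardized column-wise (a zero-variance column is an error).  Axis
    scores are the processed blocks projected on the singular vectors; when
    the second block has a single column there is exactly one axis,
    explaining 100% of the summed squared covariation.
    """
    if mode not in ("correlation", "covariance"):
        raise ValueError(f"unknown PLS mode {mode!r}")
    x1 = _as_matrix(block1)
    x2 = _as_matrix(block2)
    if x1.shape[0] != x2.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    n = x1.shape[0]
    x1 = x1 - x1.mean(axis=0)
    x2 = x2 - x2.mean(axis=0)
    if mode == "correlation":
        for name, blk in (("block1", x1), ("block2", x2)):
            sd = blk.std(axis=0, ddof=1)
            zero = np.flatnonzero(sd == 0)
            if zero.size:
                raise ValueError(f"zero-variance column {zero[0]} in {name} (correlation mode)")
            blk /= sd
    cross = x1.T @ x2 / (n - 1)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    n_axes = min(cross.shape)
    u, s, v = u[:, :n_axes], s[:n_axes], vt.T[:, :n_axes]
    scores1 = x1 @ u
    scores2 = x2 @ v
    r = np.empty(n_axes)
    for j in range(n_axes):
        sd1, sd2 = scores1[:, j].std(), scores2[:, j].std()
        r[j] = 0.0 if sd1 == 0 or sd2 == 0 else float(np.corrcoef(scores1[:, j], scores2[:, j])[0, 1])
    total = np.sum(s**2)
    pct = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    return AssociationResult(
        singular_values=s,
        percent_covariation=pct,
        axis_scores_1=scores1,
        axis_scores_2=scores2,
        axis_correlation=r,
        left_vectors=u,
        right_vectors=v,
        mode=mode,
    )


def rv_coefficient(block1, block2) -> float:
    """RV coefficient tr(S12 S21) / sqrt(tr(S11^2) tr(S22^2)) on centered blocks."""
    x1 = _as_matrix(block1)
    x2 = _as_matrix(block2)
    if x1.shape[0] != x2.shape[0] or x1.shape[0] < 3:
        raise ValueError("blocks need matching rows and at least 3 specimens")
    x1 = x1 - x1.mean(axis=0)
    x2 = x2 - x2.mean(axis=0)
    s12 = x1.T @ x2
    s11 = x1.T @ x1
    s22 = x2.T @ x2
    denom = np.sqrt(np.sum(s11**2) * np.sum(s22**2))
    if denom == 0:
        raise ValueError("zero total variance in a block")
    return float(np.sum(s12**2) / denom)


def permutation_test(
    statistic,
    block1,
    block2,
    n_perm: int = 9999,
    seed=None,
) -> float:
    """Permutation p-value for association between two blocks.

    Permutes rows of *block2*; p = (1 + #{permuted >= observed}) / (1 + n_perm),
    so p is never zero.  The statistic may be an axis correlation, the first
    singular value, or the RV coefficient -- any callable of two blocks.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    x1 = _as_matrix(block1)
    x2 = _as_matrix(block2)
    observed = float(statistic(x1, x2))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x2.shape[0])
        if float(statistic(x1, x2[perm])) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


@dataclass
class RegressionResult:
    """Multivariate regression of shape on one predictor (allometry test)."""

    wilks_lambda: float
    p_value: float
    percent_variance_predicted: float
    coefficients: np.ndarray  # shape change per unit predictor
    n_components: int = 0  # shape dimensions used for Wilks' lambda
    rank_deficient: bool = False


def shape_size_regression(shape, predictor) -> RegressionResult:
    """Regress shape variables on a single predictor (log centroid size).

    percent_variance_predicted = 100 * tr(predicted SSCP) / tr(total SSCP).
    Wilks' lambda = det(E) / det(E + H) from the regression MANOVA with its
    exact F transform for a single predictor; when the shape block has more
    columns than n - 2, lambda is computed on the leading principal
    components of the shape block (rank guard, flagged on the result).
    """
    y = _as_matrix(shape)
    x = np.asarray(predictor, float).reshape(-1)
    n, p = y.shape
    if x.size != n:
        raise ValueError("predictor length must match specimen count")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    coef = (xc @ yc) / sxx  # (p,) slope per shape variable
    yhat = np.outer(xc, coef)
    sse_total = float(np.sum(yc**2))
    percent = 100.0 * float(np.sum(yhat**2)) / sse_total

    rank_deficient = p > n - 2
    if rank_deficient:
        warnings.warn("more shape variables than residual df; Wilks on leading PCs")
        u, s, _ = np.linalg.svd(yc, full_matrices=False)
        keep = min(n - 2, int(np.sum(s > 1e-10 * s[0])))
        yw = u[:, :keep] * s[:keep]
    else:
        yw = yc
        keep = p
    resid = yw - np.outer(xc, (xc @ yw) / sxx)
    e_mat = resid.T @ resid
    t_mat = yw.T @ yw
    sign_e, logdet_e = np.linalg.slogdet(e_mat)
    sign_t, logdet_t = np.linalg.slogdet(t_mat)
    if sign_e <= 0 or sign_t <= 0:
        lam = 0.0
    else:
        lam = float(np.exp(logdet_e - logdet_t))
    # exact F for one predictor: F = ((1 - L)/L) * ((n - p - 1)/p)
    df2 = n - keep - 1
    if lam > 0 and df2 > 0:
        f_stat = (1.0 - lam) / lam * df2 / keep
        p_value = float(f_dist.sf(f_stat, keep, df2))
    else:
        p_value = 0.0
    return RegressionResult(
        wilks_lambda=lam,
        p_value=p_value,
        percent_variance_predicted=percent,
        coefficients=coef,
        n_components=keep,
        rank_deficient=rank_deficient,
    )
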