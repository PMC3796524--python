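"""Morphospace statistics: PCA, divergence distances, bootstrap CIs, ellipse overlap.

Principal components of the shape-variable covariance matrix define the
morphospace; Euclidean distances between species means on the leading PCs
(those exceeding a cumulative-variance threshold) quantify divergence, and
the distance of each species from the basal species measures the amount of
evolutionary shape change.  Uncertainty comes from bias-corrected and
accelerated (BCa) bootstrap intervals with specimen-level resampling, and
significance of a difference between two independent CIs follows the
"rule of eye" (significant when the intervals overlap by less than half the
average half-width).  Within-assemblage scatter on PC1/PC2 is summarized by
a 55% concentration ellipse, and morphological overlap between coexisting
species by the area proportion shared by their ellipses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import chi2
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .tps_shape import ShapeScores

__all__ = [
    "PCAResult",
    "ConcentrationEllipse",
    "pca_covariance",
    "select_pcs",
    "distance_between_means",
    "distance_from_basal",
    "bca_bootstrap_ci",
    "rule_of_eye",
    "concentration_ellipse",
    "ellipse_polygon",
    "ellipse_overlap",
]


@dataclass
class PCAResult:
    """Eigendecomposition of the column covariance of a score matrix."""

    eigenvalues: np.ndarray  # variances per PC, descending
    loadings: np.ndarray  # (p, m) orthonormal axes
    scores: np.ndarray  # (n, m) centered data projected on axes
    proportion_variance: np.ndarray  # per-PC fractions

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def _as_matrix(scores) -> np.ndarray:
    if isinstance(scores, ShapeScores):
        return scores.matrix
    return np.asarray(scores, float)


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pca_covariance(scores) -> PCAResult:
    """PCA on the covariance matrix (not correlations, preserving the
    special scaling of the shape variables).

    Euclidean distances among specimens are preserved when all PCs are kept.
    """
    x = _as_matrix(scores)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = _fix_sign(vt.T)
    scores_out = centered @ loadings
    total = eigvals.sum()
    prop = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAResult(
        eigenvalues=eigvals,
        loadings=loadings,
        scores=scores_out,
        proportion_variance=prop,
    )


def select_pcs(pca: PCAResult, threshold: float = 0.95) -> int:
    """Smallest number of leading PCs whose cumulative variance exceeds *threshold*."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(pca.proportion_variance)
    if threshold == 1.0:
        return int(np.sum(pca.eigenvalues > 1e-12 * max(pca.eigenvalues.max(), 1e-300)))
    k = int(np.searchsorted(cum, threshold, side="right")) + 1
    return min(k, pca.n_components)


def _group_mean(scores: np.ndarray, labels: np.ndarray, group, n_pcs: int) -> np.ndarray:
    mask = labels == group
    if not np.any(mask):
        raise ValueError(f"unknown group label {group!r}")
    return scores[mask, :n_pcs].mean(axis=0)


def distance_between_means(scores, labels, group_a, group_b, n_pcs: int) -> float:
    """Euclidean distance between two group mean score vectors on the first n_pcs PCs."""
    x = _as_matrix(scores)
    labels = np.asarray(labels)
    ma = _group_mean(x, labels, group_a, n_pcs)
    mb = _group_mean(x, labels, group_b, n_pcs)
    return float(np.linalg.norm(ma - mb))


def distance_from_basal(
    scores,
    labels,
    basal_group,
    n_pcs: int,
    reference_group,
) -> pd.DataFrame:
    """Distance of every group mean from the basal group mean.

    percent_change rescales distances so the basal group is 0% and the
    reference (most derived) group is 100%.
    """
    x = _as_matrix(scores)
    labels = np.asarray(labels)
    basal = _group_mean(x, labels, basal_group, n_pcs)
    ref_dist = float(np.linalg.norm(_group_mean(x, labels, reference_group, n_pcs) - basal))
    if ref_dist == 0:
        raise ValueError("reference group coincides with the basal mean; cannot anchor 100%")
    rows = []
    for g in pd.unique(labels):
        d = float(np.linalg.norm(_group_mean(x, labels, g, n_pcs) - basal))
        rows.append({"group": g, "distance": d, "percent_change": 100.0 * d / ref_dist})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def bca_bootstrap_ci(
    data,
    statistic,
    n_boot: int = 9999,
    level: float = 0.95,
    seed=None,
    vectorized: bool = False,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    *data* is one sample (array) or a tuple of samples; resampling is
    stratified within each sample, and *statistic* receives the resampled
    samples as positional arguments.  The bias correction z0 comes from the
    bootstrap fraction below the observed statistic; the acceleration from
    jackknife skewness with leave-one-out within each stratum.  A degenerate
    bootstrap distribution yields a zero-width interval at the observed
    value (with a warning).

    When ``vectorized`` is true, the statistic must accept a stacked
    ``(n_boot, n)`` array per sample plus an ``axis`` keyword.
    """
    samples = data if isinstance(data, tuple) else (data,)
    samples = tuple(np.asarray(s) for s in samples)
    if any(s.shape[0] < 2 for s in samples):
        raise ValueError("each sample needs at least 2 observations")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable BCa intervals")
    rng = np.random.default_rng(seed)
    observed = float(statistic(*samples))

    if vectorized:
        resamples = tuple(
            s[rng.integers(0, s.shape[0], size=(n_boot, s.shape[0]))] for s in samples
        )
        boot = np.asarray(statistic(*resamples, axis=-1), float)
    else:
        boot = np.empty(n_boot)
        for b in range(n_boot):
            draw = tuple(s[rng.integers(0, s.shape[0], size=s.shape[0])] for s in samples)
            boot[b] = statistic(*draw)
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        raise ValueError("all bootstrap statistics were non-finite")
    if np.ptp(boot) == 0 and boot[0] == observed:
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
        return observed, observed

    frac_below = np.mean(boot < observed)
    frac_below = min(max(frac_below, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1.0))
    z0 = ndtri(frac_below)

    # jackknife acceleration, leave-one-out within each stratum
    jack = []
    for si, s in enumerate(samples):
        n = s.shape[0]
        for i in range(n):
            loo = tuple(
                np.delete(t, i, axis=0) if ti == si else t for ti, t in enumerate(samples)
            )
            jack.append(statistic(*loo))
    jack = np.asarray(jack, float)
    dev = jack.mean() - jack
    denom = 6.0 * (np.sum(dev**2) ** 1.5)
    a = float(np.sum(dev**3) / denom) if denom > 0 else 0.0

    alpha = 1.0 - level
    out = []
    for z_alpha in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        out.append(float(np.quantile(boot, np.clip(ndtr(adj), 0.0, 1.0))))
    low, high = min(out), max(out)
    return low, high


def rule_of_eye(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """Significance (p <= 0.05) of the difference between two independent 95% CIs.

    Significant when the intervals overlap by less than half the average of
    the two half-widths; non-overlapping intervals are always significant.
    """
    (a_lo, a_hi), (b_lo, b_hi) = sorted(ci_a), sorted(ci_b)
    overlap = min(a_hi, b_hi) - max(a_lo, b_lo)
    if overlap < 0:
        return True
    mean_half_width = ((a_hi - a_lo) / 2.0 + (b_hi - b_lo) / 2.0) / 2.0
    return overlap < 0.5 * mean_half_width


# ---------------------------------------------------------------------------
# Concentration ellipses and overlap areas
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationEllipse:
    """Ellipse containing a stated probability mass of a fitted bivariate normal."""

    center: np.ndarray  # (2,)
    axes: np.ndarray  # semi-axis lengths, (2,) major first
    orientation: float  # radians, direction of the major axis
    level: float = 0.55

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if np.any(np.asarray(self.axes) <= 0):
            raise ValueError("degenerate ellipse: semi-axes must be positive")


def concentration_ellipse(points: np.ndarray, level: float = 0.55) -> ConcentrationEllipse:
    """Concentration ellipse of 2D points at the given probability level.

    Centered on the mean, oriented along the sample-covariance eigenvectors,
    semi-axes sqrt(eigenvalue * q) with q the chi-square(2) quantile at
    *level* (q = -2 ln(1 - level); 1.59702 for the 55% ellipse).
    Collinear point sets raise a degenerate-ellipse error.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[1], 1e-300):
        raise ValueError("degenerate ellipse: points are (nearly) collinear")
    q = chi2.ppf(level, df=2)
    order = np.argsort(eigvals)[::-1]
    semi = np.sqrt(eigvals[order] * q)
    major = eigvecs[:, order[0]]
    return ConcentrationEllipse(
        center=pts.mean(axis=0),
        axes=semi,
        orientation=float(np.arctan2(major[1], major[0])),
        level=level,
    )


def ellipse_polygon(ellipse: ConcentrationEllipse, n_vertices: int = 720) -> Polygon:
    """Polygonal approximation of an ellipse (area error < 0.01% at 720 vertices)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    xy = np.column_stack([ellipse.axes[0] * np.cos(t), ellipse.axes[1] * np.sin(t)])
    c, s = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    rot = np.array([[c, -s], [s, c]])
    return Polygon(xy @ rot.T + ellipse.center)


def ellipse_overlap(ellipses, n_vertices: int = 720) -> float:
    """Proportion of morphospace area shared by two or three ellipses.

    For a pair: intersection area / union area.  For a triple: area of the
    pairwise-overlapping region(s) / area of the union of all three -- the
    share of the total area occupied by the species that is held by more
    than one of them.
    """
    ellipses = list(ellipses)
    if len(ellipses) not in (2, 3):
        raise ValueError("overlap is defined for 2 or 3 ellipses")
    polys = [ellipse_polygon(e, n_vertices) for e in ellipses]
    union = unary_union(polys)
    if union.area == 0:
        raise ValueError("degenerate ellipses")
    if len(polys) == 2:
        inter = polys[0].intersection(polys[1])
        return float(inter.area / union.area)
    pair_inters = [
        polys[i].intersection(polys[j]) for i in range(3) for j in range(i + 1, 3)
    ]
    shared = unary_union(pair_inters)
    return float(shared.area / union.area)
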