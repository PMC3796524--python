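"""Generalized Procrustes superimposition and semilandmark sliding.

Configurations are centered, scaled to unit centroid size, and iteratively
rotated onto an evolving consensus until the summed squared residuals
stabilize.  Superimposed shapes are orthogonally projected onto the plane
tangent to shape space at the consensus, where Euclidean statistics apply.

Semilandmarks are slid along the chord through their outline neighbors,
either to minimize the thin-plate-spline bending energy of the deformation
from the consensus (default) or to minimize Procrustes distance; slid
points are projected back onto the specimen's piecewise-linear outline, and
the slide/GPA cycle repeats until the consensus stabilizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes

from .geometry_io import LandmarkConfiguration, LandmarkScheme

__all__ = [
    "ProcrustesResult",
    "SlidingSpec",
    "centroid_size",
    "center_and_scale",
    "orthogonal_align",
    "gpa",
    "full_procrustes_distance",
    "slide_semilandmarks",
    "slide_gpa",
    "procrustes_correlation",
]


def centroid_size(points: np.ndarray | LandmarkConfiguration) -> float:
    """Square root of summed squared distances of landmarks from their centroid.

    The size measure removed by superimposition; invariant to rotation and
    translation, homogeneous of degree one under scaling.
    """
    pts = points.points if isinstance(points, LandmarkConfiguration) else np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return cs


def center_and_scale(points: np.ndarray) -> np.ndarray:
    """Translate centroid to the origin and scale to unit centroid size."""
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    return centered / centroid_size(pts)


def orthogonal_align(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation of *moving* minimizing summed squared differences to *target*.

    Both configurations must be centered.  Reflections are never permitted
    (the rotation has determinant +1), so chirality is preserved; antimeres
    must be mirrored upstream.

    Returns ``(rotation, aligned)`` with ``aligned = moving @ rotation``.
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape:
        raise ValueError(f"point-count mismatch: {moving.shape} vs {target.shape}")
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, d]) @ vt
    return rot, moving @ rot


@dataclass
class ProcrustesResult:
    """Output of generalized Procrustes analysis.

    ``aligned`` holds unit-centroid-size configurations in a common
    orientation, ``mean_shape`` the unit-size consensus, ``tangent_coords``
    the flattened (x1,y1,...,xk,yk) orthogonal tangent-plane projections,
    and ``procrustes_distances`` each specimen's distance to the consensus.
    """

    aligned: np.ndarray  # (n, k, 2)
    mean_shape: np.ndarray  # (k, 2)
    tangent_coords: np.ndarray  # (n, 2k)
    procrustes_distances: np.ndarray  # (n,)
    iterations: int
    converged: bool
    specimen_ids: list[str] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_points(self) -> int:
        return self.aligned.shape[1]


@dataclass(frozen=True)
class SlidingSpec:
    """Controls for semilandmark sliding.

    criterion: 'bending_energy' (thin-plate-spline form, default) or
    'procrustes_distance' (identity form: tangential deviation from the
    consensus is removed).  The outer loop (slide -> re-GPA -> new tangents)
    runs until the consensus moves less than *tolerance* or
    *max_outer_iterations* is reached.  Slides are bounded to half the
    distance to the nearer neighbor per iteration to prevent point crossing.
    """

    criterion: str = "bending_energy"
    max_outer_iterations: int = 5
    tolerance: float = 1e-8
    project_to_outline: bool = True

    def __post_init__(self):
        if self.criterion not in ("bending_energy", "procrustes_distance"):
            raise ValueError(f"unknown sliding criterion {self.criterion!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _as_point_arrays(dataset) -> tuple[np.ndarray, list[str]]:
    pts, ids = [], []
    for i, item in enumerate(dataset):
        if isinstance(item, LandmarkConfiguration):
            pts.append(item.points)
            ids.append(item.specimen_id)
        else:
            pts.append(np.asarray(item, float))
            ids.append(f"specimen_{i}")
    arr = np.asarray(pts, float)
    if arr.ndim != 3:
        raise ValueError("dataset configurations must share one landmark scheme")
    return arr, ids


def gpa(
    dataset,
    tol: float = 1e-10,
    max_iter: int = 100,
    scheme: LandmarkScheme | None = None,
) -> ProcrustesResult:
    """Generalized Procrustes analysis of a set of configurations.

    Each configuration is scaled to unit centroid size and rotated to
    minimize its summed squared difference from the consensus; the consensus
    is the normalized mean of the aligned set and is re-estimated until the
    change in summed squared residuals falls below *tol*.  When a *scheme*
    is given, the final consensus is rotated so that its longitudinal axis
    chord (axis_points) lies along +x, making axes and loadings reproducible
    across runs.

    Non-convergence within *max_iter* is flagged on the result, not raised.
    """
    arr, ids = _as_point_arrays(dataset)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least two configurations")
    aligned = np.stack([center_and_scale(p) for p in arr])
    # initial target: first specimen, then iterate to consensus
    target = aligned[0]
    for i in range(n):
        _, aligned[i] = orthogonal_align(aligned[i], target)
    prev_ss = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        consensus = aligned.mean(axis=0)
        consensus = consensus / np.linalg.norm(consensus)
        for i in range(n):
            _, aligned[i] = orthogonal_align(aligned[i], consensus)
        ss = float(np.sum((aligned - consensus) ** 2))
        if abs(prev_ss - ss) < tol:
            converged = True
            break
        prev_ss = ss
    consensus = aligned.mean(axis=0)
    consensus = consensus / np.linalg.norm(consensus)
    if scheme is not None:
        a, b = scheme.axis0
        chord = consensus[b] - consensus[a]
        ang = np.arctan2(chord[1], chord[0])
        c, s = np.cos(-ang), np.sin(-ang)
        rot = np.array([[c, -s], [s, c]]).T
        consensus = consensus @ rot
        aligned = aligned @ rot
    tangent = _tangent_projection(aligned, consensus)
    dists = np.linalg.norm(tangent, axis=1)
    return ProcrustesResult(
        aligned=aligned,
        mean_shape=consensus,
        tangent_coords=tangent,
        procrustes_distances=dists,
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
    )


def _tangent_projection(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned pre-shapes onto the tangent plane.

    With the consensus as unit tangent point, each flattened specimen z maps
    to z - (z . mu) mu; Euclidean distances between rows equal Procrustes
    distances to first order near the mean.
    """
    mu = consensus.reshape(-1)
    mu = mu / np.linalg.norm(mu)
    z = aligned.reshape(aligned.shape[0], -1)
    return z - np.outer(z @ mu, mu)


def project_to_tangent(result: ProcrustesResult) -> np.ndarray:
    """Tangent-space coordinate matrix (rows = specimens) of a GPA result."""
    return _tangent_projection(result.aligned, result.mean_shape)


def full_procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Centers and scales both to unit norm, optimizes rotation (proper only)
    and scale, and returns sin(rho) where rho is the Procrustes angle.
    Serves as the direct pairwise oracle for tangent-space distances.
    """
    x = center_and_scale(np.asarray(a, float))
    y = center_and_scale(np.asarray(b, float))
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    d = np.linalg.det(x.T @ y)
    total = s[0] + np.sign(d) * s[1]
    return float(np.sqrt(max(0.0, 1.0 - total**2)))


# ---------------------------------------------------------------------------
# Semilandmark sliding
# ---------------------------------------------------------------------------

def _slide_directions(points: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Unit tangent direction at each sliding point: the neighbor chord."""
    dirs = np.zeros((len(scheme.sliding_indices), 2))
    for j, s in enumerate(scheme.sliding_indices):
        a, b = scheme.neighbors0(s)
        chord = points[b] - points[a]
        norm = np.linalg.norm(chord)
        if norm == 0:
            raise ValueError(f"degenerate neighbor chord at sliding landmark {s}")
        dirs[j] = chord / norm
    return dirs


def solve_slides(
    points: np.ndarray,
    reference: np.ndarray,
    energy: np.ndarray,
    sliding0: np.ndarray,
    directions: np.ndarray,
    ridge: float = 1e-12,
) -> np.ndarray:
    """Slide amounts minimizing the quadratic deformation energy.

    Minimizes E(t) = tr((D + sum_j t_j e_j u_j^T)^T L (D + ...)) where
    D = points - reference, L is the k x k energy matrix (bending energy, or
    identity for the Procrustes-distance criterion) applied to x and y
    displacements separately, and u_j the unit slide direction of sliding
    landmark j.  A ridge proportional to *ridge* times the largest diagonal
    entry stabilizes near-singular systems (a warning is emitted).
    """
    d0 = points - reference
    m = len(sliding0)
    # A_ij = (u_i . u_j) * L[p_i, p_j];  b_i = u_i . (L @ D0)[p_i]
    sub = energy[np.ix_(sliding0, sliding0)]
    a_mat = (directions @ directions.T) * sub
    ld0 = energy @ d0
    b_vec = np.einsum("jd,jd->j", directions, ld0[sliding0])
    scale = max(np.abs(np.diag(a_mat)).max(), 1e-300)
    try:
        cond_bad = np.linalg.cond(a_mat) > 1.0 / max(ridge, 1e-15)
    except np.linalg.LinAlgError:
        cond_bad = True
    if cond_bad:
        warnings.warn("near-singular slide system; applying ridge stabilization")
        a_mat = a_mat + np.eye(m) * ridge * scale
    t = np.linalg.solve(a_mat, -b_vec)
    return t


def _project_to_outline(point: np.ndarray, anchor: np.ndarray, nb_a: np.ndarray, nb_b: np.ndarray) -> np.ndarray:
    """Nearest point on the two outline segments adjacent to *anchor*."""
    best, best_d = None, np.inf
    for seg_start, seg_end in ((nb_a, anchor), (anchor, nb_b)):
        seg = seg_end - seg_start
        denom = float(seg @ seg)
        u = 0.0 if denom == 0 else float(np.clip((point - seg_start) @ seg / denom, 0.0, 1.0))
        cand = seg_start + u * seg
        d = float(np.linalg.norm(point - cand))
        if d < best_d:
            best, best_d = cand, d
    return best


def bending_energy_of(displacement: np.ndarray, energy: np.ndarray) -> float:
    """Quadratic energy of a (k, 2) displacement field under a k x k form."""
    return float(np.einsum("id,ij,jd->", displacement, energy, displacement))


def slide_semilandmarks(
    aligned: np.ndarray,
    reference: np.ndarray,
    scheme: LandmarkScheme,
    energy: np.ndarray,
    spec: SlidingSpec | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One sliding pass of every specimen against the current consensus.

    Returns the updated (k, 2) configurations and a diagnostics table
    (specimen index, RMS slide, energy before/after the unconstrained slide,
    i.e. prior to outline re-projection).
    """
    spec = spec or SlidingSpec()
    sliding0 = scheme.sliding0
    out = aligned.copy()
    rows = []
    eye = np.eye(scheme.n_points)
    form = energy if spec.criterion == "bending_energy" else eye
    for i, pts in enumerate(aligned):
        dirs = _slide_directions(pts, scheme)
        t = solve_slides(pts, reference, form, sliding0, dirs)
        # bound slides to half the distance to the nearer neighbor
        new = pts.copy()
        be_before = bending_energy_of(pts - reference, form)
        for j, s in enumerate(scheme.sliding_indices):
            a0, b0 = scheme.neighbors0(s)
            p0 = sliding0[j]
            lim = 0.5 * min(np.linalg.norm(pts[p0] - pts[a0]), np.linalg.norm(pts[p0] - pts[b0]))
            tj = float(np.clip(t[j], -lim, lim))
            new[p0] = pts[p0] + tj * dirs[j]
        be_after = bending_energy_of(new - reference, form)
        if spec.project_to_outline:
            for j, s in enumerate(scheme.sliding_indices):
                a0, b0 = scheme.neighbors0(s)
                p0 = sliding0[j]
                new[p0] = _project_to_outline(new[p0], pts[p0], pts[a0], pts[b0])
        out[i] = new
        rows.append(
            {
                "specimen": i,
                "rms_slide": float(np.sqrt(np.mean(t**2))),
                "energy_before": be_before,
                "energy_after": be_after,
            }
        )
    return out, pd.DataFrame(rows)


def slide_gpa(
    dataset,
    scheme: LandmarkScheme,
    spec: SlidingSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[ProcrustesResult, pd.DataFrame]:
    """Iterated sliding + GPA until the consensus stabilizes.

    Runs GPA, builds the bending-energy form on the consensus, slides every
    specimen, re-runs GPA, and repeats for at most
    ``spec.max_outer_iterations`` or until the consensus moves less than
    ``spec.tolerance``.  Returns the final GPA result (on slid
    configurations) and the concatenated per-iteration diagnostics.
    """
    from .tps_shape import bending_energy_matrix  # local import to avoid a cycle

    spec = spec or SlidingSpec()
    result = gpa(dataset, tol=tol, max_iter=max_iter, scheme=scheme)
    ids = result.specimen_ids
    diagnostics = []
    for outer in range(1, spec.max_outer_iterations + 1):
        prev_mean = result.mean_shape
        if spec.criterion == "bending_energy":
            model = bending_energy_matrix(result.mean_shape)
            energy = model.be_matrix
        else:
            energy = np.eye(scheme.n_points)
        slid, diag = slide_semilandmarks(result.aligned, result.mean_shape, scheme, energy, spec)
        diag.insert(0, "outer_iteration", outer)
        diag["specimen_id"] = [ids[i] for i in diag["specimen"]]
        diagnostics.append(diag)
        result = gpa(list(slid), tol=tol, max_iter=max_iter, scheme=scheme)
        result.specimen_ids = ids
        shift = float(np.linalg.norm(result.mean_shape - prev_mean))
        if shift < spec.tolerance:
            break
    return result, pd.concat(diagnostics, ignore_index=True)


# ---------------------------------------------------------------------------
# PROTEST-style correlation between two score matrices
# ---------------------------------------------------------------------------

def _pad_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = max(a.shape[1], b.shape[1])
    if a.shape[1] < p:
        a = np.hstack([a, np.zeros((a.shape[0], p - a.shape[1]))])
    if b.shape[1] < p:
        b = np.hstack([b, np.zeros((b.shape[0], p - b.shape[1]))])
    return a, b


def procrustes_correlation(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Procrustes correlation of two matched score matrices with a permutation test.

    r = sqrt(1 - m^2) where m^2 is the symmetric Procrustes disparity after
    optimal translation/rotation/scaling of B onto A.  The p-value permutes
    the rows of B: p = (1 + #{permuted r >= observed}) / (n_perm + 1), so p
    is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("score matrices must have matching rows (specimens)")
    a, b = _pad_columns(a, b)

    def _r(bb):
        _, _, m2 = _scipy_procrustes(a, bb)
        return float(np.sqrt(max(0.0, 1.0 - m2)))

    observed = _r(b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(b.shape[0])
        if _r(b[perm]) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return observed, p
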