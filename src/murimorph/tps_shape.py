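"""Thin-plate-spline shape variables: bending energy, partial warps, uniform term.

The thin-plate spline interpolates a deformation of the reference (consensus)
configuration; its bending energy is a quadratic form that is zero exactly on
affine deformations.  Eigenvectors of the bending-energy matrix with nonzero
eigenvalue are the principal warps; projecting tangent-space residuals onto
them (an x- and a y-score per warp) gives the partial-warp scores, and the
two-dimensional affine remainder within the tangent space is the linearized
uniform component.  With weight exponent alpha = 0 the combined score matrix
is an orthonormal rotation of the tangent coordinates, so all downstream
distance-based statistics are identical to those on tangent coordinates --
the property the analysis relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .gpa import ProcrustesResult

__all__ = [
    "BendingEnergyModel",
    "ShapeScores",
    "tps_kernel",
    "bending_energy_matrix",
    "shape_variables",
]

#: eigenvalues below this fraction of the largest are treated as affine (zero)
_ZERO_EIG_REL = 1e-10


def tps_kernel(r):
    """2D thin-plate-spline radial kernel U(r) = r^2 log(r^2), with U(0) = 0."""
    scalar = np.isscalar(r) or np.ndim(r) == 0
    arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(arr < 0):
        raise ValueError("kernel argument must be nonnegative")
    out = np.zeros_like(arr)
    nz = arr > 0
    out[nz] = arr[nz] ** 2 * np.log(arr[nz] ** 2)
    return float(out[0]) if scalar else out


@dataclass
class BendingEnergyModel:
    """Bending-energy matrix and principal-warp basis for a reference shape.

    ``be_matrix`` is the upper-left k x k block of the inverted augmented TPS
    system; it is symmetric positive semidefinite with exactly three zero
    eigenvalues (the 2D affine kernel) for k >= 4 points in general position.
    ``principal_warps`` columns are eigenvectors ordered by ascending
    eigenvalue; the first three span the affine null space.
    """

    reference: np.ndarray  # (k, 2)
    kernel_matrix: np.ndarray  # (k, k)
    be_matrix: np.ndarray  # (k, k)
    principal_warps: np.ndarray  # (k, k) eigenvectors, ascending eigenvalue
    eigenvalues: np.ndarray  # (k,)
    alpha: float = 0.0

    @property
    def nonzero_warps(self) -> np.ndarray:
        """Eigenvectors with positive bending energy, (k, k-3)."""
        thresh = _ZERO_EIG_REL * self.eigenvalues.max()
        return self.principal_warps[:, self.eigenvalues > thresh]

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        thresh = _ZERO_EIG_REL * self.eigenvalues.max()
        return self.eigenvalues[self.eigenvalues > thresh]


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Largest-magnitude component positive, for run-to-run reproducibility."""
    out = vectors.copy()
    idx = np.argmax(np.abs(out), axis=0)
    signs = np.sign(out[idx, np.arange(out.shape[1])])
    signs[signs == 0] = 1.0
    return out * signs


def bending_energy_matrix(reference: np.ndarray, alpha: float = 0.0) -> BendingEnergyModel:
    """Build the TPS bending-energy model for a reference configuration.

    Raises on collinear references, where the augmented system is singular.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    if k < 4:
        raise ValueError("bending energy needs at least 4 points")
    r = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    kernel = tps_kernel(r)
    q = np.hstack([np.ones((k, 1)), ref])
    l_mat = np.zeros((k + 3, k + 3))
    l_mat[:k, :k] = kernel
    l_mat[:k, k:] = q
    l_mat[k:, :k] = q.T
    # collinearity check: affine part must have rank 3
    if np.linalg.matrix_rank(q) < 3:
        raise ValueError("collinear reference configuration: TPS system is singular")
    try:
        l_inv = np.linalg.inv(l_mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system for reference configuration") from exc
    be = l_inv[:k, :k]
    be = 0.5 * (be + be.T)
    eigvals, eigvecs = np.linalg.eigh(be)
    eigvals = np.clip(eigvals, 0.0, None)
    eigvecs = _fix_sign(eigvecs)
    return BendingEnergyModel(
        reference=ref,
        kernel_matrix=kernel,
        be_matrix=be,
        principal_warps=eigvecs,
        eigenvalues=eigvals,
        alpha=alpha,
    )


@dataclass
class ShapeScores:
    """Specimens x (partial-warp ++ uniform) shape-variable matrix.

    With alpha = 0, Euclidean distances between rows equal tangent-space
    distances; the columns are labelled PW<j>X/PW<j>Y for the non-uniform
    warps and Uni1/Uni2 for the uniform component.
    """

    matrix: np.ndarray
    column_labels: list[str]

    @property
    def n_specimens(self) -> int:
        return self.matrix.shape[0]


def _interleave(warp: np.ndarray, axis: int, k: int) -> np.ndarray:
    """Embed a k-vector as a flattened (x1,y1,..) displacement on one axis."""
    v = np.zeros(2 * k)
    v[axis::2] = warp
    return v


def shape_variables(
    result: ProcrustesResult,
    model: BendingEnergyModel,
    alpha: float = 0.0,
) -> ShapeScores:
    """Partial-warp scores plus the uniform component from a GPA result.

    Non-uniform scores are projections of the tangent residuals onto each
    principal warp (one x- and one y-score per warp), scaled by
    lambda^(-alpha/2); the uniform scores are projections onto the
    orthonormal basis of the affine complement of the non-uniform subspace
    within the tangent space.  The analysis uses alpha = 0 throughout;
    other values are permitted but flagged, because only alpha = 0 keeps the
    score matrix an isometry of tangent space.
    """
    if alpha != 0.0:
        warnings.warn("alpha != 0 departs from the distance-preserving convention")
    k = model.reference.shape[0]
    warps = model.nonzero_warps  # (k, k-3), ascending bending energy
    lams = model.nonzero_eigenvalues
    tangent = result.tangent_coords  # (n, 2k)

    basis_cols, labels = [], []
    for j in range(warps.shape[1]):
        basis_cols.append(_interleave(warps[:, j], 0, k))
        basis_cols.append(_interleave(warps[:, j], 1, k))
        labels += [f"PW{j + 1}X", f"PW{j + 1}Y"]
    nonuni = np.column_stack(basis_cols)  # (2k, 2(k-3)), orthonormal

    # tangent space: orthogonal complement of translations, scaling (mean
    # direction) and rotation at the mean
    mu = model.reference.reshape(-1)
    mu = mu / np.linalg.norm(mu)
    rot = np.empty_like(mu)
    rot[0::2] = -mu[1::2]
    rot[1::2] = mu[0::2]
    tx = np.zeros_like(mu)
    tx[0::2] = 1.0
    ty = np.zeros_like(mu)
    ty[1::2] = 1.0
    constraints = np.column_stack([tx, ty, mu, rot])
    t_basis = null_space(constraints.T)  # (2k, 2k-4)

    resid = t_basis - nonuni @ (nonuni.T @ t_basis)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    uni = _fix_sign(u[:, :2])
    labels += ["Uni1", "Uni2"]

    scale = np.repeat(lams, 2) ** (-alpha / 2.0) if alpha != 0.0 else 1.0
    scores = np.hstack([(tangent @ nonuni) * scale, tangent @ uni])
    return ShapeScores(matrix=scores, column_labels=labels)
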