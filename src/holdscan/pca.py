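"""Rigid-body superposition, RMSD/RMSF, and Calpha-covariance PCA.

Prior to any fluctuation analysis each frame is least-squares fitted
(Kabsch) to a reference so that rotational and translational degrees of
freedom of the simulation box are removed.  The 3N x 3N positional covariance
matrix

    C_ij = < (X_i - <X_i>) (X_j - <X_j>) >

is then diagonalized; eigenvectors are directions of collective motion and
eigenvalues their magnitudes (A^2).  The projections onto the top two
components feed the free-energy landscape in :mod:`holdscan.landscape`.

Because the "average coordinates" reference is itself defined by the fit, the
mean is obtained by a short fixed-point iteration (fit to the running mean,
recompute the mean, twice) which converges to well below coordinate noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .traj import Trajectory

__all__ = [
    "PCAModel",
    "kabsch_superpose",
    "apply_transform",
    "superposed_coords",
    "rmsd_series",
    "rmsf",
    "fit_pca",
    "project",
    "variance_explained",
    "subspace_overlap",
]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``reference``.
    The rotation is proper (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be N x 3 with equal N")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 atoms, got {n}")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # Collinear (rank < 2) point sets leave the rotation underdetermined.
    if min(np.linalg.matrix_rank(mob_c, tol=1e-8),
           np.linalg.matrix_rank(ref_c, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) coordinates: rotation is underdetermined")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = reference.mean(axis=0) - mobile.mean(axis=0) @ R.T
    rmsd = rssd / np.sqrt(n)
    return R, t, float(rmsd)


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def _fit_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame (F x N x 3) onto a reference (N x 3)."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[f], reference)
        out[f] = apply_transform(coords[f], R, t)
    return out


def _mean_structure(coords: np.ndarray, n_iter: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively fitted mean structure and the fitted frames."""
    mean = coords[0]
    fitted = coords
    for _ in range(n_iter):
        fitted = _fit_frames(coords, mean)
        mean = fitted.mean(axis=0)
    return mean, fitted


def superposed_coords(traj: Trajectory, sel, reference: np.ndarray | None = None):
    """Selected-atom coordinates of every frame after superposition.

    If ``reference`` is None the iterated mean structure is used.
    """
    idx = traj.select(sel) if isinstance(sel, str) else np.asarray(sel)
    sub = traj.coords[:, idx, :]
    if reference is None:
        _, fitted = _mean_structure(sub)
        return fitted, idx
    return _fit_frames(sub, reference), idx


def rmsd_series(traj: Trajectory, sel, reference_frame: int = 0) -> np.ndarray:
    """Per-frame Calpha (or any selection) RMSD to a reference frame, after fit."""
    idx = traj.select(sel) if isinstance(sel, str) else np.asarray(sel)
    if idx.size == 0:
        raise ValueError("empty selection for RMSD")
    ref = traj.coords[reference_frame, idx, :]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.coords[f, idx, :], ref)
    return out


def rmsf(traj: Trajectory, sel) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the fitted mean structure."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = traj.select(sel) if isinstance(sel, str) else np.asarray(sel)
    if idx.size == 0:
        raise ValueError("empty selection for RMSF")
    mean, fitted = _mean_structure(traj.coords[:, idx, :])
    dev = fitted - mean
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


@dataclass
class PCAModel:
    """Eigendecomposition of the positional covariance of a selection.

    ``eigenvectors`` has shape (n_modes, 3N), rows sorted by descending
    eigenvalue; each row is oriented so its largest-magnitude component is
    positive (projections are then deterministic; overlaps are sign-free).
    """

    mean_coords: np.ndarray        # N x 3
    eigenvalues: np.ndarray        # descending, A^2
    eigenvectors: np.ndarray       # n_modes x 3N, orthonormal rows
    n_atoms: int
    selection: str | None = None

    def __post_init__(self) -> None:
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(len(self.eigenvalues)), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")


def fit_pca(traj: Trajectory, sel) -> PCAModel:
    """PCA of the selected atoms' positional covariance after superposition."""
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    expr = sel if isinstance(sel, str) else None
    mean, fitted = _mean_structure(
        traj.coords[:, traj.select(sel) if isinstance(sel, str) else np.asarray(sel), :]
    )
    n_atoms = mean.shape[0]
    X = fitted.reshape(traj.n_frames, 3 * n_atoms)
    mu = X.mean(axis=0)
    dev = X - mu
    cov = dev.T @ dev / traj.n_frames  # population covariance (ensemble average)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are modes
    # deterministic sign: largest-magnitude component positive
    for row in evecs:
        peak = np.argmax(np.abs(row))
        if row[peak] < 0:
            row *= -1.0
    return PCAModel(
        mean_coords=mu.reshape(n_atoms, 3),
        eigenvalues=evals,
        eigenvectors=evecs,
        n_atoms=n_atoms,
        selection=expr,
    )


def project(traj: Trajectory, model: PCAModel, k: int = 2, sel=None) -> np.ndarray:
    """Project frames onto the top ``k`` principal components (F x k).

    Frames are superposed onto the model's mean structure first; the mean
    structure itself projects to the zero vector.
    """
    sel = sel if sel is not None else model.selection
    if sel is None:
        raise ValueError("a selection is required (none stored in the model)")
    fitted, _ = superposed_coords(traj, sel, reference=model.mean_coords)
    if fitted.shape[1] != model.n_atoms:
        raise ValueError("selection size does not match the PCA model")
    dev = fitted.reshape(traj.n_frames, -1) - model.mean_coords.ravel()
    return dev @ model.eigenvectors[:k].T


def variance_explained(model: PCAModel, k: int) -> float:
    """Fraction of total positional variance captured by the top k modes."""
    total = model.eigenvalues.sum()
    if total == 0:
        raise ValueError("degenerate model: zero total variance")
    return float(model.eigenvalues[:k].sum() / total)


def subspace_overlap(model_a: PCAModel, model_b: PCAModel, k: int = 10):
    """Absolute inner products of the top-k modes of two models.

    Returns ``(matrix, summary)`` where ``matrix[i, j] = |v_i . w_j|`` and
    ``summary`` is the mean of the diagonal — the per-rank agreement of the
    principal dynamic modes between two runs.
    """
    k = min(k, len(model_a.eigenvalues), len(model_b.eigenvalues))
    M = np.abs(model_a.eigenvectors[:k] @ model_b.eigenvectors[:k].T)
    return M, float(np.mean(np.diag(M)))
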