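"""Principal component analysis of Cα positional fluctuations.

Frames are first rigid-body aligned (iterative Kabsch fit onto a
converged mean structure) so the covariance captures internal thermal
fluctuation rather than global diffusion.  The principal modes are the
eigenvectors of the 3N×3N positional variance–covariance matrix over
the analysis selection (Cα atoms), sorted by descending eigenvalue
(Å²), with a deterministic sign convention.  Snapshot weights from aMD
reweighting can be supplied to both the mean and the covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .exceptions import ConvergenceError, ValidationError
from .geometry import kabsch_superpose
from .model_io import Structure, Trajectory, write_pdb

__all__ = [
    "PrincipalMode",
    "align_frames",
    "covariance_matrix",
    "principal_modes",
    "project",
    "write_mode_arrows_pdb",
]


@dataclass(frozen=True)
class PrincipalMode:
    """One principal mode: 1-based index, eigenvalue (Å²), unit 3N vector."""

    index: int
    eigenvalue: float
    vector: np.ndarray  # (3N,), unit norm
    mean_structure: np.ndarray  # (N, 3) analysis-selection mean coordinates


def align_frames(
    trajectory: Trajectory,
    fit_selection: np.ndarray,
    weights: Optional[np.ndarray] = None,
    frame_weights: Optional[np.ndarray] = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Superpose every frame onto an iteratively refined mean structure.

    Each iteration Kabsch-fits all frames (over ``fit_selection``, with
    optional per-atom ``weights``) onto the current mean, then updates
    the mean (optionally frame-weighted).  Converged when the RMS
    displacement of the mean between iterations is < ``tol`` Å.  The
    output orientation is anchored to the first frame's pose; the
    converged mean is unique up to that global rigid frame (covariances
    and mode spectra are frame-independent).

    Returns (aligned coords (T, N, 3), mean coords (N, 3), n_iterations).
    """
    if trajectory.n_frames < 2:
        raise ValidationError("alignment needs >= 2 frames")
    fit = np.asarray(fit_selection)
    coords = np.asarray(trajectory.coords, dtype=float)
    t_frames = coords.shape[0]
    fw = (
        np.full(t_frames, 1.0 / t_frames)
        if frame_weights is None
        else np.asarray(frame_weights, dtype=float) / np.sum(frame_weights)
    )
    mean = coords[0].copy()
    aligned = coords.copy()
    for it in range(1, max_iter + 1):
        for t in range(t_frames):
            tr, _ = kabsch_superpose(coords[t, fit], mean[fit], weights)
            aligned[t] = tr.apply(coords[t])
        new_mean = np.einsum("t,tij->ij", fw, aligned)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            return aligned, mean, it
    raise ConvergenceError(
        f"mean-structure alignment did not converge in {max_iter} iterations "
        f"(last RMS mean displacement {shift:.3e} Å > tol {tol:g})"
    )


def covariance_matrix(
    aligned_coords: np.ndarray,
    analysis_selection: np.ndarray,
    frame_weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Weighted 3N×3N positional covariance C = Σₜ wₜ (xₜ−x̄)(xₜ−x̄)ᵀ (Å²)."""
    idx = np.asarray(analysis_selection)
    if idx.size == 0:
        raise ValidationError("empty analysis selection")
    x = np.asarray(aligned_coords, dtype=float)[:, idx, :].reshape(len(aligned_coords), -1)
    t_frames = x.shape[0]
    w = (
        np.full(t_frames, 1.0 / t_frames)
        if frame_weights is None
        else np.asarray(frame_weights, dtype=float) / np.sum(frame_weights)
    )
    xbar = w @ x
    d = x - xbar
    cov = (d * w[:, None]).T @ d
    return 0.5 * (cov + cov.T)


def principal_modes(
    covariance: np.ndarray,
    k: int,
    mean_structure: Optional[np.ndarray] = None,
) -> list[PrincipalMode]:
    """Top-k eigenpairs of the covariance, deterministic sign convention.

    Modes are sorted by descending eigenvalue; each eigenvector is
    oriented so its largest-magnitude component is positive.  Tiny
    negative eigenvalues from finite arithmetic are clipped to zero.
    """
    cov = np.asarray(covariance, dtype=float)
    n3 = cov.shape[0]
    if cov.shape != (n3, n3) or not np.allclose(cov, cov.T, atol=1e-8):
        raise ValidationError("covariance must be a symmetric square matrix")
    if not 1 <= k <= n3:
        raise ValidationError(f"k must be in 1..{n3}, got {k}")
    evals, evecs = scipy.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    if mean_structure is None:
        mean_structure = np.zeros((n3 // 3, 3))
    modes = []
    for rank, j in enumerate(order, start=1):
        vec = evecs[:, j]
        pivot = np.argmax(np.abs(vec))
        if vec[pivot] < 0:
            vec = -vec
        modes.append(
            PrincipalMode(rank, max(float(evals[j]), 0.0), vec, np.asarray(mean_structure))
        )
    return modes


def project(
    aligned_coords: np.ndarray,
    analysis_selection: np.ndarray,
    mean_structure: np.ndarray,
    mode: PrincipalMode,
) -> np.ndarray:
    """Per-frame projection (Å) of the displacement from the mean onto a mode."""
    idx = np.asarray(analysis_selection)
    x = np.asarray(aligned_coords, dtype=float)[:, idx, :].reshape(len(aligned_coords), -1)
    d = x - np.asarray(mean_structure, dtype=float).ravel()
    if d.shape[1] != mode.vector.shape[0]:
        raise ValidationError("mode dimensionality does not match the selection")
    return d @ mode.vector


def write_mode_arrows_pdb(
    path,
    trajectory: Trajectory,
    analysis_selection: np.ndarray,
    mean_structure: np.ndarray,
    mode: PrincipalMode,
) -> None:
    """Viewer file: mean structure plus a second MODEL displaced by +√λ·v.

    The √eigenvalue scaling is for visualization only; the data model
    keeps raw unit vectors.
    """
    idx = np.asarray(analysis_selection)
    sub = Structure(
        trajectory.topology.subset(idx), np.asarray(mean_structure, dtype=float)
    )
    disp = np.sqrt(mode.eigenvalue) * mode.vector.reshape(-1, 3)
    coords = np.stack([sub.coord, sub.coord + disp])
    write_pdb(path, Trajectory(sub.topology, coords, times=np.array([0.0, 1.0])))
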