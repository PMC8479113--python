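"""Essential dynamics: PCA of Calpha coordinates and subspace comparison.

The coordinate covariance (3n x 3n, mass-unweighted, after iterative
mean-structure alignment) is eigendecomposed; the top eigenvectors are the
dominant collective motions, per-frame projections quantify their sampling,
and porcupine vectors visualize a mode as per-atom arrows.  Two systems are
compared through the matrix of absolute eigenvector dot products, the
root-mean-square inner product (RMSIP) of their top-k subspaces, and the
average maximum dot product.  "Subspace overlap" is reported as RMSIP x 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .align import align_to_mean
from .errors import ParameterError, StructureError
from .trajio import Trajectory


@dataclass
class EssentialModes:
    mean_structure: np.ndarray    # (n, 3)
    eigenvectors: np.ndarray      # (3n, n_modes), columns orthonormal, descending
    eigenvalues: np.ndarray       # (n_modes,), Angstrom^2, descending, >= 0
    projections: np.ndarray       # (frames, n_modes)
    atom_map: np.ndarray          # mode row blocks -> atom indices

    @property
    def n_atoms(self) -> int:
        return self.mean_structure.shape[0]


def fit_pca(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    align_first: bool = True,
    n_modes: int | None = None,
) -> EssentialModes:
    """Eigendecomposition of the 3n x 3n coordinate covariance.

    Projections are (frame - mean) . eigenvector.  If more modes are
    requested than the covariance rank supports they are truncated with a
    warning.
    """
    if traj.n_frames < 2:
        raise ParameterError("PCA needs at least 2 frames")
    if mask is None:
        idx = np.arange(traj.n_atoms)
    else:
        m = np.asarray(mask)
        idx = np.flatnonzero(m) if m.dtype == bool else m.astype(int)
    coords = traj.coordinates[:, idx]
    if align_first:
        coords = align_to_mean(coords)
    n_frames, n, _ = coords.shape
    mean = coords.mean(axis=0)
    x = (coords - mean).reshape(n_frames, 3 * n)
    cov = x.T @ x / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_modes is not None:
        rank = min(3 * n, n_frames - 1)
        if n_modes > rank:
            warnings.warn(
                f"requested {n_modes} modes exceeds covariance rank {rank}; truncated"
            )
            n_modes = rank
        evals = evals[:n_modes]
        evecs = evecs[:, :n_modes]
    projections = x @ evecs
    return EssentialModes(
        mean_structure=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        projections=projections,
        atom_map=idx,
    )


@dataclass
class SubspaceComparison:
    dot_product_matrix: np.ndarray  # (k, k) of |v_i . w_j|
    rmsip: float
    average_max_dot: float
    k: int

    @property
    def subspace_overlap_percent(self) -> float:
        """RMSIP expressed as a percentage."""
        return 100.0 * self.rmsip


def compare_subspaces(a: EssentialModes, b: EssentialModes, k: int = 10) -> SubspaceComparison:
    """Top-k eigenvector dot-product matrix, RMSIP and average max dot.

    rmsip = sqrt( (1/k) sum_i sum_j (v_i . w_j)^2 ); symmetric in (a, b).
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise StructureError("eigenvector dimensions differ (mask mismatch?)")
    k = min(k, a.eigenvectors.shape[1], b.eigenvectors.shape[1])
    va = a.eigenvectors[:, :k]
    vb = b.eigenvectors[:, :k]
    dots = va.T @ vb
    rmsip = float(np.sqrt(np.sum(dots**2) / k))
    adots = np.abs(dots)
    return SubspaceComparison(
        dot_product_matrix=adots,
        rmsip=rmsip,
        average_max_dot=float(adots.max(axis=1).mean()),
        k=k,
    )


def porcupine(modes: EssentialModes, mode_index: int = 0, scale: float = 1.0) -> np.ndarray:
    """Per-atom displacement arrows for one mode: eigvec * scale * sqrt(eigval)."""
    if mode_index >= modes.eigenvectors.shape[1]:
        raise ParameterError(f"mode {mode_index} does not exist")
    vec = modes.eigenvectors[:, mode_index].reshape(-1, 3)
    return vec * scale * np.sqrt(modes.eigenvalues[mode_index])


def combined_pca(
    trajs: list[Trajectory],
    mask: np.ndarray | None = None,
    align_first: bool = True,
) -> EssentialModes:
    """PCA of several trajectories concatenated into one shared subspace."""
    if not trajs:
        raise ParameterError("need at least one trajectory")
    base = trajs[0]
    coords = np.concatenate([t.coordinates for t in trajs], axis=0)
    merged = Trajectory(topology=base.topology, coordinates=coords)
    return fit_pca(merged, mask=mask, align_first=align_first)
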