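"""Rigid-body superposition and mobility metrics.

Conventional RMSD superposes every frame on a reference over a mask;
``core_align`` instead iteratively restricts the superposition to the
fraction of atoms displaying the smallest mean displacements, separating a
rigid core from mobile regions (fraction-based robust alignment in the
MDLovoFit tradition).  RMSF and radius of gyration complete the standard
mobility toolkit.  All analyses default to mass-unweighted Calpha use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .trajio import Trajectory


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the masked RMSD.  The
    rotation is proper (det = +1).  Requires >= 3 non-collinear masked atoms.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        idx = np.flatnonzero(mask)
    else:
        idx = np.asarray(mask, int)
    if idx.size < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    x = mobile[idx]
    y = reference[idx]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # collinearity check: rank of the centered coordinates
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise GeometryError("masked atoms are collinear")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = y.mean(axis=0) - x.mean(axis=0) @ rot.T
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose_trajectory(
    traj_coords: np.ndarray,
    reference: np.ndarray,
    fit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame on ``reference`` using ``fit_mask`` atoms."""
    out = np.empty_like(traj_coords)
    for k, frame in enumerate(traj_coords):
        rot, trans, _ = kabsch_superpose(frame, reference, fit_mask)
        out[k] = frame @ rot.T + trans
    return out


def conventional_rmsd(
    traj: Trajectory,
    reference_frame: int = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD after superposing each frame on the reference over ``mask``."""
    coords = traj.coordinates
    if mask is None:
        mask = np.ones(traj.n_atoms, dtype=bool)
    idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask, int)
    ref = coords[reference_frame]
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(coords):
        _, _, out[k] = kabsch_superpose(frame, ref, idx)
    return out


@dataclass
class AlignmentResult:
    """Outcome of fraction-based core alignment."""

    fraction: float
    core_mask: np.ndarray         # boolean over masked atoms
    core_rmsd: np.ndarray         # per frame, Angstrom
    noncore_rmsd: np.ndarray      # per frame, Angstrom (NaN if core = all)
    rotations: np.ndarray         # (frames, 3, 3)
    translations: np.ndarray      # (frames, 3)
    iterations: int
    converged: bool


def core_align(
    traj: Trajectory,
    fraction: float,
    mask: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    reference_frame: int = 0,
) -> AlignmentResult:
    """Iteratively align on the ``fraction`` of atoms with smallest displacement.

    Each iteration superposes all frames on the reference over the current
    core, ranks atoms by mean displacement from the trajectory-average
    structure (ties broken by atom index), and re-selects the core as the
    ``fraction`` with the smallest displacement.  Stops when the core set is
    unchanged or the mean core RMSD moves by less than ``tol`` Angstrom.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must be in (0, 1]")
    coords = traj.coordinates
    if mask is None:
        mask = np.ones(traj.n_atoms, dtype=bool)
    sub = coords[:, np.flatnonzero(np.asarray(mask))]
    n = sub.shape[1]
    n_core = max(3, int(round(fraction * n)))

    core = np.arange(n)  # start from all atoms
    converged = False
    iterations = 0
    ref = sub[reference_frame]
    for iterations in range(1, max_iter + 1):
        aligned = superpose_trajectory(sub, ref, core)
        cur_rmsd = float(np.mean(np.sqrt(np.mean(
            np.sum((aligned[:, core] - ref[core]) ** 2, axis=2), axis=1))))
        mean_structure = aligned.mean(axis=0)
        disp = np.linalg.norm(aligned - mean_structure, axis=2).mean(axis=0)
        # stable ranking; ties broken by atom index via stable mergesort
        order = np.argsort(disp, kind="stable")
        new_core = np.sort(order[:n_core])
        new_rmsd = float(np.mean(np.sqrt(np.mean(
            np.sum((aligned[:, new_core] - ref[new_core]) ** 2, axis=2), axis=1))))
        stable_set = np.array_equal(new_core, core)
        core = new_core
        if stable_set or abs(new_rmsd - cur_rmsd) < tol:
            converged = True
            break

    # final per-frame alignment and RMSD split over the converged core
    rotations = np.empty((traj.n_frames, 3, 3))
    translations = np.empty((traj.n_frames, 3))
    core_rmsd = np.empty(traj.n_frames)
    noncore_rmsd = np.full(traj.n_frames, np.nan)
    ref = sub[reference_frame]
    noncore = np.setdiff1d(np.arange(n), core)
    for k, frame in enumerate(sub):
        rot, trans, r = kabsch_superpose(frame, ref, core)
        rotations[k], translations[k] = rot, trans
        core_rmsd[k] = r
        if noncore.size:
            fitted = frame @ rot.T + trans
            noncore_rmsd[k] = float(
                np.sqrt(np.mean(np.sum((fitted[noncore] - ref[noncore]) ** 2, axis=1)))
            )
    core_mask = np.zeros(n, dtype=bool)
    core_mask[core] = True
    return AlignmentResult(
        fraction=fraction,
        core_mask=core_mask,
        core_rmsd=core_rmsd,
        noncore_rmsd=noncore_rmsd,
        rotations=rotations,
        translations=translations,
        iterations=iterations,
        converged=converged,
    )


@dataclass
class MobilityProfile:
    rmsf: np.ndarray       # per atom, Angstrom
    rg: np.ndarray | None  # per frame, Angstrom


def align_to_mean(coords: np.ndarray, rounds: int = 2) -> np.ndarray:
    """Iteratively superpose frames on their mean structure."""
    aligned = superpose_trajectory(coords, coords[0])
    for _ in range(rounds):
        mean = aligned.mean(axis=0)
        aligned = superpose_trajectory(aligned, mean)
    return aligned


def rmsf(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    after_alignment: bool = True,
) -> MobilityProfile:
    """Per-atom root-mean-square fluctuation about the mean structure."""
    if traj.n_frames < 2:
        raise GeometryError("RMSF needs at least 2 frames")
    coords = traj.coordinates
    if mask is not None:
        coords = coords[:, np.flatnonzero(np.asarray(mask))]
    if after_alignment:
        coords = align_to_mean(coords)
    mean = coords.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return MobilityProfile(rmsf=vals, rg=None)


def radius_of_gyration(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Per-frame Rg(t) = sqrt(sum m_i |r_i - r_cm|^2 / sum m_i)."""
    coords = traj.coordinates
    masses = traj.topology.masses
    if mask is not None:
        idx = np.flatnonzero(np.asarray(mask))
        coords = coords[:, idx]
        masses = masses[idx]
    if coords.shape[1] == 0:
        raise GeometryError("empty mask")
    w = masses if mass_weighted else np.ones(coords.shape[1])
    w = w / w.sum()
    cm = np.einsum("fat,a->ft", coords, w)
    d2 = np.sum((coords - cm[:, None, :]) ** 2, axis=2)
    return np.sqrt(np.einsum("fa,a->f", d2, w))
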