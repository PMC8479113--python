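"""Dynamic cross-correlation matrix of Calpha displacement vectors.

The correlation between atoms i and j is the normalized scalar product of
their displacement vectors from the time-averaged position,

    sigma_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

with dr_i(t) = r_i(t) - <r_i> and <.> the time average.  Positive values
mark correlated, negative values anti-correlated motion.  Frames are
superposed on the mean structure first by default, since otherwise global
rotation/translation dominates the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import align_to_mean
from .errors import ParameterError
from .trajio import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class CrossCorrelationMatrix:
    values: np.ndarray        # (n, n) in [-1, 1], symmetric, unit diagonal
    atom_map: np.ndarray      # matrix row -> atom index in the source trajectory
    domain_boundaries: list = field(default_factory=list)


def compute_dccm(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    align_first: bool = True,
) -> CrossCorrelationMatrix:
    """Cross-correlation matrix of per-atom displacement vectors.

    Atoms with zero fluctuation get their row/column set to 0 (diagonal 1)
    with a logged warning, so a frozen atom never produces NaNs.
    """
    if traj.n_frames < 2:
        raise ParameterError("DCCM needs at least 2 frames")
    if mask is None:
        idx = np.arange(traj.n_atoms)
    else:
        m = np.asarray(mask)
        idx = np.flatnonzero(m) if m.dtype == bool else m.astype(int)
    coords = traj.coordinates[:, idx]
    if align_first:
        coords = align_to_mean(coords)
    disp = coords - coords.mean(axis=0)          # (frames, n, 3)
    # <dr_i . dr_j> via one tensor contraction over frames and xyz
    inner = np.einsum("fid,fjd->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 0.0
    if np.any(zero):
        logger.warning("DCCM: %d zero-fluctuation atoms; rows zeroed", zero.sum())
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    values = inner / denom
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    return CrossCorrelationMatrix(values=values, atom_map=idx)


def dccm_block_summary(
    m: CrossCorrelationMatrix,
    ranges: dict[str, tuple[int, int]],
) -> dict[tuple[str, str], float]:
    """Mean correlation over each pair of row-index blocks (diagonal excluded).

    ``ranges`` maps block names to half-open [start, stop) row intervals that
    must not overlap.
    """
    items = list(ranges.items())
    spans = [(a, b) for _, (a, b) in items]
    for i, (a1, b1) in enumerate(spans):
        if a1 >= b1:
            raise ParameterError(f"empty block {items[i][0]!r}")
        for a2, b2 in spans[i + 1:]:
            if max(a1, a2) < min(b1, b2):
                raise ParameterError("block ranges overlap")
    out: dict[tuple[str, str], float] = {}
    n = m.values.shape[0]
    eye = np.eye(n, dtype=bool)
    for name_i, (a1, b1) in items:
        for name_j, (a2, b2) in items:
            block = m.values[a1:b1, a2:b2]
            sel = ~eye[a1:b1, a2:b2]
            out[(name_i, name_j)] = float(block[sel].mean()) if sel.any() else 0.0
    return out
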