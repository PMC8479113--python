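"""Shared geometric primitives for cavity and tunnel detection."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def clearance_field(points: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Distance from each query point to the nearest atom *surface*.

    Negative values mean the point is inside an atom.  Exact for arbitrary
    radii: atoms are grouped by unique radius and one nearest-neighbour query
    is run per group (structures here carry only a handful of distinct radii).
    """
    points = np.atleast_2d(points)
    out = np.full(len(points), np.inf)
    for r in np.unique(radii):
        tree = cKDTree(centers[radii == r])
        d, _ = tree.query(points, workers=-1)
        np.minimum(out, d - r, out=out)
    return out


def ray_directions_14() -> np.ndarray:
    """Six axis and eight corner-diagonal unit vectors (burial test rays)."""
    axes = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    diag = np.array(
        [[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)],
        dtype=float,
    ) / np.sqrt(3.0)
    return np.vstack([axes, diag])


def grid_axes(lo: np.ndarray, hi: np.ndarray, spacing: float):
    """Voxel-center axes covering [lo, hi] at the given spacing."""
    return [np.arange(l, h + spacing / 2, spacing) for l, h in zip(lo, hi)]


def grid_points(axes) -> np.ndarray:
    g = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([a.ravel() for a in g])
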