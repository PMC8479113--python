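"""Tunnel detection from a buried start point to bulk solvent.

A 26-connected voxel grid covers the structure; node clearance is the
distance to the nearest atom surface and nodes with clearance below the
probe radius are inadmissible.  Edge costs follow the transport cost
functional: cost of a step of length dl at local clearance r is dl / r^2
(trapezoidal between the endpoints), so Dijkstra from the start node finds
the lowest-cost escape routes.  Nodes whose clearance reaches
``bulk_clearance`` count as bulk solvent; one candidate tunnel is taken per
first entry into bulk, trimmed back to the molecular surface (approximated
by the convex hull of the atoms), smoothed, and scored:

    length L, clearance profile r(l), bottleneck = min r(l),
    cost = integral_0^L r(l)^-2 dl   (trapezoidal),
    throughput = exp(-cost).

Tunnels from many frames are grouped by average-linkage hierarchical
clustering on a centerline matching distance and summarized per cluster
(snapshots, average/max bottleneck radius, average throughput).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra
from scipy.spatial import Delaunay

from ._geometry import clearance_field, grid_axes, grid_points
from .errors import GeometryError, ParameterError
from .trajio import Topology, Trajectory

_OFFSETS = np.array(
    [
        [dx, dy, dz]
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
)  # 13 unique positive-direction neighbour offsets


@dataclass
class TunnelPath:
    frame_index: int
    centerline: np.ndarray   # (m, 3), Angstrom
    clearances: np.ndarray   # (m,), r(l) at each centerline point
    length: float            # Angstrom
    bottleneck: float        # min r(l)
    cost: float              # integral r(l)^-2 dl
    throughput: float        # exp(-cost)


def _path_metrics(centerline: np.ndarray, clearances: np.ndarray, frame_index: int) -> TunnelPath:
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    cost = float(np.trapezoid(clearances**-2.0, arclen))
    return TunnelPath(
        frame_index=frame_index,
        centerline=centerline,
        clearances=clearances,
        length=float(arclen[-1]),
        bottleneck=float(clearances.min()),
        cost=cost,
        throughput=float(np.exp(-cost)),
    )


def _smooth(points: np.ndarray, window: int = 3) -> np.ndarray:
    if len(points) < window:
        return points
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(points[:, d], kernel, mode="same") for d in range(3)]
    )
    sm[0], sm[-1] = points[0], points[-1]
    return sm


def resample_centerline(points: np.ndarray, n: int = 64) -> np.ndarray:
    """Resample a polyline to n points equally spaced in arclength."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    if arclen[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    t = np.linspace(0.0, arclen[-1], n)
    return np.column_stack([np.interp(t, arclen, points[:, d]) for d in range(3)])


def path_dissimilarity(a: np.ndarray, b: np.ndarray, n_samples: int = 64) -> float:
    """Symmetrized mean closest-point distance between two centerlines."""
    ra = resample_centerline(a, n_samples)
    rb = resample_centerline(b, n_samples)
    d = np.linalg.norm(ra[:, None, :] - rb[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


@dataclass
class GridGraph:
    """26-connected admissible-node graph over a clearance voxel grid.

    Edge weights carry the transport cost dl * (r_u^-2 + r_v^-2) / 2; bulk
    nodes (clearance >= bulk_clearance) are sinks with no bulk-bulk edges.
    """

    graph: object                # scipy CSR, symmetric weights
    points: np.ndarray           # (n_nodes, 3) admissible node coordinates
    clearance: np.ndarray        # (n_nodes,)
    bulk: np.ndarray             # (n_nodes,) bool
    spacing: float


def grid_graph(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    spacing: float,
    bulk_clearance: float,
    anchor: np.ndarray | None = None,
) -> GridGraph:
    """Build the cost graph that tunnel search runs Dijkstra on.

    ``anchor`` shifts the lattice so that point falls exactly on a node.
    """
    margin = bulk_clearance + 2 * spacing
    lo_raw = coords.min(axis=0) - margin
    if anchor is not None:
        lo = anchor - spacing * np.ceil((anchor - lo_raw) / spacing)
    else:
        lo = lo_raw
    axes = grid_axes(lo, coords.max(axis=0) + margin, spacing)
    shape = tuple(len(a) for a in axes)
    pts = grid_points(axes)
    clear = clearance_field(pts, coords, radii)
    adm_idx = np.flatnonzero(clear >= probe_radius)
    if adm_idx.size == 0:
        raise GeometryError("no admissible grid nodes at this probe radius")
    node_of = np.full(pts.shape[0], -1)
    node_of[adm_idx] = np.arange(adm_idx.size)

    grid_idx = np.column_stack(np.unravel_index(adm_idx, shape))
    rows, cols, weights = [], [], []
    lin_strides = np.array([shape[1] * shape[2], shape[2], 1])
    inv_c2 = np.zeros(pts.shape[0])
    inv_c2[adm_idx] = clear[adm_idx] ** -2.0
    bulk_flat = clear >= bulk_clearance
    for off in _OFFSETS:
        nb = grid_idx + off
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        flat_nb = nb[ok] @ lin_strides
        src_flat = adm_idx[ok]
        valid = (node_of[flat_nb] >= 0) & ~(bulk_flat[src_flat] & bulk_flat[flat_nb])
        src_flat = src_flat[valid]
        dst_flat = flat_nb[valid]
        dist = np.linalg.norm(off) * spacing
        w = dist * 0.5 * (inv_c2[src_flat] + inv_c2[dst_flat])
        rows.append(node_of[src_flat])
        cols.append(node_of[dst_flat])
        weights.append(w)
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(adm_idx.size, adm_idx.size),
    ).tocsr()
    return GridGraph(graph=graph, points=pts[adm_idx],
                     clearance=clear[adm_idx], bulk=bulk_flat[adm_idx],
                     spacing=spacing)


def find_tunnels(
    coordinates: np.ndarray,
    topology: Topology | None = None,
    start_point: np.ndarray | None = None,
    probe_radius: float = 1.0,
    radii: np.ndarray | None = None,
    spacing: float = 0.6,
    bulk_clearance: float = 4.0,
    snap_radius: float = 4.0,
    max_paths: int = 8,
    dedup_threshold: float = 4.0,
    frame_index: int = 0,
) -> list[TunnelPath]:
    """Lowest-cost escape tunnels from ``start_point`` in one frame.

    The start is snapped to the nearest admissible grid node within
    ``snap_radius``; if no admissible node exists there, the start clearance
    is below the probe and a ParameterError is raised.  A buried start with
    no route to bulk returns an empty list (a valid result).
    """
    if probe_radius <= 0:
        raise ParameterError("probe radius must be positive")
    coords = np.asarray(coordinates, float)
    if coords.ndim == 3:
        coords = coords[frame_index]
    if radii is None:
        if topology is None:
            raise ParameterError("need topology or radii")
        radii = topology.vdw_radii
    if start_point is None:
        raise ParameterError("start_point is required")
    start = np.asarray(start_point, float)

    gg = grid_graph(coords, radii, probe_radius, spacing, bulk_clearance,
                    anchor=start)

    # snap start to the nearest admissible node
    d2 = np.sum((gg.points - start) ** 2, axis=1)
    start_node = int(np.argmin(d2))
    if np.sqrt(d2[start_node]) > snap_radius:
        raise ParameterError(
            f"start point has clearance below the probe radius "
            f"(no admissible node within {snap_radius} Angstrom)"
        )

    dist, pred = _dijkstra(
        gg.graph, directed=False, indices=start_node, return_predecessors=True
    )
    bulk = gg.bulk
    reached_bulk = np.flatnonzero(bulk & np.isfinite(dist))
    if reached_bulk.size == 0:
        return []
    # portals: first entries into bulk along the shortest-path tree
    portals = reached_bulk[
        (pred[reached_bulk] >= 0) & ~bulk[np.maximum(pred[reached_bulk], 0)]
    ]
    if portals.size == 0:
        portals = reached_bulk
    portals = portals[np.argsort(dist[portals])]

    hull = Delaunay(coords)
    adm_points = gg.points
    paths: list[TunnelPath] = []
    for portal in portals:
        if len(paths) >= max_paths:
            break
        chain = []
        node = portal
        while node >= 0:
            chain.append(node)
            node = pred[node]
        chain = chain[::-1]  # start -> portal
        pline = adm_points[chain]
        inside = hull.find_simplex(pline) >= 0
        # keep the leading run of in-hull points (the tunnel ends at the surface)
        if not inside[0]:
            first_in = np.argmax(inside) if inside.any() else len(inside)
            inside[:first_in] = True  # tolerate a start snapped just outside
        n_keep = int(np.argmin(inside)) if not inside.all() else len(pline)
        if n_keep < 3:
            continue
        pline = pline[: n_keep + 1] if n_keep < len(pline) else pline
        sm = _smooth(pline)
        r = clearance_field(sm, coords, radii)
        low = r < probe_radius
        sm[low] = pline[low]
        r[low] = clearance_field(pline[low], coords, radii)
        cand = _path_metrics(sm, r, frame_index)
        if cand.length < 2 * spacing:
            continue
        if all(path_dissimilarity(cand.centerline, p.centerline) > dedup_threshold
               for p in paths):
            paths.append(cand)
    return paths


@dataclass
class TunnelCluster:
    members: list[TunnelPath]
    representative: TunnelPath
    n_snapshots: int
    average_bottleneck: float
    max_bottleneck: float
    average_throughput: float


def cluster_tunnels(paths: list[TunnelPath], threshold: float = 4.0) -> list[TunnelCluster]:
    """Average-linkage clustering of tunnel centerlines, cut at ``threshold`` (Angstrom).

    Clusters are ranked by average bottleneck radius then average throughput,
    best first; the representative is the member with the highest throughput.
    """
    if not paths:
        raise ParameterError("need at least one tunnel path")
    if len(paths) == 1:
        labels = np.array([1])
    else:
        n = len(paths)
        condensed = []
        for i in range(n):
            for j in range(i + 1, n):
                condensed.append(path_dissimilarity(paths[i].centerline,
                                                    paths[j].centerline))
        z = linkage(np.array(condensed), method="average")
        labels = fcluster(z, t=threshold, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = [p for p, l in zip(paths, labels) if l == lab]
        bns = np.array([p.bottleneck for p in members])
        tps = np.array([p.throughput for p in members])
        rep = members[int(np.argmax(tps))]
        clusters.append(
            TunnelCluster(
                members=members,
                representative=rep,
                n_snapshots=len({p.frame_index for p in members}),
                average_bottleneck=float(bns.mean()),
                max_bottleneck=float(bns.max()),
                average_throughput=float(tps.mean()),
            )
        )
    clusters.sort(key=lambda c: (c.average_bottleneck, c.average_throughput),
                  reverse=True)
    return clusters


def tunnel_summary(clusters: list[TunnelCluster]):
    """Per-cluster summary table (snapshots, avg/max bottleneck, avg throughput)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster": np.arange(1, len(clusters) + 1),
            "n_snapshots": [c.n_snapshots for c in clusters],
            "average_bottleneck_A": [c.average_bottleneck for c in clusters],
            "max_bottleneck_A": [c.max_bottleneck for c in clusters],
            "average_throughput": [c.average_throughput for c in clusters],
        }
    )


@dataclass
class TunnelLining:
    residue_counts: dict = field(default_factory=dict)  # (chain, resindex, resname) -> count
    cutoff: float = 2.0


def lining_residues(
    cluster: TunnelCluster,
    traj: Trajectory,
    cutoff: float = 2.0,
) -> TunnelLining:
    """Residues whose atoms approach a member tunnel's surface within ``cutoff``.

    An atom lines a tunnel if its vdW surface comes within ``cutoff`` of the
    tunnel's clearance-sphere surface in that member's frame:
    |x_atom - c(l)| - r(l) - r_atom <= cutoff for some centerline point.
    Counts are per-residue occurrences over member paths.
    """
    topo = traj.topology
    counts: dict = {}
    for path in cluster.members:
        coords = traj.coordinates[path.frame_index]
        d = np.linalg.norm(coords[:, None, :] - path.centerline[None, :, :], axis=2)
        gap = d - path.clearances[None, :] - topo.vdw_radii[:, None]
        near = (gap <= cutoff).any(axis=1)
        res_hit = set()
        for ai in np.flatnonzero(near):
            res_hit.add(
                (topo.chain_ids[ai], int(topo.residue_indices[ai]), topo.residue_names[ai])
            )
        for key in res_hit:
            counts[key] = counts.get(key, 0) + 1
    return TunnelLining(residue_counts=counts, cutoff=cutoff)
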