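"""Trajectory and topology containers plus readers/writers.

Coordinates are in Angstrom throughout; atom, residue and frame indices are
0-based internally and only become 1-based at PDB serialization.  The
reference on-disk format is the multi-model PDB (``MODEL``/``ENDMDL`` records
become frames); DCD and XTC are supported through the same reader contract
when a topology file is supplied.  Parsing and writing of all three formats
is delegated to MDAnalysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import FormatError, SelectionError, StructureError

# Bondi van der Waals radii (Angstrom); metals default to 1.40.
BONDI_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_METAL_RADIUS = 1.40

ATOMIC_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "H": 1.008,
    "P": 30.974,
    "CU": 63.546,
}


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB-style atom name.

    Two-letter metal symbols (CU, FE, ZN, MG, NA, ...) are recognised before
    falling back to the first alphabetic character.
    """
    stripped = "".join(ch for ch in name.strip() if ch.isalpha()).upper()
    if stripped[:2] in ("CU", "FE", "ZN", "MG", "NA", "CL", "MN", "CA") and len(stripped) == 2:
        # bare two-letter name is taken as a metal/ion; "CA" the carbon alpha
        # is longer in context ("CA" alone within a CA-only model is carbon,
        # handled by caller passing resname); default: treat "CA" as carbon.
        if stripped == "CA":
            return "C"
        return stripped[:2]
    return stripped[:1] if stripped else "C"


def vdw_radius_for(name: str) -> float:
    elem = element_from_name(name)
    if elem in BONDI_RADII:
        return BONDI_RADII[elem]
    return DEFAULT_METAL_RADIUS


def mass_for(name: str) -> float:
    elem = element_from_name(name)
    return ATOMIC_MASSES.get(elem, ATOMIC_MASSES.get(elem[:1], 12.011))


@dataclass
class Topology:
    """Per-atom metadata: names, residues, chains, vdW radii, masses."""

    atom_names: np.ndarray       # (n,) str
    residue_indices: np.ndarray  # (n,) int, 0-based
    residue_names: np.ndarray    # (n,) str
    chain_ids: np.ndarray        # (n,) str
    vdw_radii: np.ndarray        # (n,) float, Angstrom
    masses: np.ndarray           # (n,) float, amu

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr_name in ("residue_indices", "residue_names", "chain_ids", "vdw_radii", "masses"):
            if len(getattr(self, arr_name)) != n:
                raise StructureError(f"topology field {arr_name} length != n_atoms")
        if np.any(self.vdw_radii <= 0):
            raise StructureError("vdw radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def mask(
        self,
        name: str | Sequence[str] | None = None,
        resname: str | Sequence[str] | None = None,
        chain: str | Sequence[str] | None = None,
        predicate: Callable[[int], bool] | None = None,
    ) -> np.ndarray:
        """Boolean atom mask by name/residue/chain and/or an index predicate."""
        m = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            names = {name} if isinstance(name, str) else set(name)
            m &= np.isin(self.atom_names, list(names))
        if resname is not None:
            rn = {resname} if isinstance(resname, str) else set(resname)
            m &= np.isin(self.residue_names, list(rn))
        if chain is not None:
            ch = {chain} if isinstance(chain, str) else set(chain)
            m &= np.isin(self.chain_ids, list(ch))
        if predicate is not None:
            m &= np.fromiter((predicate(i) for i in range(self.n_atoms)), bool, self.n_atoms)
        return m

    def subset(self, atom_indices: np.ndarray) -> "Topology":
        idx = np.asarray(atom_indices)
        return Topology(
            atom_names=self.atom_names[idx],
            residue_indices=self.residue_indices[idx],
            residue_names=self.residue_names[idx],
            chain_ids=self.chain_ids[idx],
            vdw_radii=self.vdw_radii[idx],
            masses=self.masses[idx],
        )


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinate array (Angstrom) plus its topology."""

    topology: Topology
    coordinates: np.ndarray          # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ps, optional

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructureError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise StructureError("coordinate atom count inconsistent with topology")
        if self.coordinates.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class FrameSelection:
    """Frame slice (start/stop/stride) combined with an atom mask.

    Atom criteria behave like :meth:`Topology.mask`; ``atom_indices``
    overrides them when given.
    """

    start: int | None = None
    stop: int | None = None
    stride: int | None = None
    name: str | Sequence[str] | None = None
    resname: str | Sequence[str] | None = None
    chain: str | Sequence[str] | None = None
    atom_indices: Sequence[int] | None = None
    predicate: Callable[[int], bool] | None = None

    def frame_indices(self, n_frames: int) -> np.ndarray:
        return np.arange(n_frames)[slice(self.start, self.stop, self.stride)]

    def atom_index_array(self, topology: Topology) -> np.ndarray:
        if self.atom_indices is not None:
            return np.asarray(self.atom_indices, dtype=int)
        m = topology.mask(name=self.name, resname=self.resname, chain=self.chain,
                          predicate=self.predicate)
        return np.flatnonzero(m)


def select(traj: Trajectory, sel: FrameSelection) -> Trajectory:
    """Slice frames and atoms, preserving order; errors on empty selections."""
    fidx = sel.frame_indices(traj.n_frames)
    aidx = sel.atom_index_array(traj.topology)
    if fidx.size == 0:
        raise SelectionError("frame selection is empty")
    if aidx.size == 0:
        raise SelectionError("atom selection is empty")
    times = traj.frame_times[fidx] if traj.frame_times is not None else None
    return Trajectory(
        topology=traj.topology.subset(aidx),
        coordinates=traj.coordinates[np.ix_(fidx, aidx)],
        frame_times=times,
    )


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    names = atoms.names.astype(str)
    try:
        resnames = atoms.resnames.astype(str)
    except Exception:
        resnames = np.array(["UNK"] * len(atoms))
    try:
        chains = atoms.chainIDs.astype(str)
    except Exception:
        try:
            chains = atoms.segids.astype(str)
        except Exception:
            chains = np.array(["A"] * len(atoms))
    chains = np.array([c if c.strip() else "A" for c in chains])
    # residue indices: contiguous 0-based in order of appearance
    resids = atoms.resindices.astype(int)
    radii = np.array([vdw_radius_for(n) for n in names])
    masses = np.array([mass_for(n) for n in names])
    return Topology(names, resids, resnames, chains, radii, masses)


def read_trajectory(
    path: str,
    topology_path: str | None = None,
    format: str = "pdb_multimodel",
) -> Trajectory:
    """Read a trajectory from disk.

    ``pdb_multimodel`` reads frames from MODEL/ENDMDL records; ``dcd`` and
    ``xtc`` require ``topology_path`` (a PDB naming the atoms).
    """
    import MDAnalysis as mda

    fmt = format.lower()
    if fmt not in ("pdb_multimodel", "pdb", "dcd", "xtc"):
        raise FormatError(f"unknown trajectory format {format!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt in ("pdb_multimodel", "pdb"):
                u = mda.Universe(path)
            else:
                if topology_path is None:
                    raise FormatError(f"{fmt} trajectories require topology_path")
                u = mda.Universe(topology_path, path)
            topo = _topology_from_universe(u)
            coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    except (OSError, ValueError, EOFError, IndexError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse {path!r} as {format}: {exc}") from exc
    if topo.n_atoms == 0 or coords.size == 0:
        raise FormatError(f"{path!r} contains no parseable atom records")
    if coords.shape[1] != topo.n_atoms:
        raise StructureError("atom count mismatch between models")
    return Trajectory(topology=topo, coordinates=coords)


def write_pdb(traj: Trajectory, path: str) -> None:
    """Write a multi-model PDB (one MODEL per frame) via MDAnalysis."""
    import MDAnalysis as mda

    topo = traj.topology
    n = topo.n_atoms
    n_res = int(topo.residue_indices.max()) + 1
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=n_res,
        n_segments=len(np.unique(topo.chain_ids)),
        atom_resindex=topo.residue_indices,
        residue_segindex=_residue_segindex(topo),
        trajectory=True,
    )
    u.add_TopologyAttr("names", topo.atom_names)
    res_names = np.empty(n_res, dtype=object)
    res_names[topo.residue_indices] = topo.residue_names
    u.add_TopologyAttr("resnames", res_names.astype(str))
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    chains_per_seg = _segment_chain_ids(topo)
    u.add_TopologyAttr("segids", chains_per_seg)
    u.add_TopologyAttr("chainIDs", topo.chain_ids)
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    u.add_TopologyAttr("elements", np.array([element_from_name(s) for s in topo.atom_names]))
    u.load_new(traj.coordinates.astype(np.float32), order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=n, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _residue_segindex(topo: Topology) -> np.ndarray:
    """Segment index per residue, segments being distinct chain ids in order."""
    chains = np.unique(topo.chain_ids)
    chain_to_seg = {c: i for i, c in enumerate(chains)}
    n_res = int(topo.residue_indices.max()) + 1
    seg = np.zeros(n_res, dtype=int)
    for ri, ci in zip(topo.residue_indices, topo.chain_ids):
        seg[ri] = chain_to_seg[ci]
    return seg


def _segment_chain_ids(topo: Topology) -> np.ndarray:
    return np.unique(topo.chain_ids)
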