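"""Seeded synthetic hexamer trajectories and toy geometries with known truth.

The generator emulates the architecture the analyses assume: a 6-subunit
dimer-of-trimers pseudo-protein (three subunits per concentric ring), each
subunit a Calpha-only bead shell enclosing a buried di-metal site flanked by
six coordinating pseudo-histidine beads (36 site beads over the hexamer).
Two distinguishable global modes are available:

``ring_counter_rotation``
    the "deoxy"/open mode — the top trimeric ring rotates clockwise and the
    bottom ring anticlockwise about the hexamer axis;
``clam_shell``
    the "oxy"/closed mode — two adjacent subunits in each ring hinge apart
    and together like a clam shell.

Mode time courses are one full sine period over the trajectory (zero-mean
displacement), plus i.i.d. isotropic Gaussian thermal noise per atom per
frame.  Each subunit shell carries an outward-facing aperture through which
a tunnel connects the internal cavity to the outside; aperture size, shell
radius and ring packing differ between the open- and closed-state presets so
that cavity volume, tunnel bottleneck and buried interface area differ
between states with known sign.

Toy geometries (sphere, sphere pair, hollow shell with cubic cavity,
straight/hourglass channel) carry their analytic ground truths alongside the
atoms and serve as oracles for the surface, pocket and tunnel modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import ParameterError
from .trajio import BONDI_RADII, Topology, Trajectory, mass_for

TOP_RING_CHAINS = ("A", "B", "C")
BOTTOM_RING_CHAINS = ("D", "E", "F")

Mode = Literal["ring_counter_rotation", "clam_shell", "rigid", "custom"]


@dataclass
class SyntheticSpec:
    """Parameters of the pseudo-hexamer generator.

    Geometry defaults correspond to the closed (oxygenated-like) packing;
    use :func:`open_state_spec` / :func:`closed_state_spec` for the canonical
    two-state pair.
    """

    n_subunits: int = 6
    residues_per_subunit: int = 60
    mode: Mode = "rigid"
    mode_amplitude: float = 6.0      # degrees for both rotation modes
    noise_sd: float = 0.3            # Angstrom, per coordinate
    n_frames: int = 100
    seed: int = 0
    shell_radius: float = 7.0        # Angstrom, subunit bead-shell radius
    aperture_half_angle: float = 28.0  # degrees, tunnel mouth in the shell
    ring_radius: float = 11.0        # Angstrom, subunit centers from axis
    ring_separation: float = 13.0    # Angstrom, top/bottom ring center gap
    site_expansion: float = 1.0      # scale of the di-metal/histidine cage
    custom_displacement: np.ndarray | None = None  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_subunits != 6:
            raise ParameterError("the dimer-of-trimers generator requires 6 subunits")
        if self.mode not in ("ring_counter_rotation", "clam_shell", "rigid", "custom"):
            raise ParameterError(f"unknown mode {self.mode!r}")


def open_state_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Deoxy-like open state: counter-rotating rings, looser packing."""
    params = dict(
        mode="ring_counter_rotation",
        shell_radius=8.0,
        aperture_half_angle=38.0,
        ring_radius=13.0,
        ring_separation=16.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def closed_state_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Oxy-like closed state: clam-shell mode, tight packing, small aperture."""
    params = dict(
        mode="clam_shell",
        shell_radius=7.0,
        aperture_half_angle=34.0,
        ring_radius=11.0,
        ring_separation=13.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle lattice), deterministic."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


# Pseudo-histidine NE2 beads coordinating the two metals, template frame.
# Three per metal, splayed away from the metal-metal (x) axis.  The cluster
# is kept compact so the tunnel constriction sits in the annulus between the
# site and the shell (state-dependent), not inside the cluster itself.
_CU_OFFSETS = np.array([[-1.2, 0.0, 0.0], [1.2, 0.0, 0.0]])
_HIS_LOCAL = 2.4 * np.array(
    [
        [-0.55, 0.83, 0.0],
        [-0.55, -0.42, 0.72],
        [-0.55, -0.42, -0.72],
    ]
)


def _subunit_template(spec: SyntheticSpec) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Bead positions and (atom_name, residue_name) labels for one subunit.

    The shell aperture faces template +x (mapped to the outward radial
    direction when the hexamer is assembled).
    """
    n = spec.residues_per_subunit
    pts = fibonacci_sphere(6 * n)
    cos_cap = np.cos(np.radians(spec.aperture_half_angle))
    keep = pts[:, 0] < cos_cap  # drop the cap around +x
    pts = pts[keep]
    idx = np.round(np.linspace(0, len(pts) - 1, n)).astype(int)
    beads = pts[idx] * spec.shell_radius

    coords = [beads]
    labels: list[tuple[str, str]] = [("CA", "GLY")] * n
    # the open (deoxygenated-like) state carries an expanded site cage: the
    # constriction formed around the metals widens before oxygen uptake
    cu = spec.site_expansion * _CU_OFFSETS
    coords.append(cu)
    labels += [("CU", "CUA")] * 2
    his_local = spec.site_expansion * _HIS_LOCAL
    his = np.concatenate([cu[0] + his_local, cu[1] - his_local])
    coords.append(his)
    labels += [("NE2", "HIS")] * 6
    return np.concatenate(coords), labels


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def hexamer_base_structure(spec: SyntheticSpec) -> tuple[np.ndarray, Topology, np.ndarray]:
    """Assemble the frame-0 hexamer.

    Returns (coords (n_atoms, 3), topology, subunit_index (n_atoms,)).
    Chains A-C form the top ring (z > 0), D-F the bottom ring; each subunit
    template is rotated so its aperture faces radially outward.
    """
    template, labels = _subunit_template(spec)
    n_per = len(template)
    chains = list(TOP_RING_CHAINS + BOTTOM_RING_CHAINS)

    all_coords = []
    atom_names: list[str] = []
    res_names: list[str] = []
    chain_ids: list[str] = []
    res_idx: list[int] = []
    subunit_of: list[int] = []
    radii: list[float] = []
    masses: list[float] = []
    next_res = 0
    for s in range(6):
        top = s < 3
        azimuth = 120.0 * (s % 3) + (0.0 if top else 60.0)
        z = spec.ring_separation / 2.0 * (1.0 if top else -1.0)
        rot = _rotation_z(azimuth)
        center = rot @ np.array([spec.ring_radius, 0.0, 0.0]) + np.array([0.0, 0.0, z])
        coords = template @ rot.T + center
        all_coords.append(coords)
        for (aname, rname) in labels:
            atom_names.append(aname)
            res_names.append(rname)
            chain_ids.append(chains[s])
            res_idx.append(next_res)
            subunit_of.append(s)
            next_res += 1
            if aname == "CU":
                radii.append(1.40)
            else:
                radii.append(BONDI_RADII["C"] if aname == "CA" else BONDI_RADII["N"])
            masses.append(mass_for(aname))

    topo = Topology(
        atom_names=np.array(atom_names),
        residue_indices=np.array(res_idx),
        residue_names=np.array(res_names),
        chain_ids=np.array(chain_ids),
        vdw_radii=np.array(radii),
        masses=np.array(masses),
    )
    return np.concatenate(all_coords), topo, np.array(subunit_of)


def tunnel_start_point(
    traj: Trajectory, chain: str, spec: SyntheticSpec, frame: int = 0
) -> np.ndarray:
    """Buried cavity point of one subunit, between the metal site and aperture.

    The start is placed on the outward ray from the di-metal centroid toward
    the shell aperture, at the sample with the largest clearance in the
    requested frame — i.e. in the solvent cavity abutting the site, not
    wedged against the metal beads themselves.
    """
    from ._geometry import clearance_field

    topo = traj.topology
    cu = np.flatnonzero(topo.mask(name="CU", chain=chain))
    if cu.size == 0:
        raise ParameterError(f"chain {chain!r} has no metal site")
    center = traj.coordinates[frame][cu].mean(axis=0)
    outward = center * np.array([1.0, 1.0, 0.0])
    outward /= np.linalg.norm(outward)
    ts = np.linspace(0.25, 0.85, 25) * spec.shell_radius
    candidates = center[None, :] + ts[:, None] * outward[None, :]
    clear = clearance_field(candidates, traj.coordinates[frame], topo.vdw_radii)
    return candidates[int(np.argmax(clear))]


def ring_assignment() -> dict[str, tuple[str, ...]]:
    """Chain ids per ring, as laid down by the generator."""
    return {"top": TOP_RING_CHAINS, "bottom": BOTTOM_RING_CHAINS}


def _apply_mode(
    spec: SyntheticSpec,
    base: np.ndarray,
    subunit_of: np.ndarray,
    phase: float,
) -> np.ndarray:
    """Displace the base structure along the requested collective mode.

    ``phase`` is the signed instantaneous mode amplitude in degrees.
    """
    coords = base.copy()
    if spec.mode == "ring_counter_rotation":
        top_atoms = subunit_of < 3
        coords[top_atoms] = coords[top_atoms] @ _rotation_z(phase).T
        coords[~top_atoms] = coords[~top_atoms] @ _rotation_z(-phase).T
    elif spec.mode == "clam_shell":
        # adjacent pair in each ring hinges about the vertical axis through
        # the pair's contact midpoint
        for pair in ((0, 1), (3, 4)):
            centers = [coords[subunit_of == s].mean(axis=0) for s in pair]
            hinge = 0.5 * (centers[0] + centers[1])
            for s, sign in zip(pair, (1.0, -1.0)):
                m = subunit_of == s
                coords[m] = (coords[m] - hinge) @ _rotation_z(sign * phase).T + hinge
    return coords


def generate_hexamer_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Seeded pseudo-hexamer trajectory with the requested collective mode.

    The mode follows a full sine period over the trajectory; thermal noise is
    i.i.d. Gaussian per coordinate with sd ``spec.noise_sd``.  The same seed
    reproduces bitwise-identical coordinates.
    """
    base, topo, subunit_of = hexamer_base_structure(spec)
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames)
    phases = spec.mode_amplitude * np.sin(2.0 * np.pi * t / spec.n_frames)

    frames = np.empty((spec.n_frames, len(base), 3))
    for k in range(spec.n_frames):
        if spec.mode in ("ring_counter_rotation", "clam_shell"):
            frames[k] = _apply_mode(spec, base, subunit_of, phases[k])
        elif spec.mode == "custom":
            if spec.custom_displacement is None:
                raise ParameterError("mode 'custom' requires custom_displacement")
            frames[k] = base + spec.custom_displacement[k]
        else:  # rigid
            frames[k] = base
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, frames.shape)
    return Trajectory(topology=topo, coordinates=frames)


# ---------------------------------------------------------------------------
# toy geometries with analytic ground truth
# ---------------------------------------------------------------------------


@dataclass
class ToyGeometry:
    """Atom centers + radii with the analytic quantities they were built to have."""

    kind: str
    coordinates: np.ndarray  # (n, 3)
    radii: np.ndarray        # (n,)
    ground_truth: dict = field(default_factory=dict)

    def topology(self) -> Topology:
        n = len(self.coordinates)
        return Topology(
            atom_names=np.array(["C"] * n),
            residue_indices=np.arange(n),
            residue_names=np.array(["TOY"] * n),
            chain_ids=np.array(["X"] * n),
            vdw_radii=self.radii.astype(float),
            masses=np.full(n, 12.011),
        )

    def as_trajectory(self) -> Trajectory:
        return Trajectory(topology=self.topology(), coordinates=self.coordinates[None])


def _lattice(box_lo: np.ndarray, box_hi: np.ndarray, spacing: float) -> np.ndarray:
    axes = [np.arange(lo, hi + 1e-9, spacing) for lo, hi in zip(box_lo, box_hi)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def generate_toy_geometry(kind: str, **params) -> ToyGeometry:
    """Build a toy geometry with stored analytic truths.

    Kinds: ``sphere`` (radius), ``sphere_pair`` (radius, distance),
    ``shell_cavity`` (cavity_side, wall_thickness), ``channel`` (radius,
    constriction_radius, length) and ``cavity_two_channels`` (cavity_side,
    channel_radius).
    """
    if kind == "sphere":
        r = float(params.get("radius", 1.7))
        probe = float(params.get("probe", 1.4))
        if r <= 0:
            raise ParameterError("sphere radius must be positive")
        return ToyGeometry(
            kind,
            np.zeros((1, 3)),
            np.array([r]),
            {"asa": 4.0 * np.pi * (r + probe) ** 2, "probe": probe},
        )

    if kind == "sphere_pair":
        r = float(params.get("radius", 1.7))
        d = float(params.get("distance", 2.0))
        probe = float(params.get("probe", 1.4))
        if r <= 0 or d <= 0:
            raise ParameterError("sphere_pair parameters must be positive")
        R = r + probe
        if d >= 2 * R:
            asa = 2 * 4.0 * np.pi * R**2
        else:
            cap = 2.0 * np.pi * R * (R - d / 2.0)  # spherical cap buried per sphere
            asa = 2 * (4.0 * np.pi * R**2 - cap)
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        return ToyGeometry(kind, coords, np.array([r, r]), {"asa": asa, "probe": probe})

    if kind == "shell_cavity":
        a = float(params.get("cavity_side", 6.0))
        wall = float(params.get("wall_thickness", 3.0))
        # dense lattice keeps the wall surfaces smooth: a coarse wall has
        # sub-probe troughs that confuse burial ray tests at fine grids
        spacing = float(params.get("lattice_spacing", 0.8))
        ra = float(params.get("atom_radius", 1.2))
        if a <= 0 or wall <= 0:
            raise ParameterError("cavity parameters must be positive")
        half = a / 2.0
        lim = half + ra + wall
        pts = _lattice(np.full(3, -lim), np.full(3, lim), spacing)
        # distance from each lattice point to the open cavity cube
        d = np.linalg.norm(np.maximum(np.abs(pts) - half, 0.0), axis=1)
        keep = (d >= ra + 0.5 * spacing) & (d <= ra + wall)
        pts = pts[keep]
        # line the six cavity faces with a dense flush layer whose atom
        # surfaces sit exactly on the cavity planes, so the constructed
        # cavity truly has side `a` (the coarse lattice alone quantizes it)
        face_ax = np.arange(-half, half + 1e-9, 0.6)
        fy, fz = np.meshgrid(face_ax, face_ax, indexing="ij")
        face = np.column_stack([np.full(fy.size, half + ra),
                                fy.ravel(), fz.ravel()])
        lining = []
        for axis in range(3):
            for sign in (1.0, -1.0):
                f = face.copy()
                f[:, 0] *= sign
                lining.append(np.roll(f, axis, axis=1))
        pts = np.vstack([pts] + lining)
        return ToyGeometry(
            kind, pts, np.full(len(pts), ra), {"cavity_volume": a**3, "cavity_side": a}
        )

    if kind == "channel":
        r0 = float(params.get("radius", 2.0))
        rc = float(params.get("constriction_radius", r0))
        length = float(params.get("length", 10.0))
        wall = float(params.get("wall_extent", 6.0))
        spacing = float(params.get("lattice_spacing", 1.0))
        ra = float(params.get("atom_radius", 1.0))
        if min(r0, rc, length) <= 0:
            raise ParameterError("channel parameters must be positive")
        if rc > r0:
            raise ParameterError("constriction must not exceed the mouth radius")
        lim = r0 + ra + wall
        pts = _lattice(
            np.array([-lim, -lim, 0.0]), np.array([lim, lim, length]), spacing
        )
        z = pts[:, 2]
        # linear hourglass profile; constant when rc == r0
        prof = rc + (r0 - rc) * np.abs(2.0 * z / length - 1.0)
        cyl = np.hypot(pts[:, 0], pts[:, 1])
        keep = cyl >= prof + ra
        pts = pts[keep]
        # line the channel with dense atom rings following the profile, so
        # the constructed clearance equals the stated radius (the coarse
        # lattice alone quantizes the constriction)
        rings = []
        for zr in np.arange(0.0, length + 1e-9, 0.5):
            pr = rc + (r0 - rc) * abs(2.0 * zr / length - 1.0)
            ring_r = pr + ra
            n_ring = max(8, int(np.ceil(2 * np.pi * ring_r / 0.6)))
            ang = 2 * np.pi * np.arange(n_ring) / n_ring
            rings.append(
                np.column_stack([ring_r * np.cos(ang), ring_r * np.sin(ang),
                                 np.full(n_ring, zr)])
            )
        pts = np.vstack([pts] + rings)
        truth = {
            "bottleneck": rc,
            "length": length,
            "probe": 1.0,
        }
        if rc == r0:
            truth["cost"] = length / r0**2
            truth["throughput"] = float(np.exp(-length / r0**2))
        return ToyGeometry(kind, pts, np.full(len(pts), ra), truth)

    if kind == "cavity_two_channels":
        a = float(params.get("cavity_side", 8.0))
        rch = float(params.get("channel_radius", 2.0))
        wall = float(params.get("wall_thickness", 5.0))
        spacing = float(params.get("lattice_spacing", 0.8))
        ra = float(params.get("atom_radius", 1.0))
        if min(a, rch, wall) <= 0:
            raise ParameterError("parameters must be positive")
        half = a / 2.0
        lim = half + ra + wall
        pts = _lattice(np.full(3, -lim), np.full(3, lim), spacing)
        d = np.linalg.norm(np.maximum(np.abs(pts) - half, 0.0), axis=1)
        in_wall = (d >= ra) & (d <= ra + wall)
        # drill channels along +x and -x
        in_channel = np.hypot(pts[:, 1], pts[:, 2]) < rch + ra
        keep = in_wall & ~in_channel
        pts = pts[keep]
        return ToyGeometry(
            kind, pts, np.full(len(pts), ra),
            {"cavity_volume": a**3, "n_exits": 2, "channel_radius": rch},
        )

    raise ParameterError(f"unknown toy geometry kind {kind!r}")


def generate_cavity_schedule_trajectory(
    n_frames: int = 200,
    open_fraction: float = 0.2,
    cavity_side: float = 6.0,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Shell-cavity trajectory whose cavity is open in a known frame subset.

    In closed frames a plug of atoms fills the cavity; in open frames the
    plug is parked far from the structure (topology must be constant across
    frames).  Returns the trajectory and the boolean open-frame mask; the
    expected voxel opening frequency equals ``open_fraction`` exactly.
    """
    shell = generate_toy_geometry("shell_cavity", cavity_side=cavity_side)
    half = cavity_side / 2.0
    plug = _lattice(np.full(3, -half), np.full(3, half), 1.2)
    # parked far enough to leave the shell's clearance field untouched, but
    # close enough that the analysis grid over all frames stays small
    park = plug + np.array([half + 28.0, 0.0, 0.0])

    n_open = int(round(open_fraction * n_frames))
    rng = np.random.default_rng(seed)
    open_mask = np.zeros(n_frames, dtype=bool)
    open_mask[rng.permutation(n_frames)[:n_open]] = True

    n_shell, n_plug = len(shell.coordinates), len(plug)
    coords = np.empty((n_frames, n_shell + n_plug, 3))
    for k in range(n_frames):
        coords[k, :n_shell] = shell.coordinates
        coords[k, n_shell:] = park if open_mask[k] else plug

    n = n_shell + n_plug
    topo = Topology(
        atom_names=np.array(["C"] * n),
        residue_indices=np.arange(n),
        residue_names=np.array(["TOY"] * n_shell + ["PLG"] * n_plug),
        chain_ids=np.array(["X"] * n_shell + ["P"] * n_plug),
        vdw_radii=np.concatenate([shell.radii, np.full(n_plug, 1.2)]),
        masses=np.full(n, 12.011),
    )
    return Trajectory(topology=topo, coordinates=coords), open_mask


def generate_site_distance_dataset(
    spec_a: SyntheticSpec,
    spec_b: SyntheticSpec,
    frames_per_state: int,
    split_seed: int = 0,
):
    """Labeled per-frame 36x36 pseudo-histidine distance matrices.

    Generates one trajectory per state spec (truncated/extended to
    ``frames_per_state`` frames), selects the NE2 site beads and builds the
    dataset through :func:`hexadyn.cvae.build_dataset`.
    """
    from .cvae import DistanceMatrixDataset, build_dataset

    if spec_a.residues_per_subunit != spec_b.residues_per_subunit:
        raise ParameterError("state specs must share the site-atom layout")
    if frames_per_state == 0:
        return DistanceMatrixDataset(
            matrices=np.empty((0, 36, 36)), labels=np.empty(0, dtype=int),
            train_idx=np.empty(0, dtype=int), val_idx=np.empty(0, dtype=int),
        )
    a = replace(spec_a, n_frames=frames_per_state)
    b = replace(spec_b, n_frames=frames_per_state)
    traj_a = generate_hexamer_trajectory(a)
    traj_b = generate_hexamer_trajectory(b)
    return build_dataset(traj_a, traj_b, name="NE2", split_seed=split_seed)
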