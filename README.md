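# hexadyn

Comparative molecular-dynamics trajectory analysis for distinguishing the
open (deoxygenated) from the closed (oxygenated) conformational dynamics of
a hemocyanin-like homo-hexamer — a dimer-of-trimers whose oxygen uptake is
controlled by inter-subunit cavities and tunnels leading to a buried
di-copper site.

The package implements, as one tested toolchain, the analyses such a
comparison needs:

* **trajectory I/O** — multi-model PDB (DCD/XTC via the same contract),
  atom/frame selections, Bondi vdW radii;
* **alignment & mobility** — Kabsch superposition, conventional RMSD,
  fraction-based robust *core* alignment (align the fraction of atoms with
  the smallest displacements, separating core from mobile regions), RMSF,
  radius of gyration;
* **dynamic cross-correlation** — sigma_ij = <dr_i . dr_j> /
  sqrt(<|dr_i|^2><|dr_j|^2>) over Calpha displacement vectors;
* **essential dynamics** — PCA of the 3n-dimensional coordinate covariance,
  porcupine mode vectors, eigenvector dot-product matrices, RMSIP subspace
  overlap between two systems;
* **surfaces** — Shrake-Rupley solvent-accessible surface area (probe
  1.4 A) and the buried interface area IASA = ASA_A + ASA_B − ASA_AB
  between chain groups;
* **cavities** — grid-based buried-pocket detection with per-voxel opening
  frequencies and cumulative volumes;
* **tunnels** — lowest-cost escape paths from a buried start point on a
  clearance-weighted voxel graph (probe 1.0 A), scored by bottleneck radius,
  cost = integral of r(l)^-2 along the centerline, and throughput =
  exp(−cost), clustered across snapshots with per-cluster summaries and
  lining residues;
* **CVAE state discrimination** — a convolutional variational autoencoder
  (numpy, hand-verified gradients) over per-frame 36 x 36 distance matrices
  of the metal-coordinating pseudo-histidines, with latent-dimension scans
  and t-SNE/linear projections.

Because the original microsecond trajectories of the real hexamer are not
deposited, the package ships a seeded synthetic generator
(`hexadyn.synthetic`) producing pseudo-hexamer trajectories with the two
states' characteristic collective modes (counter-rotating trimeric rings
vs a clam-shell hinge), a buried di-metal site ringed by six
pseudo-histidines per subunit, Gaussian thermal noise, and toy
sphere/cavity/channel geometries with analytic ground truths.  Every
analysis is validated against those truths.

## Worked example

```python
import numpy as np
from hexadyn import synthetic, tunnels, surface, essential

# a channel of known geometry: radius 2 A, length 10 A
chan = synthetic.generate_toy_geometry("channel", radius=2.0, length=10.0)
path = tunnels.find_tunnels(chan.coordinates, radii=chan.radii,
                            start_point=np.zeros(3), probe_radius=1.0)[0]
print(f"bottleneck {path.bottleneck:.2f} A  cost {path.cost:.3f}  "
      f"throughput {path.throughput:.4f}")

# open vs closed synthetic states: buried interface and subspace overlap
op = synthetic.generate_hexamer_trajectory(synthetic.open_state_spec(seed=1, n_frames=40))
cl = synthetic.generate_hexamer_trajectory(synthetic.closed_state_spec(seed=2, n_frames=40))
ia = lambda t: surface.iasa(t.__class__(topology=t.topology, coordinates=t.coordinates[:2]),
                            group_a={"A","B","C"}, group_b={"D","E","F"},
                            n_points=240).iasa.mean()
print(f"IASA open {ia(op):.0f} A^2  closed {ia(cl):.0f} A^2")
comp = essential.compare_subspaces(
    essential.fit_pca(op, mask=op.topology.mask(name="CA")),
    essential.fit_pca(cl, mask=cl.topology.mask(name="CA")), k=10)
print(f"subspace overlap {comp.subspace_overlap_percent:.1f}%  "
      f"average max dot {comp.average_max_dot:.2f}")
```

prints

```
bottleneck 2.00 A  cost 2.542  throughput 0.0787
IASA open 331 A^2  closed 937 A^2
subspace overlap 10.5%  average max dot 0.07
```

The channel's scores sit on their closed forms (cost L/r^2 = 2.5,
throughput e^-2.5 ~ 0.082; the small excess is the grid path's exit
segment).  The closed state buries ~3x more trimer-trimer interface than
the open state, while the two states share only a small fraction of their
essential-dynamics subspace — the signatures that separate the states when
plain RMSD/Rg cannot.

The `analysis/` directory holds the numbered study drivers
(`01_generate_fixtures.py` ... `06_state_discrimination_cvae.py`); each
writes its tables under `results/` and prints what it found.  A `hexadyn`
command-line interface wraps the same library calls
(`hexadyn synth`, `hexadyn rmsd --fraction 0.7`, `hexadyn tunnels --start
x,y,z`, `hexadyn run`, ...).

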