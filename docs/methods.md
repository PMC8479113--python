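# Methods

`hexadyn` re-implements, as a tested pipeline, the comparative
trajectory-analysis toolchain used to distinguish the open (deoxygenated)
from the closed (oxygenated) dynamics of a hemocyanin-like homo-hexamer:
robust core alignment, dynamic cross-correlation, essential dynamics with
subspace comparison, solvent-accessible and buried interface surface area,
grid-based cavity detection, tunnel geometry with bottleneck/throughput
scoring, and CVAE latent-space state discrimination.  Because the original
microsecond-scale trajectories of the 3768-residue hexamer are not publicly
deposited, all quantitative validation is property-based: each method runs
on synthetic inputs whose correct answer is known analytically, by
construction, or from an independent brute-force oracle.

## The synthetic hexamer

The generator emulates the statistical structure the analyses assume, not
the physics of a real protein.

* **Architecture.** Six subunits in two concentric trimeric rings (a
  dimer-of-trimers).  Each subunit is a Calpha-only bead shell (default 60
  beads, Bondi carbon radius 1.70 A) on a sphere of radius 7 A
  (closed) or 8 A (open), built from a golden-angle lattice so bead density
  is uniform and deterministic.  An aperture (a removed spherical cap facing
  radially outward; half-angle 34 deg closed, 38 deg open — the closed mouth
  stays probe-passable in every noise realization, just narrower) is the
  subunit's tunnel mouth.  Inside each shell sits a di-metal site: two metal beads
  (radius 1.40 A) flanked by six pseudo-histidine nitrogen beads — 36 site
  beads across the hexamer, mirroring the six metal-coordinating histidines
  per subunit of the real protein.
* **Modes.** The open state's collective mode is the counter-rotation of
  the two rings about the hexamer axis; the closed state's is a clam-shell
  hinge between adjacent subunits in each ring.  Both follow one full sine
  period over the trajectory (zero-mean displacement, a clean rank-one
  covariance contribution), with amplitude 6 deg by default.
* **Noise.** Isotropic i.i.d. Gaussian displacement per atom per frame
  (sd 0.3 A per coordinate), uncorrelated in time.  This makes DCCM and PCA
  expectations analytically checkable: independent atoms decorrelate as
  1/sqrt(frames), RMSF tends to sigma*sqrt(3).
* **State contrast.** The open packing (ring radius 13 A, ring separation
  16 A) versus closed (11 A, 13 A) encodes the study's direction of
  effects: the closed state buries more trimer-trimer interface; the open
  state has a larger internal cavity (larger shell) and a wider tunnel
  (larger aperture).  These are generator *conditions*, fixed once; the
  tests assert only the sign of each contrast, never tuned magnitudes.
* **What it does not emulate.** No secondary structure, no force field, no
  solvent, no anharmonic or time-correlated dynamics, no realistic packing
  of 628-residue subunits.  Passing tests therefore demonstrate that the
  *methods* recover planted signals of realistic shape and size — not that
  the biological conclusions transfer to real trajectories.

Determinism: every stochastic element draws from `numpy.random.default_rng`
seeded from the generator parameters; identical seeds give
bitwise-identical trajectories.

## Alignment and mobility

Superposition is standard Kabsch SVD (proper rotation enforced).  Core
alignment iterates: align all frames on the current core, rank atoms by
mean displacement from the trajectory-average structure (ties broken by
atom index), re-select the requested fraction with the smallest
displacements, and stop when the core set is stable or the core RMSD moves
by < 1e-4 A (max 100 iterations; non-convergence is flagged, not fatal).
Mean displacement (not max) is the ranking statistic because it is stable
under the i.i.d. noise model.  RMSF is computed after two rounds of
mean-structure alignment; Rg is mass-unweighted by default since all
analyses are Calpha-based.

## Cross-correlation and essential dynamics

The correlation is the normalized scalar product of 3-vector displacements
(not per-axis correlation), with frames aligned to the mean structure first
— without alignment, global rotation dominates the map.  Zero-fluctuation
atoms get zeroed rows (diagonal 1) with a logged warning rather than NaNs.

PCA eigendecomposes the 3n x 3n coordinate covariance (mass-unweighted,
after the same iterative alignment).  Subspace similarity between two
systems is reported as the k x k matrix of absolute eigenvector dot
products, the RMSIP of the top-k modes (k = 10 by default), and the average
maximum dot product; "subspace overlap" is RMSIP x 100%, the standard
essential-dynamics convention, and output metadata records k and whether
fits were separate or on concatenated trajectories.

## Surface areas

SASA is Shrake–Rupley quadrature with a deterministic golden-angle point
lattice (960 points by default, seed-free), water probe 1.4 A, Bondi radii,
and cKDTree neighbour search.  The buried interface between two chain
groups is IASA = ASA(A) + ASA(B) − ASA(A∪B); it is non-negative by
construction up to quadrature noise and vanishes when the groups are
farther apart than twice the probe-expanded radius.

## Cavity detection

A voxel grid (default 0.8 A; 0.5 A for volume oracles) covers the masked
atoms.  Clearance is the exact distance to the nearest atom surface.  Seed
voxels have clearance in [probe_min, probe_max] = [1.0, 3.5] A (passable by
a small molecule, excluded from bulk) and pass a burial test: of 14
axis/diagonal rays, at least 9 are blocked within 12 A, where "blocked"
means the ray meets probe-impassable space (clearance < probe_min) — using
atom interiors alone would let zero-width rays thread between beads of any
coarse-grained structure.  The pocket region is the morphological
probe-opening around the seeds (dilation by a probe_min ball intersected
with free space), so a cavity's detected volume matches its geometric
volume rather than its probe-eroded core; components below 5 voxels are
dropped.  Both cumulative-volume definitions are emitted and labelled:
union over frames of ever-open voxels, and the sum of per-frame volumes.

## Tunnels

Tunnel search runs on a 26-connected voxel graph over admissible nodes
(clearance >= probe radius, default 1.0 A).  An edge of length dl costs
dl * (r_u^-2 + r_v^-2)/2, the discrete form of the transport cost integral
of r(l)^-2 along the path; Dijkstra from the start node therefore finds
lowest-cost escape routes.  Nodes with clearance >= 4 A count as bulk
solvent and are sinks (no bulk–bulk edges), so a route cannot shortcut
through open solvent.  One candidate tunnel is taken per first entry into
bulk along the shortest-path tree, trimmed back to the molecular surface
(approximated by the convex hull of the atoms — without trimming, the
escape segment beyond the channel mouth inflates the cost of even an ideal
cylinder by ~20%), lightly smoothed, re-profiled against exact clearances,
and scored: length, clearance profile r(l), bottleneck = min r(l), cost by
trapezoidal integration of r(l)^-2, throughput = exp(−cost).  The lattice
is anchored on the start point so the start lies exactly on a node;
near-duplicate escape routes are deduplicated by centerline distance.
Tunnels across frames are clustered by average-linkage on the symmetrized
mean closest-point distance between 64-point resampled centerlines, cut at
4.0 A.  This threshold is in Angstrom and is *not* numerically comparable
to thresholds of Voronoi-based tools, whose clustering distance lives in a
different unit.  Clusters are ranked by average bottleneck then average
throughput, and lining residues are those whose vdW surface comes within a
cutoff (default 2 A) of a member tunnel's clearance-sphere surface.

## CVAE

Inputs are per-frame pairwise distance matrices over a fixed residue set
(the 36 site pseudo-histidines; 36 x 36), min-max normalized per dataset,
split 80:20 into train/validation with a stated seed.  The network is an
hourglass: three stride-2 3x3 convolutions (8, 16, 32 channels), dense 64,
then latent mean and log-variance; the decoder mirrors it with transposed
convolutions and a sigmoid output.  The loss is summed squared
reconstruction error plus the KL divergence of the latent posterior against
a unit normal, optimized with Adam (lr 1e-3, batch 32).  The
implementation is plain numpy with hand-written backpropagation; all layer
gradients are verified against central finite differences in the test
suite (worst relative deviation < 1e-5).  Training is deterministic under
a fixed seed and aborts with diagnostics on non-finite loss.  A latent
dimension scan (3–10 by default) trains one model per dimension under
identical seeds and reports the argmin of final validation loss.  Frames
are embedded by their latent means; 2D/3D projections use seeded t-SNE, or
a deterministic PCA projection of the latent cloud for tests.  State
separation is quantified by the silhouette score of the true labels in
latent space against a label-permutation null.

## Problem sizes and defaults

Defaults keep every analysis sub-minute on one CPU: 60-frame trajectories
for alignment/DCCM/PCA, 4–8 frames for surface and cavity series, single
frames for tunnel searches (grids of ~10^5–10^6 voxels), 200 frames per
state and 15–40 epochs for CVAE runs.  All parameters are explicit
function arguments recorded in run metadata, so larger runs are a config
change, not a code change.

## Known limitations

* The voxel clearance is exact, but bottleneck and volume estimates carry
  O(spacing) discretization error; the tests bound it (bottleneck within
  one grid spacing, cavity volume within 10% at 0.5 A spacing).
* The convex-hull surface proxy overestimates the molecular surface for
  strongly concave envelopes; for the fixtures used here the bias is well
  inside the tested tolerances.
* The burial rule (9 of 14 rays within 12 A) is a heuristic chosen to pass
  the geometric oracles; it is configurable and logged, and no claim is
  made that it matches any particular pocket tool's decision boundary.
* The CVAE is CPU-sized (tens of thousands of parameters); it demonstrates
  state discrimination on 36 x 36 inputs, not scalability to larger
  contact maps.
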