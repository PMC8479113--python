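import numpy as np
import pytest

from hexadyn import align, dccm, synthetic
from hexadyn.errors import GeometryError, ParameterError
from hexadyn.trajio import Topology, Trajectory

from conftest import random_rotation


def _traj_from_coords(coords: np.ndarray) -> Trajectory:
    n = coords.shape[1]
    topo = Topology(
        atom_names=np.array(["CA"] * n),
        residue_indices=np.arange(n),
        residue_names=np.array(["GLY"] * n),
        chain_ids=np.array(["A"] * n),
        vdw_radii=np.full(n, 1.7),
        masses=np.full(n, 12.011),
    )
    return Trajectory(topology=topo, coordinates=coords)


class TestKabsch:
    def test_self_superposition_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 3))
        rot, trans, rmsd = align.kabsch_superpose(x, x)
        assert rmsd < 1e-12
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((12, 3)) * 5
        applied = random_rotation(rng)
        y = x @ applied.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = align.kabsch_superpose(x, y)
        assert rmsd < 1e-8
        np.testing.assert_allclose(rot, applied, atol=1e-8)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_dense_rotation_grid_oracle(self):
        """Kabsch RMSD equals the brute-force minimum over rotations."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 3))
        y = rng.standard_normal((10, 3))
        _, _, kab = align.kabsch_superpose(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        best = np.inf
        n = 40
        for a in np.linspace(0, 2 * np.pi, n, endpoint=False):
            ca, sa = np.cos(a), np.sin(a)
            rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
            for b in np.linspace(0, np.pi, n // 2):
                cb, sb = np.cos(b), np.sin(b)
                ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
                for g in np.linspace(0, 2 * np.pi, n, endpoint=False):
                    cg, sg = np.cos(g), np.sin(g)
                    rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
                    rot = rz @ ry @ rz2
                    r = np.sqrt(np.mean(np.sum((xc @ rot.T - yc) ** 2, axis=1)))
                    best = min(best, r)
        assert kab <= best + 1e-12
        assert best - kab < 0.05  # grid resolution slack

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(GeometryError):
            align.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            align.kabsch_superpose(line, line)


class TestConventionalRmsd:
    def test_rigid_trajectory_zero(self, rigid_hexamer):
        assert align.conventional_rmsd(rigid_hexamer).max() < 1e-10

    def test_pure_translation_removed(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((20, 3))
        coords = np.stack([base, base + [4.0, -2.0, 9.0]])
        assert align.conventional_rmsd(_traj_from_coords(coords)).max() < 1e-10

    def test_gaussian_noise_mean_matches_analytic_expectation(self):
        """Noisy rigid body: mean RMSD to the (noisy) first frame ~ sigma*sqrt(6)."""
        rng = np.random.default_rng(4)
        sigma = 0.5
        base = rng.standard_normal((2000, 3)) * 20
        coords = base[None] + rng.normal(0, sigma, (20, 2000, 3))
        r = align.conventional_rmsd(_traj_from_coords(coords))
        expected = sigma * np.sqrt(6.0)  # both frames carry noise: 2 * 3 sigma^2
        assert abs(r[1:].mean() / expected - 1) < 0.05

    def test_invariant_under_global_rigid_motion(self, rotating_hexamer):
        rng = np.random.default_rng(5)
        base = align.conventional_rmsd(rotating_hexamer)
        moved = rotating_hexamer.coordinates.copy()
        for k in range(moved.shape[0]):
            moved[k] = moved[k] @ random_rotation(rng).T + rng.standard_normal(3) * 10
        r2 = align.conventional_rmsd(_traj_from_coords(moved[:, :360]))
        np.testing.assert_allclose(
            align.conventional_rmsd(
                _traj_from_coords(rotating_hexamer.coordinates[:, :360])),
            r2, atol=1e-8)


class TestCoreAlign:
    def _planted(self, sigma_core=0.05, sigma_mobile=2.0, n=200, frames=30, seed=6):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((n, 3)) * 15
        n_mobile = int(0.3 * n)
        coords = base[None] + rng.normal(0, sigma_core, (frames, n, 3))
        coords[:, :n_mobile] += rng.normal(0, sigma_mobile, (frames, n_mobile, 3))
        return _traj_from_coords(coords), np.arange(n_mobile, n)

    def test_full_fraction_reproduces_conventional_rmsd(self, rotating_hexamer):
        res = align.core_align(rotating_hexamer, 1.0)
        conv = align.conventional_rmsd(rotating_hexamer)
        np.testing.assert_allclose(res.core_rmsd, conv, atol=1e-10)

    def test_planted_core_recovered(self):
        traj, rigid_set = self._planted()
        res = align.core_align(traj, 0.7)
        found = np.flatnonzero(res.core_mask)
        overlap = np.intersect1d(found, rigid_set).size / rigid_set.size
        assert overlap >= 0.95
        assert res.core_rmsd.mean() <= 0.05 * np.sqrt(6) * 1.5

    def test_rigid_trajectory_converges_immediately(self, rigid_hexamer):
        res = align.core_align(rigid_hexamer, 0.5)
        assert res.converged
        assert res.iterations == 1
        assert res.core_rmsd.max() < 1e-10

    def test_core_rmsd_non_increasing_in_fraction(self):
        traj, _ = self._planted(seed=7)
        vals = [align.core_align(traj, f).core_rmsd.mean()
                for f in (0.9, 0.7, 0.5)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_invalid_fraction(self, rigid_hexamer):
        with pytest.raises(ParameterError):
            align.core_align(rigid_hexamer, 0.0)


class TestRmsf:
    def test_rigid_zero(self, rigid_hexamer):
        assert align.rmsf(rigid_hexamer).rmsf.max() < 1e-10

    def test_isotropic_noise_gives_sigma_sqrt3(self):
        rng = np.random.default_rng(8)
        sigma = 0.4
        base = rng.standard_normal((100, 3)) * 20
        coords = base[None] + rng.normal(0, sigma, (500, 100, 3))
        prof = align.rmsf(_traj_from_coords(coords))
        assert abs(prof.rmsf.mean() / (sigma * np.sqrt(3)) - 1) < 0.05

    def test_planted_mobile_atoms_exceed_rigid(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((100, 3)) * 20
        coords = base[None] + rng.normal(0, 0.05, (50, 100, 3))
        coords[:, :30] += rng.normal(0, 1.0, (50, 30, 3))
        prof = align.rmsf(_traj_from_coords(coords))
        assert prof.rmsf[:30].min() > prof.rmsf[30:].max()

    def test_single_frame_rejected(self, rigid_hexamer):
        single = _traj_from_coords(rigid_hexamer.coordinates[:1, :360])
        with pytest.raises(GeometryError):
            align.rmsf(single)

    def test_sum_rule_against_covariance_trace(self, rotating_hexamer):
        """Sum RMSF_i^2 equals the trace of the aligned displacement covariance."""
        mask = rotating_hexamer.topology.mask(name="CA")
        prof = align.rmsf(rotating_hexamer, mask=mask)
        coords = align.align_to_mean(
            rotating_hexamer.coordinates[:, np.flatnonzero(mask)])
        disp = coords - coords.mean(axis=0)
        trace = np.einsum("fid,fid->", disp, disp) / disp.shape[0]
        assert abs(np.sum(prof.rmsf**2) / trace - 1) < 1e-10


class TestRadiusOfGyration:
    def test_two_equal_masses_give_half_distance(self):
        coords = np.array([[[0.0, 0, 0], [4.0, 0, 0]]])
        traj = _traj_from_coords(coords)
        assert align.radius_of_gyration(traj)[0] == pytest.approx(2.0)

    def test_single_atom_zero(self):
        traj = _traj_from_coords(np.zeros((1, 1, 3)))
        assert align.radius_of_gyration(traj)[0] == 0.0

    def test_uniform_solid_sphere_closed_form(self):
        rng = np.random.default_rng(10)
        R = 5.0
        u = rng.random(100_000)
        pts = R * u[:, None] ** (1 / 3) * synthetic.fibonacci_sphere(100_000)
        traj = _traj_from_coords(pts[None])
        rg = align.radius_of_gyration(traj)[0]
        assert abs(rg / (R * np.sqrt(3 / 5)) - 1) < 0.02
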