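import numpy as np
import pytest

from hexadyn import cvae, synthetic
from hexadyn.cvae import _Network
from hexadyn.errors import ParameterError, StructureError
from hexadyn.trajio import Topology, Trajectory


@pytest.fixture(scope="module")
def two_state_dataset():
    return synthetic.generate_site_distance_dataset(
        synthetic.open_state_spec(seed=1),
        synthetic.closed_state_spec(seed=2),
        frames_per_state=120,
    )


def test_backpropagation_matches_finite_differences():
    """All layer gradients (conv, transposed conv, dense) check numerically."""
    rng = np.random.default_rng(0)
    net = _Network(12, 3, rng)
    x = rng.random((2, 1, 12, 12))
    eps = rng.standard_normal((2, 3))
    net.loss(x, eps, compute_grads=True)
    params = net.encoder.params + net.decoder.params
    analytic = [g.copy() for g in net.encoder.grads + net.decoder.grads]
    worst = 0.0
    for p, g in zip(params, analytic):
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            h = 1e-6
            old = p[idx]
            p[idx] = old + h
            lp = sum(net.loss(x, eps))
            p[idx] = old - h
            lm = sum(net.loss(x, eps))
            p[idx] = old
            num = (lp - lm) / (2 * h)
            worst = max(worst, abs(num - g[idx]) / (abs(num) + abs(g[idx]) + 1e-10))
    assert worst < 1e-5


def test_decoder_output_shape_matches_input():
    rng = np.random.default_rng(1)
    for size in (12, 20, 36):
        net = _Network(size, 4, rng)
        x = rng.random((3, 1, size, size))
        mu, logvar = net.encode(x)
        assert mu.shape == (3, 4)
        y = net.decode(mu)
        assert y.shape == x.shape


class TestBuildDataset:
    def _toy_traj(self, coords):
        n = coords.shape[1]
        topo = Topology(
            atom_names=np.array(["NE2"] * n),
            residue_indices=np.arange(n),
            residue_names=np.array(["HIS"] * n),
            chain_ids=np.array(["A"] * n),
            vdw_radii=np.full(n, 1.55),
            masses=np.full(n, 14.007),
        )
        return Trajectory(topology=topo, coordinates=coords)

    def test_hand_computed_distances(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 0, 0], [0.0, 4.0, 0]]])
        t = self._toy_traj(coords)
        d = cvae.build_dataset(t, t)
        expected = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        np.testing.assert_allclose(d.matrices[0], expected)

    def test_split_is_disjoint_80_20(self, two_state_dataset):
        d = two_state_dataset
        assert len(np.intersect1d(d.train_idx, d.val_idx)) == 0
        assert len(d.train_idx) + len(d.val_idx) == d.n_frames
        assert len(d.val_idx) == round(0.2 * d.n_frames)

    def test_selection_mismatch_rejected(self):
        a = self._toy_traj(np.zeros((1, 3, 3)))
        b = self._toy_traj(np.zeros((1, 4, 3)))
        with pytest.raises(StructureError):
            cvae.build_dataset(a, b)

    def test_uses_36_site_beads_on_hexamer(self, two_state_dataset):
        assert two_state_dataset.size == 36


class TestTraining:
    def test_zero_epochs_records_untrained_baseline(self, two_state_dataset):
        m = cvae.train_cvae(two_state_dataset, latent_dim=4, epochs=0, seed=0)
        assert m.epochs_trained == 0
        assert len(m.loss_history["val_recon"]) == 1
        assert np.isfinite(m.val_loss[0])

    def test_validation_loss_decreases(self, two_state_dataset):
        m = cvae.train_cvae(two_state_dataset, latent_dim=7, epochs=8, seed=0)
        assert m.val_loss[-1] < m.val_loss[0]
        assert len(m.val_loss) == 8

    def test_deterministic_under_seed(self, two_state_dataset):
        a = cvae.train_cvae(two_state_dataset, latent_dim=3, epochs=2, seed=5)
        b = cvae.train_cvae(two_state_dataset, latent_dim=3, epochs=2, seed=5)
        np.testing.assert_array_equal(a.val_loss, b.val_loss)

    def test_constant_dataset_reconstruction_collapses(self):
        mats = np.broadcast_to(
            np.abs(np.random.default_rng(2).standard_normal((36, 36))) + 1.0,
            (80, 36, 36)).copy()
        mats = 0.5 * (mats + np.transpose(mats, (0, 2, 1)))
        for m in mats:
            np.fill_diagonal(m, 0.0)
        d = cvae.DistanceMatrixDataset(
            matrices=mats, labels=np.zeros(80, int),
            train_idx=np.arange(64), val_idx=np.arange(64, 80),
            norm_min=float(mats.min()), norm_max=float(mats.max()))
        m0 = cvae.train_cvae(d, latent_dim=3, epochs=0, seed=0)
        m1 = cvae.train_cvae(d, latent_dim=3, epochs=150, seed=0)
        assert m1.loss_history["val_recon"][-1] < 0.2 * m0.loss_history["val_recon"][0]

    def test_too_few_frames_rejected(self):
        d = cvae.DistanceMatrixDataset(
            matrices=np.zeros((10, 8, 8)), labels=np.zeros(10, int),
            train_idx=np.arange(8), val_idx=np.arange(8, 10))
        with pytest.raises(ParameterError):
            cvae.train_cvae(d, latent_dim=2, epochs=1, batch_size=32)


class TestScanAndEmbed:
    def test_scan_reports_argmin_and_dedupes(self, two_state_dataset):
        with pytest.warns(UserWarning):
            table, best, models = cvae.scan_latent_dims(
                two_state_dataset, [3, 5, 3], epochs=2, seed=0)
        assert len(table) == 2
        assert best in (3, 5)
        assert best == int(table.loc[table["final_val_loss"].idxmin(), "latent_dim"])

    def test_single_dim_scan(self, two_state_dataset):
        table, best, _ = cvae.scan_latent_dims(two_state_dataset, [4], epochs=1,
                                               seed=0)
        assert best == 4 and len(table) == 1

    def test_embed_separates_states(self, two_state_dataset):
        from sklearn.metrics import silhouette_score

        m = cvae.train_cvae(two_state_dataset, latent_dim=7, epochs=10, seed=0)
        emb = cvae.embed(m, two_state_dataset, method="linear")
        assert emb.latent.shape == (two_state_dataset.n_frames, 7)
        assert silhouette_score(emb.latent, emb.labels) > 0.3

    def test_tiny_dataset_skips_tsne_with_warning(self):
        mats = np.zeros((2, 8, 8))
        d = cvae.DistanceMatrixDataset(
            matrices=mats, labels=np.zeros(2, int),
            train_idx=np.arange(2), val_idx=np.empty(0, int))
        m = cvae.train_cvae(d, latent_dim=4, epochs=0)
        with pytest.warns(UserWarning):
            emb = cvae.embed(m, d, method="tsne")
        assert emb.proj2d is None


class TestReconstructionReport:
    def test_errors_nonnegative_and_trained_beats_untrained(self, two_state_dataset):
        untrained = cvae.train_cvae(two_state_dataset, latent_dim=7, epochs=0,
                                    seed=0)
        trained = cvae.train_cvae(two_state_dataset, latent_dim=7, epochs=100,
                                  seed=0)
        mae_u, orig, rec = cvae.reconstruction_report(untrained, two_state_dataset)
        mae_t, _, _ = cvae.reconstruction_report(trained, two_state_dataset)
        assert (mae_u >= 0).all() and (mae_t >= 0).all()
        assert rec.shape == orig.shape
        assert mae_t.mean() <= 0.5 * mae_u.mean()
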