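"""Convolutional variational autoencoder on residue distance matrices.

Per-frame pairwise distance matrices over a fixed residue set (by default
the 36 metal-coordinating pseudo-histidines, six per subunit) are min-max
normalized and compressed through an hourglass network: three stride-2
convolutions, a dense bottleneck, and a latent mean/log-variance pair whose
KL divergence against a unit normal regularizes the latent space; the
decoder mirrors the encoder with transposed convolutions.  Training
minimizes summed squared reconstruction error plus the KL term.  Latent
means per frame are projected to 2D/3D with t-SNE (or a deterministic
linear projection) for state discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._nn import (Adam, Conv2d, ConvTranspose2d, Dense, Flatten, ReLU,
                  Reshape, Sequential, Sigmoid)
from .errors import HexadynError, ParameterError, StructureError
from .trajio import Trajectory


@dataclass
class DistanceMatrixDataset:
    """Per-frame square distance matrices with labels and an 80:20 split."""

    matrices: np.ndarray          # (n_frames, m, m), Angstrom
    labels: np.ndarray            # (n_frames,), int state labels
    train_idx: np.ndarray
    val_idx: np.ndarray
    norm_min: float = 0.0
    norm_max: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.matrices.shape[0]

    @property
    def size(self) -> int:
        return self.matrices.shape[1]

    def normalized(self) -> np.ndarray:
        """Min-max normalized matrices with a channel axis: (n, 1, m, m)."""
        span = self.norm_max - self.norm_min
        if span <= 0:
            span = 1.0
        x = (self.matrices - self.norm_min) / span
        return x[:, None, :, :]

    def denormalize(self, x: np.ndarray) -> np.ndarray:
        return x * (self.norm_max - self.norm_min) + self.norm_min


def distance_matrices(traj: Trajectory, atom_indices: np.ndarray) -> np.ndarray:
    """Per-frame pairwise distance matrices over the selected atoms."""
    idx = np.asarray(atom_indices, int)
    out = np.empty((traj.n_frames, idx.size, idx.size))
    for k in range(traj.n_frames):
        pts = traj.coordinates[k, idx]
        out[k] = cdist(pts, pts)
    return out


def build_dataset(
    traj_a: Trajectory,
    traj_b: Trajectory,
    name: str = "NE2",
    resname: str | None = None,
    split_seed: int = 0,
    val_fraction: float = 0.2,
) -> DistanceMatrixDataset:
    """Labeled distance-matrix dataset from two trajectories.

    The residue selection (atom name / residue name) must resolve to the same
    atom count in both trajectories; state labels are 0 for ``traj_a`` and 1
    for ``traj_b``.  The train/validation split is drawn with ``split_seed``.
    """
    ia = np.flatnonzero(traj_a.topology.mask(name=name, resname=resname))
    ib = np.flatnonzero(traj_b.topology.mask(name=name, resname=resname))
    if ia.size != ib.size:
        raise StructureError(
            f"selection resolves to {ia.size} atoms in A but {ib.size} in B"
        )
    if ia.size == 0:
        raise ParameterError("selection is empty")
    ma = distance_matrices(traj_a, ia)
    mb = distance_matrices(traj_b, ib)
    mats = np.concatenate([ma, mb])
    labels = np.concatenate([np.zeros(len(ma), int), np.ones(len(mb), int)])
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(len(mats))
    n_val = int(round(val_fraction * len(mats)))
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    return DistanceMatrixDataset(
        matrices=mats,
        labels=labels,
        train_idx=train_idx,
        val_idx=val_idx,
        norm_min=float(mats.min()) if mats.size else 0.0,
        norm_max=float(mats.max()) if mats.size else 1.0,
    )


class _Network:
    """Encoder/decoder pair for a given input size and latent dimension."""

    def __init__(self, size: int, latent_dim: int, rng) -> None:
        if size != 36:
            # generic: derive the conv stack output size for any input
            pass
        s1 = (size + 2 - 3) // 2 + 1
        s2 = (s1 + 2 - 3) // 2 + 1
        s3 = (s2 + 2 - 3) // 2 + 1
        self.conv_out = (32, s3, s3)
        flat = 32 * s3 * s3
        self.encoder = Sequential([
            Conv2d(1, 8, 3, 2, 1, rng), ReLU(),
            Conv2d(8, 16, 3, 2, 1, rng), ReLU(),
            Conv2d(16, 32, 3, 2, 1, rng), ReLU(),
            Flatten(),
            Dense(flat, 64, rng), ReLU(),
            Dense(64, 2 * latent_dim, rng),
        ])
        op2 = 1 if (s2 - 1) * 2 - 2 + 3 != s1 else 0
        op1 = 1 if (s1 - 1) * 2 - 2 + 3 != size else 0
        op3 = 1 if (s3 - 1) * 2 - 2 + 3 != s2 else 0
        self.decoder = Sequential([
            Dense(latent_dim, 64, rng), ReLU(),
            Dense(64, flat, rng), ReLU(),
            Reshape(self.conv_out),
            ConvTranspose2d(32, 16, 3, 2, 1, op3, rng), ReLU(),
            ConvTranspose2d(16, 8, 3, 2, 1, op2, rng), ReLU(),
            ConvTranspose2d(8, 1, 3, 2, 1, op1, rng), Sigmoid(),
        ])
        self.latent_dim = latent_dim

    @property
    def params(self) -> list:
        return self.encoder.params + self.decoder.params

    @property
    def grads(self) -> list:
        return self.encoder.grads + self.decoder.grads

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.encoder.forward(x)
        return h[:, : self.latent_dim], h[:, self.latent_dim:]

    def decode(self, z: np.ndarray) -> np.ndarray:
        return self.decoder.forward(z)

    def loss(self, x: np.ndarray, eps: np.ndarray,
             compute_grads: bool = False) -> tuple[float, float]:
        """Reconstruction (summed SE per sample) + KL, averaged over batch.

        When ``compute_grads`` the layer gradients are populated by
        backpropagation.
        """
        n = x.shape[0]
        mu, logvar = self.encode(x)
        logvar = np.clip(logvar, -10, 10)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std
        y = self.decode(z)
        recon = float(np.sum((y - x) ** 2) / n)
        kl = float(-0.5 * np.sum(1 + logvar - mu**2 - np.exp(logvar)) / n)
        if compute_grads:
            dy = 2.0 * (y - x) / n
            dz = self.decoder.backward(dy)
            dmu = dz + mu / n
            dlogvar = dz * 0.5 * eps * std + 0.5 * (np.exp(logvar) - 1.0) / n
            self.encoder.backward(np.concatenate([dmu, dlogvar], axis=1))
        return recon, kl


@dataclass
class CVAEModel:
    network: _Network
    latent_dim: int
    seed: int
    loss_history: dict = field(default_factory=lambda: {
        "train_recon": [], "train_kl": [], "val_recon": [], "val_kl": []})
    epochs_trained: int = 0

    @property
    def train_loss(self) -> np.ndarray:
        return np.asarray(self.loss_history["train_recon"]) + np.asarray(
            self.loss_history["train_kl"])

    @property
    def val_loss(self) -> np.ndarray:
        return np.asarray(self.loss_history["val_recon"]) + np.asarray(
            self.loss_history["val_kl"])

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.network.encode(x)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        mu, _ = self.network.encode(x)
        return self.network.decode(mu)


def train_cvae(
    d: DistanceMatrixDataset,
    latent_dim: int = 7,
    epochs: int = 100,
    batch_size: int = 32,
    seed: int = 0,
    lr: float = 1e-3,
) -> CVAEModel:
    """Train the CVAE on the dataset's training split.

    Deterministic under a fixed seed.  ``epochs=0`` returns the untrained
    model with its (random-weight) validation baseline recorded.  Aborts
    with diagnostics if the loss turns non-finite.
    """
    if len(d.train_idx) < 2 * batch_size and epochs > 0:
        raise ParameterError("need at least 2*batch_size training frames")
    rng = np.random.default_rng(seed)
    net = _Network(d.size, latent_dim, rng)
    model = CVAEModel(network=net, latent_dim=latent_dim, seed=seed)
    x = d.normalized()
    x_train, x_val = x[d.train_idx], x[d.val_idx]

    def _eval(batch: np.ndarray) -> tuple[float, float]:
        # evaluation uses the latent mean (eps = 0)
        return net.loss(batch, np.zeros((batch.shape[0], latent_dim)))

    if epochs == 0:
        r, k = _eval(x_val if len(x_val) else x_train)
        model.loss_history["val_recon"].append(r)
        model.loss_history["val_kl"].append(k)
        return model

    opt = Adam(net.params, lr=lr)
    n = len(x_train)
    for epoch in range(epochs):
        perm = rng.permutation(n)
        ep_recon = ep_kl = 0.0
        n_batches = 0
        for s in range(0, n - batch_size + 1, batch_size):
            batch = x_train[perm[s:s + batch_size]]
            eps = rng.standard_normal((batch.shape[0], latent_dim))
            recon, kl = net.loss(batch, eps, compute_grads=True)
            if not np.isfinite(recon + kl):
                raise HexadynError(
                    f"loss diverged at epoch {epoch} (recon={recon}, kl={kl})"
                )
            opt.step(net.grads)
            ep_recon += recon
            ep_kl += kl
            n_batches += 1
        vr, vk = _eval(x_val) if len(x_val) else (np.nan, np.nan)
        model.loss_history["train_recon"].append(ep_recon / n_batches)
        model.loss_history["train_kl"].append(ep_kl / n_batches)
        model.loss_history["val_recon"].append(vr)
        model.loss_history["val_kl"].append(vk)
        model.epochs_trained = epoch + 1
    return model


def scan_latent_dims(
    d: DistanceMatrixDataset,
    dims: list[int],
    epochs: int = 100,
    batch_size: int = 32,
    seed: int = 0,
):
    """Train one model per latent dimension; report final validation losses.

    Returns (table, best_dim, models).  Duplicate dims are deduplicated with
    a warning.
    """
    import pandas as pd

    uniq = list(dict.fromkeys(dims))
    if len(uniq) != len(dims):
        warnings.warn("duplicate latent dimensions removed from scan")
    rows = []
    models = {}
    for dim in uniq:
        m = train_cvae(d, latent_dim=dim, epochs=epochs, batch_size=batch_size,
                       seed=seed)
        models[dim] = m
        rows.append({
            "latent_dim": dim,
            "final_val_loss": float(m.val_loss[-1]),
            "final_val_recon": m.loss_history["val_recon"][-1],
            "final_train_loss": float(m.train_loss[-1]),
        })
    table = pd.DataFrame(rows)
    best_dim = int(table.loc[table["final_val_loss"].idxmin(), "latent_dim"])
    return table, best_dim, models


@dataclass
class LatentEmbedding:
    latent: np.ndarray           # (n_frames, latent_dim) latent means
    proj2d: np.ndarray | None    # (n_frames, 2)
    proj3d: np.ndarray | None    # (n_frames, 3)
    labels: np.ndarray
    method: str = "tsne"


def embed(
    m: CVAEModel,
    d: DistanceMatrixDataset,
    method: str = "tsne",
    perplexity: float = 30.0,
    seed: int = 0,
) -> LatentEmbedding:
    """Latent means per frame plus a 2D/3D projection for visualization.

    ``method='linear'`` uses the top principal components of the latent
    cloud (deterministic); t-SNE is skipped with a warning when there are
    too few frames for the requested perplexity.
    """
    x = d.normalized()
    mu, _ = m.encode(x)
    proj2d = proj3d = None
    if m.latent_dim <= 3:
        method = "linear"
    if method == "linear":
        centered = mu - mu.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj2d = centered @ vt[:2].T
        proj3d = centered @ vt[:3].T if vt.shape[0] >= 3 else None
    elif method == "tsne":
        if d.n_frames <= 5 or d.n_frames <= perplexity + 1:
            warnings.warn("too few frames for t-SNE; projections skipped")
        else:
            from sklearn.manifold import TSNE

            for n_comp, attr in ((2, "proj2d"), (3, "proj3d")):
                ts = TSNE(n_components=n_comp, perplexity=min(perplexity,
                          (d.n_frames - 2) / 3), random_state=seed,
                          init="pca", method="exact" if n_comp == 3 else "barnes_hut")
                proj = ts.fit_transform(mu)
                if attr == "proj2d":
                    proj2d = proj
                else:
                    proj3d = proj
    else:
        raise ParameterError(f"unknown projection method {method!r}")
    return LatentEmbedding(latent=mu, proj2d=proj2d, proj3d=proj3d,
                           labels=d.labels, method=method)


def reconstruction_report(m: CVAEModel, d: DistanceMatrixDataset):
    """Per-frame mean absolute reconstruction error plus matrix pairs.

    Returns (per-frame MAE on the original distance scale, originals,
    reconstructions).
    """
    x = d.normalized()
    y = m.reconstruct(x)
    orig = d.matrices
    rec = d.denormalize(y[:, 0])
    mae = np.mean(np.abs(rec - orig), axis=(1, 2))
    return mae, orig, rec
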