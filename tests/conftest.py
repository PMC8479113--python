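import numpy as np
import pytest

from hexadyn import synthetic
from hexadyn.trajio import Topology, Trajectory


@pytest.fixture(scope="session")
def rigid_hexamer():
    spec = synthetic.SyntheticSpec(mode="rigid", noise_sd=0.0, n_frames=5, seed=0)
    return synthetic.generate_hexamer_trajectory(spec)


@pytest.fixture(scope="session")
def rotating_hexamer():
    spec = synthetic.SyntheticSpec(
        mode="ring_counter_rotation", mode_amplitude=5.0, noise_sd=0.0,
        n_frames=24, seed=0,
    )
    return synthetic.generate_hexamer_trajectory(spec)


@pytest.fixture
def toy_trajectory():
    """Tiny hand-built 4-atom, 3-frame trajectory."""
    topo = Topology(
        atom_names=np.array(["CA", "CA", "CA", "CA"]),
        residue_indices=np.arange(4),
        residue_names=np.array(["GLY"] * 4),
        chain_ids=np.array(["A", "A", "B", "B"]),
        vdw_radii=np.full(4, 1.7),
        masses=np.full(4, 12.011),
    )
    base = np.array(
        [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [0.0, 3.8, 0.0], [3.8, 3.8, 1.0]]
    )
    coords = np.stack([base, base + [0.1, 0, 0], base - [0, 0.2, 0]])
    return Trajectory(topology=topo, coordinates=coords)


def random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
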