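import numpy as np
import pytest

from hexadyn import synthetic, tunnels
from hexadyn.errors import ParameterError


@pytest.fixture(scope="module")
def cylinder_paths():
    g = synthetic.generate_toy_geometry("channel", radius=2.0, length=10.0)
    return g, tunnels.find_tunnels(
        g.coordinates, radii=g.radii, start_point=np.zeros(3), probe_radius=1.0)


class TestFindTunnels:
    def test_cylinder_cost_and_throughput_closed_form(self, cylinder_paths):
        """Constant radius channel: cost = L / r^2, throughput = e^-cost."""
        g, paths = cylinder_paths
        assert len(paths) == 1
        p = paths[0]
        assert abs(p.cost / g.ground_truth["cost"] - 1) < 0.10
        assert abs(p.throughput / g.ground_truth["throughput"] - 1) < 0.10
        assert abs(p.bottleneck - 2.0) <= 0.6

    def test_path_invariants(self, cylinder_paths):
        _, paths = cylinder_paths
        p = paths[0]
        assert (p.clearances >= 1.0).all()
        assert p.bottleneck <= p.clearances.mean()
        assert 0.0 < p.throughput <= 1.0
        assert p.cost > 0.0

    @pytest.mark.parametrize("spacing", [0.6, 0.8])
    def test_hourglass_bottleneck_within_grid_spacing(self, spacing):
        g = synthetic.generate_toy_geometry(
            "channel", radius=3.0, constriction_radius=1.5, length=12.0)
        paths = tunnels.find_tunnels(g.coordinates, radii=g.radii,
                                     start_point=np.zeros(3), probe_radius=1.0,
                                     spacing=spacing)
        assert paths
        bn = max(p.bottleneck for p in paths)
        assert abs(bn - 1.5) <= spacing

    def test_dijkstra_matches_independent_shortest_path(self):
        """scipy Dijkstra on the tunnel graph equals networkx on the same graph."""
        networkx = pytest.importorskip("networkx")
        g = synthetic.generate_toy_geometry(
            "channel", radius=2.0, length=6.0, wall_extent=3.0)
        gg = tunnels.grid_graph(g.coordinates, g.radii, probe_radius=1.0,
                                spacing=1.0, bulk_clearance=4.0,
                                anchor=np.zeros(3))
        from scipy.sparse.csgraph import dijkstra

        start = int(np.argmin(np.sum(gg.points**2, axis=1)))
        dist = dijkstra(gg.graph, directed=False, indices=start)
        nxg = networkx.from_scipy_sparse_array(gg.graph)
        nxd = networkx.single_source_dijkstra_path_length(nxg, start)
        targets = np.flatnonzero(np.isfinite(dist))[::50]
        for t in targets:
            assert dist[t] == pytest.approx(nxd[int(t)], abs=1e-8)

    def test_dijkstra_matches_exhaustive_enumeration_on_tiny_graph(self):
        """Brute-force enumeration of simple paths agrees to 1e-8."""
        networkx = pytest.importorskip("networkx")
        rng = np.random.default_rng(0)
        # tiny random admissible structure: 2x2x2 grid weights from clearances
        n = 8
        import itertools
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import dijkstra

        nodes = np.array(list(itertools.product([0, 1], repeat=3)), dtype=float)
        clear = rng.uniform(1.0, 3.0, n)
        rows, cols, w = [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(nodes[i] - nodes[j])
                if d < 1.8:
                    rows.append(i)
                    cols.append(j)
                    w.append(d * 0.5 * (clear[i]**-2 + clear[j]**-2))
        graph = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
        dist = dijkstra(graph, directed=False, indices=0)
        nxg = networkx.from_scipy_sparse_array(graph)
        for target in range(1, n):
            best = min(
                sum(nxg[u][v]["weight"] for u, v in zip(path, path[1:]))
                for path in networkx.all_simple_paths(nxg, 0, target)
            )
            assert dist[target] == pytest.approx(best, abs=1e-8)

    def test_start_below_probe_clearance_rejected(self):
        g = synthetic.generate_toy_geometry("channel", radius=2.0, length=10.0)
        # deep inside the wall, far from any admissible node
        with pytest.raises(ParameterError):
            tunnels.find_tunnels(g.coordinates, radii=g.radii,
                                 start_point=np.array([8.0, 8.0, 5.0]),
                                 probe_radius=1.0, snap_radius=1.0)

    def test_throughput_monotone_in_length_and_radius(self):
        """On the cost functional directly: longer -> lower, wider -> higher."""
        def cyl_path(length, radius, n=50):
            line = np.column_stack([np.zeros(n), np.zeros(n),
                                    np.linspace(0, length, n)])
            return tunnels._path_metrics(line, np.full(n, radius), 0)

        assert cyl_path(8, 2.0).throughput > cyl_path(12, 2.0).throughput
        assert cyl_path(10, 2.5).throughput > cyl_path(10, 1.5).throughput


class TestClustering:
    def _fake_path(self, offset, frame=0):
        n = 20
        line = np.column_stack([np.full(n, offset), np.zeros(n),
                                np.linspace(0, 10, n)])
        return tunnels._path_metrics(line, np.full(n, 2.0), frame)

    def test_single_path_single_cluster(self):
        clusters = tunnels.cluster_tunnels([self._fake_path(0.0)])
        assert len(clusters) == 1
        assert clusters[0].n_snapshots == 1

    def test_identical_paths_different_frames_merge(self):
        clusters = tunnels.cluster_tunnels(
            [self._fake_path(0.0, frame=0), self._fake_path(0.0, frame=1)])
        assert len(clusters) == 1
        assert clusters[0].n_snapshots == 2

    def test_distant_paths_split(self):
        clusters = tunnels.cluster_tunnels(
            [self._fake_path(0.0), self._fake_path(30.0)], threshold=4.0)
        assert len(clusters) == 2

    def test_two_planted_channels_give_two_clusters(self):
        g = synthetic.generate_toy_geometry("cavity_two_channels",
                                            cavity_side=8.0, channel_radius=2.0)
        paths = tunnels.find_tunnels(g.coordinates, radii=g.radii,
                                     start_point=np.zeros(3), probe_radius=1.0,
                                     spacing=0.8)
        assert len(paths) >= 2
        clusters = tunnels.cluster_tunnels(paths, threshold=4.0)
        assert len(clusters) == 2

    def test_summary_table_columns(self):
        clusters = tunnels.cluster_tunnels([self._fake_path(0.0)])
        df = tunnels.tunnel_summary(clusters)
        assert list(df.columns) == ["cluster", "n_snapshots",
                                    "average_bottleneck_A", "max_bottleneck_A",
                                    "average_throughput"]


class TestLiningResidues:
    def test_channel_wall_residues_found_and_monotone_in_cutoff(self):
        g = synthetic.generate_toy_geometry("channel", radius=2.0, length=10.0)
        traj = g.as_trajectory()
        paths = tunnels.find_tunnels(g.coordinates, radii=g.radii,
                                     start_point=np.zeros(3), probe_radius=1.0)
        cluster = tunnels.cluster_tunnels(paths)[0]
        small = tunnels.lining_residues(cluster, traj, cutoff=0.5)
        large = tunnels.lining_residues(cluster, traj, cutoff=3.0)
        assert set(small.residue_counts) <= set(large.residue_counts)
        assert len(large.residue_counts) > 0
        # lining atoms sit near the channel wall
        atoms = np.array([traj.coordinates[0][r[1]] for r in small.residue_counts])
        if len(atoms):
            cyl = np.hypot(atoms[:, 0], atoms[:, 1])
            assert np.median(cyl) < 6.0
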