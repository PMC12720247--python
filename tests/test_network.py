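"""Contact scoring, interaction graphs and nearest-neighbor statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmcperm import (contact_graph, coordination_contacts, export_graph,
                     nearest_neighbors, shell_cargo_contact_series)
from bmcperm.network import read_graph
from bmcperm.trajectory import ParticleSet, Trajectory


def logistic(d):
    return 1.0 / (1.0 + np.exp(5.0 * (d - 4.0)))


def brute_force_contacts(a, b):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return logistic(d).sum()


def two_complex_traj(separation, n_frames=1, sites=3, seed=0):
    """Two rigid point clusters with nearest sites exactly `separation` apart."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(-2, 0, (sites, 3))
    base[0] = [0.0, 0.0, 0.0]
    other = base.copy()
    other[:, 0] *= -1
    other[:, 0] += separation
    pos = np.vstack([base, other])
    n = 2 * sites
    ps = ParticleSet(particle_id=np.arange(n),
                     species=np.full(n, "pseudo", dtype=object),
                     role=np.full(n, "cargo", dtype=object),
                     complex_id=np.repeat([0, 1], sites),
                     is_calpha=np.ones(n, bool),
                     coordinates=pos)
    frames = np.tile(pos, (n_frames, 1, 1))
    return Trajectory(np.arange(float(n_frames)), frames, np.zeros(3), True,
                      ps)


class TestCoordinationContacts:
    def test_logistic_midpoint_at_4A(self):
        s = coordination_contacts([[0.0, 0, 0]], [[4.0, 0, 0]])
        assert s.value == pytest.approx(0.5, abs=1e-12)

    def test_distant_pair_contributes_nothing(self):
        s = coordination_contacts([[0.0, 0, 0]], [[100.0, 0, 0]])
        assert s.value == 0.0

    def test_close_pair_value(self):
        s = coordination_contacts([[0.0, 0, 0]], [[3.0, 0, 0]])
        assert s.value == pytest.approx(1 / (1 + np.exp(-5)), rel=1e-9)
        assert s.value == pytest.approx(0.99331, abs=1e-5)

    def test_symmetric_under_group_exchange(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0, 20, (2, 40, 3))
        assert coordination_contacts(a, b).value == \
            pytest.approx(coordination_contacts(b, a).value, rel=1e-12)

    @given(st.floats(min_value=0.5, max_value=11.0),
           st.floats(min_value=0.1, max_value=0.9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_pair_distance(self, d, frac):
        closer = coordination_contacts([[0.0, 0, 0]], [[d * frac, 0, 0]])
        farther = coordination_contacts([[0.0, 0, 0]], [[d, 0, 0]])
        assert closer.value > farther.value

    def test_grid_search_equals_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(0, 40, (60, 3))
            b = rng.uniform(0, 40, (50, 3))
            fast = coordination_contacts(a, b).value
            assert fast == pytest.approx(brute_force_contacts(a, b),
                                         abs=1e-9)

    def test_minimum_image_with_box(self):
        box = np.array([20.0, 20.0, 20.0])
        s = coordination_contacts([[0.5, 0, 0]], [[19.5, 0, 0]], box=box)
        assert s.value == pytest.approx(logistic(1.0), rel=1e-9)


class TestContactGraph:
    def test_contact_at_9A_gives_one_full_weight_edge(self):
        traj = two_complex_traj(9.0, n_frames=4)
        g = contact_graph(traj, cutoff=10.0)
        assert g.number_of_edges() == 1
        assert g[0][1]["weight"] == 1.0
        assert g[0][1]["mean_min_distance"] == pytest.approx(9.0)

    def test_no_edge_beyond_cutoff(self):
        traj = two_complex_traj(12.0)
        g = contact_graph(traj, cutoff=10.0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_clustering_run_gains_edges_over_time(self, cargo_runs):
        on, _ = cargo_runs
        third = on.n_frames // 3
        counts = []
        for lo, hi in ((0, third), (third, 2 * third),
                       (2 * third, on.n_frames)):
            sub = Trajectory(on.times[lo:hi], on.positions[lo:hi],
                             on.box_edges, True, on.particles)
            counts.append(contact_graph(sub).number_of_edges())
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]

    def test_weights_invariant_under_within_complex_relabeling(self):
        traj = two_complex_traj(9.0, sites=4, seed=1)
        perm = np.arange(traj.n_particles)
        perm[:4] = perm[:4][::-1]              # shuffle complex 0's sites
        shuffled = Trajectory(traj.times, traj.positions[:, perm],
                              traj.box_edges, True, ParticleSet(
                                  particle_id=np.arange(traj.n_particles),
                                  species=traj.particles.species[perm],
                                  role=traj.particles.role[perm],
                                  complex_id=traj.particles.complex_id[perm],
                                  is_calpha=traj.particles.is_calpha[perm],
                                  coordinates=traj.positions[0][perm]))
        g1, g2 = contact_graph(traj), contact_graph(shuffled)
        assert g1[0][1]["weight"] == g2[0][1]["weight"]
        assert g1[0][1]["mean_min_distance"] == \
            pytest.approx(g2[0][1]["mean_min_distance"])


class TestNearestNeighbors:
    def test_three_point_complexes_on_a_line(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0], [25.0, 0, 0]])
        cid = np.array([0, 1, 2])
        dists, rank_means, _ = nearest_neighbors(pos, cid, k=2)
        np.testing.assert_allclose(dists, [[10, 25], [10, 15], [15, 25]])
        np.testing.assert_allclose(rank_means, [35 / 3, 65 / 3])

    def test_k_too_large_is_an_error(self):
        pos = np.zeros((3, 3))
        with pytest.raises(ValueError, match="k\\+1"):
            nearest_neighbors(pos, np.arange(3), k=3)

    def test_rank_means_match_all_pairs_sort(self, cargo_runs):
        on, _ = cargo_runs
        pos = on.positions[0]
        cid = on.particles.complex_id
        dists, rank_means, mean_k = nearest_neighbors(pos, cid, k=10)
        # O(n²) oracle over complex min-distances
        ids = np.unique(cid)
        dm = np.full((len(ids), len(ids)), np.inf)
        for i, ci in enumerate(ids):
            for j, cj in enumerate(ids):
                if i < j:
                    d = np.linalg.norm(pos[cid == ci][:, None]
                                       - pos[cid == cj][None], axis=2).min()
                    dm[i, j] = dm[j, i] = d
        oracle = np.sort(dm, axis=1)[:, :10]
        np.testing.assert_allclose(dists, oracle, rtol=1e-12)
        np.testing.assert_allclose(mean_k, oracle.mean())


class TestShellCargoSeries:
    def test_no_cargo_means_zero_cargo_contacts(self):
        n = 10
        pos = np.random.default_rng(0).uniform(0, 10, (2, n, 3))
        ps = ParticleSet(particle_id=np.arange(n),
                         species=np.full(n, "pseudo", dtype=object),
                         role=np.full(n, "shell", dtype=object),
                         complex_id=np.full(n, -1),
                         is_calpha=np.zeros(n, bool), coordinates=pos[0])
        traj = Trajectory(np.arange(2.0), pos, np.zeros(3), True, ps)
        _, sc, cc = shell_cargo_contact_series(traj)
        assert np.all(cc == 0.0) and np.all(sc == 0.0)

    def test_matches_brute_force_pairwise_sums(self):
        rng = np.random.default_rng(6)
        n_shell, n_cargo = 15, 8
        pos = rng.uniform(0, 15, (3, n_shell + n_cargo, 3))
        ps = ParticleSet(
            particle_id=np.arange(n_shell + n_cargo),
            species=np.full(n_shell + n_cargo, "pseudo", dtype=object),
            role=np.array(["shell"] * n_shell + ["cargo"] * n_cargo,
                          dtype=object),
            complex_id=np.array([-1] * n_shell + [0] * 4 + [1] * 4),
            is_calpha=np.zeros(n_shell + n_cargo, bool),
            coordinates=pos[0])
        traj = Trajectory(np.arange(3.0), pos, np.zeros(3), True, ps)
        _, sc, cc = shell_cargo_contact_series(traj)
        for f in range(3):
            shell_pos = pos[f, :n_shell]
            c0 = pos[f, n_shell:n_shell + 4]
            c1 = pos[f, n_shell + 4:]
            assert sc[f] == pytest.approx(
                brute_force_contacts(shell_pos, np.vstack([c0, c1])),
                abs=1e-9)
            assert cc[f] == pytest.approx(brute_force_contacts(c0, c1),
                                          abs=1e-9)

    def test_single_complex_touching_shell(self):
        n = 6
        pos = np.zeros((1, n, 3))
        pos[0, 3:] = [[3.0, 0, 0], [3.5, 0, 0], [4.0, 0, 0]]
        ps = ParticleSet(particle_id=np.arange(n),
                         species=np.full(n, "pseudo", dtype=object),
                         role=np.array(["shell"] * 3 + ["cargo"] * 3,
                                       dtype=object),
                         complex_id=np.array([-1, -1, -1, 0, 0, 0]),
                         is_calpha=np.zeros(n, bool), coordinates=pos[0])
        traj = Trajectory(np.array([0.0]), pos, np.zeros(3), True, ps)
        _, sc, cc = shell_cargo_contact_series(traj)
        assert cc[0] == 0.0 and sc[0] > 0.0


class TestGraphExport:
    def test_empty_graph_round_trips(self, tmp_path):
        import networkx as nx
        g = nx.Graph()
        g.graph["frame_count"] = 0
        path = tmp_path / "empty.gexf"
        export_graph(g, path)
        assert read_graph(path).number_of_nodes() == 0

    @pytest.mark.parametrize("suffix", ["gexf", "graphml"])
    def test_two_node_graph_round_trips(self, tmp_path, suffix):
        import networkx as nx
        g = nx.Graph()
        g.add_node(0, species="pseudo")
        g.add_node(1, species="pseudo")
        g.add_edge(0, 1, weight=0.75, mean_min_distance=8.5)
        path = tmp_path / f"g.{suffix}"
        export_graph(g, path)
        back = read_graph(path)
        assert set(back.nodes) == {0, 1}
        assert back[0][1]["weight"] == pytest.approx(0.75)

    def test_cluster_graph_counts_preserved(self, cargo_runs, tmp_path):
        on, _ = cargo_runs
        g = contact_graph(on)
        path = tmp_path / "cluster.graphml"
        export_graph(g, path)
        back = read_graph(path)
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
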