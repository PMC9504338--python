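"""Residue networks: contacts, shortest paths, betweenness, communities."""

import numpy as np
import pytest

from conftest import make_calpha_trajectory
from oracles import best_two_partition_modularity, exhaustive_shortest_distance
from condyn.network import (build_network, contact_occupancy, edge_betweenness,
                            girvan_newman, intercommunity_connectivity,
                            network_from_weights, optimal_paths, reconstruct_path)
from condyn.trajgen import generate_planted_graph


def _net(edge_weights):
    nodes = sorted({u for e in edge_weights for u in e})
    return network_from_weights(nodes, edge_weights)


def _random_net(rng, n=8, p=0.5):
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(i, j)] = float(rng.uniform(0.1, 2.0))
    return network_from_weights(range(n), edges)


class TestOccupancy:
    def test_permanent_contact_has_unit_occupancy(self):
        frames = np.zeros((20, 3, 3))
        frames[:, 1] = [3.0, 0, 0]
        frames[:, 2] = [0, 20.0, 0]
        traj = make_calpha_trajectory(frames)
        occ = contact_occupancy(traj, cutoff=4.5, mode="calpha", exclude_neighbors=0)
        assert occ[0, 1] == 1.0
        assert occ[0, 2] == 0.0

    @pytest.mark.parametrize("n_in, retained", [(75, True), (74, False)])
    def test_threshold_boundary_inclusive(self, n_in, retained):
        # contact in exactly n_in of 100 frames; the >= 75% rule is inclusive
        frames = np.zeros((100, 3, 3))
        frames[:, 2] = [0, 50.0, 0]
        frames[:n_in, 1] = [3.0, 0, 0]
        frames[n_in:, 1] = [30.0, 0, 0]
        traj = make_calpha_trajectory(frames)
        occ = contact_occupancy(traj, cutoff=4.5, mode="calpha", exclude_neighbors=0)
        assert occ[0, 1] == pytest.approx(n_in / 100)
        net = build_network(occ, np.full((3, 3), 0.5), occupancy_threshold=0.75)
        assert ((0, 1) in net.edges) is retained

    def test_sequence_neighbors_excluded_by_default(self):
        frames = np.zeros((10, 3, 3))
        frames[:, 1] = [3.0, 0, 0]
        frames[:, 2] = [3.0, 3.0, 0]
        traj = make_calpha_trajectory(frames)
        occ = contact_occupancy(traj, cutoff=4.5, mode="calpha")
        assert occ[0, 1] == 0.0 and occ[1, 2] == 0.0 and occ[0, 2] == 1.0

    def test_heavy_atom_mode_uses_closest_atom(self):
        # Calphas far apart but a side-chain-like atom bridges the gap
        from condyn.traj_io import Topology, Trajectory
        top = Topology(names=["CA", "CB", "CA"], resids=np.array([1, 1, 3]),
                       resnames=["ALA"] * 3, chains=["A"] * 3,
                       masses=np.full(3, 12.0), elements=["C"] * 3)
        frames = np.zeros((5, 3, 3))
        frames[:, 0] = [0, 0, 0]
        frames[:, 1] = [6.0, 0, 0]
        frames[:, 2] = [9.0, 0, 0]
        traj = Trajectory(top, frames)
        occ_min = contact_occupancy(traj, cutoff=4.5, mode="heavy-atom-min")
        occ_ca = contact_occupancy(traj, cutoff=4.5, mode="calpha")
        assert occ_min[0, 1] == 1.0    # via CB at 3 A
        assert occ_ca[0, 1] == 0.0     # CA-CA = 9 A


class TestBuild:
    def test_weight_values(self):
        occ = np.array([[0, 1.0, 1.0], [1.0, 0, 0.2], [1.0, 0.2, 0]])
        C = np.array([[1, 1.0, 0.5], [1.0, 1, 0.9], [0.5, 0.9, 1]])
        net = build_network(occ, C, 0.75)
        assert net.edges[(0, 1)].weight == pytest.approx(0.0)          # -log 1
        assert net.edges[(0, 2)].weight == pytest.approx(np.log(2))    # -log 0.5
        assert (1, 2) not in net.edges                                 # occupancy 0.2

    def test_zero_correlation_floored_with_warning(self, caplog):
        occ = np.ones((2, 2)) - np.eye(2)
        C = np.eye(2)
        with caplog.at_level("WARNING"):
            net = build_network(occ, C, 0.75)
        assert net.edges[(0, 1)].weight == pytest.approx(-np.log(1e-6))
        assert "floored" in caplog.text

    def test_edge_set_matches_threshold_rule(self, rng):
        for _ in range(10):
            occ = rng.random((6, 6))
            occ = (occ + occ.T) / 2
            np.fill_diagonal(occ, 0)
            C = np.clip(rng.random((6, 6)), 0.05, 1)
            C = (C + C.T) / 2
            net = build_network(occ, C, 0.5)
            expected = {(i, j) for i in range(6) for j in range(i + 1, 6)
                        if occ[i, j] >= 0.5}
            assert set(net.edges) == expected


class TestShortestPaths:
    def test_triangle_avoids_heavy_edge(self):
        net = _net({(0, 1): 1.0, (1, 2): 1.0, (0, 2): 3.0})
        dist, pred, _ = optimal_paths(net)
        assert dist[0, 2] == pytest.approx(2.0)
        assert reconstruct_path(pred, 0, 2) == [0, 1, 2]

    def test_single_edge_symmetric(self):
        net = _net({(0, 1): 0.7})
        dist, _, _ = optimal_paths(net)
        assert dist[0, 1] == dist[1, 0] == pytest.approx(0.7)

    def test_unreachable_marked_infinite(self):
        net = network_from_weights([0, 1, 2], {(0, 1): 1.0})
        dist, pred, _ = optimal_paths(net)
        assert np.isinf(dist[0, 2]) and pred[0, 2] == -1

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            net = _random_net(rng)
            dist, _, _ = optimal_paths(net)
            for a in range(8):
                for b in range(a + 1, 8):
                    assert dist[a, b] == pytest.approx(
                        exhaustive_shortest_distance(net.nodes, net.weight_dict(), a, b))

    def test_triangle_inequality_and_symmetry(self, rng):
        net = _random_net(rng, p=0.7)
        dist, _, _ = optimal_paths(net)
        assert np.allclose(dist, dist.T)
        n = len(net.nodes)
        for k in range(n):
            assert np.all(dist <= dist[:, [k]] + dist[[k], :] + 1e-12)


class TestBetweenness:
    def test_single_edge_carries_one_pair(self):
        assert edge_betweenness(_net({(0, 1): 1.0}))[(0, 1)] == pytest.approx(1.0)

    def test_path_graph_hand_enumeration(self):
        # pairs {a,b},{a,c} traverse ab; {b,c},{a,c} traverse bc
        eb = edge_betweenness(_net({(0, 1): 1.0, (1, 2): 1.0}))
        assert eb[(0, 1)] == pytest.approx(2.0)
        assert eb[(1, 2)] == pytest.approx(2.0)

    def test_bridge_between_cliques_is_maximal(self):
        _, edges, _ = generate_planted_graph((5, 5), intra_weight=1.0,
                                             inter_edges=[(4, 5)], inter_weight=1.0)
        net = network_from_weights(range(10), edges)
        eb = edge_betweenness(net)
        assert eb[(4, 5)] == pytest.approx(25.0)   # all 5x5 cross pairs
        others = [b for e, b in eb.items() if e != (4, 5)]
        assert eb[(4, 5)] > max(others)

    def test_tie_splitting_shares_pair_weight(self):
        # square: two co-optimal paths between opposite corners
        eb = edge_betweenness(_net({(0, 1): 1.0, (1, 3): 1.0, (0, 2): 1.0, (2, 3): 1.0}))
        assert eb[(0, 1)] == pytest.approx(1.0 + 0.5 + 0.5)
        total = sum(eb.values())
        # each adjacent pair contributes 1 edge, each diagonal pair 2 edges
        assert total == pytest.approx(4 * 1 + 2 * 2)

    def test_agrees_with_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(10):
            net = _random_net(rng, p=0.6)
            G = nx.Graph()
            G.add_nodes_from(net.nodes)
            for (u, v), d in net.edges.items():
                G.add_edge(u, v, weight=d.weight)
            ref = nx.edge_betweenness_centrality(G, weight="weight", normalized=False)
            eb = edge_betweenness(net)
            for e, b in eb.items():
                assert b == pytest.approx(ref[e if e in ref else (e[1], e[0])], abs=1e-9)

    def test_integer_mode_counts_whole_pairs(self):
        eb = edge_betweenness(_net({(0, 1): 1.0, (1, 3): 1.0, (0, 2): 1.0, (2, 3): 1.0}),
                              tie_mode="single")
        assert all(float(b).is_integer() for b in eb.values())
        assert sum(eb.values()) == pytest.approx(4 + 2 * 2)


class TestGirvanNewman:
    def test_two_cliques_recovered_exactly(self):
        # uniform weights so weighted modularity coincides with the
        # unweighted brute-force oracle
        _, edges, blocks = generate_planted_graph((5, 5), intra_weight=1.0,
                                                  inter_edges=[(4, 5)],
                                                  inter_weight=1.0)
        net = network_from_weights(range(10), edges)
        part = girvan_newman(net)
        assert [sorted(c) for c in part.communities] == blocks
        # brute-force modularity oracle agrees this 2-split is optimal
        q_best, part_best = best_two_partition_modularity(net.nodes, set(net.edges))
        assert part_best == blocks
        assert part.modularity == pytest.approx(q_best, abs=1e-9)

    def test_three_blocks_with_two_bridges(self):
        _, edges, blocks = generate_planted_graph((4, 4, 4),
                                                  inter_edges=[(3, 4), (7, 8)])
        net = network_from_weights(range(12), edges)
        part = girvan_newman(net)
        assert [sorted(c) for c in part.communities] == blocks

    def test_single_clique_stays_whole(self):
        _, edges, _ = generate_planted_graph((6,))
        net = network_from_weights(range(6), edges)
        part = girvan_newman(net)
        assert part.communities == [list(range(6))]

    def test_small_appendage_discarded(self):
        _, edges, _ = generate_planted_graph((5, 5), inter_edges=[(4, 5)])
        edges[(10, 11)] = 1.0
        edges[(4, 10)] = 1.0        # 2-node appendage hanging off clique 1
        net = network_from_weights(range(12), edges)
        part = girvan_newman(net, min_community_size=3)
        assert [10, 11] in part.discarded
        assert all(len(c) >= 3 for c in part.communities)

    def test_modularity_at_least_trivial(self, rng):
        from condyn.network import modularity
        net = _random_net(rng, p=0.4)
        part = girvan_newman(net)
        trivial = modularity(net, [net.nodes])
        assert part.modularity >= trivial - 1e-12


class TestConnectivity:
    def test_two_clique_fixture_single_entry(self):
        _, edges, blocks = generate_planted_graph((5, 5), inter_edges=[(4, 5)])
        net = network_from_weights(range(10), edges)
        conn = intercommunity_connectivity(blocks, net)
        assert conn[0, 1] == pytest.approx(25.0)
        assert conn[0, 0] == 0.0 and conn[1, 0] == conn[0, 1]

    def test_single_community_empty_table(self):
        _, edges, _ = generate_planted_graph((4,))
        net = network_from_weights(range(4), edges)
        conn = intercommunity_connectivity([list(range(4))], net)
        assert conn.shape == (1, 1) and conn.sum() == 0.0

    def test_totals_match_crossing_edge_resummation(self, rng):
        net = _random_net(rng, p=0.6)
        comms = [[0, 1, 2], [3, 4], [5, 6, 7]]
        conn = intercommunity_connectivity(comms, net)
        eb = edge_betweenness(net)
        comm_of = {u: i for i, c in enumerate(comms) for u in c}
        expect = np.zeros((3, 3))
        for (u, v), b in eb.items():
            if comm_of[u] != comm_of[v]:
                expect[comm_of[u], comm_of[v]] += b
                expect[comm_of[v], comm_of[u]] += b
        assert np.allclose(conn, expect)
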