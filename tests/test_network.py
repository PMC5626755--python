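"""Dynamical network: edges, shortest paths/CPL, communities, delta-CPL."""

import networkx as nx
import numpy as np
import pytest

from stardynet import network, synthetic
from stardynet.essential_dynamics import CorrelationMatrix
from stardynet.trajio import Trajectory


def path_graph_net(weights):
    """Simple weighted graph helper: weights is {(u, v): w}."""
    g = nx.Graph()
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture(scope="module")
def toy_net(toy_complex):
    spec = synthetic.EnsembleSpec(
        toy_complex, np.full(toy_complex.n_atoms, 0.04), 50, seed=20)
    traj = synthetic.sample_harmonic_ensemble(spec)
    return traj, network.build_network(traj)


@pytest.fixture(scope="module")
def weighted_graph():
    rng = np.random.default_rng(40)
    g = nx.gnp_random_graph(8, 0.6, seed=3)
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
    return g


class TestBuildNetwork:
    def test_full_occupancy_perfect_correlation_weight_zero(
            self, structure_factory):
        s = structure_factory([[0, 0, 0], [3, 0, 0]],
                              names=["CA", "CA"], resseqs=[1, 5],
                              resnames=["ALA", "GLY"])
        frames = np.repeat(s.coords[None], 10, axis=0)
        traj = Trajectory(s, frames)
        corr = CorrelationMatrix(["A1", "G5"], np.ones((2, 2)))
        net = network.build_network(traj, correlation=corr)
        (u, v, d), = net.graph.edges(data=True)
        assert d["occupancy"] == 1.0
        assert d["weight"] == 0.0

    def test_occupancy_below_threshold_drops_edge(self, structure_factory):
        s = structure_factory([[0, 0, 0], [3, 0, 0]],
                              names=["CA", "CA"], resseqs=[1, 5],
                              resnames=["ALA", "GLY"])
        frames = np.repeat(s.coords[None], 100, axis=0)
        frames[74:, 1, 0] = 50.0  # in contact 74% of frames
        traj = Trajectory(s, frames)
        corr = CorrelationMatrix(["A1", "G5"], np.ones((2, 2)))
        net = network.build_network(traj, correlation=corr)
        assert net.graph.number_of_edges() == 0
        frames[74, 1, 0] = 3.0  # 75%: kept (threshold closed)
        net = network.build_network(Trajectory(s, frames), correlation=corr)
        assert net.graph.number_of_edges() == 1

    def test_edges_match_brute_force(self, toy_net):
        traj, net = toy_net
        nodes = net.nodes
        corr = network.node_correlation(traj, nodes)
        expected = set()
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = nodes[i], nodes[j]
                if a.chain == b.chain and abs(a.resseq - b.resseq) <= 1:
                    continue
                hits = 0
                for f in range(traj.n_frames):
                    dmin = min(
                        np.linalg.norm(traj.frames[f, p] - traj.frames[f, q])
                        for p in a.atom_ids for q in b.atom_ids
                    )
                    hits += dmin <= 4.5
                if hits / traj.n_frames >= 0.75:
                    expected.add(tuple(sorted((a.label, b.label))))
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected
        # and weights follow -log|C|
        idx = {n.label: k for k, n in enumerate(nodes)}
        for u, v, d in net.graph.edges(data=True):
            c = corr.matrix[idx[u], idx[v]]
            assert d["weight"] == pytest.approx(-np.log(max(abs(c), 1e-6)))

    def test_occupancy_threshold_monotone(self, toy_net):
        traj, _ = toy_net
        strict = network.build_network(traj, occupancy_cutoff=0.9)
        loose = network.build_network(traj, occupancy_cutoff=0.75)
        assert set(strict.graph.edges) <= set(loose.graph.edges)


class TestShortestPaths:
    def test_indirect_path_shorter(self):
        g = path_graph_net({("A", "B"): 1.0, ("B", "C"): 1.0, ("A", "C"): 3.0})
        sp = network.shortest_paths(g)
        i, j = sp.labels.index("A"), sp.labels.index("C")
        assert sp.distances[i, j] == pytest.approx(2.0)

    def test_diagonal_zero(self):
        g = path_graph_net({("A", "B"): 2.0})
        sp = network.shortest_paths(g)
        np.testing.assert_array_equal(np.diag(sp.distances), 0.0)

    def test_cpl_three_node_path(self):
        g = path_graph_net({("A", "B"): 1.0, ("B", "C"): 1.0})
        sp = network.shortest_paths(g)
        assert sp.cpl == pytest.approx(4.0 / 3.0)

    def test_unreachable_pairs_counted(self):
        g = path_graph_net({("A", "B"): 1.0, ("C", "D"): 1.0})
        sp = network.shortest_paths(g)
        assert sp.n_unreachable_pairs == 4
        assert sp.cpl == pytest.approx(1.0)

    def test_floyd_warshall_equals_dijkstra_on_random_graphs(self):
        rng = np.random.default_rng(30)
        for trial in range(50):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 5.0))
            sp = network.shortest_paths(g)
            for a in g.nodes:
                lengths = nx.single_source_dijkstra_path_length(
                    g, a, weight="weight")
                ia = sp.labels.index(a)
                for b in g.nodes:
                    ib = sp.labels.index(b)
                    expect = lengths.get(b, np.inf)
                    assert sp.distances[ia, ib] == pytest.approx(expect)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(31)
        g = nx.gnp_random_graph(10, 0.6, seed=5)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 3.0))
        d = network.shortest_paths(g).distances
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestCommunities:
    def test_two_triangles_one_bridge(self):
        g = path_graph_net({
            ("A", "B"): 1.0, ("B", "C"): 1.0, ("A", "C"): 1.0,
            ("D", "E"): 1.0, ("E", "F"): 1.0, ("D", "F"): 1.0,
            ("C", "D"): 1.0,
        })
        part = network.communities(g)
        assert part.removal_sequence[0] == ("C", "D")
        assert part.n_communities == 2
        groups = {}
        for node, k in part.assignment.items():
            groups.setdefault(k, set()).add(node)
        assert {frozenset(v) for v in groups.values()} == {
            frozenset("ABC"), frozenset("DEF")}

    def test_single_triangle(self):
        g = path_graph_net({("A", "B"): 1.0, ("B", "C"): 1.0, ("A", "C"): 1.0})
        part = network.communities(g)
        assert part.n_communities == 1

    def test_disconnected_components_respected(self):
        g = path_graph_net({("A", "B"): 1.0, ("B", "C"): 1.0,
                            ("X", "Y"): 1.0, ("Y", "Z"): 1.0})
        part = network.communities(g)
        comp1 = {part.assignment[n] for n in "ABC"}
        comp2 = {part.assignment[n] for n in "XYZ"}
        assert comp1.isdisjoint(comp2)

    def test_planted_two_block_recovery(self):
        from sklearn.metrics import rand_score

        scores = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            g = nx.Graph()
            g.add_nodes_from(range(20))
            truth = [0] * 10 + [1] * 10
            for i in range(20):
                for j in range(i + 1, 20):
                    p = 0.9 if truth[i] == truth[j] else 0.05
                    if rng.random() < p:
                        g.add_edge(i, j, weight=1.0)
            if not nx.is_connected(g):
                continue
            part = network.communities(g)
            labels = [part.assignment[i] for i in range(20)]
            scores.append(rand_score(truth, labels))
        assert np.mean(scores) >= 0.95


class TestDeltaCpl:
    def test_isolated_node_zero_delta(self):
        g = path_graph_net({("A", "B"): 1.0})
        g.add_node("Z")
        rep = network.delta_cpl_scan(g, mode="edge_removal")
        assert rep.delta_cpl[rep.labels.index("Z")] == 0.0
        rep = network.delta_cpl_scan(g, mode="node_removal")
        assert rep.delta_cpl[rep.labels.index("Z")] == 0.0

    def test_bridge_removal_disconnects(self):
        g = path_graph_net({
            ("A", "B"): 1.0, ("B", "C"): 1.0, ("A", "C"): 1.0,
            ("C", "D"): 1.0,
            ("D", "E"): 1.0, ("E", "F"): 1.0, ("D", "F"): 1.0,
        })
        rep = network.delta_cpl_scan(g, mode="node_removal")
        i = rep.labels.index("D")
        assert rep.n_disconnected[i] > 0

    @pytest.mark.parametrize("mode", ["edge_removal", "node_removal"])
    def test_matches_brute_force(self, weighted_graph, mode):
        g = weighted_graph
        rep = network.delta_cpl_scan(g, mode=mode)
        labels = rep.labels
        base = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for v in labels:
            h = g.copy()
            if mode == "edge_removal":
                h.remove_edges_from(list(h.edges(v)))
            else:
                h.remove_node(v)
            pert = dict(nx.all_pairs_dijkstra_path_length(h, weight="weight"))
            deltas = []
            for a in h.nodes:
                for b in h.nodes:
                    if a >= b or (mode == "edge_removal" and v in (a, b)):
                        continue
                    if b in pert.get(a, {}) and b in base.get(a, {}):
                        deltas.append(pert[a][b] - base[a][b])
            expect = float(np.mean(deltas)) if deltas else 0.0
            assert rep.delta_cpl[labels.index(v)] == pytest.approx(expect)


def test_graphml_export_round_trip(tmp_path, toy_net):
    _, net = toy_net
    p = tmp_path / "net.graphml"
    network.write_graphml(net, p)
    back = nx.read_graphml(p)
    assert back.number_of_edges() == net.graph.number_of_edges()
    u, v, d = next(iter(net.graph.edges(data=True)))
    assert back[u][v]["weight"] == pytest.approx(d["weight"])
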