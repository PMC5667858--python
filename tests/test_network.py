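"""Residue interaction networks: paths, betweenness, communities, stability."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from allokin.coupling import CouplingMatrix
from allokin.network import (
    CommunitySet,
    ResidueGraph,
    build_rin,
    community_stability,
    edge_betweenness,
    girvan_newman,
    k_clique_communities,
    modularity,
    node_betweenness,
    shortest_paths,
)
from allokin.structures import Ensemble


def _graph(n, edge_list):
    return ResidueGraph(
        n_nodes=n, edges={(i, j): (float(w), 1.0) for i, j, w in edge_list}
    )


def _random_graph(rng, n, p=0.3):
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(i, j)] = (float(rng.uniform(0.5, 2.0)), 1.0)
    return ResidueGraph(n_nodes=n, edges=edges)


def _two_k4_bridge():
    edges = []
    for a, b in itertools.combinations(range(4), 2):
        edges.append((a, b, 1.0))
        edges.append((a + 4, b + 4, 1.0))
    edges.append((3, 4, 1.0))
    return _graph(8, edges)


class TestBuildRin:
    def _ens(self, frames):
        frames = np.asarray(frames, dtype=float)
        return Ensemble(
            frames=frames,
            times=np.arange(frames.shape[0], dtype=float) + 1,
            residue_ids=[("A", i + 1, "") for i in range(frames.shape[1])],
        )

    def test_collinear_single_frame(self):
        # residues 1 and 3 are 7.6 A apart, beyond the 7.5 A cutoff
        ens = self._ens([[[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]])
        coupling = CouplingMatrix(values=np.full((3, 3), np.exp(-1.0)), kind="dynamic_rMI")
        g = build_rin(ens, coupling)
        assert set(g.edges) == {(0, 1), (1, 2)}
        assert g.edges[(0, 1)][0] == pytest.approx(1.0)

    def test_occupancy_below_threshold_dropped(self):
        near = [[0.0, 0, 0], [3.7, 0, 0], [7.4, 0, 0]]
        far = [[0.0, 0, 0], [3.7, 0, 0], [3.7, 8.0, 0]]
        frames = [near] * 4 + [far] * 6  # (0,2) edge in 4 of 10 frames
        coupling = CouplingMatrix(values=np.full((3, 3), 0.5), kind="dynamic_rMI")
        g = build_rin(self._ens(frames), coupling)
        assert (0, 2) not in g.edges

    def test_occupancy_boundary_retained(self):
        near = [[0.0, 0, 0], [3.7, 0, 0], [7.4, 0, 0]]
        far = [[0.0, 0, 0], [3.7, 0, 0], [3.7, 8.0, 0]]
        coupling = CouplingMatrix(values=np.full((3, 3), 0.5), kind="dynamic_rMI")
        g = build_rin(self._ens([near, far]), coupling)
        assert g.edges[(0, 2)][1] == pytest.approx(0.5)

    def test_empty_frames_rejected(self):
        coupling = CouplingMatrix(values=np.eye(3), kind="dynamic_rMI")
        with pytest.raises(ValueError, match="empty"):
            build_rin([], coupling, mode="atom_interaction_strength")

    def test_coupling_size_mismatch(self):
        ens = self._ens([[[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]])
        coupling = CouplingMatrix(values=np.eye(4), kind="dynamic_rMI")
        with pytest.raises(ValueError):
            build_rin(ens, coupling)


class TestShortestPaths:
    def test_triangle_detour(self):
        g = _graph(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 3.0)])
        pm = shortest_paths(g)
        assert pm.distances[0, 2] == pytest.approx(2.0)

    def test_disconnected_infinite(self):
        g = _graph(4, [(0, 1, 1.0), (2, 3, 1.0)])
        pm = shortest_paths(g)
        assert np.isinf(pm.distances[0, 2])
        assert pm.counts[0, 2] == 0

    def test_matches_dijkstra_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 51))
            g = _random_graph(rng, n, p=0.2)
            pm = shortest_paths(g)
            m = g.weight_matrix().copy()
            m[~np.isfinite(m)] = 0.0
            ref = dijkstra(csr_matrix(m), directed=False)
            both = np.isfinite(pm.distances) & np.isfinite(ref)
            assert np.array_equal(np.isfinite(pm.distances), np.isfinite(ref))
            assert np.allclose(pm.distances[both], ref[both], atol=1e-9)

    def test_tie_counting_square(self):
        g = _graph(4, [(0, 1, 1.0), (1, 2, 1.0), (0, 3, 1.0), (2, 3, 1.0)])
        pm = shortest_paths(g)
        assert pm.counts[0, 2] == pytest.approx(2.0)


def _enumerate_betweenness(g):
    """Brute-force node and edge betweenness via path enumeration."""
    G = g.to_networkx()
    node = np.zeros(g.n_nodes)
    edge = {e: 0.0 for e in g.edges}
    for j, k in itertools.combinations(range(g.n_nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(G, j, k, weight="weight"))
        except nx.NetworkXNoPath:
            continue
        m = len(paths)
        for p in paths:
            for v in p[1:-1]:
                node[v] += 1.0 / m
            for a, b in zip(p, p[1:]):
                edge[(min(a, b), max(a, b))] += 1.0 / m
    return node, edge


class TestBetweenness:
    def test_path3(self):
        g = _graph(3, [(0, 1, 1.0), (1, 2, 1.0)])
        nb = node_betweenness(g).node_values
        assert np.allclose(nb, [0.0, 1.0, 0.0], atol=1e-12)
        eb = edge_betweenness(g)
        assert eb[(0, 1)] == pytest.approx(2.0)

    def test_star_center(self):
        g = _graph(4, [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
        nb = node_betweenness(g).node_values
        assert nb[0] == pytest.approx(3.0)

    def test_four_cycle_half(self):
        g = _graph(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (0, 3, 1.0)])
        assert np.allclose(node_betweenness(g).node_values, 0.5, atol=1e-12)

    def test_bridge_edge_maximal(self):
        g = _graph(
            6,
            [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0),
             (3, 4, 1.0), (3, 5, 1.0), (4, 5, 1.0), (2, 3, 1.0)],
        )
        eb = edge_betweenness(g)
        bridge = eb[(2, 3)]
        assert all(bridge > v for e, v in eb.items() if e != (2, 3))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(12):
            n = int(rng.integers(4, 13))
            g = _random_graph(rng, n, p=0.4)
            nb = node_betweenness(g).node_values
            eb = edge_betweenness(g)
            node_ref, edge_ref = _enumerate_betweenness(g)
            assert np.allclose(nb, node_ref, atol=1e-9)
            for e in eb:
                assert eb[e] == pytest.approx(edge_ref[e], abs=1e-9)


def _all_partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


class TestGirvanNewman:
    def test_two_k4_bridge_exact(self):
        g = _two_k4_bridge()
        cs = girvan_newman(g)
        assert sorted(sorted(c) for c in cs.communities) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_matches_brute_force_modularity(self):
        g = _two_k4_bridge()
        cs = girvan_newman(g)
        best = max(
            modularity(g, [frozenset(c) for c in part])
            for part in _all_partitions(range(8))
        )
        assert cs.modularity == pytest.approx(best, abs=1e-9)

    def test_k5_single_community(self):
        g = _graph(5, [(a, b, 1.0) for a, b in itertools.combinations(range(5), 2)])
        cs = girvan_newman(g)
        assert len(cs.communities) == 1

    def test_edgeless_singletons(self):
        g = ResidueGraph(n_nodes=3, edges={})
        cs = girvan_newman(g)
        assert len(cs.communities) == 3

    def test_two_lobe_partition_separates_lobes(self, two_lobe, two_lobe_ensemble):
        """No community mixes the two lobes (linker nodes may go either way)."""
        from allokin.coupling import dynamic_rmi

        coupling = dynamic_rmi(two_lobe_ensemble)
        g = build_rin(two_lobe_ensemble, coupling)
        cs = girvan_newman(g)
        lobe1, lobe2, linker = set(range(20)), set(range(23, 43)), set(range(20, 23))
        mis = 0
        for c in cs.communities:
            in1 = len(c & lobe1)
            in2 = len(c & lobe2)
            mis += min(in1, in2)  # members on the wrong side of the hinge
        assert mis <= 2


class TestKClique:
    def test_shared_edge_merges(self):
        g = _graph(4, [(0, 1, 1), (0, 2, 1), (1, 2, 1), (1, 3, 1), (2, 3, 1)])
        cs = k_clique_communities(g, k=3)
        assert [sorted(c) for c in cs.communities] == [[0, 1, 2, 3]]

    def test_shared_node_rules(self):
        g = _graph(5, [(0, 1, 1), (0, 2, 1), (1, 2, 1), (2, 3, 1), (2, 4, 1), (3, 4, 1)])
        strict = k_clique_communities(g, k=3, share=2)
        assert len(strict.communities) == 2
        relaxed = k_clique_communities(g, k=3, share=1)
        assert [sorted(c) for c in relaxed.communities] == [[0, 1, 2, 3, 4]]

    def test_matches_networkx_on_k1_rule(self, rng):
        for _ in range(5):
            g = _random_graph(rng, 12, p=0.45)
            ours = {c for c in k_clique_communities(g, k=3, share=2).communities}
            ref = {frozenset(c) for c in nx.community.k_clique_communities(g.to_networkx(), 3)}
            assert ours == ref

    def test_triangle_free_empty(self):
        g = _graph(4, [(0, 1, 1), (1, 2, 1), (2, 3, 1)])
        assert k_clique_communities(g, k=3).communities == []

    def test_k_below_3_rejected(self):
        g = _graph(3, [(0, 1, 1)])
        with pytest.raises(ValueError):
            k_clique_communities(g, k=2)


class TestCommunityStability:
    def _cs(self, *comms):
        return CommunitySet(communities=[frozenset(c) for c in comms])

    def test_identical_partitions_all_stable(self):
        p = self._cs({0, 1, 2}, {3, 4, 5})
        out = community_stability([p] * 5)
        assert len(out.communities) == 2
        assert all(f == 1.0 for f in out.stability)

    def test_seven_of_ten_dropped(self):
        present = self._cs({0, 1, 2}, {3, 4, 5})
        absent = self._cs({0, 1, 2}, {3}, {4}, {5})
        frames = [present] * 7 + [absent] * 3
        out = community_stability(frames)
        # {3,4,5} appears in 7/10 = 0.7 <= 0.75: dropped; {0,1,2} kept
        assert frozenset({0, 1, 2}) in out.communities
        assert frozenset({3, 4, 5}) not in out.communities

    def test_fluctuating_member_still_matches(self):
        a = self._cs({0, 1, 2, 3, 4}, {5, 6, 7})
        b = self._cs({0, 1, 2, 3}, {4, 5, 6, 7})  # jaccard({01234},{0123}) = 0.8
        out = community_stability([a, a, b, b])
        assert any(c >= frozenset({0, 1, 2, 3}) or len(c & {0, 1, 2, 3}) >= 4
                   for c in out.communities)

    def test_node_set_mismatch_rejected(self):
        a = self._cs({0, 1}, {2, 3})
        b = self._cs({0, 1}, {2, 4})
        with pytest.raises(ValueError):
            community_stability([a, b])


class TestEdgeCentralityDistribution:
    def test_bridge_widens_distribution(self, rng):
        """A single bottleneck edge makes edge centralities far more
        heterogeneous than in a uniformly dense graph."""
        dense = _graph(
            8, [(a, b, 1.0) for a, b in itertools.combinations(range(8), 2)]
        )
        bridged = _two_k4_bridge()

        def cv(g):
            v = np.array(list(edge_betweenness(g).values()))
            return v.std() / v.mean()

        assert cv(dense) < cv(bridged)
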