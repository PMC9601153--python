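"""Diffusion walker: mass spreading, encoding, decoding, determinism."""

import math

import pytest

import ctdpair as cp
from ctdpair.graphs import GraphError


class TestDiffuse:
    def test_star_proportional_split(self):
        G = cp.new_graph([("hub", "x", 1.0), ("hub", "y", 1.0), ("hub", "z", 2.0)])
        masses = cp.diffuse(G, visited={"hub"}, frontier={"hub"})
        assert masses == {"x": 0.25, "y": 0.25, "z": 0.5}

    def test_single_unvisited_neighbor_gets_everything(self):
        G = cp.new_graph([("a", "b", 0.3)])
        assert cp.diffuse(G, visited={"a"}, frontier={"a"}) == {"b": 1.0}

    def test_pass_through_visited_node(self):
        # a's only neighbor b is visited; mass is forwarded to b's unvisited c
        G = cp.new_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        masses = cp.diffuse(G, visited={"a", "b"}, frontier={"a"})
        assert masses == pytest.approx({"c": 1.0})

    def test_pass_through_is_one_level_only(self):
        # a-b-c-d with b, c visited: a's share goes through b to ... only c's
        # neighbors are 2 hops; c unvisited neighbors = {d}? c is visited, so
        # pass-through from a via b reaches b's unvisited neighbors only: none.
        G = cp.new_graph([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
        masses = cp.diffuse(G, visited={"a", "b", "c"}, frontier={"a"})
        assert masses == {}  # share lost: depth limit reached

    def test_visited_nodes_receive_nothing_and_mass_bounded(self):
        for seed in range(8):
            G = cp.random_connected_graph(12, 3.0, seed)
            nodes = sorted(G.nodes)
            visited = set(nodes[:4])
            masses = cp.diffuse(G, visited=visited, frontier=set(nodes[:2]))
            assert all(v not in visited for v in masses)
            assert all(m >= 0 for m in masses.values())
            assert sum(masses.values()) <= 1.0 + 1e-12

    def test_empty_frontier_rejected(self):
        G = cp.new_graph([("a", "b", 1.0)])
        with pytest.raises(ValueError, match="frontier"):
            cp.diffuse(G, visited={"a"}, frontier=set())

    def test_frontier_must_be_visited(self):
        G = cp.new_graph([("a", "b", 1.0)])
        with pytest.raises(ValueError, match="subset"):
            cp.diffuse(G, visited={"a"}, frontier={"b"})

    def test_zero_weight_edges_carry_no_mass(self):
        G = cp.new_graph([("a", "b", 0.0), ("a", "c", 1.0)])
        assert cp.diffuse(G, visited={"a"}, frontier={"a"}) == {"c": 1.0}


class TestEncodeFromStart:
    def test_singleton_module(self, path5):
        enc = cp.encode_from_start(path5, cp.NodeModule(("c",)), "c")
        assert (enc.bits, enc.l, enc.found) == ("1", 1, 1)
        assert enc.i_alt == pytest.approx(math.log2(5))

    def test_full_path_module(self, path5):
        S = cp.NodeModule(("a", "b", "c", "d", "e"))
        enc = cp.encode_from_start(path5, S, "a")
        assert enc.bits == "11111"
        assert enc.found == 5
        assert enc.i_alt == pytest.approx(math.log2(5) + 4)

    def test_gap_in_module_costs_a_zero_bit(self, path5):
        enc = cp.encode_from_start(path5, cp.NodeModule(("a", "c")), "a")
        assert enc.bits == "101"

    def test_encoding_length_bookkeeping(self, random_instance):
        for seed in range(10):
            G, S = random_instance(seed)
            enc = cp.encode_from_start(G, S, sorted(S.labels)[0])
            assert enc.found == enc.bits.count("1") <= len(S)
            assert enc.found <= enc.l
            expected = (len(S) - enc.found + 1) * math.log2(
                G.number_of_nodes()
            ) + enc.l - 1
            assert enc.i_alt == pytest.approx(expected, abs=0)

    def test_start_not_in_module_rejected(self, path5):
        with pytest.raises(GraphError, match="not in the module"):
            cp.encode_from_start(path5, cp.NodeModule(("a", "b")), "c")

    def test_module_not_in_graph_rejected(self, path5):
        with pytest.raises(GraphError, match="absent"):
            cp.encode_from_start(path5, cp.NodeModule(("a", "zz")), "a")

    def test_determinism(self, random_instance):
        G, S = random_instance(2)
        a = cp.encode_from_start(G, S, sorted(S.labels)[0])
        b = cp.encode_from_start(G, S, sorted(S.labels)[0])
        assert a == b


class TestEncodeModule:
    def test_symmetric_clique_tie_breaks_to_smallest_label(self):
        G = cp.new_graph([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        enc = cp.encode_module(G, cp.NodeModule(("c", "a", "b")))
        assert enc.start == "a"
        assert enc.bits == "111"

    def test_singleton_matches_encode_from_start(self, path5):
        S = cp.NodeModule(("d",))
        assert cp.encode_module(path5, S) == cp.encode_from_start(path5, S, "d")

    def test_equals_brute_force_minimum(self, random_instance):
        for seed in range(10):
            G, S = random_instance(seed)
            best = min(
                cp.encode_from_start(G, S, s).i_alt for s in S.labels
            )
            assert cp.encode_module(G, S).i_alt == best

    def test_ideal_case_on_dominant_planted_clique(self):
        # weights inside S dominate the background 10x: the walker captures
        # all of S directly and the encoding attains log2|V| + |S| - 1
        for seed in range(5):
            G = cp.random_connected_graph(60, 4.0, seed)
            S = cp.NodeModule(tuple(sorted(G.nodes)[:5]))
            H, S = cp.plant_module(G, S, "clique", 10.0)
            enc = cp.encode_module(H, S)
            assert enc.found == len(S)
            assert enc.i_alt == pytest.approx(
                math.log2(H.number_of_nodes()) + len(S) - 1
            )

    def test_dominating_edge_from_start_is_taken_first(self, random_instance):
        # concentration helps locally: an overwhelming edge between two module
        # nodes makes the walker capture the partner on its first step
        for seed in range(6):
            G, S = random_instance(seed)
            u, v = sorted(S.labels)[:2]
            wmax = max(d["weight"] for _, _, d in G.edges(data=True))
            G.add_edge(u, v, weight=100.0 * wmax)
            enc = cp.encode_from_start(G, cp.NodeModule((u, v)), u)
            assert enc.bits == "11"


class TestDecode:
    def test_trivial_bitstring(self, path5):
        assert cp.decode(path5, "b", "1").labels == ("b",)

    def test_round_trip_on_path(self, path5):
        S = cp.NodeModule(("a", "b", "c", "d", "e"))
        enc = cp.encode_from_start(path5, S, "a")
        assert set(cp.decode(path5, "a", enc.bits)) == set(S.labels)

    def test_visited_non_module_node_excluded(self, path5):
        assert cp.decode(path5, "a", "10").labels == ("a",)

    @staticmethod
    def _reference_found_subset(G, S, start):
        # independent replay of the walk rules using only the diffuse primitive
        n = G.number_of_nodes()
        s_set = set(S.labels)
        visited, found = {start}, {start}
        while len(found) < len(s_set) and len(visited) < n:
            masses = cp.diffuse(G, visited, frontier=found)
            if not masses:
                break
            node = min(masses.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if masses[node] < 1.0 / n**2:
                break
            visited.add(node)
            if node in s_set:
                found.add(node)
        return found

    def test_round_trip_randomized(self, random_instance):
        for seed in range(30):
            G, S = random_instance(seed, n=18, module_size=5)
            enc = cp.encode_module(G, S)
            decoded = set(cp.decode(G, enc.start, enc.bits))
            assert decoded == self._reference_found_subset(G, S, enc.start)
            assert len(decoded) == enc.found

    def test_overlong_bitstring_rejected(self):
        G = cp.new_graph([("a", "b", 1.0)])
        with pytest.raises(ValueError, match="longer"):
            cp.decode(G, "a", "1000")

    def test_must_start_with_one(self, path5):
        with pytest.raises(ValueError, match="begin"):
            cp.decode(path5, "a", "01")
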