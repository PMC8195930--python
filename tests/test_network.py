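"""Levenshtein distances, convergent groups, and network diameter."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from tcrdyn.network import (
    build_network,
    convergent_groups,
    dichotomize_by_median_diameter,
    levenshtein,
    network_diameter,
    pairwise_distance_matrix,
)
from tcrdyn.types import Timepoint

from _oracles import dp_levenshtein, floyd_warshall_diameter, union_find_clusters
from conftest import make_course, random_aa


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("CASSL", "CASSL", 0),
            ("CASSL", "CASTL", 1),
            ("kitten", "sitting", 3),
            ("", "", 0),
            ("", "ABC", 3),
            ("AB", "BA", 2),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_agrees_with_dp_oracle_on_random_pairs(self, rng):
        """1000 random string pairs, lengths 0-25, vs the DP table."""
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(1000):
            la, lb = rng.integers(0, 26, size=2)
            a = "".join(alphabet[rng.integers(0, 20, size=la)])
            b = "".join(alphabet[rng.integers(0, 20, size=lb)])
            assert levenshtein(a, b) == dp_levenshtein(a, b)

    def test_symmetry_and_identity(self, rng):
        for _ in range(50):
            a, b = random_aa(rng), random_aa(rng)
            assert levenshtein(a, b) == levenshtein(b, a)
            assert levenshtein(a, a) == 0


class TestPairwiseDistanceMatrix:
    def test_thresholded_pairs(self):
        pairs = {(i, j) for i, j, _ in pairwise_distance_matrix(["AA", "AB", "ZZ"], 1)}
        assert pairs == {(0, 1)}

    def test_single_sequence_has_no_pairs(self):
        assert pairwise_distance_matrix(["CASSL"], 1) == []

    def test_duplicates_reported_at_distance_zero(self):
        pairs = pairwise_distance_matrix(["CASSL", "CASSL"], 1)
        assert pairs == [(0, 1, 0)]

    def test_equals_dense_oracle_on_random_repertoires(self, rng):
        """Edge set matches dense DP thresholding on 100 random sequence sets."""
        for rep in range(100):
            n = int(rng.integers(2, 61))
            seqs = [random_aa(rng, 4, 9) for _ in range(n)]
            got = {(i, j, d) for i, j, d in pairwise_distance_matrix(seqs, 1)}
            want = set()
            for i in range(n):
                for j in range(i + 1, n):
                    d = dp_levenshtein(seqs[i], seqs[j])
                    if d <= 1:
                        want.add((i, j, d))
            assert got == want

    def test_handles_larger_threshold(self, rng):
        seqs = [random_aa(rng, 4, 7) for _ in range(40)]
        got = {(i, j) for i, j, _ in pairwise_distance_matrix(seqs, 3)}
        want = {
            (i, j)
            for i in range(40)
            for j in range(i + 1, 40)
            if dp_levenshtein(seqs[i], seqs[j]) <= 3
        }
        assert got == want


class TestConvergentGroups:
    def test_pair_and_singleton(self):
        seqs = ["CASSL", "CASSF", "CARRW"]
        clusters = {frozenset(c) for c in convergent_groups(seqs)}
        assert clusters == {frozenset({0, 1}), frozenset({2})}

    def test_chain_links_transitively(self):
        # d(AAAA, AABB) = 2 but both link through AAAB
        clusters = convergent_groups(["AAAA", "AAAB", "AABB"])
        assert len(clusters) == 1 and clusters[0] == {0, 1, 2}

    def test_mutually_distant_sequences_stay_singletons(self):
        clusters = convergent_groups(["AAAA", "CCCC", "GGGG"])
        assert all(len(c) == 1 for c in clusters)

    def test_equals_union_find_closure_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            seqs = [random_aa(rng, 3, 6) for _ in range(n)]
            got = {frozenset(c) for c in convergent_groups(seqs, 1)}
            assert got == union_find_clusters(seqs, 1)


class TestBuildNetwork:
    def test_cross_timepoint_and_neighbor_edges(self):
        course = make_course([("nt1", "CASSL", 1), ("nt0", "CARRW", 1)], [("nt2", "CASSL", 1), ("nt3", "CASTL", 1)])
        g = build_network(course)
        seqs = {(n.aa_cdr3, n.timepoint) for n in g.nodes}
        assert ("CASSL", Timepoint.C1D1) in seqs and ("CASSL", Timepoint.C1D15) in seqs
        edge_pairs = {
            frozenset({(g.nodes[i].aa_cdr3, g.nodes[i].timepoint.value), (g.nodes[j].aa_cdr3, g.nodes[j].timepoint.value)})
            for i, j, _ in g.edges
        }
        assert frozenset({("CASSL", "C1D1"), ("CASSL", "C1D15")}) in edge_pairs
        assert frozenset({("CASSL", "C1D1"), ("CASTL", "C1D15")}) in edge_pairs
        assert frozenset({("CASSL", "C1D15"), ("CASTL", "C1D15")}) in edge_pairs
        # CARRW is isolated; the CASSL/CASTL component has 3 nodes
        assert sorted(len(c) for c in g.components) == [1, 3]

    def test_distance_zero_edges_only_cross_timepoints(self, rng):
        base = [(f"nt{i}", aa, 1) for i, aa in enumerate({random_aa(rng, 5, 8) for _ in range(20)})]
        course = make_course(base, [(nt + "X", aa, 1) for nt, aa, _ in base])
        g = build_network(course)
        for i, j, d in g.edges:
            if d == 0:
                assert g.nodes[i].timepoint != g.nodes[j].timepoint
                assert g.nodes[i].aa_cdr3 == g.nodes[j].aa_cdr3

    def test_identical_timepoints_mirror_structure(self):
        base = [("nt1", "CASSL", 1), ("nt2", "CASTL", 1), ("nt3", "CWWWW", 1)]
        course = make_course(base, [(nt + "X", aa, c) for nt, aa, c in base])
        g = build_network(course)
        zero_edges = [e for e in g.edges if e[2] == 0]
        assert len(zero_edges) == 3  # one per shared sequence
        assert g.n_nodes == 6

    def test_empty_course_gives_empty_graph(self):
        course = make_course([("nt1", "CAS", 1), ("nt2", "CAT", 1)], None)
        course.baseline.records = []
        g = build_network(course)
        assert g.n_nodes == 0 and g.diameter == 0

    def test_isolated_nodes_have_diameter_zero(self):
        course = make_course([("nt1", "AAAA", 1), ("nt2", "CCCC", 1), ("nt3", "GGGG", 1)], None)
        g = build_network(course)
        assert g.n_edges == 0 and g.diameter == 0 and len(g.components) == 3


class TestNetworkDiameter:
    def test_path_graph(self):
        assert network_diameter(nx.path_graph(4)) == 3

    def test_max_over_components(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 0)])  # triangle
        g.add_edges_from([(10, 11), (11, 12), (12, 13), (13, 14)])  # 5-path
        assert network_diameter(g) == 4

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_complete_graph(self, n):
        assert network_diameter(nx.complete_graph(n)) == 1

    def test_agrees_with_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 61))
            p = float(rng.uniform(0.02, 0.2))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            assert network_diameter(g) == floyd_warshall_diameter(n, list(g.edges))

    def test_adding_edge_never_increases_connected_diameter(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            g = nx.connected_watts_strogatz_graph(n, 3, 0.3, seed=int(rng.integers(0, 2**31)))
            before = network_diameter(g)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(0, len(non_edges)))]
            g.add_edge(u, v)
            assert network_diameter(g) <= before


class TestMedianDichotomy:
    def test_median_itself_is_low(self):
        labels, m = dichotomize_by_median_diameter({"a": 10, "b": 12, "c": 14})
        assert m == 12 and labels == {"a": "low", "b": "low", "c": "high"}

    def test_all_equal_all_low(self):
        with pytest.warns(UserWarning):
            labels, _ = dichotomize_by_median_diameter({"a": 5, "b": 5, "c": 5})
        assert set(labels.values()) == {"low"}

    def test_even_cohort_midpoint_convention(self):
        labels, m = dichotomize_by_median_diameter({"a": 10, "b": 11, "c": 13, "d": 14})
        assert m == 12.0
        assert labels == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            dichotomize_by_median_diameter({"a": 3})
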