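import pytest

from pscluster import (
    ConflictGraph,
    Covering,
    PsPath,
    PsTuple,
    covering_weight,
    gilbert_instance,
    greedy_cover,
    slf_coloring,
    soft_assignments,
    strict_variant_check,
    validate_covering,
)
from pscluster.coloring import HEURISTICS, Coloring
from pscluster.covering import covering_from_coloring
from pscluster.graph import edge


def fs(*xs):
    return frozenset(xs)


class TestWeight:
    def test_single_stable_set_weighs_one(self):
        assert covering_weight(Covering([PsTuple(fs("a", "b"))])) == 1

    def test_joined_pair_weighs_two(self):
        t = PsTuple(fs("a"), fs("c"), (PsPath("a", "b", "c"),))
        assert covering_weight(Covering([t])) == 2

    def test_chain_sharing_a_set_weighs_three(self):
        # tuples (A,B) and (B,C) share B: 2 + 2 - 1 = 3 distinct sets
        t1 = PsTuple(fs("a"), fs("b"), (PsPath("a", "p", "b"),))
        t2 = PsTuple(fs("b"), fs("c"), (PsPath("b", "q", "c"),))
        assert covering_weight(Covering([t1, t2])) == 3

    def test_weight_counts_distinct_sets_on_random_coverings(self):
        for s in range(8):
            g = gilbert_instance(18, 0.7, 0.25, seed=40 + s)
            cov = greedy_cover(g, slf_coloring(g))
            assert covering_weight(cov) == len(cov.stable_sets)


class TestTupleInvariants:
    def test_empty_d1_rejected(self):
        with pytest.raises(ValueError, match="D1"):
            PsTuple(fs())

    def test_paths_require_d2(self):
        with pytest.raises(ValueError):
            PsTuple(fs("a"), fs(), (PsPath("a", "b", "c"),))
        with pytest.raises(ValueError):
            PsTuple(fs("a"), fs("c"), ())

    def test_path_nodes_distinct(self):
        with pytest.raises(ValueError):
            PsPath("a", "a", "c")


class TestGreedy:
    def test_example_eliminates_middle_document(self, example_graph):
        for name, heuristic in HEURISTICS.items():
            cov = greedy_cover(example_graph, heuristic(example_graph))
            assert cov.num_clusters == 2, name
            assert [p.inner for p in cov.paths] == ["b"]
            assert sorted(map(sorted, cov.stable_sets)) == [["a"], ["c"]]

    def test_no_blue_edges_keeps_start_coloring(self):
        for s in range(5):
            g = gilbert_instance(10, 0.5, 0.0, seed=s)
            start = slf_coloring(g)
            cov = greedy_cover(g, start)
            assert not cov.paths
            assert set(cov.stable_sets) == {
                frozenset(c) for c in start.classes().values()
            }

    def test_blue_star_drops_singleton_class(self):
        # v alone in its class, blue-linked to two different classes
        g = ConflictGraph(
            nodes={"v", "a", "b"},
            black_edges={edge("a", "b")},
            blue_edges={edge("v", "a"), edge("v", "b")},
        )
        start = Coloring({"v": 1, "a": 2, "b": 3})
        cov = greedy_cover(g, start)
        assert cov.num_clusters == 2
        assert cov.inner_nodes() == {"v"}

    def test_never_increases_cluster_count(self):
        for s in range(6):
            g = gilbert_instance(20, 0.75, 0.2, seed=60 + s)
            for heuristic in HEURISTICS.values():
                start = heuristic(g)
                cov = greedy_cover(g, start)
                assert cov.num_clusters <= start.num_colors
                ok, violations = validate_covering(cov, g)
                assert ok, violations
                assert cov.covered_nodes() == g.nodes

    def test_improper_start_rejected(self, triangle):
        with pytest.raises(ValueError, match="not proper"):
            greedy_cover(triangle, Coloring({"a": 1, "b": 1, "c": 2}))


class TestValidate:
    def test_unstable_set_reported(self, triangle):
        cov = Covering([PsTuple(fs("a", "b")), PsTuple(fs("c"))])
        ok, violations = validate_covering(cov, triangle)
        assert not ok and any("not stable" in m for m in violations)

    def test_non_blue_path_reported(self, example_graph):
        # a-c is black, so a path through it is invalid
        cov = Covering([PsTuple(fs("c"), fs("b"), (PsPath("c", "a", "b"),))])
        ok, violations = validate_covering(cov, example_graph)
        assert not ok and any("not blue" in m for m in violations)

    def test_uncovered_node_reported(self, example_graph):
        cov = Covering([PsTuple(fs("a"))])
        ok, violations = validate_covering(cov, example_graph)
        assert not ok and any("not covered" in m for m in violations)

    def test_shared_inner_toggle(self, example_graph):
        t1 = PsTuple(fs("a"), fs("c"), (PsPath("a", "b", "c"),))
        t2 = PsTuple(fs("c"), fs("a"), (PsPath("c", "b", "a"),))
        cov = Covering([t1, t2])
        assert validate_covering(cov, example_graph, allow_shared_inner=True)[0]
        ok, violations = validate_covering(cov, example_graph,
                                           allow_shared_inner=False)
        assert not ok and any("2 paths" in m for m in violations)


class TestStrictVariants:
    def test_chain_satisfies_restrictions(self):
        t1 = PsTuple(fs("a"), fs("b"), (PsPath("a", "p", "b"),))
        t2 = PsTuple(fs("b"), fs("c"), (PsPath("b", "q", "c"),))
        report = strict_variant_check(Covering([t1, t2]))
        assert report["acyclic"] and report["max_degree"] == 2
        assert report["satisfies_strict_restrictions"]

    def test_cycle_fails(self):
        t1 = PsTuple(fs("a"), fs("b"), (PsPath("a", "p", "b"),))
        t2 = PsTuple(fs("b"), fs("c"), (PsPath("b", "q", "c"),))
        t3 = PsTuple(fs("c"), fs("a"), (PsPath("c", "r", "a"),))
        report = strict_variant_check(Covering([t1, t2, t3]))
        assert not report["acyclic"]

    def test_single_set_passes(self):
        report = strict_variant_check(Covering([PsTuple(fs("a", "b"))]))
        assert report["satisfies_strict_restrictions"]


class TestSoftAssignments:
    def test_example_assignments(self, example_graph):
        cov = greedy_cover(example_graph, slf_coloring(example_graph))
        soft = soft_assignments(cov)
        bridge = soft["b"]
        assert bridge["bridge"] and len(bridge["clusters"]) == 2
        assert soft["a"]["clusters"] != soft["c"]["clusters"]
        assert not soft["a"]["bridge"] and not soft["c"]["bridge"]

    def test_hard_clustering_single_membership(self):
        g = gilbert_instance(12, 0.5, 0.0, seed=2)
        cov = greedy_cover(g, slf_coloring(g))
        soft = soft_assignments(cov)
        assert all(len(e["clusters"]) == 1 and not e["bridge"]
                   for e in soft.values())


class TestSerialization:
    def test_json_roundtrip(self, example_graph):
        cov = greedy_cover(example_graph, slf_coloring(example_graph))
        restored = Covering.from_json(cov.to_json())
        assert set(restored.stable_sets) == set(cov.stable_sets)
        assert {p.inner for p in restored.paths} == {p.inner for p in cov.paths}
        assert covering_weight(restored) == covering_weight(cov)

    def test_covering_from_coloring(self, triangle):
        cov = covering_from_coloring(slf_coloring(triangle))
        assert cov.num_clusters == 3 and not cov.paths
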