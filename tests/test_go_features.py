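import numpy as np
import pytest

from conftest import brute_force_lca, random_dag
from ppifuse.go_features import (
    GoDag,
    LcaIndex,
    build_lca_index,
    go_feature_vector,
    lowest_common_ancestor,
)
from ppifuse.io_formats import AnnotationTable, Pair


class TestDag:
    def test_depth_is_longest_ascending_path(self, diamond_dag):
        assert diamond_dag.depth("R") == 0
        assert diamond_dag.depth("B") == 1
        assert diamond_dag.depth("D") == 2

    def test_cycle_is_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            GoDag([("A", "B"), ("B", "A")], {"A": "bp", "B": "bp"})

    def test_multiple_roots_in_one_namespace_are_rejected(self):
        with pytest.raises(ValueError, match="roots"):
            GoDag([("C", "A")], {"A": "bp", "B": "bp", "C": "bp"})


class TestLca:
    def test_singleton_is_its_own_ancestor(self, diamond_dag):
        assert lowest_common_ancestor(diamond_dag, {"D"}) == "D"

    def test_siblings_in_star_meet_at_root(self, star_dag):
        assert lowest_common_ancestor(star_dag, {"B", "C"}) == "R"

    def test_diamond_ancestor_descendant_pair(self, diamond_dag):
        assert lowest_common_ancestor(diamond_dag, {"B", "D"}) == "B"

    def test_mixed_namespaces_are_rejected(self, diamond_dag):
        mixed = GoDag(
            [("B", "R"), ("Y", "X")], {"R": "bp", "B": "bp", "X": "mf", "Y": "mf"}
        )
        with pytest.raises(ValueError, match="namespace"):
            lowest_common_ancestor(mixed, {"B", "Y"})

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            dag = random_dag(rng, int(rng.integers(3, 31)))
            nodes = dag.nodes
            terms = set(rng.choice(nodes, size=int(rng.integers(1, 4)), replace=False))
            assert lowest_common_ancestor(dag, terms) == brute_force_lca(dag, terms)


def _annotations(dag, mapping):
    ns = {t: dag.namespace(t) for ts in mapping.values() for t in ts}
    return AnnotationTable(mapping, ns)


class TestLcaIndex:
    def test_root_anchor_claims_whole_namespace(self, star_dag):
        ann = _annotations(star_dag, {"p": {"B"}, "q": {"C"}})
        index = build_lca_index(star_dag, [Pair("p", "q", 1)], ann)
        assert index.anchors == ["R"]
        assert set(index.term_to_cluster) == {"R", "B", "C", "D"}

    def test_nested_anchors_yield_disjoint_clusters(self, diamond_dag):
        ann = _annotations(diamond_dag, {"p": {"D"}, "q": {"D"}, "r": {"B"}, "s": {"E"}})
        index = build_lca_index(
            diamond_dag, [Pair("p", "q", 1), Pair("r", "s", 0)], ann
        )
        # anchors: D (deep, pair p-q) and R (pair r-s)
        assert index.anchors == ["D", "R"]
        assert index.term_to_cluster["D"] == 0
        assert index.term_to_cluster["B"] == 1  # claimed by R, not by D's cluster

    def test_cluster_disjointness_and_anchor_coverage_on_random_universes(self, small_universe):
        universe, pairs = small_universe
        index = build_lca_index(universe.dag, list(pairs), universe.annotations)
        assert index.m >= 1
        clusters = {}
        for term, j in index.term_to_cluster.items():
            clusters.setdefault(j, set()).add(term)
        seen = set()
        for members in clusters.values():
            assert not (members & seen)
            seen |= members
        for j, anchor in enumerate(index.anchors):
            assert index.term_to_cluster[anchor] == j

    def test_shuffled_training_pairs_give_identical_index(self, small_universe):
        universe, pairs = small_universe
        rows = list(pairs)
        shuffled = [rows[i] for i in np.random.default_rng(3).permutation(len(rows))]
        a = build_lca_index(universe.dag, rows, universe.annotations)
        b = build_lca_index(universe.dag, shuffled, universe.annotations)
        assert a.anchors == b.anchors and a.term_to_cluster == b.term_to_cluster

    def test_json_round_trip(self, tmp_path, star_dag):
        ann = _annotations(star_dag, {"p": {"B"}, "q": {"C"}})
        index = build_lca_index(star_dag, [Pair("p", "q", 1)], ann)
        path = tmp_path / "index.json"
        index.to_json(path)
        loaded = LcaIndex.from_json(path)
        assert loaded.anchors == index.anchors
        assert loaded.term_to_cluster == index.term_to_cluster


class TestFeatureVector:
    @pytest.fixture
    def indexed_diamond(self, diamond_dag):
        ann = _annotations(diamond_dag, {"p": {"B"}, "q": {"C"}})
        return build_lca_index(diamond_dag, [Pair("p", "q", 1)], ann)

    def test_term_at_anchor_contributes_one(self, indexed_diamond, diamond_dag):
        vec = go_feature_vector(indexed_diamond, diamond_dag, {"R"}, set())
        np.testing.assert_array_equal(vec, [1.0])

    def test_shared_term_one_edge_below_anchor_counts_four(self, indexed_diamond, diamond_dag):
        vec = go_feature_vector(indexed_diamond, diamond_dag, {"B"}, {"B"})
        np.testing.assert_array_equal(vec, [4.0])

    def test_terms_outside_all_clusters_give_zero_vector(self, diamond_dag):
        index = LcaIndex(anchors=["B"], anchor_namespaces=["biological_process"],
                         term_to_cluster={"B": 0, "D": 0})
        vec = go_feature_vector(index, diamond_dag, {"C", "E"}, {"E"})
        np.testing.assert_array_equal(vec, [0.0])

    def test_symmetry_in_the_two_annotation_sets(self, small_universe):
        universe, pairs = small_universe
        index = build_lca_index(universe.dag, list(pairs), universe.annotations)
        gu = universe.annotations.terms_for(pairs[0].u)
        gv = universe.annotations.terms_for(pairs[0].v)
        np.testing.assert_array_equal(
            go_feature_vector(index, universe.dag, gu, gv),
            go_feature_vector(index, universe.dag, gv, gu),
        )

    def test_adding_a_term_inside_a_cluster_never_decreases_its_value(self, indexed_diamond, diamond_dag):
        base = go_feature_vector(indexed_diamond, diamond_dag, {"B"}, {"C"})
        more = go_feature_vector(indexed_diamond, diamond_dag, {"B", "D"}, {"C"})
        assert np.all(more >= base)
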