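"""Similarity graph, Markov clustering, h_orth and classes B/A."""

import itertools

import numpy as np
import pytest

from hgtscan.core import HGTThresholds, HitRecord, TaxonGroup
from hgtscan.hgt_index import BestHits, GeneScore, gene_score
from hgtscan.orthogroups import (
    MCLParams,
    OrthologGroup,
    SimilarityGraph,
    annotate_groups,
    assign_classes,
    build_similarity_graph,
    classify_class_a,
    classify_class_b,
    compute_h_orth,
    mcl_cluster,
)

from _oracles import brute_mcl

T = HGTThresholds()


def _pair(a, b, evalue, bs=200.0):
    return HitRecord(a, b, TaxonGroup.OWN_PHYLUM, bs, evalue)


class TestBuildGraph:
    def test_significant_pair_gets_one_edge(self):
        g = build_similarity_graph([_pair("a", "b", 1e-20), _pair("b", "a", 1e-18)])
        assert set(g.edges) == {("a", "b")}

    def test_cutoff_boundary_excludes(self):
        g = build_similarity_graph([_pair("a", "b", 1e-4)])
        assert g.edges == {}
        assert set(g.nodes) == {"a", "b"}

    def test_enumerated_pairs(self):
        hits = [
            _pair("p1", "p2", 1e-30),
            _pair("p2", "p3", 1e-30),
            _pair("p3", "p4", 1e-30),
            _pair("p4", "p5", 1e-30),
            _pair("p1", "p5", 1e-3),  # above cutoff
        ]
        g = build_similarity_graph(hits)
        assert len(g.nodes) == 5
        assert len(g.edges) == 4

    def test_weight_symmetrised_as_max(self):
        g = build_similarity_graph([_pair("a", "b", 1e-20), _pair("b", "a", 1e-40)])
        assert g.edges[("a", "b")] == pytest.approx(40.0)

    def test_self_hits_add_node_not_edge(self):
        g = build_similarity_graph([_pair("a", "a", 1e-50)])
        assert g.nodes == ["a"] and g.edges == {}


class TestMCL:
    def test_two_disjoint_triangles(self):
        edges = {}
        for grp in ("x", "y"):
            for a, b in itertools.combinations([f"{grp}{i}" for i in range(3)], 2):
                edges[(a, b)] = 50.0
        g = SimilarityGraph(nodes=sorted({n for e in edges for n in e}), edges=edges)
        clusters = sorted(sorted(c.members) for c in mcl_cluster(g))
        assert clusters == [["x0", "x1", "x2"], ["y0", "y1", "y2"]]

    def test_single_edge(self):
        g = SimilarityGraph(nodes=["A", "B"], edges={("A", "B"): 10.0})
        (c,) = mcl_cluster(g)
        assert c.members == {"A", "B"}

    def test_barbell_splits_at_weak_bridge(self):
        """Two K4 cliques joined by one weak edge separate at inflation 15."""
        edges = {}
        for grp in ("a", "b"):
            for x, y in itertools.combinations([f"{grp}{i}" for i in range(4)], 2):
                edges[(x, y)] = 50.0
        edges[("a0", "b0")] = 1.0
        g = SimilarityGraph(nodes=sorted({n for e in edges for n in e}), edges=edges)
        clusters = sorted(sorted(c.members) for c in mcl_cluster(g))
        oracle = sorted(sorted(c) for c in brute_mcl(g.nodes, edges))
        assert clusters == [["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"]]
        assert clusters == oracle

    def test_oracle_equivalence_random_graphs(self):
        """Dense in-package MCL equals the loop-coded reference on random
        graphs of up to 10 nodes."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(2, 11))
            nodes = [f"n{i}" for i in range(n)]
            edges = {
                (a, b): float(rng.uniform(1, 100))
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.4
            }
            g = SimilarityGraph(nodes=nodes, edges=edges)
            ours = sorted(sorted(c.members) for c in mcl_cluster(g))
            ref = sorted(sorted(c) for c in brute_mcl(nodes, edges))
            assert ours == ref

    def test_partition_properties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            nodes = [f"n{i}" for i in range(n)]
            edges = {
                (a, b): float(rng.uniform(1, 100))
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.3
            }
            g = SimilarityGraph(nodes=nodes, edges=edges)
            clusters = mcl_cluster(g)
            # coverage + disjointness
            seen = [m for c in clusters for m in c.members]
            assert sorted(seen) == sorted(nodes)
            # refinement of connected components
            comp_of = {}
            for ci, comp in enumerate(g.connected_components()):
                for node in comp:
                    comp_of[node] = ci
            for c in clusters:
                assert len({comp_of[m] for m in c.members}) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster(SimilarityGraph(nodes=[]))

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            MCLParams(inflation=1.0)


def _score(gid, h, met=39.3, cls="C"):
    has_nonmet = h is not None
    return GeneScore(gid, f"{gid}.t1", met, (met + h) if has_nonmet else 0.0,
                     True, has_nonmet, h, hgt_class=cls)


class TestHOrth:
    def test_worked_group_average(self):
        """The four-member trehalose-phosphatase group: mean of
        95.7, 102, 97.1, 86.4 is 95.3."""
        scores = {
            "gob-1": _score("gob-1", 95.7),
            "hom1": _score("hom1", 102.0, met=37.0),
            "hom2": _score("hom2", 97.1, met=38.9),
            "hom3": _score("hom3", 86.4, met=36.6),
        }
        group = OrthologGroup("OG0", set(scores))
        assert compute_h_orth(group, scores) == pytest.approx(95.3)

    def test_singleton(self):
        scores = {"g": _score("g", 40.0)}
        assert compute_h_orth(OrthologGroup("OG0", {"g"}), scores) == 40.0

    def test_symmetric_cancellation(self):
        scores = {"a": _score("a", 30.0), "b": _score("b", -30.0)}
        assert compute_h_orth(OrthologGroup("OG0", {"a", "b"}), scores) == 0.0

    def test_unscored_members_excluded_from_mean(self):
        scores = {"a": _score("a", 60.0), "b": _score("b", None)}
        assert compute_h_orth(OrthologGroup("OG0", {"a", "b"}), scores) == 60.0

    def test_no_h_bearing_members_undefined(self):
        scores = {"a": _score("a", None)}
        group = OrthologGroup("OG0", {"a"})
        assert compute_h_orth(group, scores) is None
        annotate_groups([group], scores)
        assert not classify_class_b(scores["a"], group, T)


class TestClassesBA:
    def _group(self, scores):
        g = OrthologGroup("OG0", set(scores))
        annotate_groups([g], scores)
        return g

    def test_worked_example_is_class_a(self):
        scores = {
            "gob-1": _score("gob-1", 95.7, met=39.3),
            "hom1": _score("hom1", 102.0, met=37.0),
            "hom2": _score("hom2", 97.1, met=38.9),
            "hom3": _score("hom3", 86.4, met=36.6),
        }
        g = self._group(scores)
        assert classify_class_b(scores["gob-1"], g, T)
        assert classify_class_a(scores["gob-1"], g, T)

    def test_low_h_orth_stays_class_c(self):
        scores = {"a": _score("a", 40.0), "b": _score("b", 18.0)}
        g = self._group(scores)  # h_orth = 29
        assert g.h_orth == pytest.approx(29.0)
        assert not classify_class_b(scores["a"], g, T)

    def test_native_gene_never_b(self):
        scores = {"a": _score("a", 95.0), "n": _score("n", 90.0, cls="native")}
        g = self._group(scores)
        assert not classify_class_b(scores["n"], g, T)

    def test_group_mate_vetoes_class_a(self):
        scores = {
            "a": _score("a", 95.0, met=99.9),
            "b": _score("b", 80.0, met=150.0),
        }
        g = self._group(scores)
        assert classify_class_b(scores["a"], g, T)
        assert not classify_class_a(scores["a"], g, T)

    def test_singleton_with_no_met_is_a(self):
        scores = {"a": GeneScore("a", "a.t1", 0.0, 150.0, False, True, 150.0,
                                 hgt_class="C")}
        g = self._group(scores)
        assert classify_class_a(scores["a"], g, T)

    def test_nesting_invariant_on_random_inputs(self):
        """A implies B implies C for every random configuration."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            scores = {}
            for i in range(n):
                met = float(rng.uniform(0, 200))
                h = float(rng.uniform(-50, 150))
                cls = "C" if (h >= 30 and met + h >= 100) else "native"
                scores[f"g{i}"] = _score(f"g{i}", h, met=met, cls=cls)
            g = self._group(scores)
            for s in scores.values():
                a = classify_class_a(s, g, T)
                b = classify_class_b(s, g, T)
                c = s.hgt_class == "C"
                assert (not a or b) and (not b or c)


def test_assign_classes_upgrades_in_place():
    scores = {
        "x": _score("x", 95.0, met=39.0),
        "y": _score("y", 90.0, met=40.0),
    }
    groups = [OrthologGroup("OG0", {"x", "y"})]
    membership = assign_classes(scores, groups)
    assert membership == {"x": "OG0", "y": "OG0"}
    assert scores["x"].hgt_class == "A" and scores["y"].hgt_class == "A"
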