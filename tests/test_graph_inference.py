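import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import relgraph as rg
from relgraph import datasets
from relgraph.corpus import Document
from relgraph.graph_inference import Association

GREEN = (0, 255, 0)
RED = (255, 0, 0)


def brute_force_counts(corpus, space_a, space_b):
    """Independent O(docs * |A| * |B|) recount using plain string search."""
    counts = {}
    for doc in corpus:
        padded = " " + " ".join(re.findall(r"[0-9a-z]+", doc.text.lower())) + " "
        for a in space_a.terms:
            if f" {a} " not in padded:
                continue
            for b in space_b.terms:
                if f" {b} " in padded:
                    counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


class TestCountCooccurrences:
    def test_planted_weights(self, planted_corpus, food_space, disease_space):
        corp, spec = planted_corpus
        assocs = rg.count_cooccurrences(corp, food_space, disease_space)
        got = {(a.term_a, a.term_b): a.weight for a in assocs}
        assert got == {
            ("pepper", "stroke"): 5,
            ("milk", "diabetes"): 2,
            ("yogurt", "high cholesterol"): 3,
        }

    def test_matches_brute_force_oracle(self, planted_corpus, food_space, disease_space):
        corp, _ = planted_corpus
        assocs = rg.count_cooccurrences(corp, food_space, disease_space)
        got = {(a.term_a, a.term_b): a.weight for a in assocs}
        assert got == brute_force_counts(corp, food_space, disease_space)

    def test_single_term_doc_contributes_nothing(self, food_space, disease_space):
        corp = rg.Corpus([Document("d", "just some milk here")])
        assert rg.count_cooccurrences(corp, food_space, disease_space) == []

    def test_empty_corpus(self, food_space, disease_space):
        assert rg.count_cooccurrences(rg.Corpus([]), food_space, disease_space) == []

    def test_probability_and_doc_ids(self, food_space, disease_space):
        corp = rg.Corpus(
            [
                Document("b", "pepper and stroke"),
                Document("a", "pepper near stroke"),
                Document("c", "only milk"),
            ]
        )
        (assoc,) = rg.count_cooccurrences(corp, food_space, disease_space)
        assert assoc.weight == 2
        assert assoc.doc_ids == ("a", "b")  # sorted
        assert assoc.probability == pytest.approx(2 / 3)

    def test_overlapping_spaces_rejected(self, food_space):
        other = rg.TermSpace("x", "disease", RED, ("milk", "stroke"))
        with pytest.raises(ValueError, match="disjoint"):
            rg.count_cooccurrences(rg.Corpus([]), food_space, other)

    def test_document_order_invariance(self, planted_corpus, food_space, disease_space):
        corp, _ = planted_corpus
        reversed_corp = rg.Corpus(list(corp)[::-1])
        a1 = {(a.term_a, a.term_b): a.weight
              for a in rg.count_cooccurrences(corp, food_space, disease_space)}
        a2 = {(a.term_a, a.term_b): a.weight
              for a in rg.count_cooccurrences(reversed_corp, food_space, disease_space)}
        assert a1 == a2

    def test_weight_bounded_by_corpus_size(self, planted_corpus, food_space, disease_space):
        corp, _ = planted_corpus
        for a in rg.count_cooccurrences(corp, food_space, disease_space):
            assert 0 < a.weight <= corp.size
            assert a.probability == pytest.approx(a.weight / corp.size)
            assert a.weight == len(a.doc_ids)


class TestBuildRelationshipGraph:
    def _assocs(self, *rows):
        return [Association(term_a=a, term_b=b, weight=w) for a, b, w in rows]

    def test_strict_threshold(self, food_space, disease_space):
        assocs = self._assocs(("pepper", "stroke", 51), ("milk", "stroke", 50))
        g = rg.build_relationship_graph(assocs, food_space, disease_space, min_weight=50)
        assert g.edge_count == 1
        assert g.graph.has_edge("pepper", "stroke")

    def test_threshold_zero_keeps_positive_weights(self, food_space, disease_space):
        assocs = self._assocs(("pepper", "stroke", 1), ("milk", "diabetes", 2))
        g = rg.build_relationship_graph(assocs, food_space, disease_space, min_weight=0)
        assert g.edge_count == 2

    def test_isolated_nodes_dropped(self, food_space, disease_space):
        assocs = self._assocs(("pepper", "stroke", 100), ("milk", "diabetes", 1))
        g = rg.build_relationship_graph(assocs, food_space, disease_space, min_weight=50)
        assert set(g.graph.nodes) == {"pepper", "stroke"}

    def test_negative_threshold_rejected(self, food_space, disease_space):
        with pytest.raises(ValueError):
            rg.build_relationship_graph([], food_space, disease_space, min_weight=-1)

    def test_node_attributes(self, food_space, disease_space):
        assocs = self._assocs(("pepper", "stroke", 3))
        g = rg.build_relationship_graph(assocs, food_space, disease_space)
        assert g.graph.nodes["pepper"]["category"] == "food"
        assert g.graph.nodes["stroke"]["color"] == RED

    @given(st.integers(min_value=0, max_value=10))
    @settings(max_examples=20, deadline=None)
    def test_filter_monotonicity(self, threshold):
        a = rg.TermSpace("a", "food", GREEN, ("x1", "x2", "x3"))
        b = rg.TermSpace("b", "disease", RED, ("y1", "y2", "y3"))
        assocs = [
            Association(term_a=ta, term_b=tb, weight=w)
            for (ta, tb, w) in [
                ("x1", "y1", 1), ("x1", "y2", 4), ("x2", "y2", 7),
                ("x3", "y3", 10), ("x2", "y3", 3),
            ]
        ]
        lo = rg.build_relationship_graph(assocs, a, b, min_weight=threshold)
        hi = rg.build_relationship_graph(assocs, a, b, min_weight=threshold + 1)
        assert hi.edge_count <= lo.edge_count
        assert set(map(frozenset, hi.graph.edges)) <= set(map(frozenset, lo.graph.edges))


class TestComputeMetrics:
    def test_single_edge(self, food_space, disease_space):
        g = rg.build_relationship_graph(
            [Association(term_a="pepper", term_b="stroke", weight=42)],
            food_space, disease_space)
        m = rg.compute_metrics(g)
        assert m.avg_node_degree == 1.0
        assert m.avg_edge_weight == 42.0

    def test_table3_average_weight(self):
        # hand sum of the ten printed weights: 9617 / 10
        g = datasets.obesity_edge_graph()
        m = rg.compute_metrics(g)
        assert m.avg_edge_weight == pytest.approx(961.7)
        assert m.node_count == 16
        assert m.edge_count == 10

    def test_star_degree_handshake(self):
        # star of 73 leaves: avg degree 2*73/74
        goi, _ = rg.make_worked_example(seed=1)
        m = rg.compute_metrics(goi.subgraph)
        assert m.avg_node_degree == pytest.approx(2 * 73 / 74)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty graph"):
            rg.compute_metrics(rg.RelationshipGraph())


class TestTopAssociations:
    def test_table3_top1(self):
        (top,) = rg.top_associations(datasets.obesity_edge_graph(), k=1)
        assert (top.term_b, top.term_a, top.weight) == ("stroke", "pepper", 2098)
        assert top.sign == "positive"

    def test_table4_top2(self):
        top2 = rg.top_associations(datasets.cardio_edge_graph(), k=2)
        assert [(a.term_a, a.weight) for a in top2] == [("garlic", 1910), ("salt", 1748)]

    def test_tie_breaks_lexicographic(self, food_space, disease_space):
        assocs = [
            Association(term_a="pepper", term_b="stroke", weight=5),
            Association(term_a="milk", term_b="diabetes", weight=5),
        ]
        g = rg.build_relationship_graph(assocs, food_space, disease_space)
        ranked = rg.top_associations(g, k=2)
        assert [a.term_b for a in ranked] == ["diabetes", "stroke"]

    def test_k_larger_than_graph(self):
        assert len(rg.top_associations(datasets.obesity_edge_graph(), k=99)) == 10


class TestLoadEdgeTable:
    def test_table3_shape(self):
        g = datasets.obesity_edge_graph()
        assert g.edge_count == 10
        assert g.node_count == 16
        cats = [d["category"] for _, d in g.graph.nodes(data=True)]
        assert cats.count("condition") == 7 and cats.count("food") == 9

    def test_sign_preserved(self):
        g = datasets.obesity_edge_graph()
        assert g.graph["pepper"]["stroke"]["sign"] == "positive"
        assert g.graph["milk"]["adiposity"]["sign"] == "neutral"

    def test_empty_table(self, tmp_path, food_space, disease_space):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        g = rg.load_edge_table(p, food_space, disease_space)
        assert g.edge_count == 0 and g.node_count == 0

    def test_printed_style_sign_in_weight_column(self, tmp_path, food_space, disease_space):
        p = tmp_path / "t.tsv"
        p.write_text("stroke\tpepper\t2098 (positive)\n")
        g = rg.load_edge_table(p, food_space, disease_space)
        assert g.graph["pepper"]["stroke"]["weight"] == 2098
        assert g.graph["pepper"]["stroke"]["sign"] == "positive"

    def test_unknown_term_skipped_by_default(self, tmp_path, food_space, disease_space, caplog):
        p = tmp_path / "t.tsv"
        p.write_text("stroke\tdurian\t10\n" "stroke\tpepper\t20\n")
        g = rg.load_edge_table(p, food_space, disease_space)
        assert g.edge_count == 1

    def test_unknown_term_strict(self, tmp_path, food_space, disease_space):
        p = tmp_path / "t.tsv"
        p.write_text("stroke\tdurian\t10\n")
        with pytest.raises(ValueError, match="unknown term"):
            rg.load_edge_table(p, food_space, disease_space, strict=True)

    def test_malformed_row(self, tmp_path, food_space, disease_space):
        p = tmp_path / "t.tsv"
        p.write_text("only-two\tfields\n")
        with pytest.raises(ValueError, match="expected >=3"):
            rg.load_edge_table(p, food_space, disease_space)


class TestGraphML:
    def test_round_trip(self, tmp_path, planted_corpus, food_space, disease_space):
        corp, _ = planted_corpus
        assocs = rg.count_cooccurrences(corp, food_space, disease_space)
        g = rg.build_relationship_graph(assocs, food_space, disease_space)
        p = tmp_path / "g.graphml"
        rg.write_graphml(g, p)
        back = rg.read_graphml(p)
        assert set(back.graph.nodes) == set(g.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(map(frozenset, g.graph.edges))
        for u, v, data in g.graph.edges(data=True):
            bd = back.graph[u][v]
            assert bd["weight"] == data["weight"]
            assert tuple(bd["doc_ids"]) == tuple(data["doc_ids"])
            assert back.graph.nodes[u]["color"] == g.graph.nodes[u]["color"]


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(20))
    def test_recovery_and_oracle_across_seeds(self, seed):
        from conftest import make_planted_replicate

        corpus, spec, space_a, space_b = make_planted_replicate(seed)
        assert corpus.size <= 500
        assocs = rg.count_cooccurrences(corpus, space_a, space_b)
        got = {(a.term_a, a.term_b): a.weight for a in assocs}
        truth = {
            (rg.normalize_term(a), rg.normalize_term(b)): c
            for (a, b), c in spec.pair_counts.items()
        }
        assert got == truth
        assert got == brute_force_counts(corpus, space_a, space_b)
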