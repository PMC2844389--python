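"""Shortest dependency paths, UP/DN/PRED/NEG annotation, instance rendering."""

import pytest

from walkernel.graph_prep import DependencyGraph, NodeData
from walkernel.path_extract import (
    annotate_directions,
    enumerate_instances,
    extend_single_dependency_path,
    insert_negation_mark,
    mark_predicates,
    render_instance,
    shortest_path,
)
from walkernel.records import DependencyEdge, Entity, InteractionGold, SentenceRecord, Token

from oracles import bfs_distance, random_tree_edges


def _graph(n, edges, surfaces=None):
    g = DependencyGraph()
    for i in range(1, n + 1):
        surf = surfaces[i - 1] if surfaces else f"w{i}"
        g.nodes[i] = NodeData(surf, "NN")
    g.edges = set(edges)
    return g


class TestShortestPath:
    def test_direct_dependency_gives_two_nodes(self):
        g = _graph(2, [(2, 1, "subj")])
        assert shortest_path(g, 1, 2) == [1, 2]

    def test_matches_bfs_oracle_on_random_trees(self, rng):
        for _ in range(200):
            n = rng.randint(2, 15)
            edges = random_tree_edges(rng, n)
            g = _graph(n, edges)
            a, b = rng.sample(range(1, n + 1), 2)
            path = shortest_path(g, a, b)
            assert len(path) - 1 == bfs_distance(edges, a, b)

    def test_tie_break_prefers_smallest_node_sequence(self):
        # diamond: 1-2-4 and 1-3-4 are both length 2
        g = _graph(4, [(1, 2, "a"), (1, 3, "a"), (2, 4, "b"), (3, 4, "b")])
        assert shortest_path(g, 1, 4) == [1, 2, 4]

    def test_disconnected_pair_returns_empty(self):
        g = _graph(4, [(1, 2, "a"), (3, 4, "b")])
        assert shortest_path(g, 1, 4) == []


class TestDirectionAnnotation:
    def test_up_down_labels_follow_traversal(self):
        # 1 <-subj- 2 -obj-> 3: traversing 1->2 goes dependent-to-head
        g = _graph(3, [(2, 1, "subj"), (2, 3, "obj")])
        path = annotate_directions([1, 2, 3], g)
        assert path.directions == ["UP", "DN"]
        rev = annotate_directions([3, 2, 1], g)
        assert rev.directions == ["UP", "DN"]  # reversal swaps every UP/DN

    def test_direction_count_equals_edge_count(self, rng):
        for _ in range(50):
            n = rng.randint(2, 12)
            g = _graph(n, random_tree_edges(rng, n))
            a, b = rng.sample(range(1, n + 1), 2)
            nodes = shortest_path(g, a, b)
            path = annotate_directions(nodes, g)
            assert len(path.directions) == len(nodes) - 1
            assert set(path.directions) <= {"UP", "DN"}


class TestPredicateMarking:
    def test_single_pivot_gets_exactly_one_pred(self, rng):
        """On a tree, any path has exactly one direction pivot: its apex."""
        for _ in range(100):
            n = rng.randint(3, 12)
            g = _graph(n, random_tree_edges(rng, n))
            a, b = rng.sample(range(1, n + 1), 2)
            path = mark_predicates(annotate_directions(shortest_path(g, a, b), g))
            apex_count = sum(path.pred)
            # monotone paths (ancestor/descendant pairs) have no pivot
            if path.directions and "UP" in path.directions and "DN" in path.directions:
                assert apex_count == 1
            else:
                assert apex_count == 0
            assert not path.pred[0] and not path.pred[-1]

    def test_monotone_path_unmarked(self):
        g = _graph(3, [(3, 2, "a"), (2, 1, "b")])  # chain, all UP from 1
        path = mark_predicates(annotate_directions([1, 2, 3], g))
        assert path.directions == ["UP", "UP"] and not any(path.pred)


class TestPathExtension:
    def _conj_graph(self):
        # "interaction between A and B": interaction -prep_between-> A -conj_and-> B
        return _graph(
            3,
            [(1, 2, "prep_between"), (2, 3, "conj_and")],
            surfaces=["interaction", "A", "B"],
        )

    def test_conjunction_path_pulls_in_governing_head(self):
        g = self._conj_graph()
        path = annotate_directions([2, 3], g)
        ext = extend_single_dependency_path(path, g)
        assert ext.nodes == [1, 2, 3]
        assert "interaction" in {g.nodes[n].surface for n in ext.nodes}
        assert len(ext.nodes) * 2 - 1 - 3 <= 4  # at most 4 extra symbols

    def test_non_conjunction_single_path_unchanged(self):
        g = _graph(2, [(1, 2, "obj")])
        path = annotate_directions([1, 2], g)
        assert extend_single_dependency_path(path, g) is path

    def test_longer_paths_unchanged(self):
        g = self._conj_graph()
        path = annotate_directions([1, 2, 3], g)
        assert extend_single_dependency_path(path, g) is path


class TestNegation:
    def test_neg_relation_child_marks_predicate(self):
        g = _graph(4, [(2, 1, "subj"), (2, 3, "obj"), (2, 4, "neg")])
        path = insert_negation_mark(mark_predicates(annotate_directions([1, 2, 3], g)), g)
        assert path.neg == [False, True, False]

    def test_lexical_cue_child_marks_predicate(self):
        g = _graph(4, [(2, 1, "subj"), (2, 3, "obj"), (2, 4, "mod")])
        g.nodes[4] = NodeData("not", "RB")
        path = insert_negation_mark(mark_predicates(annotate_directions([1, 2, 3], g)), g)
        assert path.neg[1]

    def test_no_cue_leaves_path_unchanged(self):
        g = _graph(3, [(2, 1, "subj"), (2, 3, "obj")])
        path = insert_negation_mark(mark_predicates(annotate_directions([1, 2, 3], g)), g)
        assert not any(path.neg)


def _simple_record(gold_agent=None):
    rec = SentenceRecord(
        doc_id="d",
        sent_id="d.s",
        tokens=[
            Token(1, "sigK", "NN"),
            Token(2, "activates", "VBZ"),
            Token(3, "cotD", "NN"),
        ],
        edges=[DependencyEdge(2, 1, "subj"), DependencyEdge(2, 3, "obj")],
        entities=[Entity("e1", (1,)), Entity("e2", (3,))],
    )
    if gold_agent:
        other = "e2" if gold_agent == "e1" else "e1"
        rec.golds.append(InteractionGold(agent=gold_agent, target=other, directed=True))
    return rec


class TestRenderInstance:
    def test_agent_first_is_AT_and_strings_blind_entities(self):
        rec = _simple_record(gold_agent="e1")
        inst = render_instance(rec, rec.entities[0], rec.entities[1])
        assert inst.label == "AT"
        assert inst.lexical.symbols == ("NE", "subj(UP)", "activates:PRED", "obj(DN)", "NE")
        assert inst.syntactic.symbols == ("NN", "subj(UP)", "VBZ:PRED", "obj(DN)", "NN")

    def test_swapping_arguments_flips_label_and_reverses_path(self):
        rec = _simple_record(gold_agent="e1")
        fwd = render_instance(rec, rec.entities[0], rec.entities[1])
        rev = render_instance(rec, rec.entities[1], rec.entities[0])
        assert (fwd.label, rev.label) == ("AT", "TA")

        def flip(sym):
            return sym.replace("(UP)", "(XX)").replace("(DN)", "(UP)").replace("(XX)", "(DN)")

        assert rev.lexical.symbols == tuple(flip(s) for s in reversed(fwd.lexical.symbols))

    def test_pair_without_gold_is_O(self):
        rec = _simple_record()
        inst = render_instance(rec, rec.entities[0], rec.entities[1])
        assert inst.label == "O"

    def test_self_pair_is_negative(self):
        rec = _simple_record(gold_agent="e1")
        inst = render_instance(rec, rec.entities[0], rec.entities[0])
        assert inst.label == "O"

    def test_disconnected_pair_yields_empty_O_instance(self):
        rec = _simple_record(gold_agent="e1")
        rec.edges = [DependencyEdge(2, 1, "subj")]  # cotD now isolated
        inst = render_instance(rec, rec.entities[0], rec.entities[1])
        assert inst.label == "O" and inst.is_empty and not inst.connected

    def test_rendering_is_deterministic(self, small_corpus):
        rec = next(r for r in small_corpus if len(r.entities) >= 2)
        a = render_instance(rec, rec.entities[0], rec.entities[1])
        b = render_instance(rec, rec.entities[0], rec.entities[1])
        assert a == b


class TestEnumerateInstances:
    def test_three_entities_give_three_pairs_plus_self_pairs(self):
        rec = _simple_record()
        rec.entities.append(Entity("e3", (2,)))
        with_self = enumerate_instances(rec)
        without = enumerate_instances(rec, include_self_pairs=False)
        assert len(without) == 3 and len(with_self) == 6
        assert all(i.label == "O" for i in with_self if i.e1 == i.e2)

    def test_pairs_come_in_word_order(self, small_corpus):
        for rec in small_corpus:
            for inst in enumerate_instances(rec, include_self_pairs=False):
                t1 = min(rec.entity_by_id(inst.e1).token_indices)
                t2 = min(rec.entity_by_id(inst.e2).token_indices)
                assert t1 <= t2

    def test_alternation_invariant_on_all_instances(self, small_instances):
        for inst in small_instances:
            for ps in (inst.lexical, inst.syntactic):
                assert len(ps.symbols) % 2 == (1 if ps.symbols else 0)
                for i, role in enumerate(ps.roles):
                    assert role == ("n" if i % 2 == 0 else "e")
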