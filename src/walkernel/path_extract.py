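"""Directed shortest dependency paths and relation-instance rendering.

Given a repaired :class:`~walkernel.graph_prep.DependencyGraph` and a
candidate entity pair, this module computes the shortest path between the two
entity nodes over the undirected view of the graph, then decorates it:

* every traversed edge carries ``(UP)`` (dependent -> head) or ``(DN)``
  (head -> dependent), preserving the original relation orientation;
* an internal node whose left edge is ``(UP)`` and right edge is ``(DN)`` is
  a direction pivot — typically the governing predicate — and is marked
  ``PRED``;
* degenerate single-dependency paths joined by a coordinating conjunction
  are extended upward with the first entity's head (and its head) so that
  clue words like "interaction between ~ and ~" enter the path;
* a ``NEG`` mark is prefixed to a predicate that has a negation cue among its
  direct dependents.

The decorated path is rendered twice — lexically (lower-cased surfaces,
candidate entities blinded to ``NE``) and syntactically (POS tags) — and,
together with the path-internal dependency lists and the AT/TA/O label,
forms one :class:`RelationInstance`, the unit all kernels operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .graph_prep import DependencyGraph, prepare_graph
from .records import Entity, SentenceRecord

__all__ = [
    "PathString",
    "DependencyList",
    "RelationInstance",
    "DependencyPath",
    "shortest_path",
    "annotate_directions",
    "mark_predicates",
    "extend_single_dependency_path",
    "insert_negation_mark",
    "render_instance",
    "enumerate_instances",
    "DEFAULT_CONJ_RELATIONS",
    "DEFAULT_NEGATION_CUES",
]

#: Coordinating-conjunction relations that trigger single-path extension.
DEFAULT_CONJ_RELATIONS = frozenset({"conj_and", "conj_or", "conj", "cc"})

#: Lexical negation cues; a predicate with one of these (or a ``neg``-labelled
#: edge) among its direct dependents receives the NEG mark.
DEFAULT_NEGATION_CUES = frozenset(
    {"not", "no", "n't", "never", "cannot", "fail", "unable", "without", "lack", "absence"}
)


@dataclass(frozen=True)
class PathString:
    """Alternating node/edge symbol sequence with per-symbol role tags.

    Roles strictly alternate ``n, e, n, ...`` and the sequence starts and
    ends on a node. For unextended paths the terminal nodes are the two
    candidate entities; upward extension of degenerate conjunction paths may
    prepend context nodes. An empty PathString (disconnected pair) has no
    symbols and scores zero against everything.
    """

    symbols: tuple[str, ...]
    roles: tuple[str, ...]
    variant: str  # "lexical" | "syntactic"

    def __post_init__(self) -> None:
        assert len(self.symbols) == len(self.roles)
        for i, r in enumerate(self.roles):
            assert r == ("n" if i % 2 == 0 else "e"), "roles must alternate n,e,n,..."

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "_".join(self.symbols)


@dataclass(frozen=True)
class DependencyList:
    """Path-internal dependency structure for the dependency kernel.

    ``symbols[i]`` names path node ``i``; ``children[i]`` holds
    ``(edge_symbol, child_path_index)`` pairs restricted to direct dependents
    that are themselves on the path; ``subcats[i]`` is the (left edge symbol,
    right edge symbol) pair around node ``i`` — endpoints have one ``None``
    side.
    """

    symbols: tuple[str, ...]
    subcats: tuple[tuple[str | None, str | None], ...]
    children: tuple[tuple[tuple[str, int], ...], ...]


@dataclass(frozen=True)
class RelationInstance:
    """One candidate entity pair, fully rendered for the kernels."""

    doc_id: str
    sent_id: str
    e1: str
    e2: str
    label: str  # AT | TA | O
    lexical: PathString
    syntactic: PathString
    word_deps: DependencyList
    pos_deps: DependencyList
    connected: bool = True

    @property
    def is_empty(self) -> bool:
        return len(self.lexical) == 0


@dataclass
class DependencyPath:
    """Working representation: node ids plus per-step/per-node annotation."""

    nodes: list[int]
    relations: list[str] = field(default_factory=list)     # per step
    directions: list[str] = field(default_factory=list)    # "UP" | "DN" per step
    pred: list[bool] = field(default_factory=list)         # per node
    neg: list[bool] = field(default_factory=list)          # per node


def _adjacency(g: DependencyGraph) -> nx.Graph:
    ug = nx.Graph()
    ug.add_nodes_from(g.nodes)
    for h, d, _ in g.edges:
        ug.add_edge(h, d)
    return ug


def shortest_path(g: DependencyGraph, e1: int, e2: int) -> list[int]:
    """Minimum-edge path between two nodes on the undirected view.

    Returns the node-id sequence, or ``[]`` when the nodes lie in different
    components. Among equal-length paths the lexicographically smallest
    node-index sequence is chosen, which makes extraction deterministic.
    """
    if e1 == e2:
        return [e1]
    ug = _adjacency(g)
    if e1 not in ug or e2 not in ug:
        return []
    d1 = nx.single_source_shortest_path_length(ug, e1)
    if e2 not in d1:
        return []
    d2 = nx.single_source_shortest_path_length(ug, e2)
    total = d1[e2]
    path = [e1]
    cur = e1
    for k in range(1, total + 1):
        nxt = min(
            n for n in ug.neighbors(cur) if d1.get(n) == k and d2.get(n) == total - k
        )
        path.append(nxt)
        cur = nxt
    return path


def _edge_between(g: DependencyGraph, a: int, b: int) -> tuple[str, str]:
    """Relation and direction for traversing a -> b on the original edges."""
    down = sorted(r for h, d, r in g.edges if h == a and d == b)
    up = sorted(r for h, d, r in g.edges if h == b and d == a)
    if down:
        return down[0], "DN"  # a is head: head-to-dependent
    if up:
        return up[0], "UP"  # a is dependent: dependent-to-head
    raise KeyError(f"no edge between nodes {a} and {b}")


def annotate_directions(nodes: list[int], g: DependencyGraph) -> DependencyPath:
    """Attach relation labels and UP/DN direction to every step of a path."""
    relations, directions = [], []
    for a, b in zip(nodes, nodes[1:]):
        r, direc = _edge_between(g, a, b)
        relations.append(r)
        directions.append(direc)
    return DependencyPath(
        nodes=list(nodes),
        relations=relations,
        directions=directions,
        pred=[False] * len(nodes),
        neg=[False] * len(nodes),
    )


def mark_predicates(path: DependencyPath) -> DependencyPath:
    """Mark direction pivots: internal nodes with left UP and right DN.

    Such a node heads both its neighbours on the path — the typical predicate
    whose arguments the two entities (directly or indirectly) fill. Endpoints
    are never marked.
    """
    for i in range(1, len(path.nodes) - 1):
        if path.directions[i - 1] == "UP" and path.directions[i] == "DN":
            path.pred[i] = True
    return path


def _base_relation(rel: str) -> str:
    return rel.split(":")[0]


def extend_single_dependency_path(
    path: DependencyPath,
    g: DependencyGraph,
    conj_relations: frozenset[str] = DEFAULT_CONJ_RELATIONS,
) -> DependencyPath:
    """Extend a degenerate two-node conjunction path with governing context.

    Applies only when the path is exactly ``NE -conj- NE``: the immediate
    head of the first entity and the head of that head (up to two hops, at
    most four extra symbols) are prepended, pulling clue words such as
    "interaction" into the path. Any other path is returned unchanged.
    """
    if len(path.nodes) != 2 or _base_relation(path.relations[0]) not in conj_relations:
        return path
    first = path.nodes[0]
    on_path = set(path.nodes)
    prefix_nodes: list[int] = []
    prefix_rels: list[str] = []
    cur = first
    for _hop in range(2):
        heads = sorted((h, r) for h, d, r in g.edges if d == cur and h not in on_path)
        if not heads:
            break
        h, r = heads[0]
        prefix_nodes.append(h)
        prefix_rels.append(r)
        on_path.add(h)
        cur = h
    if not prefix_nodes:
        return path
    # prefix is ordered entity -> head -> grand-head; prepend reversed
    new_nodes = list(reversed(prefix_nodes)) + path.nodes
    return annotate_directions(new_nodes, g)


def insert_negation_mark(
    path: DependencyPath,
    g: DependencyGraph,
    cues: frozenset[str] = DEFAULT_NEGATION_CUES,
) -> DependencyPath:
    """Prefix NEG to each PRED node that governs a negation cue.

    A cue is a direct dependent reached by a ``neg`` relation or whose
    surface form is in the cue lexicon.
    """
    for i, node in enumerate(path.nodes):
        if not path.pred[i]:
            continue
        for h, d, r in g.edges:
            if h != node:
                continue
            dep = g.nodes.get(d)
            if _base_relation(r) == "neg" or (
                dep is not None and dep.surface.lower() in cues
            ):
                path.neg[i] = True
                break
    return path


def _node_symbol(g: DependencyGraph, node: int, variant: str, pair_ids: set[str]) -> str:
    data = g.nodes[node]
    if variant == "lexical":
        if data.entity_id is not None and data.entity_id in pair_ids:
            return "NE"
        return data.surface.lower()
    return data.pos


def _render_path_string(
    path: DependencyPath, g: DependencyGraph, variant: str, pair_ids: set[str]
) -> PathString:
    symbols: list[str] = []
    roles: list[str] = []
    for i, node in enumerate(path.nodes):
        sym = _node_symbol(g, node, variant, pair_ids)
        if path.pred[i]:
            sym = f"{sym}:PRED"
        if path.neg[i]:
            sym = f"NEG:{sym}"
        symbols.append(sym)
        roles.append("n")
        if i < len(path.relations):
            symbols.append(f"{path.relations[i]}({path.directions[i]})")
            roles.append("e")
    return PathString(symbols=tuple(symbols), roles=tuple(roles), variant=variant)


def _render_dependency_list(
    path: DependencyPath, g: DependencyGraph, variant: str, pair_ids: set[str]
) -> DependencyList:
    n = len(path.nodes)
    symbols = tuple(_node_symbol(g, node, variant, pair_ids) for node in path.nodes)
    edge_syms = [f"{r}({d})" for r, d in zip(path.relations, path.directions)]
    subcats = tuple(
        (edge_syms[i - 1] if i > 0 else None, edge_syms[i] if i < n - 1 else None)
        for i in range(n)
    )
    children: list[tuple[tuple[str, int], ...]] = []
    for i in range(n):
        ch: list[tuple[str, int]] = []
        if i > 0 and path.directions[i - 1] == "UP":
            ch.append((edge_syms[i - 1], i - 1))  # left neighbour is my dependent
        if i < n - 1 and path.directions[i] == "DN":
            ch.append((edge_syms[i], i + 1))  # right neighbour is my dependent
        children.append(tuple(ch))
    return DependencyList(symbols=symbols, subcats=subcats, children=tuple(children))


_EMPTY_LEX = PathString(symbols=(), roles=(), variant="lexical")
_EMPTY_SYN = PathString(symbols=(), roles=(), variant="syntactic")
_EMPTY_DEPS = DependencyList(symbols=(), subcats=(), children=())


def _label_for_pair(rec: SentenceRecord, e1: Entity, e2: Entity) -> str:
    """AT if a gold names e1 as agent, TA if e2; undirected golds are AT."""
    if e1.id == e2.id:
        return "O"  # self interactions are regarded as negative
    for g in rec.golds:
        if g.agent == e1.id and g.target == e2.id:
            return "AT"
        if g.agent == e2.id and g.target == e1.id:
            return "TA" if g.directed else "AT"
    return "O"


def render_instance(
    rec: SentenceRecord,
    e1: Entity,
    e2: Entity,
    *,
    conj_relations: frozenset[str] = DEFAULT_CONJ_RELATIONS,
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES,
    extend_paths: bool = True,
) -> RelationInstance:
    """Build the full RelationInstance for one ordered candidate pair.

    The caller passes entities in word order (see :func:`enumerate_instances`);
    swapping the arguments flips AT/TA and reverses the path with every UP/DN
    exchanged.
    """
    pair_ids = {e1.id, e2.id}
    g = prepare_graph(rec, (e1, e2))
    node_of: dict[str, int] = {}
    for nid, data in g.nodes.items():
        if data.entity_id in pair_ids:
            node_of[data.entity_id] = nid
    label = _label_for_pair(rec, e1, e2)
    n1 = node_of.get(e1.id)
    n2 = node_of.get(e2.id)
    if n1 is None or n2 is None:
        nodes: list[int] = []
    else:
        nodes = shortest_path(g, n1, n2)
    if not nodes:
        return RelationInstance(
            doc_id=rec.doc_id, sent_id=rec.sent_id, e1=e1.id, e2=e2.id, label="O",
            lexical=_EMPTY_LEX, syntactic=_EMPTY_SYN,
            word_deps=_EMPTY_DEPS, pos_deps=_EMPTY_DEPS, connected=False,
        )
    path = annotate_directions(nodes, g)
    if extend_paths:
        path = extend_single_dependency_path(path, g, conj_relations)
    path = mark_predicates(path)
    path = insert_negation_mark(path, g, negation_cues)
    return RelationInstance(
        doc_id=rec.doc_id,
        sent_id=rec.sent_id,
        e1=e1.id,
        e2=e2.id,
        label=label,
        lexical=_render_path_string(path, g, "lexical", pair_ids),
        syntactic=_render_path_string(path, g, "syntactic", pair_ids),
        word_deps=_render_dependency_list(path, g, "lexical", pair_ids),
        pos_deps=_render_dependency_list(path, g, "syntactic", pair_ids),
    )


def enumerate_instances(
    rec: SentenceRecord,
    *,
    include_self_pairs: bool = True,
    **render_kwargs,
) -> list[RelationInstance]:
    """All entity-occurrence pairs of a sentence, in word order.

    Every unordered pair of entity occurrences (nested and repeated-name
    occurrences included) yields one instance; self-pairs (the same
    occurrence twice) are O by definition and can be switched off.
    """
    ents = sorted(rec.entities, key=lambda e: (min(e.token_indices), e.id))
    out: list[RelationInstance] = []
    for a, b in combinations(ents, 2):
        out.append(render_instance(rec, a, b, **render_kwargs))
    if include_self_pairs:
        for e in ents:
            out.append(render_instance(rec, e, e, **render_kwargs))
    return out


def instances_to_tsv(instances: list[RelationInstance]) -> str:
    """Tabular export (doc, sentence, pair, strings, label) for inspection."""
    lines = ["doc_id\tsent_id\te1\te2\tlexical\tsyntactic\tlabel"]
    for inst in instances:
        lines.append(
            f"{inst.doc_id}\t{inst.sent_id}\t{inst.e1}\t{inst.e2}\t"
            f"{inst.lexical}\t{inst.syntactic}\t{inst.label}"
        )
    return "\n".join(lines) + "\n"
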