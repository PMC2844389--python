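"""Dependency-graph construction and repair.

Automatically converted parses suffer three defects that must be repaired
before path extraction: (1) multiple typed relations between the same ordered
node pair, (2) two-cycles — an edge (x, y) coexisting with its inverse
(y, x) — and (3) named-entity words split over several nodes, whose incident
relations must be regrouped onto a single merged node. All repairs are
deterministic, idempotent, and counted in the graph's provenance so a corpus
run can report how much repair was applied.

Entity grouping is performed *per analysed candidate pair* (nested entities
mean one sentence can legitimately yield differently grouped graphs for
different pairs), so :func:`group_entity_tokens` takes the entities to merge
explicitly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .records import CorpusIntegrityError, Entity, SentenceRecord

__all__ = [
    "NodeData",
    "DependencyGraph",
    "build_graph",
    "remove_multiple_relations",
    "remove_self_cycles",
    "group_entity_tokens",
    "prepare_graph",
]

#: Placeholder surface for a merged named-entity node; path rendering blinds
#: candidate entities to this symbol.
NE_PLACEHOLDER = "NE"


@dataclass
class NodeData:
    surface: str
    pos: str
    entity_id: str | None = None


@dataclass
class DependencyGraph:
    """Directed typed graph over word (or merged-entity) nodes."""

    nodes: dict[int, NodeData] = field(default_factory=dict)
    edges: set[tuple[int, int, str]] = field(default_factory=set)
    provenance: Counter = field(default_factory=Counter)

    def copy(self) -> "DependencyGraph":
        return DependencyGraph(
            nodes={k: NodeData(v.surface, v.pos, v.entity_id) for k, v in self.nodes.items()},
            edges=set(self.edges),
            provenance=Counter(self.provenance),
        )

    def neighbors(self, n: int) -> set[int]:
        out = set()
        for h, d, _ in self.edges:
            if h == n:
                out.add(d)
            elif d == n:
                out.add(h)
        return out

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        seen = set()
        stack = [next(iter(self.nodes))]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(self.neighbors(n) - seen)
        return seen == set(self.nodes)


def build_graph(rec: SentenceRecord) -> DependencyGraph:
    """One node per token, all edges copied verbatim; no repairs yet."""
    g = DependencyGraph()
    for t in rec.tokens:
        g.nodes[t.index] = NodeData(surface=t.surface, pos=t.pos)
    for e in rec.edges:
        g.edges.add((e.head, e.dependent, e.relation))
    return g


def remove_multiple_relations(g: DependencyGraph) -> DependencyGraph:
    """Keep exactly one edge per ordered (head, dependent) pair.

    Tie-break: the lexicographically smallest relation label survives, which
    is deterministic and independent of input order.
    """
    out = g.copy()
    best: dict[tuple[int, int], str] = {}
    removed = 0
    for h, d, r in sorted(out.edges):
        if (h, d) in best:
            removed += 1  # sorted order means the kept label came first
        else:
            best[(h, d)] = r
    out.edges = {(h, d, r) for (h, d), r in best.items()}
    out.provenance["multiple_relations_removed"] += removed
    return out


def _head_support(g: DependencyGraph, node: int, exclude: frozenset) -> int:
    """Number of edges (outside ``exclude``) in which ``node`` acts as head."""
    return sum(1 for h, d, r in g.edges if h == node and (h, d, r) not in exclude)


def remove_self_cycles(g: DependencyGraph) -> DependencyGraph:
    """Break every two-cycle, keeping one direction.

    The surviving edge is the one whose dependent has the larger external
    support as a head (more other edges headed by it, so the subtree below it
    is better attested); remaining ties break lexicographically by relation,
    then by direction.
    """
    out = g.copy()
    by_pair: dict[tuple[int, int], list[tuple[int, int, str]]] = {}
    for h, d, r in out.edges:
        by_pair.setdefault((min(h, d), max(h, d)), []).append((h, d, r))
    removed = 0
    for pair, es in by_pair.items():
        directions = {(h, d) for h, d, _ in es}
        if len(directions) < 2:
            continue
        cyc = frozenset(es)

        def rank(edge: tuple[int, int, str]):
            h, d, r = edge
            return (-_head_support(out, d, cyc), r, h, d)

        keep = min(es, key=rank)
        for e in es:
            if e != keep:
                out.edges.discard(e)
                removed += 1
    out.provenance["self_cycles_removed"] += removed
    return out


def group_entity_tokens(
    g: DependencyGraph,
    entities: list[Entity],
    head_token: str = "last",
) -> DependencyGraph:
    """Collapse each entity's token nodes into a single merged node.

    The merged node keeps the id of the entity's head token (the last token
    of the span under the right-headed noun-compound assumption; set
    ``head_token='first'`` to flip). Edges internal to the entity are
    deleted; edges between an entity token and an outside token re-attach to
    the merged node; duplicates created by the re-attachment are
    re-deduplicated. The merged node's surface is the NE placeholder and its
    POS is the head token's POS.
    """
    if head_token not in ("last", "first"):
        raise ValueError("head_token must be 'last' or 'first'")
    out = g.copy()
    for ent in entities:
        if not ent.token_indices:
            raise CorpusIntegrityError(f"entity {ent.id} has no tokens")
        present = [i for i in ent.token_indices if i in out.nodes]
        if not present:
            raise CorpusIntegrityError(f"entity {ent.id}: no tokens present in graph")
        head = present[-1] if head_token == "last" else present[0]
        members = set(present)
        head_data = out.nodes[head]
        merged = NodeData(surface=NE_PLACEHOLDER, pos=head_data.pos, entity_id=ent.id)
        new_edges = set()
        dropped_internal = 0
        for h, d, r in out.edges:
            h2 = head if h in members else h
            d2 = head if d in members else d
            if h2 == d2:
                dropped_internal += 1
                continue
            new_edges.add((h2, d2, r))
        out.edges = new_edges
        for m in members:
            out.nodes.pop(m, None)
        out.nodes[head] = merged
        if len(members) > 1 or dropped_internal:
            out.provenance["entity_group_operations"] += 1
    # re-attachment can recreate parallel edges or two-cycles
    out = remove_multiple_relations(out)
    out = remove_self_cycles(out)
    return out


def prepare_graph(rec: SentenceRecord, pair: tuple[Entity, Entity] | None = None) -> DependencyGraph:
    """Full repair pipeline for one sentence (and one analysed entity pair).

    Dedup, two-cycle removal, then grouping of the candidate pair's entities
    (only the analysed pair is grouped; other entities keep their tokens).
    """
    g = build_graph(rec)
    g = remove_multiple_relations(g)
    g = remove_self_cycles(g)
    if pair is not None:
        uniq: list[Entity] = []
        for ent in pair:
            if all(ent.id != u.id for u in uniq):
                uniq.append(ent)
        g = group_entity_tokens(g, uniq)
    return g
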