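"""Core sentence-level record types shared by every stage of the pipeline.

A parsed sentence is modelled as a list of :class:`Token` objects, a list of
typed :class:`DependencyEdge` objects (head -> dependent), the named entities
annotated on it, and the gold interaction pairs. Character offsets are stored
0-based half-open; corpus readers convert from whatever convention their
dialect uses at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator


class CorpusIntegrityError(ValueError):
    """A record violates a structural invariant (dangling ids, bad offsets)."""


@dataclass(frozen=True)
class Token:
    """One token of a sentence.

    ``index`` is 1-based within the sentence; ``span`` is a 0-based half-open
    character interval into the sentence text.
    """

    index: int
    surface: str
    pos: str
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.span != (0, 0) and not self.span[0] < self.span[1]:
            raise CorpusIntegrityError(
                f"token {self.index} ({self.surface!r}): span begin must precede end"
            )


@dataclass(frozen=True)
class DependencyEdge:
    """A typed grammatical relation, oriented head -> dependent."""

    head: int
    dependent: int
    relation: str

    def __post_init__(self) -> None:
        if not self.relation:
            raise CorpusIntegrityError("dependency edge with empty relation label")


@dataclass(frozen=True)
class Entity:
    """A named entity (protein/gene/RNA/chemical) over one or more tokens.

    Entities may nest or overlap: an embedded entity lies entirely inside a
    longer one and both are legal interaction candidates.
    """

    id: str
    token_indices: tuple[int, ...]
    etype: str = "protein"

    def __post_init__(self) -> None:
        if not self.token_indices:
            raise CorpusIntegrityError(f"entity {self.id}: no tokens")
        if list(self.token_indices) != sorted(self.token_indices):
            raise CorpusIntegrityError(f"entity {self.id}: token indices not sorted")


@dataclass(frozen=True)
class InteractionGold:
    """A gold interaction between two entities of one sentence.

    ``directed`` marks corpora that annotate agent/target roles; undirected
    corpora store the pair with ``directed=False`` and the agent/target
    assignment carries no meaning beyond pair identity.
    """

    agent: str
    target: str
    directed: bool = True


@dataclass
class SentenceRecord:
    """One dependency-parsed sentence with entity and interaction annotation."""

    doc_id: str
    sent_id: str
    text: str = ""
    tokens: list[Token] = field(default_factory=list)
    edges: list[DependencyEdge] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    golds: list[InteractionGold] = field(default_factory=list)

    def validate(self) -> "SentenceRecord":
        idx = {t.index for t in self.tokens}
        if len(idx) != len(self.tokens):
            raise CorpusIntegrityError(f"{self.sent_id}: duplicate token indices")
        for e in self.edges:
            if e.head not in idx or e.dependent not in idx:
                raise CorpusIntegrityError(
                    f"{self.sent_id}: edge {e.head}->{e.dependent} references missing token"
                )
        for ent in self.entities:
            for ti in ent.token_indices:
                if ti not in idx:
                    raise CorpusIntegrityError(
                        f"{self.sent_id}: entity {ent.id} references missing token {ti}"
                    )
        eids = {ent.id for ent in self.entities}
        for g in self.golds:
            if g.agent not in eids or g.target not in eids:
                raise CorpusIntegrityError(
                    f"{self.sent_id}: gold {g.agent}->{g.target} references missing entity"
                )
        return self

    def entity_by_id(self, eid: str) -> Entity:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(eid)

    # ---- JSON-lines serialization (internal fixture format) ----

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "SentenceRecord":
        d = json.loads(line)
        return cls(
            doc_id=d["doc_id"],
            sent_id=d["sent_id"],
            text=d.get("text", ""),
            tokens=[Token(t["index"], t["surface"], t["pos"], tuple(t["span"])) for t in d["tokens"]],
            edges=[DependencyEdge(e["head"], e["dependent"], e["relation"]) for e in d["edges"]],
            entities=[Entity(e["id"], tuple(e["token_indices"]), e["etype"]) for e in d["entities"]],
            golds=[InteractionGold(g["agent"], g["target"], g["directed"]) for g in d["golds"]],
        ).validate()


def write_jsonl(records: Iterable[SentenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_jsonl(path) -> Iterator[SentenceRecord]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield SentenceRecord.from_json(line)
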