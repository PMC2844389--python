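"""Synthetic PPI corpus generator.

Emits :class:`~walkernel.records.SentenceRecord` collections with the same
structural shape as the real genic-interaction corpora: random projective
dependency trees over a small vocabulary, two (occasionally nested) named
entities per sentence, and — in a configurable fraction of sentences — a
planted positive interaction pattern connecting the two entities through a
predicate, with a known agent/target direction. Remaining entity pairs are
gold-negative. Everything is driven by one integer seed and regeneration with
the same config is byte-identical.

Two corpus modes are provided:

``plain``
    Positives use a subject/object predicate frame (``NE <-subj- V -obj-> NE``)
    with an interaction verb; negatives attach both entities to a
    non-interaction noun. The two classes are separable from contiguous
    dependency n-grams alone.

``gapped_contrast``
    Both classes share the same five-node frame
    ``NE <-subj- V -mod-> X -comp_*-> NE`` with a random filler noun ``X``;
    class membership is an exclusive-or over the two *distant* symbols
    (verb, final complement relation), so every contiguous three-symbol
    window is class-balanced and only gapped subsequences carry signal.
    This isolates the benefit of subsequence kernels over purely contiguous
    (spectrum / n-gram) matching.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .records import DependencyEdge, Entity, InteractionGold, SentenceRecord, Token

__all__ = [
    "SynthConfig",
    "generate_synthetic_corpus",
    "INTERACTION_VERBS",
    "NEGATIVE_NOUNS",
    "DEFAULT_RELATION_VOCABULARY",
]

#: The seven main grammatical functions used for dependency labels.
DEFAULT_RELATION_VOCABULARY = ("appos", "comp_prep", "mod", "mod_att", "neg", "obj", "subj")

INTERACTION_VERBS = ("activates", "inhibits", "regulates", "represses", "controls")
NEGATIVE_NOUNS = ("level", "sample", "sequence", "presence", "region")
FILLER_NOUNS = (
    "transcription", "promoter", "expression", "sporulation", "gene",
    "protein", "cell", "pathway", "complex", "domain",
)
PROTEIN_NAMES = ("sigK", "ywhE", "sigF", "gerE", "cotD", "spoIIID", "katX", "yvyD", "csbB", "sigB")

#: Verb/relation pairings for the gapped_contrast mode. Class is the XOR of
#: the two coordinates, so each symbol alone is uninformative.
_GAPPED_POSITIVE = (("activates", "comp_from"), ("inhibits", "comp_by"))
_GAPPED_NEGATIVE = (("activates", "comp_by"), ("inhibits", "comp_from"))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic corpus.

    ``negative_rate`` is the fraction of sentences with no planted
    interaction (so the template rate is its complement, giving a roughly
    balanced corpus at the default 0.5, matching the class balance of the
    LLL-style genic-interaction setting). ``nesting_rate`` is the per-sentence
    probability that one entity is widened to two tokens with an embedded
    single-token entity inside it.
    """

    n_docs: int = 20
    sentences_per_doc: int = 10
    mean_sentence_length: int = 9
    relation_vocabulary: tuple[str, ...] = DEFAULT_RELATION_VOCABULARY
    pattern_bank: tuple[str, ...] = ("subj_obj",)
    negative_rate: float = 0.5
    nesting_rate: float = 0.1
    mode: str = "plain"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("negative_rate", "nesting_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_sentence_length < 5:
            raise ValueError(
                "mean_sentence_length must be >= 5 (a planted pattern needs room)"
            )
        if self.mode not in ("plain", "gapped_contrast"):
            raise ValueError(f"unknown corpus mode {self.mode!r}")


def _spans(surfaces: list[str]) -> list[tuple[int, int]]:
    spans, pos = [], 0
    for s in surfaces:
        spans.append((pos, pos + len(s)))
        pos += len(s) + 1
    return spans


class _SentenceBuilder:
    """Accumulates fragment tokens then pads with projective filler chains."""

    def __init__(self, rng: random.Random, cfg: SynthConfig):
        self.rng = rng
        self.cfg = cfg
        self.surfaces: list[str] = []
        self.poses: list[str] = []
        self.frag_edges: list[tuple[int, int, str]] = []  # 0-based within fragment

    def add(self, surface: str, pos: str) -> int:
        self.surfaces.append(surface)
        self.poses.append(pos)
        return len(self.surfaces) - 1

    def edge(self, head: int, dep: int, rel: str) -> None:
        self.frag_edges.append((head, dep, rel))

    def finish(self, root: int, target_len: int):
        """Pad to ``target_len`` tokens with filler chains hanging off ``root``."""
        n_frag = len(self.surfaces)
        n_fill = max(0, target_len - n_frag)
        left = n_fill // 2
        right = n_fill - left
        surfaces = []
        poses = []
        # left chain f1 <- f2 <- ... <- root keeps the tree projective
        for _ in range(left):
            w = self.rng.choice(FILLER_NOUNS)
            surfaces.append(w)
            poses.append("NN")
        offset = left
        surfaces += self.surfaces
        poses += self.poses
        for _ in range(right):
            w = self.rng.choice(FILLER_NOUNS)
            surfaces.append(w)
            poses.append("NN")
        edges = [(h + offset, d + offset, r) for h, d, r in self.frag_edges]
        fill_rels = [r for r in self.cfg.relation_vocabulary if r not in ("subj", "obj", "neg")]
        for i in range(left):  # 0..left-1 linear; chain toward the fragment
            head = i + 1 if i + 1 < left else root + offset
            edges.append((head, i, self.rng.choice(fill_rels)))
        for j in range(right):
            pos_j = left + n_frag + j
            head = pos_j - 1 if j > 0 else root + offset
            edges.append((head, pos_j, self.rng.choice(fill_rels)))
        return surfaces, poses, edges, offset


def _make_sentence(rng: random.Random, cfg: SynthConfig, doc_id: str, sent_id: str) -> SentenceRecord:
    positive = rng.random() >= cfg.negative_rate
    b = _SentenceBuilder(rng, cfg)
    ne1_name, ne2_name = rng.sample(PROTEIN_NAMES, 2)
    mirrored = rng.random() < 0.5  # agent on the right half of the time

    if cfg.mode == "plain" and positive:
        i1 = b.add(ne1_name, "NN")
        v = b.add(rng.choice(INTERACTION_VERBS), "VBZ")
        i2 = b.add(ne2_name, "NN")
        if not mirrored:
            b.edge(v, i1, "subj")
            b.edge(v, i2, "obj")
        else:
            b.edge(v, i1, "obj")
            b.edge(v, i2, "subj")
        root = v
    elif cfg.mode == "plain":
        i1 = b.add(ne1_name, "NN")
        noun = b.add(rng.choice(NEGATIVE_NOUNS), "NN")
        i2 = b.add(ne2_name, "NN")
        b.edge(noun, i1, "mod_att")
        b.edge(noun, i2, "mod")
        root = noun
    else:  # gapped_contrast: shared frame, XOR class signal
        verb, comp = rng.choice(_GAPPED_POSITIVE if positive else _GAPPED_NEGATIVE)
        filler = rng.choice(FILLER_NOUNS)
        if not mirrored:
            i1 = b.add(ne1_name, "NN")
            v = b.add(verb, "VBZ")
            x = b.add(filler, "NN")
            i2 = b.add(ne2_name, "NN")
            b.edge(v, i1, "subj")
            b.edge(v, x, "mod")
            b.edge(x, i2, comp)
        else:
            i1 = b.add(ne1_name, "NN")
            x = b.add(filler, "NN")
            v = b.add(verb, "VBZ")
            i2 = b.add(ne2_name, "NN")
            b.edge(x, i1, comp)
            b.edge(v, x, "mod")
            b.edge(v, i2, "subj")
        root = v

    length = max(5, int(round(rng.gauss(cfg.mean_sentence_length, 2.0))))
    surfaces, poses, edges, offset = b.finish(root, length)

    # optionally widen one entity and embed a nested entity inside it
    nested_entity = None
    widened: dict[int, int] = {}
    if rng.random() < cfg.nesting_rate:
        which = rng.choice((i1, i2))
        pos_lin = which + offset
        mod = rng.choice(FILLER_NOUNS)
        surfaces = surfaces[:pos_lin] + [mod] + surfaces[pos_lin:]
        poses = poses[:pos_lin] + ["NN"] + poses[pos_lin:]

        def shift(i: int) -> int:
            return i + 1 if i >= pos_lin else i

        edges = [(shift(h), shift(d), r) for h, d, r in edges]
        head_lin = pos_lin + 1  # entity head = last (right-headed) token
        edges.append((head_lin, pos_lin, "mod_att"))
        widened[which] = head_lin
        nested_entity = (which, head_lin)

    spans = _spans(surfaces)
    tokens = [
        Token(index=i + 1, surface=s, pos=p, span=spans[i])
        for i, (s, p) in enumerate(zip(surfaces, poses))
    ]

    def lin(frag_idx: int) -> int:
        if frag_idx in widened:
            return widened[frag_idx]
        base = frag_idx + offset
        if nested_entity is not None and base >= nested_entity[0] + offset:
            base += 1
        return base

    dep_edges = [DependencyEdge(head=h + 1, dependent=d + 1, relation=r) for h, d, r in edges]

    e1_toks = (lin(i1) + 1,) if i1 not in widened else (widened[i1], widened[i1] + 1)
    e2_toks = (lin(i2) + 1,) if i2 not in widened else (widened[i2], widened[i2] + 1)
    entities = [
        Entity(id=f"{sent_id}.e1", token_indices=tuple(sorted(e1_toks))),
        Entity(id=f"{sent_id}.e2", token_indices=tuple(sorted(e2_toks))),
    ]
    if nested_entity is not None:
        which, head_lin = nested_entity
        entities.append(Entity(id=f"{sent_id}.e3", token_indices=(head_lin + 1,)))

    golds = []
    if positive:
        agent, target = (entities[0].id, entities[1].id)
        if mirrored:
            agent, target = target, agent
        golds.append(InteractionGold(agent=agent, target=target, directed=True))

    text = " ".join(surfaces)
    return SentenceRecord(
        doc_id=doc_id,
        sent_id=sent_id,
        text=text,
        tokens=tokens,
        edges=dep_edges,
        entities=entities,
        golds=golds,
    ).validate()


def generate_synthetic_corpus(cfg: SynthConfig) -> list[SentenceRecord]:
    """Generate a full corpus; deterministic in ``cfg`` (including seed)."""
    rng = random.Random(cfg.seed)
    records = []
    for d in range(cfg.n_docs):
        doc_id = f"d{d}"
        for s in range(cfg.sentences_per_doc):
            records.append(_make_sentence(rng, cfg, doc_id, f"{doc_id}.s{s}"))
    return records
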