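"""Readers and writers for the two PPI corpus formats.

Two on-disk dialects are supported:

* the unified PPI corpus XML dialect shared by the five converted benchmark
  corpora (AIMed, BioInfer, HPRD50, IEPA, LLL): ``corpus/document/sentence``
  elements carrying ``entity`` and ``interaction`` children plus a
  ``sentenceanalyses`` subtree with a tokenization and a typed-dependency
  parse;
* the LLL-05 genic-interaction challenge plain-text tuple format
  (``word(...)``, ``relation(...)``, ``agent``/``target``/``genic_interaction``
  lines), whose interactions are directed.

Both readers emit the same :class:`~walkernel.records.SentenceRecord` model.
Entity character offsets are inclusive in the XML dialect and are converted to
0-based half-open spans at this boundary; offsets that split a token are
snapped to the covering token(s) with a warning (named-entity regrouping is
handled downstream).
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

from lxml import etree

from .records import (
    CorpusIntegrityError,
    DependencyEdge,
    Entity,
    InteractionGold,
    SentenceRecord,
    Token,
)

__all__ = [
    "read_unified_xml",
    "write_unified_xml",
    "read_lll",
    "UnknownRelationWarning",
    "OffsetSnapWarning",
    "LLL_RELATION_INVENTORY",
]


class UnknownRelationWarning(UserWarning):
    """A typed-dependency label outside the declared inventory was seen."""


class OffsetSnapWarning(UserWarning):
    """An entity offset fell inside a token and was snapped to cover it."""


#: Grammatical-relation inventory of the LLL-05 dependency annotation
#: (27 simplified labels; transcribed by the implementers from the challenge
#: documentation — used only to warn on out-of-inventory labels, never to
#: reject input).
LLL_RELATION_INVENTORY = frozenset(
    {
        "subj", "obj", "comp", "appos", "mod_att", "mod_pred", "mod", "neg",
        "comp_by", "comp_of", "comp_from", "comp_in", "comp_with", "comp_to",
        "comp_for", "comp_at", "comp_on", "comp_as", "comp_prep", "aux",
        "det", "coord", "conj_and", "conj_or", "rel", "punct", "dep",
    }
)


def _parse_offsets(text: str) -> list[tuple[int, int]]:
    """Parse an inclusive ``b-e[,b-e...]`` charOffset into half-open spans."""
    spans = []
    for part in text.split(","):
        b, e = part.split("-")
        spans.append((int(b), int(e) + 1))
    return spans


def _token_number(token_id: str) -> int:
    m = re.search(r"(\d+)$", token_id)
    if m is None:
        raise CorpusIntegrityError(f"cannot parse token id {token_id!r}")
    return int(m.group(1))


def _align_entity(spans, tokens, entity_id, sent_id) -> tuple[int, ...]:
    """Map entity character spans to covering token indices (sorted)."""
    hit: set[int] = set()
    snapped = False
    for b, e in spans:
        for t in tokens:
            tb, te = t.span
            if tb < e and b < te:  # any overlap
                hit.add(t.index)
                if not (b <= tb and te <= e):
                    snapped = True
    if not hit:
        raise CorpusIntegrityError(
            f"{sent_id}: entity {entity_id} offsets {spans} align to no token"
        )
    if snapped:
        warnings.warn(
            f"{sent_id}: entity {entity_id} offsets split a token; snapped to covering token(s)",
            OffsetSnapWarning,
            stacklevel=3,
        )
    return tuple(sorted(hit))


def read_unified_xml(path) -> list[SentenceRecord]:
    """Read a unified-dialect PPI corpus XML file into SentenceRecords.

    Undirected corpora (no ``directed`` attribute on ``interaction``) yield
    golds with ``directed=False``; ``e1`` is stored as agent, ``e2`` as
    target, which for undirected pairs is an arbitrary but stable choice.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusIntegrityError(f"malformed XML in {path}: {exc}") from exc
    records: list[SentenceRecord] = []
    for doc in tree.getroot().iter("document"):
        doc_id = doc.get("id", "d?")
        for sent in doc.iter("sentence"):
            sent_id = sent.get("id", f"{doc_id}.s?")
            text = sent.get("text", "")
            tokens: list[Token] = []
            edges: list[DependencyEdge] = []
            for tok in sent.iter("token"):
                (b, e), *rest = _parse_offsets(tok.get("charOffset"))
                tokens.append(
                    Token(
                        index=_token_number(tok.get("id")),
                        surface=tok.get("text"),
                        pos=tok.get("POS", "X"),
                        span=(b, e),
                    )
                )
            for dep in sent.iter("dependency"):
                edges.append(
                    DependencyEdge(
                        head=_token_number(dep.get("t1")),
                        dependent=_token_number(dep.get("t2")),
                        relation=dep.get("type"),
                    )
                )
            entities: list[Entity] = []
            for ent in sent.findall("entity"):
                spans = _parse_offsets(ent.get("charOffset"))
                entities.append(
                    Entity(
                        id=ent.get("id"),
                        token_indices=_align_entity(spans, tokens, ent.get("id"), sent_id),
                        etype=ent.get("type", "protein"),
                    )
                )
            golds: list[InteractionGold] = []
            for inter in sent.findall("interaction"):
                golds.append(
                    InteractionGold(
                        agent=inter.get("e1"),
                        target=inter.get("e2"),
                        directed=inter.get("directed", "false").lower() == "true",
                    )
                )
            records.append(
                SentenceRecord(
                    doc_id=doc_id,
                    sent_id=sent_id,
                    text=text,
                    tokens=sorted(tokens, key=lambda t: t.index),
                    edges=edges,
                    entities=entities,
                    golds=golds,
                ).validate()
            )
    return records


def write_unified_xml(records, path) -> None:
    """Serialize SentenceRecords back to the unified XML dialect.

    Inverse of :func:`read_unified_xml` up to attribute ordering; entity
    offsets are emitted as the inclusive union of the covered token spans.
    """
    root = etree.Element("corpus", source="walkernel")
    by_doc: dict[str, list[SentenceRecord]] = {}
    for rec in records:
        by_doc.setdefault(rec.doc_id, []).append(rec)
    for doc_id, recs in by_doc.items():
        doc_el = etree.SubElement(root, "document", id=doc_id)
        for rec in recs:
            sent_el = etree.SubElement(doc_el, "sentence", id=rec.sent_id, text=rec.text)
            tok_by_index = {t.index: t for t in rec.tokens}
            for ent in rec.entities:
                b = min(tok_by_index[i].span[0] for i in ent.token_indices)
                e = max(tok_by_index[i].span[1] for i in ent.token_indices)
                etree.SubElement(
                    sent_el,
                    "entity",
                    id=ent.id,
                    charOffset=f"{b}-{e - 1}",
                    type=ent.etype,
                    text=rec.text[b:e],
                )
            for g in rec.golds:
                etree.SubElement(
                    sent_el,
                    "interaction",
                    e1=g.agent,
                    e2=g.target,
                    directed="true" if g.directed else "false",
                )
            analyses = etree.SubElement(sent_el, "sentenceanalyses")
            tks = etree.SubElement(etree.SubElement(analyses, "tokenizations"), "tokenization")
            for t in rec.tokens:
                etree.SubElement(
                    tks,
                    "token",
                    id=f"t_{t.index}",
                    text=t.surface,
                    POS=t.pos,
                    charOffset=f"{t.span[0]}-{t.span[1] - 1}",
                )
            parse = etree.SubElement(etree.SubElement(analyses, "parses"), "parse")
            for i, edge in enumerate(rec.edges):
                etree.SubElement(
                    parse,
                    "dependency",
                    id=f"dep_{i}",
                    t1=f"t_{edge.head}",
                    t2=f"t_{edge.dependent}",
                    type=edge.relation,
                )
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------- LLL format

_WORD_RE = re.compile(r"word\s*\(\s*(\d+)\s*,\s*'((?:[^'\\]|\\.)*)'\s*(?:,\s*(\d+)\s*,\s*(\d+)\s*)?\)")
_REL_RE = re.compile(r"relation\s*\(\s*'((?:[^'\\]|\\.)*)'\s*,\s*(\d+)\s*,\s*(\d+)\s*\)")
_AGENT_RE = re.compile(r"agent\s*\(\s*(\d+)\s*\)")
_TARGET_RE = re.compile(r"target\s*\(\s*(\d+)\s*\)")
_INTER_RE = re.compile(r"genic_interaction\s*\(\s*(\d+)\s*,\s*(\d+)\s*\)")


def _lll_blocks(path) -> dict[str, dict[str, str]]:
    """Split an LLL file into per-sentence blocks of ``key<TAB>value`` lines."""
    blocks: dict[str, dict[str, str]] = {}
    current: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines() + [""]:
        line = raw.rstrip()
        if not line or line.startswith("%"):
            if current.get("ID"):
                blocks[current["ID"]] = current
            current = {}
            continue
        key, _, value = line.partition("\t")
        if not value:
            key, _, value = line.partition(" ")
        current[key.strip()] = value.strip()
    return blocks


def read_lll(sentence_file, annotation_file=None) -> list[SentenceRecord]:
    """Read the LLL-05 challenge tuple format.

    ``sentence_file`` holds ``ID``/``sentence``/``words``/``syntactic_relations``
    blocks; agent/target/interaction lines may live in the same file or in a
    separate ``annotation_file`` keyed by the same sentence IDs. Word ids are
    0-based in the format and become 1-based token indices; all gold
    interactions are directed (agent -> target). Relation labels outside the
    27-label LLL inventory trigger an :class:`UnknownRelationWarning`.
    """
    blocks = _lll_blocks(sentence_file)
    ann = _lll_blocks(annotation_file) if annotation_file is not None else {}
    records: list[SentenceRecord] = []
    for sid, block in blocks.items():
        extra = ann.get(sid, {})
        merged = dict(block)
        for k, v in extra.items():
            merged[k] = v
        tokens: list[Token] = []
        for m in _WORD_RE.finditer(merged.get("words", "")):
            wid, form, b, e = m.groups()
            span = (int(b), int(e) + 1) if b is not None else (0, 0)
            tokens.append(Token(index=int(wid) + 1, surface=form, pos="X", span=span))
        valid = {t.index for t in tokens}
        edges: list[DependencyEdge] = []
        for m in _REL_RE.finditer(merged.get("syntactic_relations", "")):
            rtype, h, d = m.group(1), int(m.group(2)) + 1, int(m.group(3)) + 1
            if h not in valid or d not in valid:
                raise CorpusIntegrityError(
                    f"{sid}: relation {rtype!r} references unknown word id"
                )
            base = rtype.split(":")[0]
            if base not in LLL_RELATION_INVENTORY:
                warnings.warn(
                    f"{sid}: relation label {rtype!r} outside the LLL inventory",
                    UnknownRelationWarning,
                    stacklevel=2,
                )
            edges.append(DependencyEdge(head=h, dependent=d, relation=rtype))
        ent_ids: set[int] = set()
        for rex in (_AGENT_RE, _TARGET_RE):
            for m in rex.finditer(merged.get("agents", "") + " " + merged.get("targets", "")):
                ent_ids.add(int(m.group(1)))
        golds: list[InteractionGold] = []
        for m in _INTER_RE.finditer(merged.get("genic_interactions", "")):
            a, t = int(m.group(1)), int(m.group(2))
            ent_ids.update((a, t))
            golds.append(InteractionGold(agent=f"w{a}", target=f"w{t}", directed=True))
        entities = [
            Entity(id=f"w{wid}", token_indices=(wid + 1,), etype="gene")
            for wid in sorted(ent_ids)
            if wid + 1 in valid
        ]
        for wid in ent_ids:
            if wid + 1 not in valid:
                raise CorpusIntegrityError(f"{sid}: agent/target references unknown word {wid}")
        records.append(
            SentenceRecord(
                doc_id=sid.split(".")[0],
                sent_id=sid,
                text=merged.get("sentence", ""),
                tokens=sorted(tokens, key=lambda t: t.index),
                edges=edges,
                entities=entities,
                golds=golds,
            ).validate()
        )
    return records
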