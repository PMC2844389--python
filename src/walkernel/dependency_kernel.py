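"""The extended dependency kernel over path-internal dependency lists.

The kernel scores two relation instances by recursively counting common
dependency subgraphs rooted at matching nodes, in a word variant (C_w) and a
POS variant (C_p). Relative to a plain common-subgraph count it adds:

* **partial matches** — a bare node pair with the same word scores even when
  its children differ (leaf base case 1.0), and a pair with no common child
  dependencies still scores 3.0 when the two nodes share the same
  subcategorization (left edge, right edge) frame — the e-walk information;
* **subcategorization weighting** — recursive matches are amplified by 3.0
  when the frames agree and 2.0 otherwise, so structurally parallel
  predicates count more;
* **composition** — the graph-level kernel sums C_w over all same-word node
  pairs and C_p over all same-POS node pairs, with the lexical term weighted
  above the syntactic one (default 2:1).

The POS variant drops all subcategorization terms (no 3.0 branch, recursion
weight 1). All constants sit in :class:`DependencyKernelWeights`; zeroing the
bonuses recovers the plain complete-path-match kernel as a configuration
preset.
"""

from __future__ import annotations

from dataclasses import dataclass

from .path_extract import DependencyList, RelationInstance

__all__ = [
    "DependencyKernelWeights",
    "common_dependency_set",
    "match_count_word",
    "match_count_pos",
    "extended_dependency_kernel",
]


@dataclass(frozen=True)
class DependencyKernelWeights:
    """Weight table of the extended dependency kernel.

    ``subcat_bonus`` is the score for a same-frame pair with no common child
    dependencies and also the recursion weight when frames agree;
    ``recursion_weight`` applies when frames differ; ``lexical``/``pos``
    compose the two variants (lexical > pos). ``restricted`` mode (all
    bonuses off) reduces to complete-path matching only.
    """

    subcat_bonus: float = 3.0
    recursion_weight: float = 2.0
    leaf_match: float = 1.0
    lexical: float = 2.0
    pos: float = 1.0
    use_subcat: bool = True
    allow_partial: bool = True


def common_dependency_set(
    deps1: DependencyList, deps2: DependencyList, n1: int, n2: int
) -> list[tuple[int, int]]:
    """Pairs of direct children of (n1, n2) matching in symbol and relation.

    A pair (x, y) qualifies only when the two child nodes carry the same
    symbol *and* hang off their parents by the same relation.
    """
    out = []
    for rel1, c1 in deps1.children[n1]:
        for rel2, c2 in deps2.children[n2]:
            if rel1 == rel2 and deps1.symbols[c1] == deps2.symbols[c2]:
                out.append((c1, c2))
    return out


def match_count_word(
    deps1: DependencyList,
    deps2: DependencyList,
    n1: int,
    n2: int,
    w: DependencyKernelWeights = DependencyKernelWeights(),
) -> float:
    """C_w: weighted common-subgraph count rooted at a same-word node pair.

    Case order (first match wins): different words -> 0; either node is a
    leaf -> ``leaf_match`` (1.0); no common child dependencies but equal
    subcat frames -> ``subcat_bonus`` (3.0); otherwise recurse over the
    common child pairs with the frame-dependent weight.
    """
    if deps1.symbols[n1] != deps2.symbols[n2]:
        return 0.0
    ch1, ch2 = deps1.children[n1], deps2.children[n2]
    if not ch1 or not ch2:
        if not ch1 and not ch2:
            return w.leaf_match  # leaf/leaf: a complete (trivial) match
        return w.leaf_match if w.allow_partial else 0.0
    sc = common_dependency_set(deps1, deps2, n1, n2)
    same_subcat = deps1.subcats[n1] == deps2.subcats[n2]
    if not sc:
        if w.use_subcat and same_subcat:
            return w.subcat_bonus
        return 0.0
    weight = w.subcat_bonus if (w.use_subcat and same_subcat) else w.recursion_weight
    return weight * (
        1.0 + sum(match_count_word(deps1, deps2, x, y, w) for x, y in sc)
    )


def match_count_pos(
    deps1: DependencyList,
    deps2: DependencyList,
    p1: int,
    p2: int,
    w: DependencyKernelWeights = DependencyKernelWeights(),
) -> float:
    """C_p: as C_w on POS symbols, with subcategorization excluded."""
    if deps1.symbols[p1] != deps2.symbols[p2]:
        return 0.0
    ch1, ch2 = deps1.children[p1], deps2.children[p2]
    if not ch1 or not ch2:
        if not ch1 and not ch2:
            return w.leaf_match
        return w.leaf_match if w.allow_partial else 0.0
    sc = common_dependency_set(deps1, deps2, p1, p2)
    if not sc:
        return 0.0
    return 1.0 + sum(match_count_pos(deps1, deps2, x, y, w) for x, y in sc)


def extended_dependency_kernel(
    a: RelationInstance,
    b: RelationInstance,
    w: DependencyKernelWeights = DependencyKernelWeights(),
) -> float:
    """Graph-level similarity: weighted sum of C_w and C_p over node pairs."""
    total = 0.0
    wd1, wd2 = a.word_deps, b.word_deps
    for n1 in range(len(wd1.symbols)):
        for n2 in range(len(wd2.symbols)):
            total += w.lexical * match_count_word(wd1, wd2, n1, n2, w)
    pd1, pd2 = a.pos_deps, b.pos_deps
    for p1 in range(len(pd1.symbols)):
        for p2 in range(len(pd2.symbols)):
            total += w.pos * match_count_pos(pd1, pd2, p1, p2, w)
    return total
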