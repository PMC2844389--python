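"""v-walk / e-walk extraction and the feature-based walk kernel.

A walk of length 3 on a path string is a contiguous three-symbol window:
a *v-walk* is node-edge-node (a labelled head/modifier dependency, e.g.
``(word1, relation, word2)``); an *e-walk* is edge-node-edge and captures the
local argument structure around a node — for a predicate this is its
subcategorization frame, the information most predictive of an interaction.
The walk kernel is the inner product of walk count vectors over both the
lexical and the syntactic variant of the path, optionally restricted to one
walk type; it is the baseline the walk-weighted subsequence kernel builds on.
"""

from __future__ import annotations

from collections import Counter

from .path_extract import PathString, RelationInstance

__all__ = ["extract_walks", "walk_kernel"]


def extract_walks(ps: PathString, kind: str) -> Counter:
    """All contiguous 3-symbol windows of the requested kind, with multiplicity.

    ``kind`` is ``"v"`` (windows starting on a node role) or ``"e"``
    (windows starting on an edge role). Paths shorter than three symbols
    have no walks.
    """
    if kind not in ("v", "e"):
        raise ValueError(f"walk kind must be 'v' or 'e', got {kind!r}")
    start_role = "n" if kind == "v" else "e"
    walks: Counter = Counter()
    for i in range(len(ps.symbols) - 2):
        if ps.roles[i] == start_role:
            walks[ps.symbols[i : i + 3]] += 1
    return walks


def _dot(a: Counter, b: Counter) -> float:
    if len(b) < len(a):
        a, b = b, a
    return float(sum(c * b[k] for k, c in a.items() if k in b))


def walk_kernel(a: RelationInstance, b: RelationInstance, mode: str = "both") -> float:
    """Inner product of walk count vectors, summed over lexical + syntactic.

    ``mode`` selects the feature space: ``"v"``, ``"e"``, or ``"both"``; the
    two spaces are disjoint, so ``both`` equals the sum of the restricted
    kernels. Symmetric and non-negative by construction.
    """
    if mode not in ("v", "e", "both"):
        raise ValueError(f"mode must be 'v', 'e' or 'both', got {mode!r}")
    kinds = ("v", "e") if mode == "both" else (mode,)
    total = 0.0
    for ps_a, ps_b in ((a.lexical, b.lexical), (a.syntactic, b.syntactic)):
        for kind in kinds:
            total += _dot(extract_walks(ps_a, kind), extract_walks(ps_b, kind))
    return total
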