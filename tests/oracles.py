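"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — exhaustive enumeration, textbook BFS —
and shares no code with the package under test.
"""

from __future__ import annotations

import itertools
from collections import deque


def brute_spectrum(s, t, p):
    """Count common contiguous p-gram occurrence pairs by double loop."""
    count = 0
    for i in range(len(s) - p + 1):
        for j in range(len(t) - p + 1):
            if tuple(s[i : i + p]) == tuple(t[j : j + p]):
                count += 1
    return float(count)


def brute_subsequence(s, t, p):
    """Count matched index-tuple pairs by full enumeration."""
    count = 0
    for i in itertools.combinations(range(len(s)), p):
        for j in itertools.combinations(range(len(t)), p):
            if all(s[a] == t[b] for a, b in zip(i, j)):
                count += 1
    return float(count)


def brute_gap_weighted(s, t, p, lam):
    """Sum lam^(span_i + span_j) over matched occurrence pairs."""
    total = 0.0
    for i in itertools.combinations(range(len(s)), p):
        for j in itertools.combinations(range(len(t)), p):
            if all(s[a] == t[b] for a, b in zip(i, j)):
                total += lam ** ((i[-1] - i[0] + 1) + (j[-1] - j[0] + 1))
    return total


def classify_triple(indices, roles):
    i1, i2, i3 = indices
    if i2 == i1 + 1 and i3 == i2 + 1:
        return "contig_e" if roles[i1] == "e" else "contig_v"
    return "noncontig"


def brute_walk_weighted(ps, pt, weights=(3.0, 2.0, 1.0), lam=1.0, mixed_policy="noncontig"):
    """Type-weighted enumeration over all matched length-3 occurrence pairs."""
    w_e, w_v, w_nc = weights
    total = 0.0
    for i in itertools.combinations(range(len(ps.symbols)), 3):
        for j in itertools.combinations(range(len(pt.symbols)), 3):
            if not all(ps.symbols[a] == pt.symbols[b] for a, b in zip(i, j)):
                continue
            ci = classify_triple(i, ps.roles)
            cj = classify_triple(j, pt.roles)
            if ci == cj == "contig_e":
                total += w_e
            elif ci == cj == "contig_v":
                total += w_v
            elif mixed_policy == "min" and "noncontig" not in (ci, cj):
                total += min(w_e, w_v)
            else:
                gaps = (i[-1] - i[0] - 2) + (j[-1] - j[0] - 2)
                total += w_nc * lam ** gaps
    return total


def brute_walk_features(ps, kind):
    """All contiguous 3-windows of a path string starting on the given role."""
    start = "n" if kind == "v" else "e"
    out = []
    for i in range(len(ps.symbols) - 2):
        if ps.roles[i] == start:
            out.append(ps.symbols[i : i + 3])
    return out


def bfs_distance(edges, a, b):
    """Unweighted undirected distance via textbook BFS; None if unreachable."""
    adj = {}
    for h, d, *_ in edges:
        adj.setdefault(h, set()).add(d)
        adj.setdefault(d, set()).add(h)
    if a == b:
        return 0
    seen = {a}
    queue = deque([(a, 0)])
    while queue:
        node, dist = queue.popleft()
        for n in adj.get(node, ()):  # noqa: B905
            if n == b:
                return dist + 1
            if n not in seen:
                seen.add(n)
                queue.append((n, dist + 1))
    return None


def random_tree_edges(rng, n, labels=("subj", "obj", "mod", "comp_prep", "appos")):
    """Random labelled tree on nodes 1..n: each node attaches to an earlier one."""
    edges = []
    for i in range(2, n + 1):
        head = rng.randint(1, i - 1)
        edges.append((head, i, rng.choice(labels)))
    return edges
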