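"""String kernels over shortest-dependency-path strings.

A path string is a sequence of symbols over the alphabet of words (or POS
tags) and directed dependency relations. Four kernels compare two such
strings by the substructures they share, in increasing order of coverage:

``spectrum``
    number of common contiguous p-grams (default p = 3);
``subsequence``
    number of common length-p subsequences, gaps allowed, every occurrence
    pair counted once;
``gap_weighted``
    each occurrence pair down-weighted by ``lambda ** (l(i) + l(j))`` where
    ``l`` is the span of the occurrence's index tuple (decay 0 < lambda <= 1,
    default 0.5; lambda = 1 recovers the subsequence kernel);
``walk_weighted``
    subsequences of length 3 weighted by structural type instead of span:
    a pair of contiguous e-walk occurrences scores w_e (default 3.0), a pair
    of contiguous v-walk occurrences w_v (2.0), anything else — gapped on
    either side, or contiguity types that disagree — w_noncontig (1.0),
    optionally decayed in its gaps by ``lambda`` (default 1.0, i.e. no decay).

All subsequence-family kernels run in O(p |s| |t|) by dynamic programming
over match matrices with (decayed) prefix sums; tests verify them against
exhaustive occurrence enumeration. :func:`instance_kernel` composes any
kernel over a relation instance as the sum of its lexical-string and
syntactic-string similarities, and dispatches the two non-string kernels
(feature-based walk kernel, extended dependency kernel) so a single
:class:`KernelSpec` names every model variant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from math import sqrt
from typing import Sequence

from .dependency_kernel import DependencyKernelWeights, extended_dependency_kernel
from .path_extract import PathString, RelationInstance
from .walk_features import walk_kernel

__all__ = [
    "KernelSpec",
    "spectrum_kernel",
    "subsequence_kernel",
    "gap_weighted_kernel",
    "classify_subsequence",
    "walk_weighted_kernel",
    "instance_kernel",
    "instance_feature_map",
]

KERNEL_NAMES = (
    "spectrum",
    "subsequence",
    "gap_weighted",
    "walk_weighted",
    "walk_feature",
    "extended_dependency",
)

#: Per-kernel default decay factor.
_DEFAULT_LAMBDA = {"gap_weighted": 0.5, "walk_weighted": 1.0}


@dataclass(frozen=True)
class KernelSpec:
    """A kernel name plus every hyperparameter needed to evaluate it.

    ``weights`` is (w_e, w_v, w_noncontig) for the walk-weighted kernel;
    ``lam`` defaults to 0.5 for gap_weighted and 1.0 for walk_weighted;
    ``mode`` restricts the feature-based walk kernel (v / e / both);
    ``mixed_policy`` resolves walk-weighted occurrence pairs whose
    contiguity types differ ("noncontig": score w_noncontig; "min": score
    the smaller of the two type weights).
    """

    name: str
    p: int = 3
    lam: float | None = None
    weights: tuple[float, float, float] = (3.0, 2.0, 1.0)
    mode: str = "both"
    mixed_policy: str = "noncontig"
    dependency: DependencyKernelWeights = field(default_factory=DependencyKernelWeights)

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}")
        if self.p < 1:
            raise ValueError("subsequence length p must be >= 1")
        lam = self.resolved_lambda
        if lam is not None and not 0.0 < lam <= 1.0:
            raise ValueError("decay lambda must lie in (0, 1]")
        if any(w <= 0 for w in self.weights):
            raise ValueError("walk weights must be positive")
        if self.mixed_policy not in ("noncontig", "min"):
            raise ValueError("mixed_policy must be 'noncontig' or 'min'")

    @property
    def resolved_lambda(self) -> float | None:
        if self.lam is not None:
            return self.lam
        return _DEFAULT_LAMBDA.get(self.name)

    def with_(self, **kw) -> "KernelSpec":
        return replace(self, **kw)


# ------------------------------------------------------------- plain strings

def spectrum_kernel(s: Sequence[str], t: Sequence[str], p: int = 3) -> float:
    """Number of common contiguous p-gram occurrence pairs."""
    if p < 1:
        raise ValueError("p must be >= 1")
    cs = Counter(tuple(s[i : i + p]) for i in range(len(s) - p + 1))
    ct = Counter(tuple(t[j : j + p]) for j in range(len(t) - p + 1))
    if len(ct) < len(cs):
        cs, ct = ct, cs
    return float(sum(c * ct[g] for g, c in cs.items() if g in ct))


def _match_matrix(s: Sequence[str], t: Sequence[str]) -> list[list[bool]]:
    return [[a == b for b in t] for a in s]


def subsequence_kernel(s: Sequence[str], t: Sequence[str], p: int = 3) -> float:
    """Number of common length-p subsequence occurrence pairs (gaps allowed).

    Integer-count dynamic programme: ``A_k(i, j)`` counts matched k-tuples
    ending exactly at positions (i, j); each level is the match matrix times
    the 2-D prefix sum of the previous level.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    n, m = len(s), len(t)
    if n < p or m < p:
        return 0.0
    E = _match_matrix(s, t)
    A = [[1 if E[i][j] else 0 for j in range(m)] for i in range(n)]
    for _level in range(1, p):
        # prefix[i][j] = sum of A over the strict upper-left rectangle
        S = [[0] * (m + 1) for _ in range(n + 1)]
        for i in range(n):
            for j in range(m):
                S[i + 1][j + 1] = A[i][j] + S[i][j + 1] + S[i + 1][j] - S[i][j]
        A = [
            [S[i][j] if E[i][j] else 0 for j in range(m)]
            for i in range(n)
        ]
    return float(sum(map(sum, A)))


def gap_weighted_kernel(
    s: Sequence[str], t: Sequence[str], p: int = 3, lam: float = 0.5
) -> float:
    """Sum over common subsequence occurrence pairs of lambda^(l(i)+l(j)).

    ``l(i)`` is the span of the index tuple, last - first + 1, so even a
    contiguous occurrence pair carries lambda^(2p). The decayed prefix sum
    is separable, giving O(p n m) time.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("lambda must lie in (0, 1]")
    n, m = len(s), len(t)
    if n < p or m < p:
        return 0.0
    E = _match_matrix(s, t)
    lam2 = lam * lam
    M = [[lam2 if E[i][j] else 0.0 for j in range(m)] for i in range(n)]
    for _level in range(1, p):
        # T(i,j) = sum_{i'<=i, j'<=j} M(i',j') lam^{(i-i') + (j-j')}
        R = [[0.0] * m for _ in range(n)]
        for i in range(n):
            acc = 0.0
            for j in range(m):
                acc = lam * acc + M[i][j]
                R[i][j] = acc
        T = [[0.0] * m for _ in range(n)]
        for j in range(m):
            acc = 0.0
            for i in range(n):
                acc = lam * acc + R[i][j]
                T[i][j] = acc
        M = [
            [lam2 * T[i - 1][j - 1] if (E[i][j] and i > 0 and j > 0) else 0.0 for j in range(m)]
            for i in range(n)
        ]
    return float(sum(map(sum, M)))


def _gap_only_weighted_count(
    s: Sequence[str], t: Sequence[str], p: int, lam: float
) -> float:
    """Occurrence pairs weighted by lambda^(total gap length) only.

    The gap of an occurrence is its span minus p; contiguous occurrences are
    unpenalized, so lambda = 1 reduces to the plain subsequence count.
    """
    n, m = len(s), len(t)
    if n < p or m < p:
        return 0.0
    E = _match_matrix(s, t)
    M = [[1.0 if E[i][j] else 0.0 for j in range(m)] for i in range(n)]
    for _level in range(1, p):
        R = [[0.0] * m for _ in range(n)]
        for i in range(n):
            acc = 0.0
            for j in range(m):
                acc = lam * acc + M[i][j]
                R[i][j] = acc
        T = [[0.0] * m for _ in range(n)]
        for j in range(m):
            acc = 0.0
            for i in range(n):
                acc = lam * acc + R[i][j]
                T[i][j] = acc
        M = [
            [T[i - 1][j - 1] if (E[i][j] and i > 0 and j > 0) else 0.0 for j in range(m)]
            for i in range(n)
        ]
    return float(sum(map(sum, M)))


# ------------------------------------------------------- walk-weighted kernel

def classify_subsequence(indices: Sequence[int], roles: Sequence[str]) -> str:
    """Type of one length-3 occurrence: contig_e, contig_v or noncontig.

    A contiguous index triple starting on an edge role is a contiguous
    e-walk; starting on a node role, a contiguous v-walk; any gapped triple
    is non-contiguous. Classification uses the role tags, not position
    parity, so strings modified by path extension stay correct.
    """
    if len(indices) != 3:
        raise ValueError("walk typing is defined for length-3 subsequences")
    i1, i2, i3 = indices
    if i2 == i1 + 1 and i3 == i2 + 1:
        return "contig_e" if roles[i1] == "e" else "contig_v"
    return "noncontig"


def _contiguous_trigrams(ps: PathString, start_role: str) -> Counter:
    out: Counter = Counter()
    for i in range(len(ps.symbols) - 2):
        if ps.roles[i] == start_role:
            out[ps.symbols[i : i + 3]] += 1
    return out


def _dot(a: Counter, b: Counter) -> float:
    if len(b) < len(a):
        a, b = b, a
    return float(sum(c * b[k] for k, c in a.items() if k in b))


def walk_weighted_kernel(
    s: PathString,
    t: PathString,
    weights: tuple[float, float, float] = (3.0, 2.0, 1.0),
    lam: float = 1.0,
    mixed_policy: str = "noncontig",
) -> float:
    """Type-weighted sum over common length-3 subsequence occurrence pairs.

    A pair where both occurrences are contiguous e-walks scores ``w_e``;
    both contiguous v-walks, ``w_v``; every other combination scores
    ``w_noncontig`` (or, under ``mixed_policy='min'``, the smaller type
    weight when both sides are contiguous), decayed by ``lam`` per unit of
    gap. With the default lam = 1 the gaps are ignored entirely.
    """
    w_e, w_v, w_nc = weights
    base = _gap_only_weighted_count(s.symbols, t.symbols, 3, lam)
    ce_s, ce_t = _contiguous_trigrams(s, "e"), _contiguous_trigrams(t, "e")
    cv_s, cv_t = _contiguous_trigrams(s, "n"), _contiguous_trigrams(t, "n")
    k = (
        w_nc * base
        + (w_e - w_nc) * _dot(ce_s, ce_t)
        + (w_v - w_nc) * _dot(cv_s, cv_t)
    )
    if mixed_policy == "min":
        cross = _dot(ce_s, cv_t) + _dot(cv_s, ce_t)
        k += (min(w_e, w_v) - w_nc) * cross
    return k


# --------------------------------------------------------- instance dispatch

def instance_kernel(a: RelationInstance, b: RelationInstance, spec: KernelSpec) -> float:
    """Kernel value between two relation instances under ``spec``.

    String kernels sum the lexical-path and syntactic-path similarities;
    ``walk_feature`` and ``extended_dependency`` dispatch to their modules.
    Empty-path (disconnected) instances score 0 against everything.
    """
    if a.is_empty or b.is_empty:
        return 0.0
    if spec.name == "walk_feature":
        return walk_kernel(a, b, spec.mode)
    if spec.name == "extended_dependency":
        return extended_dependency_kernel(a, b, spec.dependency)
    total = 0.0
    for sa, sb in ((a.lexical, b.lexical), (a.syntactic, b.syntactic)):
        if spec.name == "spectrum":
            total += spectrum_kernel(sa.symbols, sb.symbols, spec.p)
        elif spec.name == "subsequence":
            total += subsequence_kernel(sa.symbols, sb.symbols, spec.p)
        elif spec.name == "gap_weighted":
            total += gap_weighted_kernel(sa.symbols, sb.symbols, spec.p, spec.resolved_lambda)
        elif spec.name == "walk_weighted":
            total += walk_weighted_kernel(
                sa, sb, spec.weights, spec.resolved_lambda, spec.mixed_policy
            )
    return total


# Explicit feature maps, where they exist, let the learner build Gram
# matrices by sparse dot products instead of quadratic DP calls.

def _all_subsequences(symbols: tuple[str, ...], p: int) -> Counter:
    out: Counter = Counter()

    def rec(start: int, chosen: tuple[str, ...]) -> None:
        if len(chosen) == p:
            out[chosen] += 1
            return
        for i in range(start, len(symbols)):
            if len(symbols) - i < p - len(chosen):
                break
            rec(i + 1, chosen + (symbols[i],))

    rec(0, ())
    return out


def instance_feature_map(inst: RelationInstance, spec: KernelSpec) -> Counter | None:
    """Explicit (possibly scaled) feature vector realizing ``instance_kernel``.

    Returns ``None`` when the spec has no finite-dimensional explicit map in
    this form (gap_weighted with lambda < 1, extended_dependency,
    walk_weighted with lambda < 1 or non-default mixed policy or weights
    below w_noncontig); callers then fall back to pairwise evaluation.
    """
    if inst.is_empty:
        return Counter()
    feats: Counter = Counter()
    if spec.name == "spectrum":
        for tag, ps in (("lex", inst.lexical), ("syn", inst.syntactic)):
            for i in range(len(ps.symbols) - spec.p + 1):
                feats[(tag, "g", ps.symbols[i : i + spec.p])] += 1.0
        return feats
    if spec.name == "subsequence":
        for tag, ps in (("lex", inst.lexical), ("syn", inst.syntactic)):
            for u, c in _all_subsequences(ps.symbols, spec.p).items():
                feats[(tag, "u", u)] += float(c)
        return feats
    if spec.name == "walk_feature":
        kinds = ("v", "e") if spec.mode == "both" else (spec.mode,)
        for tag, ps in (("lex", inst.lexical), ("syn", inst.syntactic)):
            for kind in kinds:
                start = "n" if kind == "v" else "e"
                for i in range(len(ps.symbols) - 2):
                    if ps.roles[i] == start:
                        feats[(tag, kind, ps.symbols[i : i + 3])] += 1.0
        return feats
    if spec.name == "walk_weighted":
        w_e, w_v, w_nc = spec.weights
        if (
            spec.p != 3
            or spec.resolved_lambda != 1.0
            or spec.mixed_policy != "noncontig"
            or w_e < w_nc
            or w_v < w_nc
        ):
            return None
        for tag, ps in (("lex", inst.lexical), ("syn", inst.syntactic)):
            for u, c in _all_subsequences(ps.symbols, 3).items():
                feats[(tag, "u", u)] += sqrt(w_nc) * c
            for start, kind, w in (("e", "e", w_e), ("n", "v", w_v)):
                scale = sqrt(w - w_nc)
                if scale == 0.0:
                    continue
                for i in range(len(ps.symbols) - 2):
                    if ps.roles[i] == start:
                        feats[(tag, kind, ps.symbols[i : i + 3])] += scale
        return feats
    return None
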