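# Methods

This note documents the models and procedures implemented in `walkernel`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Problem setting

Given a dependency-parsed sentence with annotated named entities (NEs), the
task is to decide, for every pair of entity occurrences, whether the
sentence asserts an interaction between them and, when the corpus annotates
roles, in which direction. Instances are labelled in word order: `AT`
(first-occurring entity is the agent), `TA` (first is the target), `O` (no
interaction). Self-pairs — the same occurrence paired with itself — are
negative by definition but are kept as candidates.

## Data representation

Each candidate pair is represented by the shortest path between its two
entity nodes over the **undirected view** of the repaired dependency graph
(every dependency points to the syntactic head, so traversal must ignore
orientation). The original orientation is preserved on the path: an edge
traversed dependent→head is tagged `(UP)`, head→dependent `(DN)`. An
internal node whose left edge is `(UP)` and right edge is `(DN)` heads both
its path neighbours — on a tree path that is the unique apex, typically the
governing predicate — and is suffixed `:PRED`. A predicate governing a
negation cue (a `neg`-labelled dependent, or a dependent whose surface is in
a small cue lexicon: *not, no, n't, never, cannot, fail, unable, without,
lack, absence*) is prefixed `NEG:`. The path is rendered twice: lexically
(lower-cased surfaces, candidate entities blinded to `NE`; other entities
keep their surfaces) and syntactically (POS tags), with identical edge
symbols. Path-internal dependency lists (per node: its direct dependents on
the path with their relations) feed the dependency kernel.

Degenerate paths of exactly two entity nodes joined by a coordinating
conjunction (`conj_and`, `conj_or`, `conj`, `cc`; configurable) carry almost
no signal on their own — most conjoined NE pairs do not interact except in
clue contexts such as "interaction between X and Y". Such paths are
extended upward by the immediate head of the first (word-order) entity and
the head of that head, at most four extra symbols. The source description
speaks of "the NE" in the singular; we extend from the left entity only and
expose the conjunction set in the API. Extension relaxes the invariant that
the path's terminal symbols are the two entities; all other invariants
(odd length, strict node/edge alternation) always hold.

Pairs whose entities fall in different graph components yield an instance
with empty path strings; every kernel scores such an instance 0 against
everything, it is excluded from the margin problem and auto-predicted `O`.

## Graph repair

Automatically converted corpora exhibit three defects: multiple typed
relations between the same ordered node pair, two-cycles (an edge and its
inverse coexisting), and NEs split over several tokens. Repairs, in order:

1. **Duplicate removal** — keep the lexicographically smallest relation
   label per ordered pair. Any fixed rule would do; lexicographic order is
   deterministic and independent of input order.
2. **Two-cycle resolution** — keep the direction whose dependent has more
   external support as a head (more non-cycle edges headed by it), i.e. the
   direction consistent with the better-attested subtree; residual ties
   break lexicographically.
3. **NE grouping** — collapse each analysed entity's tokens into one node:
   internal edges are deleted, external edges re-attach to the merged node
   (head = last token of the span, the right-headed noun-compound
   assumption; configurable), and steps 1–2 re-run on the merged result.
   Grouping is applied **per candidate pair**, because nested entities mean
   the same sentence legitimately yields differently grouped graphs for
   different pairs. All embedded entities remain candidates.

All repairs are idempotent and counted in a provenance ledger that the CLI
reports per corpus.

## Kernels

All kernels are functions of the rendered instance; each string kernel is
evaluated on the lexical and the syntactic path string and summed.

* **Walk kernel** (baseline): inner product of counts of length-3 windows —
  v-walks (node–edge–node, a labelled dependency) and e-walks
  (edge–node–edge, a node's local argument frame). Modes `v`, `e`, `both`;
  the two feature spaces are disjoint so `both` is their sum.
* **Extended dependency kernel**: recursive common-subgraph count over the
  path-internal dependency lists. For a same-word node pair: leaves score
  1.0; a pair with children but no common child dependency scores 3.0 when
  the two subcategorization frames (left edge, right edge) agree, else 0;
  otherwise `C_w = w · (1 + Σ C_w(child pairs))` with `w = 3.0` when frames
  agree and `2.0` otherwise. The closed recursion is our reconstruction
  from the stated case values (the constants 3.0 / 1.0 / 0 are reproduced
  as limiting cases and frame agreement always scores higher); all four
  constants are configurable, and a restricted preset (no partial matches,
  no subcategorization) recovers plain complete-path matching and is
  provably never larger. The POS variant `C_p` drops all subcategorization
  terms and recurses with weight 1. Graph-level score:
  `2.0 · Σ C_w + 1.0 · Σ C_p` over all same-symbol node pairs (the lexical
  term deliberately outweighs the syntactic one; the 2:1 ratio is a
  default, only the ordering is essential).
* **String kernels**: spectrum (common contiguous 3-grams), fixed-length
  subsequence (common length-3 subsequences, gaps allowed, occurrence pairs
  counted once), gap-weighted (`λ^(l(i)+l(j))` per occurrence pair, span
  `l`, default `λ = 0.5`), and walk-weighted (3.0 / 2.0 / 1.0 by structural
  type, as in the README). Occurrence-pair semantics are used throughout,
  consistent with the gap-weighted definition; a pair whose two occurrences
  have different contiguity types scores the non-contiguous weight
  (configurable to min-of-types). Non-contiguous pairs can optionally be
  decayed per unit of gap; the default `λ = 1` applies no decay, which is
  also the best-performing setting. The subsequence kernel has its own
  integer-count dynamic programme, independent of the gap-weighted
  recursion, so the identity `gap(λ=1) ≡ subsequence` is a genuine
  cross-check of two code paths.

Useful ordering facts, all tested: spectrum ≤ subsequence;
gap-weighted(λ≤1) ≤ subsequence; walk-weighted ≥ subsequence for weights
≥ 1; walk-weighted with unit weights equals subsequence.

## Learning and evaluation

Kernels are cosine-normalized (`K' = K(x,y)/√(K(x,x)K(y,y))`; idempotent,
scale-invariant, unit diagonal on retained instances) and fed to a
soft-margin SVM on the precomputed Gram matrix (libsvm through
scikit-learn, native one-vs-one multiclass, `C = 1000`, no inner grid
search). Where a kernel admits an explicit feature map (spectrum,
subsequence, walk kernel, walk-weighted with `λ = 1`), the Gram matrix is
assembled by sparse feature dot products; a test pins this fast path to the
pairwise kernel loop.

Evaluation is micro-averaged precision / recall / F over positive labels.
Directed mode requires the predicted AT/TA orientation to match; undirected
mode collapses both to a single interaction label, so directed F never
exceeds undirected F. Cross-validation partitions **documents** (seeded
shuffle of sorted document ids, round-robin into 10 folds): instance-level
splitting leaks intra-document correlation and measurably inflates scores,
which a test demonstrates on a corpus with duplicated sentences. For
corpora that annotate interactions without direction, instances carry the
canonical label `AT` and only undirected evaluation is meaningful.

## Synthetic corpus generator

The generator emulates the *structure* of the genic-interaction corpora:
random projective dependency trees (filler chains hanging off the fragment
root), a small LLL-style relation vocabulary (`appos, comp_prep, mod,
mod_att, neg, obj, subj`), two NEs per sentence, and a planted positive
pattern in a configurable fraction of sentences, with the agent on either
side so both AT and TA occur. Defaults: 20 documents × 10 sentences,
mean length 9 tokens, negative rate 0.5 (the class balance of the LLL-style
setting), nesting rate 0.1 (a nested single-token entity inside a widened
two-token entity; nested entities share the outer entity's structure but
not its label, deliberately reproducing the learning difficulty they cause).
The mean length is kept short of real biomedical sentences to keep
kernel matrices small; path structure, not sentence padding, carries all
class signal.

Two modes:

* `plain` — positives use an interaction-verb subject/object frame,
  negatives attach both entities to a non-interaction noun; separable from
  contiguous n-grams alone.
* `gapped_contrast` — both classes share one five-node frame
  `NE ←subj– V –mod→ X –comp_*→ NE` with random filler `X`; the class is
  the exclusive-or of (verb, final complement relation). Each symbol is
  marginally class-balanced and the two informative symbols never co-occur
  in one contiguous 3-window, so contiguous kernels see (asymptotically) no
  signal while any kernel with gapped length-3 subsequences sees a linearly
  separable feature. This isolates exactly the capability the walk-weighted
  kernel adds over the spectrum kernel.

What the generator does **not** emulate: real parser error distributions,
long-range coordination and apposition, lexical variety beyond small symbol
pools, multi-sentence discourse. Passing end-to-end tests therefore show
that the pipeline recovers plantable path-level signal under realistic
structural noise — not that it attains any particular accuracy on real
corpora, which require the external datasets.

End-to-end checks use pattern-separable corpora (nesting rate 0): nested
entities are structurally identical but differently labelled, which makes
perfect recovery impossible by construction and is tested separately.

## Numerical and degenerate-input choices

* Shortest-path ties: among equal-length paths the lexicographically
  smallest node-index sequence wins (two breadth-first passes plus greedy
  forward selection).
* Kernel dynamic programmes are plain O(p·n·m) float recursions; the
  brute-force comparisons require agreement to 1e-10, and empirical Gram
  PSD checks use an eigenvalue floor of −1e-8.
* Self-pairs render as a single-node path: zero self-similarity under the
  string kernels, hence excluded by normalization and auto-predicted `O`.
* Single-class training folds return a majority predictor with a warning.
* Sentences with fewer than 5 tokens cannot host a planted pattern; the
  generator rejects such configurations up front.

## Known limitations

* The LLL 27-relation inventory is transcribed from challenge
  documentation and used only for warnings; the XML reader accepts any
  relation label string (the converted corpora use a 55-label scheme that
  is nowhere enumerated).
* Negation marking covers `neg` dependents and a fixed cue lexicon around
  the predicate; coordination-scope negation ("interacts with A but not
  with B") is a documented miss.
* Path extension handles only two-node conjunction paths; coordinated
  entities whose clue words lie farther away remain uncovered.
* The extended dependency kernel's empirical PSD check is not a proof; its
  case structure does not obviously decompose into an explicit feature
  map. All observed Gram spectra are PSD to numerical precision.
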