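"""Kernel normalization, Gram matrices, SVM learning and P/R/F evaluation.

Training operates on precomputed Gram matrices: every kernel value is
cosine-normalized, ``K'(x, y) = K(x, y) / sqrt(K(x, x) K(y, y))``, and fed
to a soft-margin SVM (scikit-learn's libsvm binding with
``kernel='precomputed'``, one-vs-one over the three labels AT / TA / O,
C = 1000). Instances with zero self-similarity — disconnected pairs with
empty paths — are excluded from the margin problem and auto-predicted O.

Evaluation is precision / recall / F over the positive labels, pooled
(micro) across folds, in two modes: *directed* (a prediction counts only if
its agent/target orientation matches the gold) and *undirected* (AT and TA
collapse to a single interaction label). Cross-validation partitions
*documents*, never instances, so no document contributes to both train and
test — instance-level splitting leaks intra-document correlation and
inflates scores.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .path_extract import RelationInstance, enumerate_instances
from .records import SentenceRecord
from .string_kernels import KernelSpec, instance_feature_map, instance_kernel

__all__ = [
    "EvalReport",
    "CVResult",
    "build_instances",
    "gram_matrix",
    "cross_gram",
    "normalize",
    "train",
    "predict",
    "evaluate",
    "cross_validate",
]

NEGATIVE_LABEL = "O"


def build_instances(
    records: list[SentenceRecord], *, include_self_pairs: bool = True, **render_kwargs
) -> list[RelationInstance]:
    """Flatten a corpus into relation instances, sentence by sentence."""
    out: list[RelationInstance] = []
    for rec in records:
        out.extend(
            enumerate_instances(rec, include_self_pairs=include_self_pairs, **render_kwargs)
        )
    return out


def _feature_gram(instances: list[RelationInstance], spec: KernelSpec):
    """Sparse explicit-feature Gram, or None when the spec has no such map."""
    maps = []
    for inst in instances:
        fm = instance_feature_map(inst, spec)
        if fm is None:
            return None
        maps.append(fm)
    vocab: dict = {}
    rows, cols, vals = [], [], []
    for i, fm in enumerate(maps):
        for key, v in fm.items():
            j = vocab.setdefault(key, len(vocab))
            rows.append(i)
            cols.append(j)
            vals.append(v)
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(instances), max(len(vocab), 1))
    )
    return np.asarray((X @ X.T).todense(), dtype=float)


def gram_matrix(instances: list[RelationInstance], spec: KernelSpec) -> np.ndarray:
    """Pairwise kernel matrix; uses the explicit feature map when one exists."""
    g = _feature_gram(instances, spec)
    if g is not None:
        return g
    n = len(instances)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = instance_kernel(instances[i], instances[j], spec)
    return K


def cross_gram(
    test: list[RelationInstance], train_: list[RelationInstance], spec: KernelSpec
) -> np.ndarray:
    K = np.zeros((len(test), len(train_)))
    for i, a in enumerate(test):
        for j, b in enumerate(train_):
            K[i, j] = instance_kernel(a, b, spec)
    return K


def normalize(K: np.ndarray, diag: np.ndarray | None = None) -> np.ndarray:
    """Cosine normalization; rows/columns with zero self-similarity go to 0.

    For a square Gram pass nothing; for a rectangular test-vs-train block
    pass ``diag=(diag_test, diag_train)``. Idempotent on square inputs and
    invariant to positive rescaling of K.
    """
    if diag is None:
        d_row = d_col = np.sqrt(np.clip(np.diag(K), 0.0, None))
    else:
        d_row, d_col = (np.sqrt(np.clip(d, 0.0, None)) for d in diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = K / np.outer(d_row, d_col)
    out[~np.isfinite(out)] = 0.0
    return out


@dataclass
class _MajorityModel:
    label: str

    def predict(self, K: np.ndarray):
        return np.array([self.label] * K.shape[0], dtype=object)


def train(gram: np.ndarray, labels: list[str], C: float = 1000.0):
    """Fit the precomputed-kernel SVM (one-vs-one multiclass, default C=1000)."""
    from sklearn.svm import SVC

    uniq = sorted(set(labels))
    if len(uniq) < 2:
        warnings.warn(
            "training data contains a single class; returning a majority predictor",
            UserWarning,
            stacklevel=2,
        )
        return _MajorityModel(uniq[0] if uniq else NEGATIVE_LABEL)
    model = SVC(kernel="precomputed", C=C)
    model.fit(gram, np.asarray(labels, dtype=object))
    return model


def predict(model, gram_test_vs_train: np.ndarray, empty_mask=None) -> list[str]:
    """One label per test row; empty-path instances are forced to O."""
    preds = list(model.predict(gram_test_vs_train))
    if empty_mask is not None:
        preds = [NEGATIVE_LABEL if m else p for p, m in zip(preds, empty_mask)]
    return [str(p) for p in preds]


@dataclass
class EvalReport:
    """Precision / recall / F over positive labels, with raw counts."""

    precision: float
    recall: float
    fscore: float
    mode: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_fold: list[tuple[float, float, float]] = field(default_factory=list)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _counts(pred: list[str], gold: list[str], mode: str) -> tuple[int, int, int]:
    if mode == "undirected":
        collapse = lambda l: "I" if l in ("AT", "TA") else l  # noqa: E731
        pred = [collapse(p) for p in pred]
        gold = [collapse(g) for g in gold]
    tp = sum(1 for p, g in zip(pred, gold) if p == g != NEGATIVE_LABEL)
    fp = sum(1 for p, g in zip(pred, gold) if p != NEGATIVE_LABEL and p != g)
    fn = sum(1 for p, g in zip(pred, gold) if g != NEGATIVE_LABEL and p != g)
    return tp, fp, fn


def evaluate(pred: list[str], gold: list[str], mode: str = "directed") -> EvalReport:
    """Micro P/R/F. Directed mode requires the AT/TA orientation to match."""
    if mode not in ("directed", "undirected"):
        raise ValueError("mode must be 'directed' or 'undirected'")
    if len(pred) != len(gold):
        raise ValueError("prediction/gold length mismatch")
    tp, fp, fn = _counts(pred, gold, mode)
    p, r, f = _prf(tp, fp, fn)
    return EvalReport(precision=p, recall=r, fscore=f, mode=mode, tp=tp, fp=fp, fn=fn)


@dataclass
class CVResult:
    """Document-level cross-validation outcome."""

    predictions: list[str]
    golds: list[str]
    fold_of_doc: dict[str, int]
    directed: EvalReport
    undirected: EvalReport

    def report(self, mode: str = "directed") -> EvalReport:
        return self.directed if mode == "directed" else self.undirected


def cross_validate(
    instances: list[RelationInstance],
    spec: KernelSpec,
    folds: int = 10,
    seed: int = 0,
    C: float = 1000.0,
) -> CVResult:
    """10-fold document-level CV with pooled (micro) P/R/F in both modes.

    Folds partition documents; assignment is keyed by sorted document id and
    a seeded shuffle, so instance order never changes fold membership.
    """
    docs = sorted({inst.doc_id for inst in instances})
    if len(docs) < folds:
        raise ValueError(
            f"{len(docs)} documents cannot fill {folds} folds; reduce the fold count"
        )
    shuffled = list(docs)
    random.Random(seed).shuffle(shuffled)
    fold_of_doc = {doc: i % folds for i, doc in enumerate(shuffled)}

    K = normalize(gram_matrix(instances, spec))
    labels = [inst.label for inst in instances]
    empty = [inst.is_empty for inst in instances]
    predictions: list[str | None] = [None] * len(instances)
    per_fold: dict[str, list[tuple[float, float, float]]] = {
        "directed": [], "undirected": []
    }
    for fold in range(folds):
        test_ix = [i for i, inst in enumerate(instances) if fold_of_doc[inst.doc_id] == fold]
        train_ix = [
            i
            for i, inst in enumerate(instances)
            if fold_of_doc[inst.doc_id] != fold and not empty[i]
        ]
        if not test_ix:
            continue
        model = train(K[np.ix_(train_ix, train_ix)], [labels[i] for i in train_ix], C=C)
        preds = predict(
            model, K[np.ix_(test_ix, train_ix)], empty_mask=[empty[i] for i in test_ix]
        )
        for i, p in zip(test_ix, preds):
            predictions[i] = p
        for mode in ("directed", "undirected"):
            tp, fp, fn = _counts(preds, [labels[i] for i in test_ix], mode)
            per_fold[mode].append(_prf(tp, fp, fn))
    final = [p if p is not None else NEGATIVE_LABEL for p in predictions]
    reports = {}
    for mode in ("directed", "undirected"):
        rep = evaluate(final, labels, mode)
        rep.per_fold = per_fold[mode]
        reports[mode] = rep
    return CVResult(
        predictions=final,
        golds=labels,
        fold_of_doc=fold_of_doc,
        directed=reports["directed"],
        undirected=reports["undirected"],
    )
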