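"""Study-type triage: text chunking, cross-validated evaluation, calibration,
and inter-annotator agreement.

Each abstract's text is assembled by concatenating title, abstract, MeSH
terms and keywords, then split into non-overlapping chunks of at most
``max_chunk_len`` whitespace tokens (the fixed input width of
transformer-style classifiers).  Classifiers are pluggable objects with
``fit(chunk_lists, labels)`` / ``predict_record(chunk_lists)``; the bundled
reference classifier is a regularized logistic regression over token counts
whose chunk-level scores are max-pooled per record, so any positive chunk
flags the record.

Evaluation is one study type at a time — positive records of that type
versus non-relevant records — under stratified k-fold cross-validation, so
every sample is predicted exactly once as a held-out item.  Metrics are
reported both pooled over the union of test folds and per fold.

Calibration re-reviews the labels of misclassified records via a review
function (a human in practice, an oracle in tests) and reports metrics
before and after.  Agreement between two annotators is exact-tuple agreement
(relevance plus the full study-type set); disagreements are adjudicated by a
third annotator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .lexicon import STUDY_TYPES, AbstractRecord, validate_study_labels

__all__ = [
    "LabeledAbstract",
    "TextSample",
    "EvalMetrics",
    "AgreementReport",
    "CrossvalResult",
    "assemble_and_chunk",
    "crossval_evaluate",
    "calibration_pass",
    "agreement_and_adjudicate",
    "inclusion_rule",
    "ReferenceClassifier",
]


@dataclass(frozen=True)
class LabeledAbstract:
    """An abstract with relevance and study-type labels."""

    record: AbstractRecord
    relevant: bool
    labels: frozenset

    def __post_init__(self) -> None:
        validate_study_labels(self.labels)
        if not self.relevant and self.labels:
            raise ValueError("non-relevant abstracts cannot carry study-type labels")


@dataclass(frozen=True)
class TextSample:
    record_id: str
    chunks: tuple[tuple[str, ...], ...]

    @property
    def text(self) -> str:
        return " ".join(t for chunk in self.chunks for t in chunk)


def assemble_and_chunk(record: AbstractRecord, max_chunk_len: int = 512) -> TextSample:
    """Assemble title + abstract + MeSH + keywords and chunk by token count.

    Tokenization is whitespace splitting; chunks hold exactly
    ``max_chunk_len`` tokens except possibly the last.  An empty record
    yields a single empty chunk.
    """
    if max_chunk_len < 1:
        raise ValueError("max_chunk_len must be >= 1")
    text = " ".join(
        part for part in (
            record.title, record.abstract,
            " ".join(record.mesh_terms), " ".join(record.keywords),
        ) if part
    )
    tokens = text.split()
    if not tokens:
        return TextSample(record.record_id, ((),))
    chunks = tuple(
        tuple(tokens[i: i + max_chunk_len])
        for i in range(0, len(tokens), max_chunk_len)
    )
    return TextSample(record.record_id, chunks)


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @classmethod
    def from_confusion(cls, tp: int, fp: int, fn: int, tn: int) -> "EvalMetrics":
        n = tp + fp + fn + tn
        acc = (tp + tn) / n if n else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        return cls(acc, prec, rec, f1, tp, fp, fn, tn)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    return EvalMetrics.from_confusion(tp, fp, fn, tn)


class ReferenceClassifier:
    """Token-count logistic regression with per-record chunk max-pooling.

    A lightweight stand-in honouring the pluggable classifier interface:
    ``fit`` trains on individual chunks (each chunk inherits its record's
    label); ``predict_record`` scores every chunk and max-pools, so one
    positive chunk makes the record positive.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self._vec: CountVectorizer | None = None
        self._clf: LogisticRegression | None = None

    @staticmethod
    def _chunk_texts(samples: Sequence[TextSample]) -> list[tuple[int, str]]:
        out = []
        for i, s in enumerate(samples):
            for chunk in s.chunks:
                out.append((i, " ".join(chunk)))
        return out

    def fit(self, samples: Sequence[TextSample], labels: Sequence[bool]) -> "ReferenceClassifier":
        pairs = self._chunk_texts(samples)
        texts = [t for _, t in pairs]
        y = np.array([bool(labels[i]) for i, _ in pairs])
        self._vec = CountVectorizer(token_pattern=r"(?u)\b\w\w+\b")
        X = self._vec.fit_transform(texts)
        self._clf = LogisticRegression(C=self.C, max_iter=2000)
        self._clf.fit(X, y)
        return self

    def predict_record(self, samples: Sequence[TextSample]) -> np.ndarray:
        if self._clf is None or self._vec is None:
            raise RuntimeError("classifier is not fitted")
        pairs = self._chunk_texts(samples)
        X = self._vec.transform([t for _, t in pairs])
        scores = self._clf.decision_function(X)
        pooled = np.full(len(samples), -np.inf)
        for (i, _), s in zip(pairs, scores):
            pooled[i] = max(pooled[i], s)
        return pooled > 0.0


@dataclass
class CrossvalResult:
    pooled: EvalMetrics
    per_fold: list[EvalMetrics]
    predictions: dict[str, bool]  # record_id -> held-out prediction


def _binary_task(
    samples: Sequence[LabeledAbstract], study_type: str, max_chunk_len: int
) -> tuple[list[TextSample], np.ndarray, list[str]]:
    """Positive = carries the study type; negative = non-relevant records."""
    if study_type not in STUDY_TYPES:
        raise ValueError(f"unknown study type {study_type!r}")
    texts, y, ids = [], [], []
    for s in samples:
        if study_type in s.labels:
            label = True
        elif not s.relevant:
            label = False
        else:
            continue  # relevant records of other types are out of this task
        texts.append(assemble_and_chunk(s.record, max_chunk_len))
        y.append(label)
        ids.append(s.record.record_id)
    return texts, np.array(y, dtype=bool), ids


def crossval_evaluate(
    samples: Sequence[LabeledAbstract],
    classifier_factory: Callable[[], object] = ReferenceClassifier,
    study_type: str = "PK",
    k_folds: int = 3,
    seed: int = 0,
    max_chunk_len: int = 512,
) -> CrossvalResult:
    """Stratified k-fold evaluation of one study-type-vs-non-relevant task.

    Folds are disjoint and exhaustive, each sample is predicted exactly once
    as a held-out item, and the same seed reproduces the same folds.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    texts, y, ids = _binary_task(samples, study_type, max_chunk_len)
    for cls_value, name in ((True, study_type), (False, "non-relevant")):
        if int(np.sum(y == cls_value)) < k_folds:
            raise ValueError(
                f"need >= {k_folds} '{name}' samples for {k_folds}-fold "
                "stratified evaluation")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    preds = np.zeros_like(y)
    per_fold = []
    for train, test in skf.split(np.zeros(len(y)), y):
        clf = classifier_factory()
        clf.fit([texts[i] for i in train], y[train])
        p = np.asarray(clf.predict_record([texts[i] for i in test]), dtype=bool)
        preds[test] = p
        per_fold.append(_confusion(y[test], p))
    pooled = _confusion(y, preds)
    return CrossvalResult(pooled, per_fold,
                          {rid: bool(p) for rid, p in zip(ids, preds)})


@dataclass
class CalibrationReport:
    before: EvalMetrics
    after: EvalMetrics
    n_reviewed: int
    n_relabeled: int

    @property
    def f1_delta(self) -> float:
        return self.after.f1 - self.before.f1


def calibration_pass(
    predictions: Mapping[str, bool],
    truth: Mapping[str, bool],
    review_fn: Callable[[Sequence[str]], Mapping[str, bool]],
) -> tuple[dict[str, bool], CalibrationReport]:
    """Re-review misclassified labels and report metrics before/after.

    ``predictions`` and ``truth`` are aligned by record id.  Ids where they
    disagree are handed to ``review_fn``, which returns corrected labels for
    (a subset of) exactly those ids; touching any other id is an error.
    Metrics compare predictions against the label sets before and after the
    corrections.
    """
    if set(predictions) != set(truth):
        raise ValueError("predictions and truth must cover the same record ids")
    ids = sorted(predictions)
    pred = np.array([predictions[i] for i in ids], dtype=bool)
    before_labels = np.array([truth[i] for i in ids], dtype=bool)
    misclassified = [i for i in ids if predictions[i] != truth[i]]
    corrections = dict(review_fn(misclassified))
    stray = set(corrections) - set(misclassified)
    if stray:
        raise ValueError(
            f"review altered ids outside the misclassified set: {sorted(stray)}")
    corrected = {i: bool(corrections.get(i, truth[i])) for i in ids}
    after_labels = np.array([corrected[i] for i in ids], dtype=bool)
    report = CalibrationReport(
        before=_confusion(before_labels, pred),
        after=_confusion(after_labels, pred),
        n_reviewed=len(misclassified),
        n_relabeled=sum(corrected[i] != truth[i] for i in ids),
    )
    return corrected, report


@dataclass(frozen=True)
class AgreementReport:
    n_items: int
    n_agree: int
    disagreement_ids: tuple[str, ...]

    @property
    def agreement_rate(self) -> float:
        return self.n_agree / self.n_items if self.n_items else 0.0


LabelTuple = tuple  # (relevant: bool, labels: frozenset)


def agreement_and_adjudicate(
    labels_a: Mapping[str, LabelTuple],
    labels_b: Mapping[str, LabelTuple],
    labels_c: Mapping[str, LabelTuple],
) -> tuple[AgreementReport, dict[str, LabelTuple]]:
    """Exact-tuple agreement between two annotators with third-party tiebreak.

    Agreement is counted on the full (relevant, study-type set) tuple.  The
    final label is the shared one where a and b agree, otherwise annotator
    c's, who must cover every disagreement id.
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("annotators a and b must cover identical id sets")
    ids = sorted(labels_a)
    disagreements = [i for i in ids if labels_a[i] != labels_b[i]]
    missing = [i for i in disagreements if i not in labels_c]
    if missing:
        raise ValueError(f"missing adjudication for ids: {missing}")
    final = {i: labels_a[i] if labels_a[i] == labels_b[i] else labels_c[i]
             for i in ids}
    report = AgreementReport(len(ids), len(ids) - len(disagreements),
                             tuple(disagreements))
    return report, final


def inclusion_rule(per_type_predictions: Mapping[str, bool]) -> bool:
    """Include a record iff it is predicted positive in at least one of
    PK, PE, CT."""
    missing = set(STUDY_TYPES) - set(per_type_predictions)
    if missing:
        raise ValueError(f"missing study types: {sorted(missing)}")
    return any(bool(per_type_predictions[t]) for t in STUDY_TYPES)
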