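"""Three-way diagnosis by fusing the three calibrated binary classifiers.

Each class appears in exactly two of the three binary problems. A subject's
raw score for class X is the mean of the two Platt-calibrated probabilities
of belonging to X, each weighted by the training-averaged recall of X in
that problem (sensitivity if X is the positive class, specificity if
negative). The three raw scores are normalized to sum to one.

A MoCA gate precedes the score comparison: subjects scoring 23 or below on
the Montreal Cognitive Assessment are cognitively impaired and are assigned
to AD or AD-CVD by the higher of those two normalized scores; subjects
above the cutoff compete over all three classes. Exact ties resolve in the
fixed order AD > AD-CVD > Control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import PROBLEMS, BinaryPerf

CLASSES = ("AD", "AD-CVD", "Control")  # also the tie-break priority
MOCA_CUTOFF = 23

#: problems containing each class
PROBLEMS_FOR_CLASS: dict[str, tuple[str, ...]] = {
    cls: tuple(p for p, pair in PROBLEMS.items() if cls in pair) for cls in CLASSES
}


@dataclass(frozen=True)
class ClassProbabilities:
    """Per-subject Platt probabilities: (class, problem) -> P, where the two
    class probabilities within one problem sum to 1. A problem may be
    absent when the subject lacks all of its features."""

    probs: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for problem, (pos, neg) in PROBLEMS.items():
            p_pos = self.probs.get((pos, problem))
            p_neg = self.probs.get((neg, problem))
            if (p_pos is None) != (p_neg is None):
                raise ValueError(f"problem {problem} has only one class probability")
            if p_pos is not None and abs(p_pos + p_neg - 1.0) > 1e-6:
                raise ValueError(f"probabilities of {problem} do not sum to 1")

    def get(self, cls: str, problem: str) -> float | None:
        return self.probs.get((cls, problem))


@dataclass(frozen=True)
class ClassWeights:
    """(class, problem) -> training-averaged recall of the class."""

    weights: Mapping[tuple[str, str], float]

    @classmethod
    def from_perfs(cls, perfs: Mapping[str, BinaryPerf]) -> "ClassWeights":
        w = {}
        for problem, perf in perfs.items():
            pos, neg = PROBLEMS[problem]
            w[(pos, problem)] = perf.weight_for(pos)
            w[(neg, problem)] = perf.weight_for(neg)
        return cls(w)

    def get(self, c: str, problem: str) -> float:
        try:
            return self.weights[(c, problem)]
        except KeyError:
            raise KeyError(f"missing weight for class {c} in {problem}") from None


@dataclass
class SubjectScores:
    subject_id: str
    raw: dict[str, float]
    normalized: dict[str, float] = field(default_factory=dict)
    moca: int | None = None
    gate_applied: bool = False
    diagnosis: str | None = None


def class_scores(
    subject_id: str, p: ClassProbabilities, w: ClassWeights
) -> SubjectScores:
    """Raw score per class: mean of the weighted probabilities over the two
    problems containing the class. Falls back to the single available
    problem when the other problem's probabilities are missing."""
    raw = {}
    for cls in CLASSES:
        terms = []
        for problem in PROBLEMS_FOR_CLASS[cls]:
            prob = p.get(cls, problem)
            if prob is None:
                continue
            terms.append(prob * w.get(cls, problem))
        if not terms:
            raise ValueError(f"subject {subject_id}: no probabilities for class {cls}")
        raw[cls] = float(np.mean(terms))
    return SubjectScores(subject_id, raw)


def normalize_scores(s: SubjectScores) -> SubjectScores:
    total = sum(s.raw.values())
    if total <= 0:
        warnings.warn(f"subject {s.subject_id}: all-zero scores; uniform fallback",
                      stacklevel=2)
        s.normalized = {c: 1 / 3 for c in CLASSES}
    else:
        s.normalized = {c: v / total for c, v in s.raw.items()}
    return s


def diagnose(
    s: SubjectScores, moca_cutoff: int = MOCA_CUTOFF
) -> SubjectScores:
    """MoCA-gated argmax: MoCA <= cutoff restricts the argmax to AD/AD-CVD;
    otherwise all three classes compete. Ties resolve AD > AD-CVD > Control."""
    if not s.normalized:
        normalize_scores(s)
    if s.moca is None:
        warnings.warn(
            f"subject {s.subject_id}: missing MoCA; ungated three-way argmax",
            stacklevel=2,
        )
        candidates = CLASSES
        s.gate_applied = False
    elif s.moca <= moca_cutoff:
        candidates = ("AD", "AD-CVD")
        s.gate_applied = True
    else:
        candidates = CLASSES
        s.gate_applied = False
    # CLASSES order is the tie-break priority; max is stable on first-best
    s.diagnosis = max(candidates, key=lambda c: (s.normalized[c], -CLASSES.index(c)))
    return s


def platt_probabilities(
    classifiers: Mapping[str, tuple],
    feature_rows: Mapping[str, Mapping[str, pd.Series]],
) -> dict[str, ClassProbabilities]:
    """Calibrated probabilities for each subject from trained classifiers.

    ``classifiers`` maps problem name -> (ImputerScaler, fitted SVC with
    probability=True, column names); ``feature_rows`` maps problem ->
    subject_id -> feature Series. Subjects missing every feature of a
    problem get no probabilities for it.
    """
    per_subject: dict[str, dict[tuple[str, str], float]] = {}
    for problem, (prep, clf, columns) in classifiers.items():
        pos, neg = PROBLEMS[problem]
        rows = feature_rows[problem]
        ids = [s for s, r in rows.items() if not r[list(columns)].isna().all()]
        if not ids:
            continue
        X = pd.DataFrame(
            {c: [rows[s][c] for s in ids] for c in columns}, index=ids
        )
        proba = clf.predict_proba(prep.transform(X))
        pos_col = list(clf.classes_).index(True)
        for i, sid in enumerate(ids):
            d = per_subject.setdefault(sid, {})
            d[(pos, problem)] = float(proba[i, pos_col])
            d[(neg, problem)] = float(1.0 - proba[i, pos_col])
    return {sid: ClassProbabilities(p) for sid, p in per_subject.items()}


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ThreeWayMetrics:
    confusion: pd.DataFrame  # rows = predicted, columns = true
    sensitivity: dict[str, float]  # one-vs-rest
    specificity: dict[str, float]
    balanced_accuracy: float


def three_way_metrics(
    true_labels: Sequence[str], diagnoses: Sequence[str]
) -> ThreeWayMetrics:
    """Confusion matrix (rows predicted, columns true), one-vs-rest
    sensitivity/specificity per class, and balanced accuracy (mean of the
    per-class sensitivities/recalls)."""
    true_labels = list(true_labels)
    diagnoses = list(diagnoses)
    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for t, d in zip(true_labels, diagnoses, strict=True):
        conf.loc[d, t] += 1
    sens, spec = {}, {}
    for cls in CLASSES:
        tp = conf.loc[cls, cls]
        fn = conf[cls].sum() - tp
        fp = conf.loc[cls].sum() - tp
        tn = conf.to_numpy().sum() - tp - fn - fp
        sens[cls] = tp / (tp + fn) if (tp + fn) else float("nan")
        spec[cls] = tn / (tn + fp) if (tn + fp) else float("nan")
    available = [v for v in sens.values() if np.isfinite(v)]
    if len(available) < len(CLASSES):
        warnings.warn("empty class; balanced accuracy over available classes",
                      stacklevel=2)
    return ThreeWayMetrics(
        confusion=conf,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=float(np.mean(available)),
    )


def metrics_from_confusion(conf: pd.DataFrame) -> ThreeWayMetrics:
    """Same metrics computed directly from a printed confusion matrix
    (rows = predicted class, columns = true class)."""
    true_labels, diagnoses = [], []
    for pred in conf.index:
        for true in conf.columns:
            n = int(conf.loc[pred, true])
            true_labels += [true] * n
            diagnoses += [pred] * n
    return three_way_metrics(true_labels, diagnoses)
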