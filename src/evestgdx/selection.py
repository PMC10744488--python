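"""Feature reduction, selection and cross-validated SVM evaluation.

Per resampled training set, candidate region features are reduced by an
exhaustive search over all subsets of at most three features, scored by SVM
training accuracy (ties broken by the subset with fewer missing values,
then lexicographically). Across training sets the most frequently selected
features are retained, their bin regions collapsed to the "common region"
(bins present in more than half of the repetitions), and the final subset
is the one with the highest cross-validated test accuracy recomputed on
common regions. The whole procedure is repeated with fresh resamples to
check stability.

Imputation and Z-scoring are always fitted on training data only: observed
values are standardized, missing entries imputed with class-conditional
means (pooled means for unlabeled/blind rows) in standardized space, and
the result re-standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .classify import BinaryPerf, ConfusionCounts, accuracy as _acc, sensitivity, specificity
from .features import (
    CandidateFeature,
    FeatureDef,
    TrainingSet,
    compute_feature,
    find_separation_regions,
    test_feature,
)
from .ih33 import IH33Signal, SignalKey, signals_for_tilt


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    C: float = 1.0
    calibration_folds: int = 5

    def make(self, probability: bool = False, seed: int = 0):
        """Plain SVC, or a Platt-calibrated (sigmoid) wrapper when posterior
        probabilities are needed."""
        svc = SVC(kernel=self.kernel, C=self.C, random_state=seed)
        if not probability:
            return svc
        from sklearn.calibration import CalibratedClassifierCV

        return CalibratedClassifierCV(
            svc, method="sigmoid", cv=self.calibration_folds, ensemble=False
        )


@dataclass
class FeatureMatrix:
    """Subjects x features with missingness, plus binary class labels."""

    values: pd.DataFrame  # index: subject ids; columns: feature names; NaN = missing
    labels: pd.Series  # index-aligned class labels
    positive: str
    negative: str
    feature_defs: dict[str, FeatureDef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)

    def subset(self, columns: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[list(columns)],
            self.labels,
            self.positive,
            self.negative,
            {c: self.feature_defs[c] for c in columns if c in self.feature_defs},
        )

    def n_missing(self, columns: Sequence[str]) -> int:
        return int(self.values[list(columns)].isna().sum().sum())


def feature_name(f: FeatureDef) -> str:
    lo = ",".join(map(str, f.region_low))
    hi = ",".join(map(str, f.region_high))
    return f"{f.key}|[{lo}]-[{hi}]"


def build_feature_matrix(
    signals_by_subject: Mapping[str, Mapping[SignalKey, IH33Signal]],
    features: Sequence[FeatureDef],
    labels: Mapping[str, str],
    positive: str,
    negative: str,
    subject_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    if subject_ids is None:
        subject_ids = [s for s in signals_by_subject if labels.get(s) in (positive, negative)]
    cols = {}
    for f in features:
        name = feature_name(f)
        cols[name] = [
            compute_feature(signals_by_subject[s].get(f.key), f) for s in subject_ids
        ]
    values = pd.DataFrame(cols, index=list(subject_ids), dtype=float)
    return FeatureMatrix(
        values=values,
        labels=pd.Series({s: labels[s] for s in subject_ids}),
        positive=positive,
        negative=negative,
        feature_defs={feature_name(f): f for f in features},
    )


# ---------------------------------------------------------------------------
# leakage-safe imputation + double Z-scoring


class ImputerScaler:
    """Z-score observed values, impute in standardized space with
    class-conditional training means, and re-standardize.

    All statistics come from the training rows passed to :meth:`fit`;
    :meth:`transform` imputes unseen rows with the pooled training mean.
    """

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "ImputerScaler":
        self.mu1_ = X.mean(skipna=True)
        sd = X.std(skipna=True, ddof=0)
        self.sd1_ = sd.where(sd > 0, 1.0).fillna(1.0)
        self.mu1_ = self.mu1_.fillna(0.0)
        z = (X - self.mu1_) / self.sd1_
        self.class_means_ = {
            cls: z[y == cls].mean(skipna=True).fillna(0.0) for cls in y.unique()
        }
        self.pooled_mean_ = z.mean(skipna=True).fillna(0.0)
        z_imp = z.copy()
        for cls, m in self.class_means_.items():
            rows = y == cls
            z_imp.loc[rows] = z_imp.loc[rows].fillna(m)
        z_imp = z_imp.fillna(self.pooled_mean_)
        self.mu2_ = z_imp.mean()
        sd2 = z_imp.std(ddof=0)
        self.sd2_ = sd2.where(sd2 > 0, 1.0).fillna(1.0)
        self._train_out = (z_imp - self.mu2_) / self.sd2_
        return self

    def transform_train(self) -> np.ndarray:
        return self._train_out.to_numpy()

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        z = (X - self.mu1_) / self.sd1_
        z = z.fillna(self.pooled_mean_)
        return ((z - self.mu2_) / self.sd2_).to_numpy()


# ---------------------------------------------------------------------------
# exhaustive subset search (per training set, by SVM training accuracy)


def _train_accuracy(fm: FeatureMatrix, columns: Sequence[str], svm: SVMConfig) -> float:
    sub = fm.values[list(columns)]
    prep = ImputerScaler().fit(sub, fm.labels)
    X = prep.transform_train()
    y = (fm.labels == fm.positive).to_numpy()
    clf = svm.make()
    clf.fit(X, y)
    return float((clf.predict(X) == y).mean())


def exhaustive_subset_search(
    fm: FeatureMatrix,
    max_size: int = 3,
    svm: SVMConfig = SVMConfig(),
) -> list[str]:
    """Best feature subset of size 1..max_size by SVM training accuracy.

    Ties are broken by the subset with the lowest number of missing values,
    then by lexicographic order of the (sorted) column names. Returns an
    empty list when there are no candidate columns.

    Imputation/scaling statistics are column-wise, so they are fitted once
    on the full candidate matrix and sliced per subset.
    """
    columns = sorted(fm.values.columns)
    if not columns:
        return []
    prep = ImputerScaler().fit(fm.values[columns], fm.labels)
    X_full = prep.transform_train()
    col_idx = {c: i for i, c in enumerate(columns)}
    miss = fm.values[columns].isna().sum()
    y = (fm.labels == fm.positive).to_numpy()
    best: tuple[float, int, tuple[str, ...]] | None = None
    for size in range(1, min(max_size, len(columns)) + 1):
        for subset in combinations(columns, size):
            X = X_full[:, [col_idx[c] for c in subset]]
            clf = svm.make()
            clf.fit(X, y)
            acc = float((clf.predict(X) == y).mean())
            key = (-acc, int(miss[list(subset)].sum()), subset)
            if best is None or key < best:
                best = key
    return list(best[2])


# ---------------------------------------------------------------------------
# cross-validated evaluation


def evaluate_cv(
    fm: FeatureMatrix,
    folds: int = 10,
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
    tilt: str = "pooled",
    problem: str | None = None,
) -> BinaryPerf:
    """Stratified k-fold CV with leakage-safe per-fold imputation/scaling.

    Returns fold-averaged sensitivity, specificity, accuracy and AUC on the
    held-out folds (undefined per-fold metrics are skipped in the average).
    """
    y = (fm.labels == fm.positive).to_numpy()
    min_class = min(int(y.sum()), int((~y).sum()))
    if min_class < 2:
        raise ValueError("both classes need at least 2 members for CV")
    if min_class < folds:
        warnings.warn(
            f"reducing folds from {folds} to {min_class} (smallest class size)",
            stacklevel=2,
        )
        folds = min_class
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sens, spec, acc, aucs = [], [], [], []
    for train_idx, test_idx in skf.split(fm.values, y):
        X_train = fm.values.iloc[train_idx]
        y_train = y[train_idx]
        prep = ImputerScaler().fit(X_train, fm.labels.iloc[train_idx])
        clf = svm.make(seed=seed)
        clf.fit(prep.transform_train(), y_train)
        X_test = prep.transform(fm.values.iloc[test_idx])
        y_test = y[test_idx]
        pred = clf.predict(X_test)
        c = ConfusionCounts(
            tp=int(np.sum(pred & y_test)),
            tn=int(np.sum(~pred & ~y_test)),
            fp=int(np.sum(pred & ~y_test)),
            fn=int(np.sum(~pred & y_test)),
        )
        acc.append(_acc(c))
        sens.append(sensitivity(c))
        spec.append(specificity(c))
        if len(np.unique(y_test)) == 2:
            aucs.append(roc_auc_score(y_test, clf.decision_function(X_test)))
    return BinaryPerf(
        problem=problem or f"{fm.positive}-vs-{fm.negative}",
        tilt=tilt,
        sensitivity=float(np.nanmean(sens)),
        specificity=float(np.nanmean(spec)),
        accuracy=float(np.nanmean(acc)),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        n_folds=folds,
    )


def cv_subset_search(
    fm: FeatureMatrix,
    max_size: int = 3,
    folds: int = 10,
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
    tilt: str = "pooled",
    problem: str | None = None,
) -> tuple[list[str], BinaryPerf]:
    """Best subset of size 1..max_size by fold-averaged CV test accuracy.

    Equivalent to calling :func:`evaluate_cv` on every subset (same folds,
    same per-fold imputation/scaling, which is column-wise and therefore
    sliceable), with ties broken by fewer missing values then
    lexicographic order.
    """
    columns = sorted(fm.values.columns)
    if not columns:
        raise ValueError("no candidate columns")
    y = (fm.labels == fm.positive).to_numpy()
    min_class = min(int(y.sum()), int((~y).sum()))
    if min_class < 2:
        raise ValueError("both classes need at least 2 members for CV")
    if min_class < folds:
        warnings.warn(
            f"reducing folds from {folds} to {min_class} (smallest class size)",
            stacklevel=2,
        )
        folds = min_class
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_data = []
    for train_idx, test_idx in skf.split(fm.values, y):
        prep = ImputerScaler().fit(
            fm.values[columns].iloc[train_idx], fm.labels.iloc[train_idx]
        )
        fold_data.append(
            (
                prep.transform_train(),
                y[train_idx],
                prep.transform(fm.values[columns].iloc[test_idx]),
                y[test_idx],
            )
        )
    col_idx = {c: i for i, c in enumerate(columns)}
    miss = fm.values[columns].isna().sum()
    best = None
    for size in range(1, min(max_size, len(columns)) + 1):
        for subset in combinations(columns, size):
            idx = [col_idx[c] for c in subset]
            sens, spec, acc, aucs = [], [], [], []
            for X_tr, y_tr, X_te, y_te in fold_data:
                clf = svm.make(seed=seed)
                clf.fit(X_tr[:, idx], y_tr)
                pred = clf.predict(X_te[:, idx])
                c = ConfusionCounts(
                    tp=int(np.sum(pred & y_te)),
                    tn=int(np.sum(~pred & ~y_te)),
                    fp=int(np.sum(pred & ~y_te)),
                    fn=int(np.sum(~pred & y_te)),
                )
                acc.append(_acc(c))
                sens.append(sensitivity(c))
                spec.append(specificity(c))
                if len(np.unique(y_te)) == 2:
                    aucs.append(roc_auc_score(y_te, clf.decision_function(X_te[:, idx])))
            perf = BinaryPerf(
                problem=problem or f"{fm.positive}-vs-{fm.negative}",
                tilt=tilt,
                sensitivity=float(np.nanmean(sens)),
                specificity=float(np.nanmean(spec)),
                accuracy=float(np.nanmean(acc)),
                auc=float(np.mean(aucs)) if aucs else float("nan"),
                n_folds=folds,
            )
            key = (-perf.accuracy, int(miss[list(subset)].sum()), subset)
            if best is None or key < best[0]:
                best = (key, list(subset), perf)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# per-training-set extraction + reduction


@dataclass
class PerSetResult:
    set_index: int
    candidates: list[CandidateFeature]
    chosen: list[FeatureDef]
    train_accuracy: float
    n_signals_searched: int


def extract_candidates_for_set(
    tset: TrainingSet,
    signals_by_subject: Mapping[str, Mapping[SignalKey, IH33Signal]],
    keys: Sequence[SignalKey],
    positive: str,
    negative: str,
    require_both_sides: bool = True,
) -> list[CandidateFeature]:
    """Band-separation search + significance test on one training set."""
    out: list[CandidateFeature] = []
    pos_ids = tset.retained_ids(positive)
    neg_ids = tset.retained_ids(negative)
    for key in keys:
        group_a = [
            signals_by_subject[s][key] for s in pos_ids if key in signals_by_subject[s]
        ]
        group_b = [
            signals_by_subject[s][key] for s in neg_ids if key in signals_by_subject[s]
        ]
        if len(group_a) < 2 or len(group_b) < 2:
            continue
        fdef = find_separation_regions(
            group_a, group_b, labels=(positive, negative),
            require_both_sides=require_both_sides,
        )
        if fdef is None:
            continue
        va = [compute_feature(signals_by_subject[s].get(key), fdef) for s in pos_ids]
        vb = [compute_feature(signals_by_subject[s].get(key), fdef) for s in neg_ids]
        va = [v for v in va if v is not None]
        vb = [v for v in vb if v is not None]
        if len(va) < 3 or len(vb) < 3:
            continue
        p, test = test_feature(va, vb)
        cand = CandidateFeature(fdef, p, test, tset.index)
        if cand.significant:
            out.append(cand)
    return out


def reduce_set(
    candidates: Sequence[CandidateFeature],
    tset: TrainingSet,
    signals_by_subject: Mapping[str, Mapping[SignalKey, IH33Signal]],
    labels: Mapping[str, str],
    positive: str,
    negative: str,
    max_size: int = 3,
    max_candidates: int | None = None,
    svm: SVMConfig = SVMConfig(),
) -> PerSetResult:
    """Exhaustive <=3-subset SVM search over one set's significant features.

    ``max_candidates`` optionally caps the candidate pool to the smallest
    p-values before the combinatorial search (a problem-size control for
    very large candidate pools; the search itself is always exhaustive over
    the pool).
    """
    cands = sorted(candidates, key=lambda c: (c.p_value, feature_name(c.feature)))
    if max_candidates is not None:
        cands = cands[:max_candidates]
    if not cands:
        return PerSetResult(tset.index, [], [], float("nan"), 0)
    retained = list(tset.retained_ids(positive)) + list(tset.retained_ids(negative))
    fm = build_feature_matrix(
        signals_by_subject,
        [c.feature for c in cands],
        labels,
        positive,
        negative,
        subject_ids=retained,
    )
    chosen_names = exhaustive_subset_search(fm, max_size=max_size, svm=svm)
    chosen = [fm.feature_defs[n] for n in chosen_names]
    train_acc = _train_accuracy(fm, chosen_names, svm) if chosen_names else float("nan")
    return PerSetResult(tset.index, list(cands), chosen, train_acc, len(cands))


# ---------------------------------------------------------------------------
# consensus across training sets


@dataclass
class SelectionResult:
    final_features: list[FeatureDef]
    frequencies: dict[str, float]  # consensus identity -> selection frequency
    consensus_features: list[FeatureDef]  # common-region versions, all identities
    perf: BinaryPerf | None
    n_sets: int
    significant_yield: float  # mean fraction of searched signals yielding a candidate


def _common_region(regions: Sequence[tuple[int, ...]]) -> tuple[int, ...]:
    """Bins present in more than 50% of the repetitions."""
    counts: dict[int, int] = {}
    for r in regions:
        for b in r:
            counts[b] = counts.get(b, 0) + 1
    n = len(regions)
    return tuple(sorted(b for b, c in counts.items() if c > n / 2))


def consensus_and_common_regions(
    per_set: Sequence[PerSetResult],
    signals_by_subject: Mapping[str, Mapping[SignalKey, IH33Signal]],
    labels: Mapping[str, str],
    positive: str,
    negative: str,
    n_signals_per_set: int,
    max_size: int = 3,
    top_pool: int = 6,
    folds: int = 10,
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
    tilt: str = "pooled",
) -> SelectionResult:
    """Frequency-ranked consensus with >50% common regions, then the final
    subset by highest cross-validated test accuracy on common regions."""
    if not per_set:
        raise ValueError("need at least one per-set selection")
    n_sets = len(per_set)
    by_identity: dict[tuple, list[FeatureDef]] = {}
    for res in per_set:
        for f in res.chosen:
            by_identity.setdefault(f.identity(), []).append(f)

    n_cand = [len(r.candidates) for r in per_set]
    yield_frac = (
        float(np.mean([c / n_signals_per_set for c in n_cand]))
        if n_signals_per_set
        else 0.0
    )

    consensus: list[tuple[float, FeatureDef]] = []
    for identity, instances in by_identity.items():
        freq = len(instances) / n_sets
        low = _common_region([f.region_low for f in instances])
        high = _common_region([f.region_high for f in instances])
        if not low or not high or max(low) >= min(high):
            warnings.warn(
                f"feature {identity[0]} has no >50% common region; dropped",
                stacklevel=2,
            )
            continue
        consensus.append(
            (freq, FeatureDef(identity[0], low, high, identity[1]))
        )
    consensus.sort(key=lambda t: (-t[0], feature_name(t[1])))
    frequencies = {feature_name(f): freq for freq, f in consensus}
    pool = [f for _, f in consensus[:top_pool]]

    if not pool:
        return SelectionResult([], frequencies, [], None, n_sets, yield_frac)

    fm = build_feature_matrix(
        signals_by_subject, pool, labels, positive, negative
    )
    chosen_names, perf = cv_subset_search(
        fm, max_size=max_size, folds=folds, svm=svm, seed=seed, tilt=tilt
    )
    final = [fm.feature_defs[n] for n in chosen_names]
    return SelectionResult(
        final, frequencies, [f for _, f in consensus], perf, n_sets, yield_frac
    )


def run_binary_selection(
    signals_by_subject: Mapping[str, Mapping[SignalKey, IH33Signal]],
    labels: Mapping[str, str],
    positive: str,
    negative: str,
    training_sets: Sequence[TrainingSet],
    tilt: str,
    keys: Sequence[SignalKey] | None = None,
    max_size: int = 3,
    max_candidates: int | None = 10,
    folds: int = 10,
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
    require_both_sides: bool = True,
) -> SelectionResult:
    """Full per-tilt pipeline: per-set extraction + reduction, then consensus."""
    if keys is None:
        keys = signals_for_tilt(tilt)
    per_set = []
    for tset in training_sets:
        cands = extract_candidates_for_set(
            tset, signals_by_subject, keys, positive, negative, require_both_sides
        )
        per_set.append(
            reduce_set(
                cands, tset, signals_by_subject, labels, positive, negative,
                max_size=max_size, max_candidates=max_candidates, svm=svm,
            )
        )
    return consensus_and_common_regions(
        per_set, signals_by_subject, labels, positive, negative,
        n_signals_per_set=len(keys), max_size=max_size, folds=folds,
        svm=svm, seed=seed, tilt=tilt,
    )


# ---------------------------------------------------------------------------
# stability


@dataclass
class StabilityReport:
    per_repeat_keys: list[set[str]]
    key_jaccard: float
    stable: bool
    threshold: float


def stability_check(
    run: Callable[[int], SelectionResult],
    n_repeats: int = 3,
    seeds: Sequence[int] | None = None,
    threshold: float = 2 / 3,
) -> StabilityReport:
    """Re-run extraction + selection with fresh resamples and report the
    agreement of the final feature signal keys across repeats."""
    if seeds is None:
        seeds = list(range(n_repeats))
    key_sets: list[set[str]] = []
    for s in seeds[:n_repeats]:
        result = run(int(s))
        key_sets.append({str(f.key) for f in result.final_features})
    union = set().union(*key_sets) if key_sets else set()
    inter = set.intersection(*key_sets) if key_sets and all(key_sets) else set()
    jac = len(inter) / len(union) if union else 0.0
    return StabilityReport(key_sets, jac, jac >= threshold, threshold)
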