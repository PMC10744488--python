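"""End-to-end orchestration: simulate -> build -> extract -> select ->
train -> diagnose -> evaluate.

Every stage is seeded from one master seed, and a manifest records every
threshold actually used, so identical configurations reproduce identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import PROBLEMS, BinaryPerf, informative_tilts, pool_features
from .features import make_training_sets
from .grid import BinGrid, DEFAULT_GRID
from .hierarchy import (
    CLASSES,
    ClassProbabilities,
    ClassWeights,
    SubjectScores,
    class_scores,
    diagnose,
    normalize_scores,
    platt_probabilities,
    three_way_metrics,
    ThreeWayMetrics,
)
from .ih33 import (
    SEGMENT_DURATION_MS,
    TILTS,
    IH33Signal,
    SignalKey,
    build_ih33,
    derive_signals,
    qc_segment,
)
from .selection import (
    FeatureMatrix,
    ImputerScaler,
    SelectionResult,
    SVMConfig,
    build_feature_matrix,
    cv_subset_search,
    evaluate_cv,
    exhaustive_subset_search,
    feature_name,
    run_binary_selection,
)
from .synthetic import CohortConfig, SyntheticSubject, generate_cohort, generate_ih33_cohort


def derive_seed(master: int, *tags: str) -> int:
    """Deterministic stream seed below 2**31 from a master seed and tags."""
    return (int(master) ^ zlib.crc32("|".join(tags).encode())) % (2**31)


# ---------------------------------------------------------------------------
# building signals from FP-level data


def build_signals(
    subjects: Sequence[SyntheticSubject],
    grid: BinGrid = DEFAULT_GRID,
    duration_ms: float = SEGMENT_DURATION_MS,
) -> tuple[dict[str, dict[SignalKey, IH33Signal]], pd.DataFrame]:
    """QC each segment, histogram the passing ones, derive combinations.

    Returns per-subject signal dictionaries and a QC report table.
    """
    signals: dict[str, dict[SignalKey, IH33Signal]] = {}
    qc_rows = []
    for subj in subjects:
        per_segment: dict[SignalKey, IH33Signal] = {}
        for (tilt, phase, ear), seg in subj.segments.items():
            qc = qc_segment(seg, duration_ms=duration_ms, grid=grid)
            qc_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "tilt": tilt,
                    "phase": phase,
                    "ear": ear,
                    "pass": qc.passed,
                    "reason": qc.reason,
                }
            )
            if qc.passed:
                sig = build_ih33(seg, grid)
                per_segment[sig.key] = sig
        signals[subj.subject_id] = derive_signals(per_segment)
    return signals, pd.DataFrame(qc_rows)


def signals_wide_table(
    signals: Mapping[str, Mapping[SignalKey, IH33Signal]]
) -> pd.DataFrame:
    rows = []
    for sid, sigs in signals.items():
        for key, sig in sigs.items():
            row = {
                "subject_id": sid,
                "tilt": key.tilt,
                "phase": key.phase,
                "side": key.side,
                "normalized": sig.normalized,
                "n_averaged": sig.n_averaged,
            }
            row.update({f"b{i}": v for i, v in enumerate(sig.values)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    level: str = "ih33"  # "ih33" (direct histograms) or "fp" (FP-time simulation)
    tilts: tuple[str, ...] = TILTS
    n_sets: int = 100
    holdout: float = 0.2
    max_size: int = 3
    max_candidates: int | None = 10
    folds: int = 10
    svm: SVMConfig = field(default_factory=SVMConfig)
    informative_threshold_pct: float = 75.0
    moca_cutoff: int = 23
    top_pool: int = 6
    blind: CohortConfig | None = None
    blind_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in ("ih33", "fp"):
            raise ValueError("level must be 'ih33' or 'fp'")
        unknown = set(self.tilts) - set(TILTS)
        if unknown:
            raise ValueError(f"unknown tilts: {unknown}")
        if not (0 <= self.informative_threshold_pct <= 100):
            raise ValueError("informative threshold must be a percentage")
        if not (0 <= self.moca_cutoff <= 30):
            raise ValueError("MoCA cutoff must be within [0, 30]")


@dataclass
class ProblemModel:
    """Final pooled-feature classifier of one binary problem."""

    problem: str
    features: list  # FeatureDefs (may be empty -> trivial classifier)
    perf: BinaryPerf
    prep: ImputerScaler | None
    clf: object | None
    columns: list[str]
    fm: FeatureMatrix | None  # feature matrix over all subjects


@dataclass
class PipelineResult:
    config: PipelineConfig
    per_tilt: dict[str, dict[str, SelectionResult]]
    informative: dict[str, list[str]]
    models: dict[str, ProblemModel]
    weights: ClassWeights
    scores: list[SubjectScores]
    train_metrics: ThreeWayMetrics
    blind_scores: list[SubjectScores] | None = None
    blind_metrics: ThreeWayMetrics | None = None
    blind_perfs: dict[str, BinaryPerf] | None = None
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers


class _TrivialClassifier:
    """Fallback when no feature survives selection: predicts the positive
    class with probability 0.5, so the problem contributes no evidence."""

    classes_ = np.array([False, True])

    def predict_proba(self, X):
        n = len(X)
        return np.full((n, 2), 0.5)


def _trivial_model(problem: str) -> ProblemModel:
    perf = BinaryPerf(
        problem=problem, tilt="pooled", sensitivity=1.0, specificity=0.0,
        accuracy=float("nan"), auc=0.5, n_folds=0,
    )
    return ProblemModel(problem, [], perf, None, _TrivialClassifier(), [], None)


def _generate(config: PipelineConfig):
    """Returns (subjects, signals_by_subject, qc_report or None)."""
    if config.level == "ih33":
        pairs = generate_ih33_cohort(config.cohort)
        subjects = [s for s, _ in pairs]
        signals = {s.subject_id: sigs for s, sigs in pairs}
        return subjects, signals, None
    subjects = generate_cohort(config.cohort)
    signals, qc = build_signals(subjects)
    return subjects, signals, qc


def pooled_selection(
    fm: FeatureMatrix,
    training_sets,
    max_size: int,
    top_pool: int,
    folds: int,
    svm: SVMConfig,
    seed: int,
) -> tuple[list[str], BinaryPerf]:
    """Reduction + selection on a pooled feature matrix with known features:
    per-set exhaustive search, frequency ranking, final subset by CV."""
    counts: dict[str, int] = {}
    for tset in training_sets:
        retained = list(tset.retained_ids(fm.positive)) + list(
            tset.retained_ids(fm.negative)
        )
        sub = FeatureMatrix(
            fm.values.loc[retained], fm.labels.loc[retained],
            fm.positive, fm.negative, fm.feature_defs,
        )
        for name in exhaustive_subset_search(sub, max_size=max_size, svm=svm):
            counts[name] = counts.get(name, 0) + 1
    pool = sorted(counts, key=lambda n: (-counts[n], n))[:top_pool]
    if not pool:
        raise ValueError("pooled selection found no features")
    labeled = fm.labels.isin([fm.positive, fm.negative])
    fm_lab = FeatureMatrix(
        fm.values.loc[labeled, pool], fm.labels.loc[labeled],
        fm.positive, fm.negative, fm.feature_defs,
    )
    return cv_subset_search(fm_lab, max_size=max_size, folds=folds, svm=svm, seed=seed)


def _score_subjects(
    subjects: Sequence[SyntheticSubject],
    models: Mapping[str, ProblemModel],
    weights: ClassWeights,
    feature_rows: Mapping[str, Mapping[str, pd.Series]],
    moca_cutoff: int,
) -> list[SubjectScores]:
    classifiers = {
        p: (m.prep, m.clf, m.columns)
        for p, m in models.items()
        if m.clf is not None and m.columns
    }
    probs = platt_probabilities(classifiers, {p: feature_rows[p] for p in classifiers})
    scores = []
    for subj in subjects:
        sid = subj.subject_id
        p = probs.get(sid)
        if p is None:
            p = ClassProbabilities({})
        # trivial problems contribute flat 0.5 probabilities
        merged = dict(p.probs)
        for problem, m in models.items():
            pos, neg = PROBLEMS[problem]
            if (pos, problem) not in merged:
                merged[(pos, problem)] = 0.5
                merged[(neg, problem)] = 0.5
        s = class_scores(sid, ClassProbabilities(merged), weights)
        s.moca = subj.moca
        normalize_scores(s)
        diagnose(s, moca_cutoff=moca_cutoff)
        scores.append(s)
    return scores


def _feature_rows_for(
    fm: FeatureMatrix | None, columns: Sequence[str]
) -> dict[str, pd.Series]:
    if fm is None or not columns:
        return {}
    return {sid: fm.values.loc[sid, list(columns)] for sid in fm.values.index}


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(
    config: PipelineConfig,
    external_features: Mapping[str, FeatureMatrix] | None = None,
    fixed_features: Mapping[str, Sequence] | None = None,
) -> PipelineResult:
    """Execute the full analysis on a (synthetic) cohort.

    Stages: generate the cohort; build quality-controlled IH33 signals;
    per binary problem and per tilt, discover and select region features
    over resampled training sets; keep the informative tilts (averaged test
    accuracy above threshold, with a fall-back to the single best tilt);
    pool their features (plus any externally supplied feature columns) and
    re-select; train calibrated classifiers; fuse into MoCA-gated three-way
    diagnoses; evaluate.

    ``fixed_features`` (problem -> FeatureDefs) skips the discovery stages
    entirely and trains on the given definitions -- the reproduction mode
    for pre-published feature sets.
    """
    subjects, signals, _qc = _generate(config)
    labels = {s.subject_id: s.true_label for s in subjects}

    per_tilt: dict[str, dict[str, SelectionResult]] = {}
    informative: dict[str, list[str]] = {}
    models: dict[str, ProblemModel] = {}
    perfs: dict[str, BinaryPerf] = {}

    for problem, (positive, negative) in PROBLEMS.items():
        pair_labels = {
            sid: lab for sid, lab in labels.items() if lab in (positive, negative)
        }
        per_tilt[problem] = {}
        tilts_to_search = () if fixed_features is not None else config.tilts
        for tilt in tilts_to_search:
            tsets = make_training_sets(
                pair_labels,
                n_sets=config.n_sets,
                holdout=config.holdout,
                seed=derive_seed(config.seed, "sets", problem, tilt),
            )
            per_tilt[problem][tilt] = run_binary_selection(
                signals, pair_labels, positive, negative, tsets, tilt,
                max_size=config.max_size, max_candidates=config.max_candidates,
                folds=config.folds, svm=config.svm,
                seed=derive_seed(config.seed, "cv", problem, tilt),
            )
        if fixed_features is not None:
            informative[problem] = []
            pooled_feats = list(fixed_features.get(problem, ()))
        else:
            tilt_perf = {
                t: r.perf for t, r in per_tilt[problem].items() if r.perf is not None
            }
            chosen = informative_tilts(tilt_perf, config.informative_threshold_pct)
            if not chosen and tilt_perf:
                best = max(tilt_perf, key=lambda t: tilt_perf[t].accuracy)
                warnings.warn(
                    f"{problem}: no tilt reached "
                    f"{config.informative_threshold_pct}% accuracy; "
                    f"falling back to best tilt {best!r}",
                    stacklevel=2,
                )
                chosen = [best]
            informative[problem] = chosen

            pooled_feats = []
            seen = set()
            for tilt in chosen:
                for f in per_tilt[problem][tilt].final_features:
                    if feature_name(f) not in seen:
                        seen.add(feature_name(f))
                        pooled_feats.append(f)
        if not pooled_feats:
            warnings.warn(f"{problem}: no features survived selection; "
                          "using a trivial classifier", stacklevel=2)
            models[problem] = _trivial_model(problem)
            perfs[problem] = models[problem].perf
            continue

        all_ids = list(labels)
        fm_all = build_feature_matrix(
            signals, pooled_feats, labels, positive, negative, subject_ids=all_ids
        )
        if external_features and problem in external_features:
            fm_all = pool_features(fm_all, external_features[problem])
        tsets = make_training_sets(
            pair_labels, n_sets=config.n_sets, holdout=config.holdout,
            seed=derive_seed(config.seed, "pooled-sets", problem),
        )
        columns, perf = pooled_selection(
            fm_all, tsets, config.max_size, config.top_pool, config.folds,
            config.svm, derive_seed(config.seed, "pooled-cv", problem),
        )
        perf = replace(perf, problem=problem, tilt="pooled")
        labeled = fm_all.labels.isin([positive, negative])
        prep = ImputerScaler().fit(
            fm_all.values.loc[labeled, columns], fm_all.labels.loc[labeled]
        )
        clf = config.svm.make(
            probability=True, seed=derive_seed(config.seed, "platt", problem)
        )
        y = (fm_all.labels.loc[labeled] == positive).to_numpy()
        clf.fit(prep.transform_train(), y)
        models[problem] = ProblemModel(
            problem, [fm_all.feature_defs[c] for c in columns if c in fm_all.feature_defs],
            perf, prep, clf, list(columns), fm_all,
        )
        perfs[problem] = perf

    weights = ClassWeights.from_perfs(perfs)
    feature_rows = {
        p: _feature_rows_for(m.fm, m.columns) for p, m in models.items()
    }
    scores = _score_subjects(subjects, models, weights, feature_rows,
                             config.moca_cutoff)
    train_metrics = three_way_metrics(
        [labels[s.subject_id] for s in subjects], [s.diagnosis for s in scores]
    )

    result = PipelineResult(
        config=config, per_tilt=per_tilt, informative=informative, models=models,
        weights=weights, scores=scores, train_metrics=train_metrics,
    )

    if config.blind is not None:
        result.blind_scores, result.blind_metrics, result.blind_perfs = (
            _evaluate_blind(config, models, weights)
        )

    result.manifest = _manifest(config, result)
    return result


def _evaluate_blind(
    config: PipelineConfig,
    models: Mapping[str, ProblemModel],
    weights: ClassWeights,
):
    blind_cfg = replace(config.blind, seed=derive_seed(config.seed, "blind"))
    blind_pipe_cfg = replace(config, cohort=blind_cfg, blind=None)
    subjects, signals, _ = _generate(blind_pipe_cfg)
    labels = {s.subject_id: s.true_label for s in subjects}
    all_ids = list(labels)

    feature_rows: dict[str, dict[str, pd.Series]] = {}
    blind_perfs: dict[str, BinaryPerf] = {}
    for problem, m in models.items():
        pos, neg = PROBLEMS[problem]
        if not m.features:
            feature_rows[problem] = {}
            continue
        fm = build_feature_matrix(
            signals, m.features, labels, pos, neg, subject_ids=all_ids
        )
        feature_rows[problem] = _feature_rows_for(fm, m.columns)
        labeled = fm.labels.isin([pos, neg])
        fm_lab = FeatureMatrix(
            fm.values.loc[labeled], fm.labels.loc[labeled], pos, neg, fm.feature_defs
        )
        try:
            blind_perfs[problem] = evaluate_cv(
                fm_lab.subset(m.columns), folds=config.blind_folds,
                svm=config.svm, seed=derive_seed(config.seed, "blind-cv", problem),
                tilt="blind",
            )
        except ValueError:
            pass

    blind_scores = _score_subjects(subjects, models, weights, feature_rows,
                                   config.moca_cutoff)
    blind_metrics = three_way_metrics(
        [labels[s.subject_id] for s in subjects],
        [s.diagnosis for s in blind_scores],
    )
    return blind_scores, blind_metrics, blind_perfs


def _manifest(config: PipelineConfig, result: PipelineResult) -> dict:
    cfg = asdict(config)
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    numeric = {
        "balanced_accuracy": result.train_metrics.balanced_accuracy,
        "diagnoses": [s.diagnosis for s in result.scores],
        "perf": {
            p: [m.perf.sensitivity, m.perf.specificity, m.perf.accuracy]
            for p, m in result.models.items()
        },
    }
    return {
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "thresholds": {
            "informative_pct": config.informative_threshold_pct,
            "moca_cutoff": config.moca_cutoff,
            "alpha": 0.05,
            "holdout": config.holdout,
        },
        "output_hash": hashlib.sha256(
            json.dumps(numeric, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "numeric": numeric,
    }


def config_from_dict(d: Mapping) -> PipelineConfig:
    """Build a PipelineConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    kwargs: dict = {}
    if "cohort" in d:
        cohort = dict(d.pop("cohort"))
        for key in ("moca_params", "age_params"):
            if key in cohort:
                cohort[key] = {
                    k: tuple(v) for k, v in dict(cohort[key]).items()
                }
        if cohort.get("shift_segments") is not None:
            cohort["shift_segments"] = tuple(
                tuple(x) for x in cohort["shift_segments"]
            )
        kwargs["cohort"] = CohortConfig(**cohort)
    if "blind" in d and d["blind"] is not None:
        blind = dict(d.pop("blind"))
        kwargs["blind"] = CohortConfig(**blind)
    elif "blind" in d:
        d.pop("blind")
    if "svm" in d:
        kwargs["svm"] = SVMConfig(**dict(d.pop("svm")))
    if "tilts" in d:
        kwargs["tilts"] = tuple(d.pop("tilts"))
    kwargs.update(d)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# report writing


def write_reports(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for problem, tilts in result.per_tilt.items():
        for tilt, sel in tilts.items():
            if sel.perf is None:
                continue
            rows.append(
                {
                    "problem": problem,
                    "tilt": tilt,
                    "sens_pct": 100 * sel.perf.sensitivity,
                    "spec_pct": 100 * sel.perf.specificity,
                    "acc_pct": 100 * sel.perf.accuracy,
                    "auc": sel.perf.auc,
                    "informative": tilt in result.informative[problem],
                }
            )
    pd.DataFrame(rows).to_csv(out / "per_tilt_performance.csv", index=False)

    selection = {
        problem: {
            "final_features": [feature_name(f) for f in m.features],
            "perf": {
                "sens_pct": 100 * m.perf.sensitivity,
                "spec_pct": 100 * m.perf.specificity,
                "acc_pct": 100 * m.perf.accuracy,
                "auc": m.perf.auc,
            },
        }
        for problem, m in result.models.items()
    }
    (out / "selection_report.json").write_text(json.dumps(selection, indent=2))

    score_rows = []
    for s in result.scores:
        row = {"subject_id": s.subject_id, "moca": s.moca,
               "gate_applied": s.gate_applied, "diagnosis": s.diagnosis}
        row.update({f"raw_{c}": s.raw[c] for c in CLASSES})
        row.update({f"norm_{c}": s.normalized[c] for c in CLASSES})
        score_rows.append(row)
    pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)

    result.train_metrics.confusion.to_csv(out / "confusion_train.csv")
    evaluation = {
        "train": {
            "balanced_accuracy_pct": 100 * result.train_metrics.balanced_accuracy,
            "sens_vs_rest_pct": {c: 100 * v for c, v in result.train_metrics.sensitivity.items()},
            "spec_vs_rest_pct": {c: 100 * v for c, v in result.train_metrics.specificity.items()},
        }
    }
    if result.blind_metrics is not None:
        result.blind_metrics.confusion.to_csv(out / "confusion_blind.csv")
        evaluation["blind"] = {
            "balanced_accuracy_pct": 100 * result.blind_metrics.balanced_accuracy,
            "sens_vs_rest_pct": {c: 100 * v for c, v in result.blind_metrics.sensitivity.items()},
            "spec_vs_rest_pct": {c: 100 * v for c, v in result.blind_metrics.specificity.items()},
        }
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
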