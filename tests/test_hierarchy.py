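"""Weighted score fusion, MoCA gate, and three-way evaluation."""

import numpy as np
import pandas as pd
import pytest

from evestgdx.classify import PROBLEMS, BinaryPerf
from evestgdx.hierarchy import (
    CLASSES,
    ClassProbabilities,
    ClassWeights,
    SubjectScores,
    class_scores,
    diagnose,
    metrics_from_confusion,
    normalize_scores,
    platt_probabilities,
    three_way_metrics,
)

TRAIN_CONF = pd.DataFrame(
    [[15, 2, 2], [1, 11, 3], [0, 0, 19]],
    index=["AD", "AD-CVD", "Control"], columns=["AD", "AD-CVD", "Control"],
)
BLIND_CONF = pd.DataFrame(
    [[10, 0, 0], [2, 8, 2], [0, 1, 4]],
    index=["AD", "AD-CVD", "Control"], columns=["AD", "AD-CVD", "Control"],
)


def _probs(pc_cad=0.5, pad_adcvd=0.5, padcvd_c=0.5):
    """Build a full six-probability set from the three positive-class probs."""
    return ClassProbabilities({
        ("Control", "Control-vs-AD"): pc_cad,
        ("AD", "Control-vs-AD"): 1 - pc_cad,
        ("AD", "AD-vs-AD-CVD"): pad_adcvd,
        ("AD-CVD", "AD-vs-AD-CVD"): 1 - pad_adcvd,
        ("AD-CVD", "AD-CVD-vs-Control"): padcvd_c,
        ("Control", "AD-CVD-vs-Control"): 1 - padcvd_c,
    })


def _weights(default=1.0, **overrides):
    w = {}
    for problem, (pos, neg) in PROBLEMS.items():
        w[(pos, problem)] = overrides.get(f"{pos}|{problem}", default)
        w[(neg, problem)] = overrides.get(f"{neg}|{problem}", default)
    return ClassWeights(w)


class TestClassScores:
    def test_certain_control_scores_one(self):
        s = class_scores("x", _probs(pc_cad=1.0, padcvd_c=0.0), _weights(1.0))
        assert s.raw["Control"] == pytest.approx(1.0)

    def test_worked_weighted_average(self):
        # hand arithmetic: (0.8*0.867 + 0.6*0.903)/2 = 0.61770/... -> 0.6177/2*2
        p = _probs(pc_cad=0.8, padcvd_c=0.4)  # P_Control in AD-CVD-vs-C = 0.6
        w = _weights(1.0, **{"Control|Control-vs-AD": 0.867,
                             "Control|AD-CVD-vs-Control": 0.903})
        s = class_scores("x", p, w)
        assert s.raw["Control"] == pytest.approx((0.8 * 0.867 + 0.6 * 0.903) / 2)
        assert s.raw["Control"] == pytest.approx(0.6177, abs=1e-4)

    def test_uniform_probabilities_equal_scores(self):
        s = class_scores("x", _probs(), _weights(0.8))
        assert len(set(round(v, 12) for v in s.raw.values())) == 1

    def test_missing_problem_falls_back_to_single_term(self):
        probs = dict(_probs(pc_cad=0.9).probs)
        for k in list(probs):
            if k[1] == "AD-CVD-vs-Control":
                del probs[k]
        s = class_scores("x", ClassProbabilities(probs), _weights(1.0))
        assert s.raw["Control"] == pytest.approx(0.9)

    def test_missing_weight_errors(self):
        with pytest.raises(KeyError, match="missing weight"):
            class_scores("x", _probs(), ClassWeights({}))


class TestNormalizeAndDiagnose:
    def test_normalization(self):
        s = SubjectScores("x", {"AD": 0.21, "AD-CVD": 0.33, "Control": 0.6177})
        normalize_scores(s)
        total = 0.21 + 0.33 + 0.6177
        assert s.normalized["Control"] == pytest.approx(0.6177 / total)
        assert sum(s.normalized.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_scores_uniform_with_warning(self):
        s = SubjectScores("x", {c: 0.0 for c in CLASSES})
        with pytest.warns(UserWarning, match="all-zero"):
            normalize_scores(s)
        assert s.normalized["AD"] == pytest.approx(1 / 3)

    def test_gate_excludes_control_when_impaired(self):
        s = SubjectScores("x", {"Control": 0.5, "AD": 0.2, "AD-CVD": 0.3}, moca=20)
        s.normalized = dict(s.raw)
        diagnose(s)
        assert s.diagnosis == "AD-CVD" and s.gate_applied

    def test_ungated_argmax(self):
        s = SubjectScores("x", {"Control": 0.5, "AD": 0.2, "AD-CVD": 0.3}, moca=28)
        s.normalized = dict(s.raw)
        diagnose(s)
        assert s.diagnosis == "Control" and not s.gate_applied

    def test_moca_exactly_23_is_gated(self):
        s = SubjectScores("x", {"Control": 0.9, "AD": 0.06, "AD-CVD": 0.04}, moca=23)
        s.normalized = dict(s.raw)
        diagnose(s)
        assert s.gate_applied and s.diagnosis == "AD"

    def test_tie_break_priority(self):
        s = SubjectScores("x", {c: 1 / 3 for c in CLASSES}, moca=28)
        s.normalized = dict(s.raw)
        assert diagnose(s).diagnosis == "AD"

    def test_diagnosis_invariant_under_rescaling(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = {c: float(rng.random()) for c in CLASSES}
            moca = int(rng.integers(0, 31))
            a = diagnose(normalize_scores(SubjectScores("x", dict(raw), moca=moca)))
            scaled = {c: 7.3 * v for c, v in raw.items()}
            b = diagnose(normalize_scores(SubjectScores("x", scaled, moca=moca)))
            assert a.diagnosis == b.diagnosis


def _oracle_diagnose(p_pos, weights, moca, cutoff=23):
    """Independent literal transcription of the score equations and gate."""
    P = {
        ("Control", "Control-vs-AD"): p_pos["Control-vs-AD"],
        ("AD", "Control-vs-AD"): 1 - p_pos["Control-vs-AD"],
        ("AD", "AD-vs-AD-CVD"): p_pos["AD-vs-AD-CVD"],
        ("AD-CVD", "AD-vs-AD-CVD"): 1 - p_pos["AD-vs-AD-CVD"],
        ("AD-CVD", "AD-CVD-vs-Control"): p_pos["AD-CVD-vs-Control"],
        ("Control", "AD-CVD-vs-Control"): 1 - p_pos["AD-CVD-vs-Control"],
    }
    score = {
        "Control": (P[("Control", "Control-vs-AD")] * weights[("Control", "Control-vs-AD")]
                    + P[("Control", "AD-CVD-vs-Control")] * weights[("Control", "AD-CVD-vs-Control")]) / 2,
        "AD": (P[("AD", "Control-vs-AD")] * weights[("AD", "Control-vs-AD")]
               + P[("AD", "AD-vs-AD-CVD")] * weights[("AD", "AD-vs-AD-CVD")]) / 2,
        "AD-CVD": (P[("AD-CVD", "AD-vs-AD-CVD")] * weights[("AD-CVD", "AD-vs-AD-CVD")]
                   + P[("AD-CVD", "AD-CVD-vs-Control")] * weights[("AD-CVD", "AD-CVD-vs-Control")]) / 2,
    }
    total = sum(score.values())
    norm = {k: v / total for k, v in score.items()}
    if moca <= cutoff:
        return "AD" if norm["AD"] >= norm["AD-CVD"] else "AD-CVD"
    best = max(norm.values())
    for c in ("AD", "AD-CVD", "Control"):
        if norm[c] == best:
            return c


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_tuples(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p_pos = {prob: float(rng.random()) for prob in PROBLEMS}
            w = {(c, prob): float(rng.random())
                 for prob, pair in PROBLEMS.items() for c in pair}
            moca = int(rng.integers(0, 31))
            s = class_scores("x", _probs(*[p_pos[k] for k in
                                           ("Control-vs-AD", "AD-vs-AD-CVD",
                                            "AD-CVD-vs-Control")]),
                             ClassWeights(w))
            s.moca = moca
            diagnose(normalize_scores(s))
            assert s.diagnosis == _oracle_diagnose(p_pos, w, moca)

    def test_gate_never_outputs_control(self):
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            raw = {c: float(rng.random()) for c in CLASSES}
            moca = int(rng.integers(0, 24))  # <= 23
            s = diagnose(normalize_scores(SubjectScores("x", raw, moca=moca)))
            assert s.diagnosis != "Control"


class TestThreeWayMetrics:
    def test_train_matrix_reproduces_printed_metrics(self):
        m = metrics_from_confusion(TRAIN_CONF)
        assert 100 * m.sensitivity["AD"] == pytest.approx(93.8, abs=0.05)
        assert 100 * m.sensitivity["AD-CVD"] == pytest.approx(84.6, abs=0.05)
        assert 100 * m.sensitivity["Control"] == pytest.approx(79.2, abs=0.05)
        assert 100 * m.specificity["AD"] == pytest.approx(89.2, abs=0.05)
        assert 100 * m.specificity["AD-CVD"] == pytest.approx(90.0, abs=0.05)
        assert 100 * m.specificity["Control"] == pytest.approx(100.0, abs=0.05)

    def test_blind_matrix_balanced_accuracy(self):
        m = metrics_from_confusion(BLIND_CONF)
        assert m.balanced_accuracy == pytest.approx((10/12 + 8/9 + 4/6) / 3)
        assert 100 * m.balanced_accuracy == pytest.approx(79.6, abs=0.05)

    def test_perfect_diagonal(self):
        labels = ["AD"] * 3 + ["AD-CVD"] * 4 + ["Control"] * 5
        m = three_way_metrics(labels, labels)
        assert m.balanced_accuracy == 1.0
        assert all(v == 1.0 for v in m.specificity.values())

    def test_balanced_equals_plain_accuracy_for_equal_classes(self):
        rng = np.random.default_rng(9)
        labels = ["AD"] * 10 + ["AD-CVD"] * 10 + ["Control"] * 10
        preds = [str(rng.choice(CLASSES)) for _ in labels]
        m = three_way_metrics(labels, preds)
        plain = np.mean([t == p for t, p in zip(labels, preds)])
        assert m.balanced_accuracy == pytest.approx(plain)


class TestPlattProbabilities:
    def test_complements_and_monotonicity(self):
        from evestgdx.selection import ImputerScaler, SVMConfig

        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(-2, 1, 20), rng.normal(2, 1, 20)])
        X = pd.DataFrame({"f": x}, index=[f"s{i}" for i in range(40)])
        y = pd.Series(["Control"] * 20 + ["AD"] * 20, index=X.index)
        prep = ImputerScaler().fit(X, y)
        clf = SVMConfig().make(probability=True, seed=0)
        clf.fit(prep.transform_train(), (y == "Control").to_numpy())

        grid_ids = [f"g{i}" for i in range(9)]
        rows = {sid: pd.Series({"f": v})
                for sid, v in zip(grid_ids, np.linspace(-4, 4, 9))}
        probs = platt_probabilities(
            {"Control-vs-AD": (prep, clf, ["f"])}, {"Control-vs-AD": rows}
        )
        p_control = [probs[sid].get("Control", "Control-vs-AD") for sid in grid_ids]
        for sid in grid_ids:
            pc = probs[sid].get("Control", "Control-vs-AD")
            pa = probs[sid].get("AD", "Control-vs-AD")
            assert pc + pa == pytest.approx(1.0, abs=1e-9)
        # probability of Control decreases monotonically toward the AD side
        assert all(a >= b - 1e-9 for a, b in zip(p_control, p_control[1:]))
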