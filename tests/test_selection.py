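"""Exhaustive subset search, cross-validated evaluation, consensus, stability."""

import numpy as np
import pandas as pd
import pytest

from evestgdx.features import FeatureDef, make_training_sets
from evestgdx.ih33 import SignalKey
from evestgdx.selection import (
    FeatureMatrix,
    ImputerScaler,
    SVMConfig,
    consensus_and_common_regions,
    evaluate_cv,
    exhaustive_subset_search,
    feature_name,
    run_binary_selection,
    stability_check,
    PerSetResult,
)

KEY = SignalKey("supine up/down", "OnBB", "R")


def _fm(values: dict, labels: list, positive="A", negative="B"):
    n = len(labels)
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(n)], dtype=float)
    return FeatureMatrix(df, pd.Series(labels, index=df.index), positive, negative)


class _CountingSVM(SVMConfig):
    """SVMConfig that counts how many classifiers were fitted."""

    def __init__(self):
        super().__init__()
        object.__setattr__(self, "fits", [0])

    def make(self, probability=False, seed=0):
        self.fits[0] += 1
        return super().make(probability, seed)


class TestExhaustiveSearch:
    def test_dominant_feature_chosen_as_singleton(self):
        rng = np.random.default_rng(0)
        labels = ["A"] * 10 + ["B"] * 10
        sep = [0.0] * 10 + [5.0] * 10
        fm = _fm(
            {"good": sep, "noise1": rng.normal(size=20), "noise2": rng.normal(size=20)},
            labels,
        )
        assert exhaustive_subset_search(fm, max_size=1) == ["good"]

    def test_tie_broken_by_fewer_missing_values(self):
        labels = ["A"] * 6 + ["B"] * 6
        perfect = [0.0] * 6 + [5.0] * 6
        with_missing = list(perfect)
        with_missing[0] = np.nan
        fm = _fm({"m": with_missing, "clean": perfect}, labels)
        assert exhaustive_subset_search(fm, max_size=1) == ["clean"]

    def test_evaluates_all_41_subsets_of_six_candidates(self):
        rng = np.random.default_rng(1)
        labels = ["A"] * 8 + ["B"] * 8
        fm = _fm({f"f{i}": rng.normal(size=16) for i in range(6)}, labels)
        svm = _CountingSVM()
        exhaustive_subset_search(fm, max_size=3, svm=svm)
        # C(6,1) + C(6,2) + C(6,3) = 6 + 15 + 20 = 41, one fit per subset
        assert svm.fits[0] == 41

    def test_no_candidates_returns_empty(self):
        fm = _fm({}, ["A"] * 4 + ["B"] * 4)
        assert exhaustive_subset_search(fm) == []


class TestImputerScaler:
    def test_no_leakage_from_test_rows(self):
        rng = np.random.default_rng(2)
        X_train = pd.DataFrame({"f": rng.normal(0, 1, 20)})
        y = pd.Series(["A"] * 10 + ["B"] * 10, index=X_train.index)
        prep = ImputerScaler().fit(X_train, y)
        # statistics are exactly those of the training rows
        assert prep.mu1_["f"] == pytest.approx(X_train["f"].mean())
        # transforming extreme test data cannot change fitted statistics
        X_test = pd.DataFrame({"f": [1e6, np.nan]})
        out = prep.transform(X_test)
        assert prep.mu1_["f"] == pytest.approx(X_train["f"].mean())
        # the missing test cell got the pooled mean in standardized space
        expected = (prep.pooled_mean_["f"] - prep.mu2_["f"]) / prep.sd2_["f"]
        assert out[1, 0] == pytest.approx(expected)

    def test_imputation_is_class_conditional_on_training_rows(self):
        X = pd.DataFrame({"f": [0.0, 0.0, np.nan, 10.0, 10.0, np.nan]})
        y = pd.Series(["A", "A", "A", "B", "B", "B"], index=X.index)
        prep = ImputerScaler().fit(X, y)
        out = prep.transform_train()
        # imputed A-row equals the other A rows, same for B
        assert out[2, 0] == pytest.approx(out[0, 0])
        assert out[5, 0] == pytest.approx(out[3, 0])


class TestEvaluateCV:
    def test_perfectly_separated_feature(self):
        rng = np.random.default_rng(3)
        labels = ["A"] * 20 + ["B"] * 20
        fm = _fm({"f": list(rng.normal(-5, 1, 20)) + list(rng.normal(5, 1, 20))}, labels)
        perf = evaluate_cv(fm, folds=10, seed=0)
        assert perf.accuracy == pytest.approx(1.0)
        assert perf.auc == pytest.approx(1.0)
        assert perf.n_folds == 10

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(4)
        accs = []
        for seed in range(20):
            x = rng.normal(size=24)
            labels = list(rng.permutation(["A"] * 12 + ["B"] * 12))
            fm = _fm({"f": x}, labels)
            accs.append(evaluate_cv(fm, folds=4, seed=seed).accuracy)
        assert 0.35 < np.mean(accs) < 0.65

    def test_folds_reduced_with_warning(self):
        labels = ["A"] * 3 + ["B"] * 12
        fm = _fm({"f": np.arange(15.0)}, labels)
        with pytest.warns(UserWarning, match="reducing folds"):
            perf = evaluate_cv(fm, folds=10, seed=1)
        assert perf.n_folds == 3


class TestConsensus:
    def _per_set(self, defs_by_set):
        return [
            PerSetResult(i, [], list(defs), float("nan"), 20)
            for i, defs in enumerate(defs_by_set)
        ]

    def test_unanimous_region_is_common_region(self, planted_cohort):
        signals, labels, _ = planted_cohort
        pair = {s: l for s, l in labels.items() if l in ("Control", "AD")}
        f = FeatureDef(KEY, (13, 14), (18, 19), orientation="AD")
        res = consensus_and_common_regions(
            self._per_set([[f]] * 10), signals, pair, "Control", "AD",
            n_signals_per_set=20, seed=0,
        )
        assert res.consensus_features[0].region_low == (13, 14)
        assert res.consensus_features[0].region_high == (18, 19)
        assert res.frequencies[feature_name(res.consensus_features[0])] == 1.0

    def test_minority_bin_excluded_from_common_region(self, planted_cohort):
        signals, labels, _ = planted_cohort
        pair = {s: l for s, l in labels.items() if l in ("Control", "AD")}
        wide = FeatureDef(KEY, (12, 13, 14), (18, 19), orientation="AD")
        narrow = FeatureDef(KEY, (13, 14), (18, 19), orientation="AD")
        # bin 12 present in 4 of 10 instances (40%) -> excluded
        per_set = self._per_set([[wide]] * 4 + [[narrow]] * 6)
        res = consensus_and_common_regions(
            per_set, signals, pair, "Control", "AD", n_signals_per_set=20, seed=0
        )
        assert res.consensus_features[0].region_low == (13, 14)


class TestPlantedRecovery:
    def test_consensus_finds_planted_key_and_stability(self, planted_cohort):
        """With a strong planted shift in one signal, the planted key must
        dominate the consensus frequencies and the stability check must
        agree across repeats."""
        signals, labels, _ = planted_cohort
        pair = {s: l for s, l in labels.items() if l in ("Control", "AD")}

        def run(seed):
            tsets = make_training_sets(pair, n_sets=12, seed=seed)
            return run_binary_selection(
                signals, pair, "Control", "AD", tsets, "supine up/down",
                seed=seed,
            )

        res = run(0)
        top = max(res.frequencies, key=res.frequencies.get)
        assert "supine up/down|OnBB" in top
        assert any(str(f.key).startswith("supine up/down|OnBB")
                   for f in res.final_features)
        assert res.perf.accuracy >= 0.85

        report = stability_check(run, n_repeats=2, seeds=[0, 1])
        keys = set.intersection(*report.per_repeat_keys)
        assert any("supine up/down|OnBB" in k for k in keys)
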