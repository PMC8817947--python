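import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from earseg.classification import (
    FEATURE_PRESETS,
    ClassifierSpec,
    accuracy,
    learning_curve_table,
    predict,
    sbfs,
    standardize,
    train_classifier,
    tune_hyperparameters,
)


def toy_table(n=120, n_noise=1, seed=0, separation=3.0):
    """Two informative features separating the classes, plus pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["ear", "leaf"])[rng.integers(0, 2, n)]
    shift = np.where(y == "ear", separation, 0.0)
    data = {"f1": rng.normal(0, 1, n) + shift,
            "f2": rng.normal(0, 1, n) - shift}
    for i in range(n_noise):
        data[f"noise{i}"] = rng.normal(0, 1, n)
    data["class"] = y
    return pd.DataFrame(data)


class TestStandardize:
    def test_hand_arithmetic_population_sd(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "class": ["ear", "leaf", "ear"]})
        (scaled,), params = standardize(table, feature_columns=["x"])
        np.testing.assert_allclose(scaled["x"], [-1.22474487, 0.0, 1.22474487])

    def test_train_columns_zero_mean_unit_sd(self):
        table = toy_table(80)
        (scaled,), _ = standardize(table, feature_columns=["f1", "f2", "noise0"])
        assert abs(scaled[["f1", "f2", "noise0"]].mean()).max() < 1e-9
        np.testing.assert_allclose(scaled[["f1", "f2"]].std(ddof=0), 1.0, atol=1e-9)

    def test_constant_column_dropped(self):
        table = toy_table(50)
        table["const"] = 5.0
        (scaled,), params = standardize(
            table, feature_columns=["f1", "const"])
        assert "const" in params.dropped
        assert "const" not in scaled.columns

    def test_other_tables_use_train_parameters(self):
        train = toy_table(60, seed=1)
        test = toy_table(60, seed=2)
        test["f1"] += 10  # shifted distribution
        (tr, te), params = standardize(train, test, feature_columns=["f1", "f2"])
        expected = (test["f1"] - params.mean["f1"]) / params.std["f1"]
        np.testing.assert_allclose(te["f1"], expected)
        assert abs(te["f1"].mean()) > 1  # not re-centred on its own stats


class TestAccuracy:
    def test_arithmetic(self):
        assert accuracy(50, 40, 5, 5) == pytest.approx(0.90)

    def test_perfect_and_zero(self):
        assert accuracy(3, 4, 0, 0) == 1.0
        assert accuracy(0, 0, 2, 3) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(0, 0, 0, 0)


class TestTuning:
    def test_single_point_grid_returned(self):
        table = toy_table(60)
        spec, _ = tune_hyperparameters(
            "SVM", table, {"kernel": ["rbf"], "C": [10], "gamma": [0.1]},
            feature_columns=["f1", "f2"], seed=0)
        assert spec.param_dict == {"kernel": "rbf", "C": 10, "gamma": 0.1}

    def test_separable_data_reaches_perfect_cv(self):
        table = toy_table(100, separation=6.0)
        (scaled,), _ = standardize(table, feature_columns=["f1", "f2"])
        _, acc = tune_hyperparameters(
            "SVM", scaled, {"kernel": ["linear"], "C": [1, 100], "gamma": [0.1]},
            feature_columns=["f1", "f2"], seed=0)
        assert acc == 1.0

    def test_result_invariant_to_grid_ordering(self):
        table = toy_table(80)
        g1 = {"kernel": ["rbf", "linear"], "C": [0.1, 1, 10], "gamma": [0.01, 0.1]}
        g2 = {"C": [10, 0.1, 1], "gamma": [0.1, 0.01], "kernel": ["linear", "rbf"]}
        s1, a1 = tune_hyperparameters("SVM", table, g1,
                                      feature_columns=["f1", "f2"], seed=3)
        s2, a2 = tune_hyperparameters("SVM", table, g2,
                                      feature_columns=["f1", "f2"], seed=3)
        assert s1 == s2 and a1 == a2

    def test_deterministic_per_seed(self):
        table = toy_table(80)
        grid = {"kernel": ["rbf"], "C": [1, 10], "gamma": [0.01, 0.1]}
        r1 = tune_hyperparameters("SVM", table, grid, feature_columns=["f1", "f2"], seed=4)
        r2 = tune_hyperparameters("SVM", table, grid, feature_columns=["f1", "f2"], seed=4)
        assert r1 == r2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters("SVM", toy_table(30), {"C": []},
                                 feature_columns=["f1"])


def brute_force_first_removal(table, spec, cols, seed, cv_folds=5):
    """Independent exhaustive search over all (n-1)-subsets, same folds."""
    y = table["class"].to_numpy()
    folds = list(StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                 random_state=seed).split(np.zeros(len(y)), y))
    best_acc, best_removed = -1.0, None
    for removed in cols:  # first-wins tie break by column order
        subset = [c for c in cols if c != removed]
        X = table[subset].to_numpy(float)
        scores = []
        for tr, te in folds:
            m = spec.build(seed)
            m.fit(X[tr], y[tr])
            scores.append(np.mean(m.predict(X[te]) == y[te]))
        acc = float(np.mean(scores))
        if acc > best_acc:
            best_acc, best_removed = acc, removed
    return best_removed


class TestSBFS:
    SPEC = ClassifierSpec("SVM", (("kernel", "linear"), ("C", 1.0)))

    def test_first_removal_matches_bruteforce_oracle(self):
        for seed in (0, 1, 2):
            table = toy_table(90, n_noise=4, seed=seed)
            cols = ["f1", "f2", "noise0", "noise1", "noise2", "noise3"]
            trace = sbfs(table, self.SPEC, feature_columns=cols,
                         min_features=5, seed=seed)
            expected = brute_force_first_removal(table, self.SPEC, cols, seed)
            assert trace.removed[0] == expected

    def test_noise_feature_removed_before_informative(self):
        hits = 0
        for seed in range(10):
            table = toy_table(150, n_noise=1, seed=seed)
            trace = sbfs(table, self.SPEC,
                         feature_columns=["f1", "f2", "noise0"],
                         min_features=2, seed=seed)
            hits += trace.removed[0] == "noise0"
        assert hits >= 9

    def test_single_feature_trace_has_no_removals(self):
        table = toy_table(60)
        trace = sbfs(table, self.SPEC, feature_columns=["f1"], min_features=1)
        assert trace.removed == []
        assert trace.n_features == [1]
        assert len(trace.mean_accuracy) == 1

    def test_trace_lengths_consistent(self):
        table = toy_table(80, n_noise=2)
        trace = sbfs(table, self.SPEC,
                     feature_columns=["f1", "f2", "noise0", "noise1"],
                     min_features=1, seed=0)
        assert len(trace.mean_accuracy) == 4  # 4 -> 1 features: 4 entries
        assert trace.n_features == [4, 3, 2, 1]
        frame = trace.to_frame()
        assert list(frame["removed_feature"])[0] == ""

    def test_reproducible_per_seed(self):
        table = toy_table(80, n_noise=2)
        cols = ["f1", "f2", "noise0", "noise1"]
        t1 = sbfs(table, self.SPEC, feature_columns=cols, seed=7)
        t2 = sbfs(table, self.SPEC, feature_columns=cols, seed=7)
        assert t1.removed == t2.removed
        assert t1.mean_accuracy == t2.mean_accuracy


class TestTrainPredict:
    def test_memorizes_separable_data(self):
        table = toy_table(100, separation=6.0)
        (scaled,), _ = standardize(table, feature_columns=["f1", "f2"])
        model, cols = train_classifier(
            ClassifierSpec("SVM", (("kernel", "rbf"), ("C", 100.0), ("gamma", 0.1))),
            scaled, ["f1", "f2"])
        assert (predict(model, scaled, cols) == scaled["class"]).all()

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        table = toy_table(400, separation=3.0, seed=0)
        table["class"] = rng.permutation(table["class"].to_numpy())
        (scaled,), _ = standardize(table, feature_columns=["f1", "f2"])
        _, acc = tune_hyperparameters(
            "SVM", scaled, {"kernel": ["rbf"], "C": [1.0], "gamma": [0.1]},
            feature_columns=["f1", "f2"], seed=0)
        assert 0.4 <= acc <= 0.6

    def test_presets_are_subsets_of_the_feature_set(self):
        from earseg.features import FEATURE_COLUMNS

        assert {len(FEATURE_PRESETS[k]) for k in ("svm13", "mlp15", "rf8")} == {13, 15, 8}
        for cols in FEATURE_PRESETS.values():
            assert set(cols) <= set(FEATURE_COLUMNS)

    def test_learning_curve_converges_on_easy_data(self):
        table = toy_table(300, separation=6.0)
        (scaled,), _ = standardize(table, feature_columns=["f1", "f2"])
        curve = learning_curve_table(
            ClassifierSpec("SVM", (("kernel", "linear"), ("C", 1.0))),
            scaled, feature_columns=["f1", "f2"], sizes=(0.3, 1.0), seed=0)
        final = curve.iloc[-1]
        assert abs(final["train_acc"] - final["cv_acc"]) < 0.05
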