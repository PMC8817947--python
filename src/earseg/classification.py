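"""Superpixel classification: scaling, tuning, backward feature selection.

Three shallow classifier families (SVM, MLP, random forest) are trained
on standardized 29-feature superpixel tables. Hyperparameters are tuned
by exhaustive grid search under stratified seeded 5-fold
cross-validation; sequential backward feature selection (SBFS) then
prunes the feature set by repeatedly dropping the feature whose removal
leaves the best-scoring subset. The production default is the tuned
SVM: RBF kernel, C=100, gamma=0.1.
"""

from __future__ import annotations

import itertools
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from earseg.features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

CLASS_COLUMN = "class"

#: Feature subsets found by backward selection in the original study,
#: shipped as named presets selectable at train time.
FEATURE_PRESETS: dict[str, list[str]] = {
    "svm13": ["ct", "das", "hue", "saturation", "value", "g", "b",
              "m680", "SR", "NDVI", "NDRE", "VARI", "mNDblue"],
    "mlp15": ["ct", "das", "hue", "saturation", "value", "g", "b",
              "m900", "GNDVI", "RDVI", "OSAVI", "NDRE", "TCARI", "CIRE", "mNDblue"],
    "rf8": ["ct", "das", "hue", "saturation", "value", "b", "NDVI", "mNDblue"],
}

#: Default tuning grids spanning the reported optima.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"kernel": ["rbf", "linear"], "C": [0.1, 1, 10, 100, 1000],
            "gamma": [0.001, 0.01, 0.1, 1]},
    "MLP": {"hidden_layer_sizes": [(10,), (50,), (100,)],
            "activation": ["relu", "tanh"], "alpha": [1e-4, 1e-3, 1e-2]},
    "RF": {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20],
           "min_samples_leaf": [1, 5], "min_samples_split": [2, 10]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its tunable hyperparameters."""

    kind: str  # "SVM" | "MLP" | "RF"
    params: tuple[tuple[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("SVM", "MLP", "RF"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        allowed = set(DEFAULT_GRIDS[self.kind])
        extra = {k for k, _ in self.params} - allowed
        if extra:
            raise ValueError(f"hyperparameters {sorted(extra)} not tunable for {self.kind}")

    @property
    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)

    def complexity(self) -> tuple:
        """Sort key preferring simpler models on accuracy ties."""
        p = self.param_dict
        if self.kind == "SVM":
            return (p.get("C", 1.0), p.get("gamma", 0.0),
                    0 if p.get("kernel") == "linear" else 1)
        if self.kind == "MLP":
            return (sum(p.get("hidden_layer_sizes", (100,))), p.get("alpha", 0.0))
        return (p.get("n_estimators", 100),
                np.inf if p.get("max_depth") is None else p["max_depth"])

    def build(self, seed: int = 0):
        p = self.param_dict
        if self.kind == "SVM":
            return SVC(kernel=p.get("kernel", "rbf"), C=p.get("C", 100.0),
                       gamma=p.get("gamma", 0.1))
        if self.kind == "MLP":
            return MLPClassifier(
                hidden_layer_sizes=p.get("hidden_layer_sizes", (50,)),
                activation=p.get("activation", "relu"),
                alpha=p.get("alpha", 1e-4),
                max_iter=800, random_state=seed,
            )
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 300),
            max_depth=p.get("max_depth", None),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            min_samples_split=p.get("min_samples_split", 2),
            random_state=seed,
        )


#: Tuned production classifier: RBF SVM with C=100, gamma=0.1.
DEFAULT_SPEC = ClassifierSpec("SVM", (("kernel", "rbf"), ("C", 100.0), ("gamma", 0.1)))


@dataclass
class ScalerParams:
    """Per-feature mean and population standard deviation from training rows."""

    mean: pd.Series
    std: pd.Series
    dropped: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.mean.index)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[self.columns] = (table[self.columns] - self.mean) / self.std
        return out.drop(columns=[c for c in self.dropped if c in out.columns])


def standardize(
    train: pd.DataFrame,
    *apply_to: pd.DataFrame,
    feature_columns: Sequence[str] | None = None,
) -> tuple[list[pd.DataFrame], ScalerParams]:
    """Center and scale by training mean / population sd; reuse on other tables.

    Zero-variance features are dropped from all outputs with a warning.
    Returns ([scaled_train, *scaled_others], params).
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    cols = list(feature_columns) if feature_columns is not None else [
        c for c in FEATURE_COLUMNS if c in train.columns
    ]
    mean = train[cols].mean()
    std = train[cols].std(ddof=0)
    dropped = [c for c in cols if std[c] == 0]
    if dropped:
        logger.warning("dropping zero-variance features: %s", dropped)
    kept = [c for c in cols if c not in dropped]
    params = ScalerParams(mean=mean[kept], std=std[kept], dropped=dropped)
    scaled = [params.transform(t.drop(columns=dropped, errors="ignore"))
              for t in (train, *apply_to)]
    return scaled, params


def _xy(table: pd.DataFrame, feature_columns: Sequence[str]):
    return table[list(feature_columns)].to_numpy(float), table[CLASS_COLUMN].to_numpy()


def _cv_accuracy(spec, X, y, folds, seed) -> tuple[float, float]:
    scores = []
    for tr, te in folds:
        model = spec.build(seed)
        model.fit(X[tr], y[tr])
        scores.append(float(np.mean(model.predict(X[te]) == y[te])))
    return float(np.mean(scores)), float(np.std(scores))


def _make_folds(y, cv_folds, seed):
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(tp+tn) / (tp+tn+fp+fn)."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion table is empty")
    return (tp + tn) / total


def tune_hyperparameters(
    kind: str,
    train: pd.DataFrame,
    grid: Mapping[str, Sequence] | None = None,
    feature_columns: Sequence[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[ClassifierSpec, float]:
    """Exhaustive grid search by mean stratified-CV accuracy.

    Ties go to the simpler model (smaller C / fewer hidden units /
    fewer trees), making the result invariant to grid ordering.
    """
    grid = dict(grid) if grid is not None else DEFAULT_GRIDS[kind]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in train.columns]
    X, y = _xy(train, cols)
    folds = _make_folds(y, cv_folds, seed)
    keys = sorted(grid)
    candidates = [
        ClassifierSpec(kind, tuple(zip(keys, combo)))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]
    # deterministic complexity order => first max is the simplest best
    candidates.sort(key=lambda s: s.complexity())
    best_spec, best_acc = None, -1.0
    for spec in candidates:
        acc, _ = _cv_accuracy(spec, X, y, folds, seed)
        if acc > best_acc:
            best_spec, best_acc = spec, acc
    return best_spec, best_acc


@dataclass
class SelectionTrace:
    """SBFS history: removal order plus the CV accuracy at each width."""

    removed: list[str]                      # in removal order
    n_features: list[int]                   # remaining-count per entry
    mean_accuracy: list[float]
    sd_accuracy: list[float]
    feature_sets: list[list[str]]           # surviving features per entry

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": range(len(self.n_features)),
            "n_features": self.n_features,
            "removed_feature": [""] + self.removed,
            "mean_acc": self.mean_accuracy,
            "sd_acc": self.sd_accuracy,
        })

    def best_subset(self) -> list[str]:
        return self.feature_sets[int(np.argmax(self.mean_accuracy))]


def sbfs(
    train: pd.DataFrame,
    spec: ClassifierSpec,
    feature_columns: Sequence[str] | None = None,
    min_features: int = 1,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionTrace:
    """Sequential backward feature selection.

    At each step every subset of size n-1 is scored by mean CV accuracy
    on fixed stratified folds; the feature absent from the best subset
    is removed. Ties break by feature column order (first candidate
    wins). The trace starts with the full set, so it holds
    ``n_initial - min_features + 1`` accuracy entries.
    """
    cols = list(feature_columns) if feature_columns is not None else [
        c for c in FEATURE_COLUMNS if c in train.columns
    ]
    if len(cols) == 0:
        raise ValueError("no feature columns")
    y = train[CLASS_COLUMN].to_numpy()
    folds = _make_folds(y, cv_folds, seed)

    def score(subset: list[str]) -> tuple[float, float]:
        X = train[subset].to_numpy(float)
        return _cv_accuracy(spec, X, y, folds, seed)

    current = list(cols)
    m, s = score(current)
    trace = SelectionTrace(removed=[], n_features=[len(current)],
                           mean_accuracy=[m], sd_accuracy=[s],
                           feature_sets=[list(current)])
    while len(current) > min_features:
        best = None  # (acc, candidate_index, removed_name, subset, sd)
        for i, feat in enumerate(current):
            subset = [f for f in current if f != feat]
            m, s = score(subset)
            if best is None or m > best[0]:
                best = (m, i, feat, subset, s)
        m, _, feat, subset, s = best
        current = subset
        trace.removed.append(feat)
        trace.n_features.append(len(current))
        trace.mean_accuracy.append(m)
        trace.sd_accuracy.append(s)
        trace.feature_sets.append(list(current))
        logger.debug("SBFS removed %s -> %d features, acc %.4f", feat, len(current), m)
    return trace


def train_classifier(
    spec: ClassifierSpec,
    train: pd.DataFrame,
    feature_columns: Sequence[str] | None = None,
    seed: int = 0,
):
    """Fit a model on scaled features; returns (model, feature_columns)."""
    cols = list(feature_columns) if feature_columns is not None else [
        c for c in FEATURE_COLUMNS if c in train.columns
    ]
    X, y = _xy(train, cols)
    if np.abs(X.mean(axis=0)).max() > 10:
        logger.warning("feature means far from 0: input may not be standardized")
    model = spec.build(seed)
    model.fit(X, y)
    return model, cols


def predict(model, table: pd.DataFrame, feature_columns: Sequence[str]) -> np.ndarray:
    """Class per row ('ear' / 'leaf')."""
    return model.predict(table[list(feature_columns)].to_numpy(float))


def learning_curve_table(
    spec: ClassifierSpec,
    train: pd.DataFrame,
    feature_columns: Sequence[str] | None = None,
    sizes: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Training vs cross-validation accuracy per training-set size.

    Used for the overfitting audit: converging curves indicate neither
    under- nor overfitting.
    """
    cols = list(feature_columns) if feature_columns is not None else [
        c for c in FEATURE_COLUMNS if c in train.columns
    ]
    X, y = _xy(train, cols)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    rows = []
    for frac in sizes:
        n = max(cv_folds * 2, int(round(frac * len(y))))
        idx = order[: min(n, len(y))]
        Xs, ys = X[idx], y[idx]
        folds = _make_folds(ys, cv_folds, seed)
        cv_acc, cv_sd = _cv_accuracy(spec, Xs, ys, folds, seed)
        model = spec.build(seed)
        model.fit(Xs, ys)
        train_acc = float(np.mean(model.predict(Xs) == ys))
        rows.append({"n_train": len(idx), "train_acc": train_acc,
                     "cv_acc": cv_acc, "cv_sd": cv_sd})
    return pd.DataFrame(rows)


def save_model(path: str | Path, model, scaler: ScalerParams,
               feature_columns: Sequence[str], spec: ClassifierSpec) -> None:
    payload = {"version": 1, "model": model, "scaler": scaler,
               "feature_columns": list(feature_columns), "spec": spec}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != 1:
        raise ValueError("unsupported model file version")
    return payload
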