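"""Classifiers: the hybrid multi-class CNN -> binary SVM, and three baselines.

The hybrid detector first trains a compact convnet to separate genuine gait
(class 0) from the two auto-walker geometries (classes 1 and 2); the softmax
probability vectors it emits are then re-classified by a binary SVM into
genuine (1) vs. fraudulent (0).  The baselines (kNN, random forest, SVM)
consume the 174 hand-crafted features instead of raw windows.

Every model exposes a scalar decision value per window: the signed distance
to the separating boundary for SVM-family models, and the genuine-class
probability (neighbor fraction / tree-vote fraction) for kNN and RF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._cnn import TinyConvNet
from .features import FEATURE_NAMES, N_FEATURES

N_CLASSES = 3  # gait + two auto-walker geometries

#: hyperparameter grid of every binary SVM (head and baseline): 3 x 4 x 4 = 48
SVM_GRID = {
    "kernel": ["linear", "rbf", "poly"],
    "C": [0.1, 1, 10, 100],
    "gamma": [1, 0.1, 0.01, 0.001],
}

#: polynomial kernels are used in their inhomogeneous form (coef0 = 1):
#: on simplex-valued probability vectors the homogeneous cubic kernel takes
#: values of order gamma**3, leaving the fit dominated by its intercept, while
#: coef0 = 1 keeps the decision values centered on the class boundary
SVM_COEF0 = 1.0

#: tuned operating points for each model family
HYBRID_SVM_PRESET = {"kernel": "poly", "C": 1, "gamma": 0.1}
BASELINE_PRESETS = {
    "knn": {"n_neighbors": 3, "weights": "uniform"},
    "rf": {"n_estimators": 200, "max_features": "sqrt", "max_depth": 7,
           "criterion": "gini"},
    "svm": {"kernel": "poly", "C": 0.1, "gamma": 1},
}

KNN_GRID = {"n_neighbors": [3, 5, 7, 9, 11], "weights": ["uniform", "distance"]}


@dataclass
class CnnHyper:
    """Training protocol of the convnet feature extractor."""

    batch_size: int = 40
    steps_per_epoch: int = 10
    epochs: int = 10
    lr: float = 2e-3
    filters: tuple[int, int] = (32, 64)
    kernel: int = 5
    dense: int = 64
    seed: int = 0
    #: "window" = z-score each window per channel (amplitude/offset invariant,
    #: the default: the net then reads waveform shape, which is what transfers
    #: across phones and subjects); "train" = training-split statistics;
    #: None = raw
    standardize: str | None = "window"

    def __post_init__(self) -> None:
        if min(self.batch_size, self.steps_per_epoch, self.epochs) <= 0:
            raise ValueError("batch_size, steps_per_epoch and epochs must be positive")


class CnnClassifier:
    """A trained convnet plus the input standardization it was fit with."""

    def __init__(self, net: TinyConvNet, standardize: str | None,
                 channel_mean: np.ndarray, channel_sd: np.ndarray,
                 history: list[float]):
        self.net = net
        self.standardize = standardize
        self.channel_mean = channel_mean
        self.channel_sd = channel_sd
        self.history = history

    def _prepare(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=float)
        if x.ndim != 3 or x.shape[1:] != self.net.input_shape:
            raise ValueError(f"expected (n, {self.net.input_shape[0]}, "
                             f"{self.net.input_shape[1]}) windows, got {x.shape}")
        if self.standardize == "window":
            mean = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            return (x - mean) / (sd + 1e-8)
        return (x - self.channel_mean) / self.channel_sd

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._prepare(windows))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.predict_proba(windows).argmax(axis=1)


def train_cnn(windows: np.ndarray, labels: Sequence[int],
              hyper: CnnHyper | None = None) -> CnnClassifier:
    """Train the multi-class convnet on (n, 200, 6) windows.

    Labels must cover every class 0..2; inputs are standardized per channel
    with training-set statistics.  Deterministic under ``hyper.seed``.
    """
    hyper = hyper or CnnHyper()
    x = np.asarray(windows, dtype=float)
    y = np.asarray(labels, dtype=int)
    present = set(np.unique(y))
    missing = sorted(set(range(N_CLASSES)) - present)
    if missing:
        raise ValueError(f"training data lacks classes {missing}")
    mean = np.zeros(x.shape[2])
    sd = np.ones(x.shape[2])
    if hyper.standardize == "train":
        mean = x.mean(axis=(0, 1))
        sd = x.std(axis=(0, 1))
        sd[sd < 1e-12] = 1.0
    elif hyper.standardize not in (None, "window"):
        raise ValueError("standardize must be 'window', 'train' or None")
    net = TinyConvNet(input_shape=x.shape[1:], n_classes=N_CLASSES,
                      filters=hyper.filters, kernel=hyper.kernel,
                      dense=hyper.dense, seed=hyper.seed)
    model = CnnClassifier(net, hyper.standardize, mean, sd, [])
    history = net.fit(model._prepare(x), y, batch_size=hyper.batch_size,
                      steps_per_epoch=hyper.steps_per_epoch, epochs=hyper.epochs,
                      lr=hyper.lr, seed=hyper.seed)
    model.history.extend(history)
    return model


def cnn_probabilities(model: CnnClassifier, windows: np.ndarray) -> np.ndarray:
    """Softmax probability vectors, one row per window (rows sum to 1)."""
    return model.predict_proba(windows)


@dataclass
class HybridModel:
    """The convnet feature extractor with its binary SVM decision head."""

    cnn: CnnClassifier
    svm: SVC
    search_results: pd.DataFrame | None = None
    family: str = "hybrid"

    def decision_values(self, windows: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(self.cnn.predict_proba(windows))


def train_hybrid_head(prob_vectors: np.ndarray, binary_labels: Sequence[int],
                      mode: str = "preset", seed: int = 0) -> tuple[SVC, pd.DataFrame | None]:
    """Fit the binary SVM head on (n, 3) probability vectors.

    ``mode='search'`` runs the 48-point grid with 5-fold cross-validation;
    ``mode='preset'`` uses the tuned operating point (poly, C=1, gamma=0.1).
    Genuine gait is label 1, auto-walker 0; both must be present.
    """
    p = np.asarray(prob_vectors, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("binary labels must contain both classes {0, 1}")
    if mode == "preset":
        svm = SVC(coef0=SVM_COEF0, **HYBRID_SVM_PRESET)
        svm.fit(p, y)
        return svm, None
    if mode != "search":
        raise ValueError("mode must be 'preset' or 'search'")
    search = GridSearchCV(SVC(coef0=SVM_COEF0), SVM_GRID, cv=5, n_jobs=1)
    search.fit(p, y)
    return search.best_estimator_, pd.DataFrame(search.cv_results_)


def train_hybrid(windows: np.ndarray, multiclass_labels: Sequence[int],
                 hyper: CnnHyper | None = None, mode: str = "preset",
                 seed: int = 0) -> HybridModel:
    """End-to-end hybrid training: convnet, then the SVM head on its outputs."""
    hyper = hyper or CnnHyper(seed=seed)
    y_multi = np.asarray(multiclass_labels, dtype=int)
    cnn = train_cnn(windows, y_multi, hyper)
    probs = cnn.predict_proba(windows)
    y_bin = (y_multi == 0).astype(int)
    svm, results = train_hybrid_head(probs, y_bin, mode=mode, seed=seed)
    return HybridModel(cnn, svm, results)


@dataclass
class BaselineModel:
    """A feature-based binary classifier bound to the 174-name feature schema."""

    kind: str
    estimator: object
    schema: tuple[str, ...] = field(default=tuple(FEATURE_NAMES))
    search_results: pd.DataFrame | None = None

    @property
    def family(self) -> str:
        return self.kind

    def _validate(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            if tuple(features.columns) != self.schema:
                raise ValueError("feature schema mismatch: column names differ from "
                                 "the schema this model was trained on")
            return features.to_numpy(dtype=float)
        x = np.asarray(features, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self.schema):
            raise ValueError(f"expected (n, {len(self.schema)}) features, got {x.shape}")
        return x

    def decision_values(self, features) -> np.ndarray:
        x = self._validate(features)
        if self.kind == "svm":
            return self.estimator.decision_function(x)
        proba = self.estimator.predict_proba(x)
        genuine_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, genuine_col]


def _make_baseline_estimator(kind: str, params: dict, seed: int):
    if kind == "knn":
        return KNeighborsClassifier(**params)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "svm":
        # polynomial kernels are scale-sensitive, so the SVM standardizes features
        return Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(coef0=SVM_COEF0, **params))])
    raise ValueError(f"unknown baseline kind {kind!r}")


def train_baseline(features, binary_labels: Sequence[int], kind: str,
                   mode: str = "preset", seed: int = 0) -> BaselineModel:
    """Train one feature-based baseline (``knn``, ``rf`` or ``svm``).

    ``mode='preset'`` uses the tuned hyperparameters; ``mode='search'`` runs
    5-fold grid search (10 points for kNN, 48 for the SVM; the RF preset has
    no spec-defined grid and is searched over tree depth only).
    """
    if kind not in BASELINE_PRESETS:
        raise ValueError(f"unknown baseline kind {kind!r}")
    if isinstance(features, pd.DataFrame):
        schema = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        schema = tuple(FEATURE_NAMES) if X.shape[1] == N_FEATURES else tuple(
            f"f{i}" for i in range(X.shape[1]))
    y = np.asarray(binary_labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("binary labels must contain both classes {0, 1}")

    results = None
    if mode == "preset":
        est = _make_baseline_estimator(kind, BASELINE_PRESETS[kind], seed)
        est.fit(X, y)
    elif mode == "search":
        if kind == "knn":
            search = GridSearchCV(KNeighborsClassifier(), KNN_GRID, cv=5, n_jobs=1)
        elif kind == "svm":
            grid = {f"svc__{k}": v for k, v in SVM_GRID.items()}
            search = GridSearchCV(_make_baseline_estimator("svm", {}, seed), grid,
                                  cv=5, n_jobs=1)
        else:
            search = GridSearchCV(RandomForestClassifier(random_state=seed,
                                                         n_estimators=200,
                                                         max_features="sqrt"),
                                  {"max_depth": [3, 5, 7, 9]}, cv=5, n_jobs=1)
        search.fit(X, y)
        est = search.best_estimator_
        results = pd.DataFrame(search.cv_results_)
    else:
        raise ValueError("mode must be 'preset' or 'search'")
    return BaselineModel(kind, est, schema, results)


DEFAULT_THRESHOLDS = {"hybrid": 0.0, "svm": 0.0, "knn": 0.5, "rf": 0.5}


def decision_values(model: HybridModel | BaselineModel, inputs) -> np.ndarray:
    """Scalar score per input; higher means more genuine-looking."""
    return model.decision_values(inputs)


def classify(model: HybridModel | BaselineModel, inputs,
             threshold: float | None = None) -> np.ndarray:
    """Binary call per input: 1 (genuine) iff decision value > threshold.

    Defaults to 0 for SVM-family scores and 0.5 for probability scores.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[model.family]
    return (decision_values(model, inputs) > threshold).astype(int)


def save_model(model: HybridModel | BaselineModel, directory) -> None:
    """Serialize a model bundle to a directory (JSON meta + arrays/estimators)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, HybridModel):
        meta = {"family": "hybrid", "input_shape": list(model.cnn.net.input_shape),
                "filters": list(model.cnn.net.filters), "kernel": model.cnn.net.kernel,
                "dense": model.cnn.net.dense, "seed": model.cnn.net.seed,
                "standardize": model.cnn.standardize, "history": model.cnn.history}
        np.savez(directory / "cnn_weights.npz", channel_mean=model.cnn.channel_mean,
                 channel_sd=model.cnn.channel_sd, **model.cnn.net.get_weights())
        joblib.dump(model.svm, directory / "svm_head.joblib")
    else:
        meta = {"family": model.kind, "schema": list(model.schema)}
        joblib.dump(model.estimator, directory / "estimator.joblib")
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> HybridModel | BaselineModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    if meta["family"] == "hybrid":
        with np.load(directory / "cnn_weights.npz") as data:
            arrays = {k: data[k] for k in data.files}
        net = TinyConvNet(input_shape=tuple(meta["input_shape"]), n_classes=N_CLASSES,
                          filters=tuple(meta["filters"]), kernel=meta["kernel"],
                          dense=meta["dense"], seed=meta["seed"])
        net.set_weights({k: arrays[k] for k in net.params})
        cnn = CnnClassifier(net, meta.get("standardize", "window"),
                            arrays["channel_mean"], arrays["channel_sd"],
                            list(meta.get("history", [])))
        svm = joblib.load(directory / "svm_head.joblib")
        return HybridModel(cnn, svm)
    est = joblib.load(directory / "estimator.joblib")
    return BaselineModel(meta["family"], est, tuple(meta["schema"]))
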