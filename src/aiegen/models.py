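"""The seven wavelength regressors behind one fit/predict contract.

Models: linear-kernel SVM, k-nearest neighbours (Euclidean, k <= 20),
random forest, gradient-boosted regression trees, XGBoost, a multilayer
perceptron (ReLU), and a 1-D CNN reading the raw fingerprint vector as
a one-channel signal.  One model is trained per target (absorption or
emission); a trained model remembers the descriptor layout it was
trained with and refuses feature matrices with a different layout.

Also here: the CART Gini-impurity and Euclidean-distance utilities.
Regression trees in this package split on squared error (variance
reduction); the Gini impurity is defined for class-probability vectors
and is exposed as a documented utility for any future classification
mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import LinearSVR
from xgboost import XGBRegressor

from .cnn import CNNRegressor
from .featurize import (
    DescriptorSpec,
    FeatureMatrix,
    QuantitativeScaler,
    featurize_dataset,
)

__all__ = [
    "MODEL_NAMES",
    "TARGETS",
    "ModelSpec",
    "TrainedModel",
    "NeuralLayer",
    "LayoutMismatchError",
    "gini_impurity",
    "euclidean_distance",
    "default_hyperparameters",
    "fit",
    "train_on_dataset",
    "stage_predictions",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("svm", "knn", "rf", "gbrt", "xgb", "mlp", "cnn")
TARGETS = ("absorption", "emission")

_SCHEMA_VERSION = 1


class LayoutMismatchError(ValueError):
    """Feature layout does not match the layout the model was trained with."""


# --------------------------------------------------------------------------
# utilities


def gini_impurity(p) -> float:
    """Gini impurity 1 - sum(p_i^2) of a class-probability vector."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-D probability vector")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p must be nonnegative and sum to 1")
    return float(1.0 - np.sum(p**2))


def euclidean_distance(x, y) -> float:
    """Euclidean distance sqrt(sum((x_i - y_i)^2)) between equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


@dataclass(frozen=True)
class NeuralLayer:
    """One fully-connected network layer: f(W x + b).

    ``weights`` has shape (units, inputs); the default activation is the
    rectified linear unit, whose output is always >= 0.  This is the
    building block the MLP and the CNN dense head realize.
    """

    weights: np.ndarray
    bias: np.ndarray
    activation: str = "relu"

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = self.weights @ x + self.bias
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "linear":
            return z
        raise ValueError(f"unknown activation {self.activation!r}")


# --------------------------------------------------------------------------
# specs and estimator construction

_DEFAULTS: dict[str, dict] = {
    "svm": {"C": 1.0, "max_iter": 5000, "tol": 1e-4},
    "knn": {"n_neighbors": 5},
    "rf": {"n_estimators": 300, "max_depth": None},
    "gbrt": {"n_estimators": 300, "max_depth": 3, "learning_rate": 0.1},
    "xgb": {
        "n_estimators": 300,
        "max_depth": 6,
        "learning_rate": 0.1,
        "reg_lambda": 1.0,
        "reg_alpha": 0.0,
    },
    "mlp": {
        "hidden_layer_sizes": (256, 64),
        "alpha": 1e-4,
        "learning_rate_init": 1e-3,
        "max_iter": 300,
    },
    "cnn": {
        "channels": (32, 64),
        "kernel_size": 7,
        "stride": 2,
        "dense_units": 128,
        "epochs": 60,
        "batch_size": 32,
        "lr": 1e-3,
    },
}


def default_hyperparameters(name: str) -> dict:
    """Default hyperparameters of one model (copy; safe to mutate)."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return dict(_DEFAULTS[name])


@dataclass(frozen=True)
class ModelSpec:
    """A model choice plus hyperparameter overrides and a seed."""

    name: Literal["svm", "knn", "rf", "gbrt", "xgb", "mlp", "cnn"]
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        unknown = set(self.hyperparameters) - set(_DEFAULTS[self.name])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.name}: {sorted(unknown)}")

    def resolved(self) -> dict:
        params = default_hyperparameters(self.name)
        params.update(self.hyperparameters)
        return params

    def to_dict(self) -> dict:
        return {"name": self.name, "hyperparameters": dict(self.hyperparameters), "seed": self.seed}


def _build_estimator(spec: ModelSpec):
    p = spec.resolved()
    if spec.name == "svm":
        return LinearSVR(C=p["C"], max_iter=p["max_iter"], tol=p["tol"], random_state=spec.seed)
    if spec.name == "knn":
        return KNeighborsRegressor(n_neighbors=p["n_neighbors"], metric="euclidean")
    if spec.name == "rf":
        return RandomForestRegressor(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.name == "gbrt":
        return GradientBoostingRegressor(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            random_state=spec.seed,
        )
    if spec.name == "xgb":
        return XGBRegressor(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            reg_lambda=p["reg_lambda"],
            reg_alpha=p["reg_alpha"],
            tree_method="hist",
            n_jobs=1,
            random_state=spec.seed,
            verbosity=0,
        )
    if spec.name == "mlp":
        return MLPRegressor(
            hidden_layer_sizes=tuple(p["hidden_layer_sizes"]),
            activation="relu",
            alpha=p["alpha"],
            learning_rate_init=p["learning_rate_init"],
            max_iter=p["max_iter"],
            random_state=spec.seed,
        )
    return CNNRegressor(
        channels=tuple(p["channels"]),
        kernel_size=p["kernel_size"],
        stride=p["stride"],
        dense_units=p["dense_units"],
        epochs=p["epochs"],
        batch_size=p["batch_size"],
        lr=p["lr"],
        random_state=spec.seed,
    )


# --------------------------------------------------------------------------
# trained model


@dataclass
class TrainedModel:
    """A fitted regressor for one target, bound to its feature layout."""

    spec: ModelSpec
    target: str
    estimator: object
    n_features: int
    layout_hash: str | None = None
    descriptor_spec: DescriptorSpec | None = None
    scaler: QuantitativeScaler | None = None
    training_bits: np.ndarray | None = None  # packed fingerprint rows of training molecules
    y_range: tuple[float, float] | None = None

    def predict(self, X) -> np.ndarray:
        """Predict wavelengths (nm) for a feature matrix.

        ``X`` may be an ndarray of matching width or a
        :class:`~aiegen.featurize.FeatureMatrix`, whose layout hash must
        equal the training layout.
        """
        if isinstance(X, FeatureMatrix):
            if self.layout_hash is not None and X.fingerprint != self.layout_hash:
                raise LayoutMismatchError(
                    f"feature layout {X.fingerprint} != training layout {self.layout_hash}"
                )
            X = X.X
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or (X.shape[0] and X.shape[1] != self.n_features):
            raise LayoutMismatchError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        out = np.asarray(self.estimator.predict(X), dtype=float).ravel()
        if not np.all(np.isfinite(out)):
            raise RuntimeError("model produced non-finite predictions")
        return out

    @property
    def bundle_hash(self) -> str:
        import hashlib

        payload = json.dumps(
            {"spec": self.spec.to_dict(), "target": self.target, "layout": self.layout_hash}
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, directory: str | Path) -> None:
        """Write a model bundle: manifest JSON plus fitted state."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schema_version": _SCHEMA_VERSION,
            "model_spec": self.spec.to_dict(),
            "target": self.target,
            "n_features": self.n_features,
            "layout_hash": self.layout_hash,
            "descriptor_spec": self.descriptor_spec.to_dict() if self.descriptor_spec else None,
            "y_range": list(self.y_range) if self.y_range else None,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(
            {"estimator": self.estimator, "scaler": self.scaler, "training_bits": self.training_bits},
            directory / "state.joblib",
        )


def load_model(directory: str | Path) -> TrainedModel:
    """Load a model bundle written by :meth:`TrainedModel.save`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["schema_version"] != _SCHEMA_VERSION:
        raise ValueError(f"unsupported bundle schema {manifest['schema_version']}")
    state = joblib.load(directory / "state.joblib")
    ms = manifest["model_spec"]
    return TrainedModel(
        spec=ModelSpec(name=ms["name"], hyperparameters=ms["hyperparameters"], seed=ms["seed"]),
        target=manifest["target"],
        estimator=state["estimator"],
        n_features=manifest["n_features"],
        layout_hash=manifest["layout_hash"],
        descriptor_spec=(
            DescriptorSpec.from_dict(manifest["descriptor_spec"])
            if manifest["descriptor_spec"]
            else None
        ),
        scaler=state["scaler"],
        training_bits=state["training_bits"],
        y_range=tuple(manifest["y_range"]) if manifest["y_range"] else None,
    )


# --------------------------------------------------------------------------
# fitting


def fit(
    spec: ModelSpec,
    X,
    y,
    target: str = "absorption",
    scaler: QuantitativeScaler | None = None,
) -> TrainedModel:
    """Fit one regressor on a feature matrix.

    Deterministic given (spec, X, y, spec.seed).  ``X`` may be a plain
    ndarray or a :class:`FeatureMatrix` (whose layout is then bound to
    the model).  A ``scaler`` fitted on the training rows is applied
    before fitting and stored for prediction.
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    layout_hash = None
    descriptor_spec = None
    if isinstance(X, FeatureMatrix):
        layout_hash = X.fingerprint
        descriptor_spec = X.spec
        X = X.X
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 training rows, got {n}")
    if spec.name == "knn" and n < spec.resolved()["n_neighbors"]:
        raise ValueError(f"knn needs at least k={spec.resolved()['n_neighbors']} rows, got {n}")
    if np.ptp(y) == 0:
        logger.warning("constant training target; model will predict a constant")
    if scaler is not None:
        X = scaler.transform(X)
    estimator = _build_estimator(spec)
    estimator.fit(X, y)
    return TrainedModel(
        spec=spec,
        target=target,
        estimator=estimator,
        n_features=X.shape[1],
        layout_hash=layout_hash,
        descriptor_spec=descriptor_spec,
        scaler=scaler,
        y_range=(float(y.min()), float(y.max())),
    )


def train_on_dataset(
    ds,
    model_spec: ModelSpec,
    descriptor_spec: DescriptorSpec,
    target: str,
    scale: bool = True,
) -> TrainedModel:
    """Featurize a dataset and fit a final model on all of it.

    The returned model carries the descriptor spec (so screening can
    featurize candidates identically), the quantitative-block scaler and
    the packed training fingerprints used for the low-overlap warning.
    """
    sub = ds.with_target(target)
    fm = featurize_dataset(sub, descriptor_spec)
    y = sub.targets(target)
    scaler = QuantitativeScaler.fit(fm) if scale and fm.quantitative_columns().size else None
    model = fit(model_spec, fm, y, target=target, scaler=scaler)
    fp_cols = _fingerprint_columns(fm)
    if fp_cols.size:
        unique_rows = np.unique(fm.X[:, fp_cols].astype(np.uint8), axis=0)
        model.training_bits = np.packbits(unique_rows, axis=1)
    return model


def _fingerprint_columns(fm: FeatureMatrix) -> np.ndarray:
    cols: list[int] = []
    for b in fm.layout:
        if not b.name.endswith((":quantitative", ":one_hot")):
            cols.extend(range(b.offset, b.offset + b.length))
    return np.asarray(cols, dtype=int)


def stage_predictions(model: TrainedModel, X, n_stages: int) -> np.ndarray:
    """Prediction of a boosted ensemble truncated to its first n stages.

    Supports gbrt and xgb; lets callers verify that boosting is additive
    (full prediction = truncated prediction + remaining stage outputs).
    """
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=np.float32)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    est = model.estimator
    if model.spec.name == "gbrt":
        if n_stages == 0:
            # the initial constant model of the forward-stagewise expansion
            return np.full(X.shape[0], est.init_.constant_.ravel()[0], dtype=float)
        for i, pred in enumerate(est.staged_predict(X), start=1):
            if i == n_stages:
                return np.asarray(pred, dtype=float)
        raise ValueError(f"model has fewer than {n_stages} stages")
    if model.spec.name == "xgb":
        if n_stages == 0:
            cfg = json.loads(est.get_booster().save_config())
            base = float(cfg["learner"]["learner_model_param"]["base_score"])
            return np.full(X.shape[0], base, dtype=float)
        return np.asarray(
            est.predict(X, iteration_range=(0, n_stages)), dtype=float
        )
    raise ValueError(f"{model.spec.name} is not a staged boosted model")
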