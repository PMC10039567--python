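"""Sequential model-based (Bayesian) hyperparameter search.

The objective is the mean k-fold cross-validation MAE of a model on a
fixed feature matrix.  A Gaussian-process surrogate (Matern 5/2 plus
white noise) is fitted to the trials observed so far in a unit-cube
encoding of the search space; the next trial maximizes expected
improvement over a random candidate set.  The first 20% of the budget
is spent on random initialization.  Everything is driven by one seed,
so a search is exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel

__all__ = ["ParamSpec", "HyperparameterSpace", "DEFAULT_SPACES", "tune", "TuneResult"]


@dataclass(frozen=True)
class ParamSpec:
    """One searched hyperparameter: an int/float range (optionally on a
    log scale) or a finite choice set."""

    kind: str  # int | float | logfloat | choice
    low: float | None = None
    high: float | None = None
    choices: tuple | None = None

    def __post_init__(self):
        if self.kind in {"int", "float", "logfloat"}:
            if self.low is None or self.high is None or not (
                math.isfinite(self.low) and math.isfinite(self.high)
            ):
                raise ValueError(f"{self.kind} parameter needs finite bounds")
            if self.kind == "logfloat" and self.low <= 0:
                raise ValueError("logfloat bounds must be positive")
        elif self.kind == "choice":
            if not self.choices:
                raise ValueError("choice parameter needs choices")
        else:
            raise ValueError(f"unknown parameter kind {self.kind!r}")

    def decode(self, u: float):
        """Map a unit-interval coordinate to a parameter value."""
        u = min(max(u, 0.0), 1.0)
        if self.kind == "choice":
            return self.choices[min(int(u * len(self.choices)), len(self.choices) - 1)]
        if self.kind == "logfloat":
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        value = self.low + u * (self.high - self.low)
        return int(round(value)) if self.kind == "int" else float(value)


HyperparameterSpace = Mapping[str, ParamSpec]

#: Default search spaces per model (k bounded by 20; tree ensembles search
#: size/depth/learning rate; the xgb regularization weights are searched too).
DEFAULT_SPACES: dict[str, dict[str, ParamSpec]] = {
    "knn": {"n_neighbors": ParamSpec("int", 1, 20)},
    "svm": {"C": ParamSpec("logfloat", 1e-3, 1e3)},
    "rf": {
        "n_estimators": ParamSpec("int", 100, 1000),
        "max_depth": ParamSpec("int", 2, 10),
    },
    "gbrt": {
        "n_estimators": ParamSpec("int", 100, 1000),
        "max_depth": ParamSpec("int", 2, 10),
        "learning_rate": ParamSpec("float", 0.01, 0.3),
    },
    "xgb": {
        "n_estimators": ParamSpec("int", 100, 1000),
        "max_depth": ParamSpec("int", 2, 10),
        "learning_rate": ParamSpec("float", 0.01, 0.3),
        "reg_lambda": ParamSpec("float", 0.0, 10.0),
        "reg_alpha": ParamSpec("float", 0.0, 10.0),
    },
    "mlp": {
        "alpha": ParamSpec("logfloat", 1e-6, 1e-1),
        "learning_rate_init": ParamSpec("logfloat", 1e-4, 1e-2),
    },
    "cnn": {
        "lr": ParamSpec("logfloat", 1e-4, 1e-2),
        "epochs": ParamSpec("int", 20, 80),
    },
}


@dataclass
class TuneResult:
    best_spec: "ModelSpec"  # noqa: F821 - forward ref to models.ModelSpec
    best_objective: float
    trace: pd.DataFrame


def _decode(space: HyperparameterSpace, u: np.ndarray) -> dict:
    return {name: p.decode(ui) for (name, p), ui in zip(space.items(), u)}


def _expected_improvement(gp, U: np.ndarray, best: float) -> np.ndarray:
    mu, sd = gp.predict(U, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def tune(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    space: HyperparameterSpace | None = None,
    budget: int = 20,
    seed: int = 0,
    cv_k: int = 10,
    objective: Callable[[dict], float] | None = None,
    initial_points: Sequence[dict] | None = None,
) -> TuneResult:
    """Search ``space`` for the hyperparameters minimizing mean CV MAE.

    ``objective`` may override the default cross-validation objective
    (it receives a hyperparameter dict and returns a scalar to
    minimize).  ``initial_points`` seeds the first trials with explicit
    configurations (counted against the budget).  Returns the argmin
    over the full trace.
    """
    from . import models as _models  # local import to avoid a cycle

    if budget < 5:
        raise ValueError(f"budget must be >= 5, got {budget}")
    space = dict(space if space is not None else DEFAULT_SPACES[name])
    if not space:
        raise ValueError(f"empty search space for {name!r}")
    n_init = max(2, int(round(budget * 0.2)))
    if budget < n_init:
        raise ValueError("budget smaller than the number of initial random points")

    if objective is None:
        from .evaluate import make_folds

        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        plan = make_folds(len(y), k=min(cv_k, len(y)), seed=seed)

        def objective(params: dict) -> float:
            maes = []
            for fold in range(plan.k):
                tr = plan.assignments != fold
                te = ~tr
                spec = _models.ModelSpec(name=name, hyperparameters=params, seed=seed)
                model = _models.fit(spec, X[tr], y[tr])
                pred = model.predict(X[te])
                maes.append(float(np.mean(np.abs(y[te] - pred))))
            return float(np.mean(maes))

    rng = np.random.default_rng(seed)
    dim = len(space)
    names = list(space)

    def _encode(params: dict) -> np.ndarray:
        u = np.zeros(dim)
        for j, pname in enumerate(names):
            p = space[pname]
            v = params[pname]
            if p.kind == "choice":
                u[j] = (p.choices.index(v) + 0.5) / len(p.choices)
            elif p.kind == "logfloat":
                u[j] = (np.log(v) - np.log(p.low)) / (np.log(p.high) - np.log(p.low))
            else:
                u[j] = (v - p.low) / (p.high - p.low) if p.high > p.low else 0.5
        return np.clip(u, 0.0, 1.0)

    U_obs: list[np.ndarray] = []
    f_obs: list[float] = []
    rows = []
    initial = list(initial_points or [])

    for trial in range(budget):
        if trial < len(initial):
            params = dict(initial[trial])
            u = _encode(params)
            method = "seeded"
        elif trial < n_init + len(initial):
            u = rng.random(dim)
            params = _decode(space, u)
            method = "random-init"
        else:
            # fixed kernel hyperparameters: robust on the handful of points
            # observed during a search, and exactly reproducible
            kernel = Matern(nu=2.5, length_scale=np.full(dim, 0.3), length_scale_bounds="fixed") + WhiteKernel(
                1e-4, noise_level_bounds="fixed"
            )
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=seed, alpha=1e-8, optimizer=None
            )
            gp.fit(np.vstack(U_obs), np.asarray(f_obs))
            cand = rng.random((512, dim))
            ei = _expected_improvement(gp, cand, min(f_obs))
            u = cand[int(np.argmax(ei))]
            params = _decode(space, u)
            method = "gp-ei"
        value = float(objective(params))
        U_obs.append(u)
        f_obs.append(value)
        rows.append(
            {"trial": trial, "method": method, "objective": value, "params": json.dumps(params)}
        )

    trace = pd.DataFrame(rows)
    best_i = int(np.argmin(f_obs))
    best_params = json.loads(rows[best_i]["params"])
    best_spec = _models.ModelSpec(name=name, hyperparameters=best_params, seed=seed)
    return TuneResult(best_spec=best_spec, best_objective=float(f_obs[best_i]), trace=trace)
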