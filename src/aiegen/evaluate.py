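"""Cross-validation harness, metrics and error analyses.

Model quality is measured by 10-fold cross-validation: records are
randomly divided into ten mutually exclusive, size-balanced subsets;
each subset is predicted once by a model trained on the other nine, and
the reported score is the mean over the ten held-out tests.  Metrics are
MAE and RMSE in nm and the coefficient of determination R².  On top of
the harness sit the error-distribution summary (|error| <= 10 nm /
(10, 20] nm / > 20 nm), a learning-curve ("scalability") study and a
models x descriptors benchmark grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .dataset import Dataset
from .featurize import DescriptorSpec, QuantitativeScaler, featurize_dataset, preset

__all__ = [
    "mae",
    "rmse",
    "r2",
    "FoldPlan",
    "make_folds",
    "make_group_folds",
    "EvalReport",
    "cross_validate",
    "ErrorDistribution",
    "error_distribution",
    "ScalabilityPoint",
    "ScalabilityCurve",
    "scalability_study",
    "BenchmarkResult",
    "benchmark_grid",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# metrics


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty input")
    return y_true, y_pred


def mae(y_true, y_pred) -> float:
    """Mean absolute error (nm): (1/n) sum |y_true - y_pred|."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(y_true - y_pred)))


def rmse(y_true, y_pred) -> float:
    """Root mean squared error (nm): sqrt((1/n) sum (y_true - y_pred)^2)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r2(y_true, y_pred) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r2 undefined for constant y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of record indices to k mutually exclusive folds."""

    k: int
    seed: int
    assignments: np.ndarray  # fold id per record index

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignments, minlength=self.k)
        if counts.sum() != self.assignments.size:
            raise ValueError("assignments outside fold range")

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


def make_folds(n: int, k: int = 10, seed: int = 0) -> FoldPlan:
    """Randomly split n records into k folds with sizes differing by <= 1."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    # first (n % k) folds take the extra record
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignments[perm[start : start + size]] = fold
        start += size
    return FoldPlan(k=k, seed=seed, assignments=assignments)


def make_group_folds(groups: Sequence, k: int = 10, seed: int = 0) -> FoldPlan:
    """Fold split keeping all records of a group (e.g. one molecule) together.

    Groups are shuffled and assigned greedily to the currently smallest
    fold, so fold sizes are balanced but may differ by more than one.
    """
    groups = list(groups)
    unique = sorted(set(groups))
    if len(unique) < k:
        raise ValueError(f"need at least k={k} groups, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    group_size = {g: 0 for g in unique}
    for g in groups:
        group_size[g] += 1
    fold_of: dict = {}
    fold_load = np.zeros(k, dtype=int)
    for g in sorted(order, key=lambda g: -group_size[g]):
        fold = int(np.argmin(fold_load))
        fold_of[g] = fold
        fold_load[fold] += group_size[g]
    assignments = np.array([fold_of[g] for g in groups], dtype=int)
    return FoldPlan(k=k, seed=seed, assignments=assignments)


# --------------------------------------------------------------------------
# cross-validation


@dataclass
class EvalReport:
    """Per-fold and aggregate scores plus pooled out-of-fold residuals.

    The aggregate MAE/RMSE/R² are the means of the per-fold values (the
    "mean of the ten tests"); ``pooled_r2`` is additionally computed on
    the pooled out-of-fold predictions.  ``residuals`` holds prediction
    minus truth for every record, in record order.
    """

    model_name: str
    descriptor_name: str
    target: str
    k: int
    seed: int
    n: int
    fold_mae: np.ndarray
    fold_rmse: np.ndarray
    fold_r2: np.ndarray
    residuals: np.ndarray
    mae: float = field(init=False)
    rmse: float = field(init=False)
    r2: float = field(init=False)
    pooled_r2: float = 0.0

    def __post_init__(self) -> None:
        self.mae = float(np.mean(self.fold_mae))
        self.rmse = float(np.mean(self.fold_rmse))
        self.r2 = float(np.mean(self.fold_r2))

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "descriptor": self.descriptor_name,
            "target": self.target,
            "k": self.k,
            "seed": self.seed,
            "n": self.n,
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "pooled_r2": self.pooled_r2,
            "fold_mae": self.fold_mae.tolist(),
            "fold_rmse": self.fold_rmse.tolist(),
            "fold_r2": self.fold_r2.tolist(),
        }


def cross_validate(
    model_spec: _models.ModelSpec,
    descriptor_spec: DescriptorSpec,
    ds: Dataset,
    target: str,
    k: int = 10,
    seed: int = 0,
    group_by_molecule: bool = False,
    feature_matrix=None,
) -> EvalReport:
    """k-fold cross-validation of one model/descriptor pair on one target.

    For each fold the model is fitted on the other k-1 folds and
    predicts the held-out fold; quantitative-block scaling statistics
    are computed on the training folds only.  ``feature_matrix`` may
    pass a precomputed featurization of ``ds`` (it must match row for
    row) to avoid repeated fingerprinting in grid runs.
    """
    sub = ds.with_target(target)
    if len(sub) < len(ds):
        logger.info("dropping %d records lacking %s", len(ds) - len(sub), target)
    y = sub.targets(target)
    fm = feature_matrix if feature_matrix is not None else featurize_dataset(sub, descriptor_spec)
    if len(fm) != len(sub):
        raise ValueError("feature matrix does not match dataset")
    if group_by_molecule:
        plan = make_group_folds([r.molecule_smiles for r in sub], k=k, seed=seed)
    else:
        plan = make_folds(len(sub), k=k, seed=seed)

    needs_scaling = fm.quantitative_columns().size > 0
    fold_mae = np.empty(k)
    fold_rmse = np.empty(k)
    fold_r2 = np.empty(k)
    residuals = np.empty(len(sub))
    for fold in range(k):
        te = plan.fold_indices(fold)
        tr = np.flatnonzero(plan.assignments != fold)
        if te.size < 2:
            raise ValueError(f"fold {fold} has fewer than 2 records")
        scaler = QuantitativeScaler.fit(fm, train_idx=tr) if needs_scaling else None
        model = _models.fit(model_spec, fm.X[tr], y[tr], target=target, scaler=scaler)
        pred = model.predict(fm.X[te])
        fold_mae[fold] = mae(y[te], pred)
        fold_rmse[fold] = rmse(y[te], pred)
        fold_r2[fold] = r2(y[te], pred)
        residuals[te] = pred - y[te]

    report = EvalReport(
        model_name=model_spec.name,
        descriptor_name=descriptor_spec.name or "custom",
        target=target,
        k=k,
        seed=seed,
        n=len(sub),
        fold_mae=fold_mae,
        fold_rmse=fold_rmse,
        fold_r2=fold_r2,
        residuals=residuals,
    )
    report.pooled_r2 = r2(y, y + residuals)
    return report


# --------------------------------------------------------------------------
# error distribution


@dataclass(frozen=True)
class ErrorDistribution:
    """Counts/fractions of |residual| in <= 10 nm, (10, 20] nm, > 20 nm."""

    counts: tuple[int, int, int]
    fractions: tuple[float, float, float]
    edges: tuple[float, float] = (10.0, 20.0)


def error_distribution(report_or_residuals) -> ErrorDistribution:
    """Bin absolute prediction errors at the 10 nm and 20 nm thresholds."""
    residuals = (
        report_or_residuals.residuals
        if isinstance(report_or_residuals, EvalReport)
        else np.asarray(report_or_residuals, dtype=float)
    )
    if residuals.size == 0:
        raise ValueError("no residuals")
    a = np.abs(residuals)
    counts = (int(np.sum(a <= 10)), int(np.sum((a > 10) & (a <= 20))), int(np.sum(a > 20)))
    total = residuals.size
    return ErrorDistribution(counts=counts, fractions=tuple(c / total for c in counts))


# --------------------------------------------------------------------------
# scalability


@dataclass(frozen=True)
class ScalabilityPoint:
    train_fraction: float
    mean_mae: float
    se_mae: float
    n_repeats: int


@dataclass(frozen=True)
class ScalabilityCurve:
    points: tuple[ScalabilityPoint, ...]

    def __iter__(self):
        return iter(self.points)


def scalability_study(
    model_spec: _models.ModelSpec,
    descriptor_spec: DescriptorSpec,
    ds: Dataset,
    target: str,
    fractions: Iterable[float],
    seed: int = 0,
    repeats: int = 5,
    feature_matrix=None,
) -> ScalabilityCurve:
    """Test MAE as the training fraction grows (learning curve).

    For each fraction f, ``repeats`` random splits train on a fraction f
    of the records and test on the rest; the mean MAE and its standard
    error over repeats are reported.
    """
    fractions = [float(f) for f in fractions]
    if any(not 0 < f < 1 for f in fractions):
        raise ValueError("fractions must lie strictly in (0, 1)")
    if sorted(set(fractions)) != fractions:
        raise ValueError("fractions must be strictly increasing")
    sub = ds.with_target(target)
    y = sub.targets(target)
    fm = feature_matrix if feature_matrix is not None else featurize_dataset(sub, descriptor_spec)
    needs_scaling = fm.quantitative_columns().size > 0
    n = len(sub)
    seeds = np.random.SeedSequence(seed).spawn(len(fractions) * repeats)
    points = []
    for i, f in enumerate(fractions):
        n_train = int(round(f * n))
        if n_train < 10:
            raise ValueError(f"fraction {f} yields {n_train} < 10 training rows")
        maes = []
        for rep in range(repeats):
            rng = np.random.default_rng(seeds[i * repeats + rep])
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            scaler = QuantitativeScaler.fit(fm, train_idx=tr) if needs_scaling else None
            model = _models.fit(model_spec, fm.X[tr], y[tr], target=target, scaler=scaler)
            maes.append(mae(y[te], model.predict(fm.X[te])))
        maes = np.asarray(maes)
        se = float(maes.std(ddof=1) / np.sqrt(repeats)) if repeats > 1 else 0.0
        points.append(
            ScalabilityPoint(train_fraction=f, mean_mae=float(maes.mean()), se_mae=se, n_repeats=repeats)
        )
    return ScalabilityCurve(points=tuple(points))


# --------------------------------------------------------------------------
# benchmark grid


@dataclass
class BenchmarkResult:
    """Model x descriptor grid of cross-validation scores."""

    table: pd.DataFrame
    reports: dict[tuple[str, str, str], EvalReport]
    winners: dict[str, tuple[str, str]]  # target -> (model, descriptor)

    def report(self, model: str, descriptor: str, target: str) -> EvalReport:
        return self.reports[(model, descriptor, target)]


def benchmark_grid(
    model_names: Sequence[str],
    descriptor_presets: Sequence[str] | dict[str, DescriptorSpec],
    ds: Dataset,
    targets: Sequence[str] = ("absorption", "emission"),
    k: int = 10,
    seed: int = 0,
    model_hyperparameters: dict[str, dict] | None = None,
) -> BenchmarkResult:
    """Cross-validate every model x descriptor x target combination.

    Returns a table sortable by MAE plus the winning (model, descriptor)
    pair per target.  Featurization is shared across models of the same
    descriptor to keep grid runs affordable.
    """
    if not model_names or not descriptor_presets:
        raise ValueError("need at least one model and one descriptor preset")
    if isinstance(descriptor_presets, dict):
        specs = dict(descriptor_presets)
    else:
        specs = {name: preset(name) for name in descriptor_presets}
    overrides = model_hyperparameters or {}

    rows = []
    reports: dict[tuple[str, str, str], EvalReport] = {}
    for target in targets:
        sub = ds.with_target(target)
        for d_name, d_spec in specs.items():
            fm = featurize_dataset(sub, d_spec)
            for m_name in model_names:
                spec = _models.ModelSpec(
                    name=m_name, hyperparameters=overrides.get(m_name, {}), seed=seed
                )
                report = cross_validate(
                    spec, d_spec, sub, target, k=k, seed=seed, feature_matrix=fm
                )
                reports[(m_name, d_name, target)] = report
                rows.append(
                    {
                        "target": target,
                        "model": m_name,
                        "descriptor": d_name,
                        "mae": report.mae,
                        "rmse": report.rmse,
                        "r2": report.r2,
                        "pooled_r2": report.pooled_r2,
                    }
                )
    table = pd.DataFrame(rows).sort_values(["target", "mae"]).reset_index(drop=True)
    winners = {}
    for target in targets:
        best = table[table["target"] == target].iloc[0]
        winners[target] = (best["model"], best["descriptor"])
    return BenchmarkResult(table=table, reports=reports, winners=winners)
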