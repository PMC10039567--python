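"""Large-scale screening of candidate luminogens.

Given trained absorption and emission models, every valid candidate
SMILES is featurized in the query solvent with each model's own
descriptor recipe and receives both wavelength predictions; a shortlist
is obtained by filtering on inclusive absorption/emission wavelength
windows.  The default model pairing follows the best benchmarked
combinations: XGBoost on the toptorsion-daylight fused fingerprint for
absorption, and the 1-D CNN on the atompair-daylight fused fingerprint
for emission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset, SmilesParseError, SpectralRecord, canonicalize
from .featurize import FeatureMatrix, featurize_dataset, preset
from .models import ModelSpec, TrainedModel, train_on_dataset

__all__ = [
    "ScreeningQuery",
    "ScreeningReport",
    "DEFAULT_PAIRING",
    "predict_spectra",
    "filter_by_window",
    "train_default_models",
    "read_candidates",
]

logger = logging.getLogger(__name__)

#: Best benchmarked model/descriptor pairing per target.
DEFAULT_PAIRING = {
    "absorption": ("xgb", "toptorsion-daylight"),
    "emission": ("cnn", "atompair-daylight"),
}

#: Warn when a candidate shares less than this fraction of its set bits
#: with every training molecule (weak applicability-domain signal).
MIN_BIT_OVERLAP = 0.05


@dataclass(frozen=True)
class ScreeningQuery:
    """Candidate SMILES plus solvent and optional wavelength windows (nm)."""

    candidates: tuple[str, ...]
    solvent_name: str | None = None
    solvent_smiles: str | None = None
    abs_window: tuple[float, float] | None = None
    em_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidate list is empty")
        if self.solvent_name is None and self.solvent_smiles is None:
            raise ValueError("a solvent is required")
        for window, name in ((self.abs_window, "abs_window"), (self.em_window, "em_window")):
            if window is not None and not window[0] <= window[1]:
                raise ValueError(f"{name} is not well-ordered: {window}")


@dataclass
class ScreeningReport:
    """One row per valid candidate; invalid SMILES listed with reasons."""

    table: pd.DataFrame
    invalid: list[tuple[str, str]]
    abs_model_hash: str
    em_model_hash: str

    def __len__(self) -> int:
        return len(self.table)


def read_candidates(path: str | Path) -> list[str]:
    """Read candidate SMILES from a plain file (one per line) or a CSV
    with a ``candidate_smiles`` or ``smiles`` column."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        for col in ("candidate_smiles", "smiles", "molecule_smiles"):
            if col in frame.columns:
                return [str(s) for s in frame[col].dropna()]
        raise ValueError(f"{path} has no candidate_smiles/smiles column")
    return [line.strip() for line in path.read_text().splitlines() if line.strip() and not line.startswith("#")]


def _overlap_warning(fm: FeatureMatrix, model: TrainedModel, smiles: list[str]) -> None:
    if model.training_bits is None:
        return
    from .models import _fingerprint_columns

    cols = _fingerprint_columns(fm)
    if cols.size == 0:
        return
    train = np.unpackbits(model.training_bits, axis=1)[:, : cols.size].astype(bool)
    for i, smi in enumerate(smiles):
        cand = fm.X[i, cols].astype(bool)
        n_set = cand.sum()
        if n_set == 0:
            continue
        overlap = (train & cand).sum(axis=1).max() / n_set
        if overlap < MIN_BIT_OVERLAP:
            logger.warning(
                "candidate %s shares only %.1f%% of its fingerprint bits with the "
                "closest training molecule; prediction may be unreliable",
                smi,
                100 * overlap,
            )


def predict_spectra(
    query: ScreeningQuery,
    abs_model: TrainedModel,
    em_model: TrainedModel,
) -> ScreeningReport:
    """Predict absorption and emission wavelengths for every candidate.

    Invalid SMILES are collected (not fatal) unless no candidate
    survives.  Each model featurizes the candidates with its own stored
    descriptor spec; predictions are deterministic and duplicates of a
    candidate receive identical values.
    """
    for model, target in ((abs_model, "absorption"), (em_model, "emission")):
        if model.descriptor_spec is None:
            raise ValueError(f"{target} model carries no descriptor spec; train it via train_on_dataset")

    valid: list[str] = []
    canonical: list[str] = []
    invalid: list[tuple[str, str]] = []
    for smi in query.candidates:
        try:
            canonical.append(canonicalize(smi))
            valid.append(smi)
        except SmilesParseError:
            invalid.append((smi, "unparseable SMILES"))
    if not valid:
        raise ValueError("no valid candidates")

    records = [
        SpectralRecord(
            molecule_smiles=c,
            solvent_smiles=query.solvent_smiles,
            solvent_name=query.solvent_name,
            lambda_abs=1.0,  # placeholder target; screening records carry no measurement
        )
        for c in canonical
    ]
    ds = Dataset(records=records)

    preds = {}
    for target, model in (("absorption", abs_model), ("emission", em_model)):
        fm = featurize_dataset(ds, model.descriptor_spec)
        _overlap_warning(fm, model, valid)
        preds[target] = model.predict(fm)

    table = pd.DataFrame(
        {
            "candidate_smiles": valid,
            "canonical_smiles": canonical,
            "pred_lambda_abs_nm": preds["absorption"],
            "pred_lambda_em_nm": preds["emission"],
        }
    )
    if query.abs_window is not None:
        lo, hi = query.abs_window
        table["pass_abs"] = (table["pred_lambda_abs_nm"] >= lo) & (table["pred_lambda_abs_nm"] <= hi)
    if query.em_window is not None:
        lo, hi = query.em_window
        table["pass_em"] = (table["pred_lambda_em_nm"] >= lo) & (table["pred_lambda_em_nm"] <= hi)
    return ScreeningReport(
        table=table,
        invalid=invalid,
        abs_model_hash=abs_model.bundle_hash,
        em_model_hash=em_model.bundle_hash,
    )


def filter_by_window(
    report: ScreeningReport,
    abs_window: tuple[float, float] | None = None,
    em_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Shortlist candidates whose predictions fall inside every supplied
    window (inclusive bounds), sorted by predicted emission descending."""
    if len(report) == 0:
        raise ValueError("empty screening report")
    table = report.table
    mask = np.ones(len(table), dtype=bool)
    if abs_window is not None:
        if not abs_window[0] <= abs_window[1]:
            raise ValueError(f"abs_window is not well-ordered: {abs_window}")
        mask &= (table["pred_lambda_abs_nm"] >= abs_window[0]) & (
            table["pred_lambda_abs_nm"] <= abs_window[1]
        )
    if em_window is not None:
        if not em_window[0] <= em_window[1]:
            raise ValueError(f"em_window is not well-ordered: {em_window}")
        mask &= (table["pred_lambda_em_nm"] >= em_window[0]) & (
            table["pred_lambda_em_nm"] <= em_window[1]
        )
    shortlist = table[mask].sort_values("pred_lambda_em_nm", ascending=False)
    return shortlist.reset_index(drop=True)


def train_default_models(
    ds: Dataset,
    seed: int = 0,
    hyperparameters: dict[str, dict] | None = None,
) -> tuple[TrainedModel, TrainedModel]:
    """Train the default screening pair on a dataset.

    Absorption: XGBoost on toptorsion-daylight.  Emission: 1-D CNN on
    atompair-daylight.
    """
    overrides = hyperparameters or {}
    abs_name, abs_preset = DEFAULT_PAIRING["absorption"]
    em_name, em_preset = DEFAULT_PAIRING["emission"]
    abs_model = train_on_dataset(
        ds,
        ModelSpec(name=abs_name, hyperparameters=overrides.get(abs_name, {}), seed=seed),
        preset(abs_preset),
        target="absorption",
    )
    em_model = train_on_dataset(
        ds,
        ModelSpec(name=em_name, hyperparameters=overrides.get(em_name, {}), seed=seed),
        preset(em_preset),
        target="emission",
    )
    return abs_model, em_model
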