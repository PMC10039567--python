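"""Reading, validation and curation of solvated-luminogen spectral records.

The unit of data is one (molecule, solvent) observation carrying an
absorption peak wavelength and/or an emission peak wavelength in nm.
Databases of this kind are curated from heterogeneous literature reports:
a single solvated luminogen may exhibit several absorption and emission
peaks, from which one representative value per target is kept — the
longest-wavelength absorption peak and the highest-intensity emission
peak.  Molecules are identified by canonical SMILES so that duplicate
detection and distinct-molecule counts are invariant to how a structure
was drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "SpectralRecord",
    "RawEntry",
    "Dataset",
    "DatasetSummary",
    "SmilesParseError",
    "DatasetFormatError",
    "EmptyDatasetError",
    "NoPeakError",
    "canonicalize",
    "curate_peaks",
    "read_dataset",
    "write_dataset",
    "summarize",
]

logger = logging.getLogger(__name__)

# RDKit's C++ logging is noisy about every rejected SMILES; invalid rows are
# reported through this module's own logger instead.
RDLogger.DisableLog("rdApp.error")

#: Fixed column order for CSV/TSV interchange.
COLUMNS = (
    "molecule_smiles",
    "solvent_smiles",
    "solvent_name",
    "lambda_abs_nm",
    "lambda_em_nm",
    "source_id",
)

REQUIRED_COLUMNS = ("molecule_smiles",)


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed into a molecular graph."""


class DatasetFormatError(ValueError):
    """The input table is missing required columns."""


class EmptyDatasetError(ValueError):
    """No valid record survived validation."""


class NoPeakError(ValueError):
    """A raw entry carries neither absorption nor emission peaks."""


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for ``smiles``.

    Two SMILES spellings of the same molecular graph map to an identical
    string.  Multi-fragment inputs (salts, mixtures) are reduced to the
    largest fragment by heavy-atom count, with a log message.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        logger.info(
            "multi-fragment SMILES %r: keeping largest fragment (%d heavy atoms)",
            smiles,
            mol.GetNumHeavyAtoms(),
        )
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class SpectralRecord:
    """One validated (molecule, solvent) observation.

    At least one of ``lambda_abs``/``lambda_em`` must be present and
    positive; at least one solvent field must be set.  SMILES fields are
    canonicalized on construction, so record identity is independent of
    how a structure was drawn.
    """

    molecule_smiles: str
    solvent_smiles: str | None = None
    solvent_name: str | None = None
    lambda_abs: float | None = None
    lambda_em: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecule_smiles", canonicalize(self.molecule_smiles))
        if self.solvent_smiles is not None:
            object.__setattr__(self, "solvent_smiles", canonicalize(self.solvent_smiles))
        if self.lambda_abs is None and self.lambda_em is None:
            raise ValueError("record needs at least one of lambda_abs, lambda_em")
        for value, name in ((self.lambda_abs, "lambda_abs"), (self.lambda_em, "lambda_em")):
            if value is not None and not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and positive, got {value}")
        if self.solvent_smiles is None and self.solvent_name is None:
            raise ValueError("record needs at least one solvent field")

    @property
    def solvent_key(self) -> str:
        """Canonical identity of the solvent for counting/deduplication."""
        return self.solvent_smiles if self.solvent_smiles is not None else f"name:{self.solvent_name}"


@dataclass(frozen=True)
class RawEntry:
    """An uncurated literature entry with all reported peaks.

    ``abs_peaks`` lists absorption peak wavelengths (nm); ``em_peaks``
    lists (wavelength nm, intensity a.u.) pairs.  Either list may be
    empty, but not both.
    """

    molecule_smiles: str
    solvent_smiles: str | None = None
    solvent_name: str | None = None
    abs_peaks: tuple[float, ...] = ()
    em_peaks: tuple[tuple[float, float], ...] = ()
    source_id: str | None = None


def curate_peaks(entry: RawEntry) -> SpectralRecord:
    """Reduce a multi-peak entry to one record.

    The absorption value kept is the longest-wavelength absorption peak;
    the emission value kept is the wavelength of the highest-intensity
    emission peak (ties broken toward the longer wavelength, i.e. the
    red-shifted peak).
    """
    if not entry.abs_peaks and not entry.em_peaks:
        raise NoPeakError("entry has neither absorption nor emission peaks")
    if any(i < 0 for _, i in entry.em_peaks):
        raise ValueError("emission intensities must be nonnegative")
    lambda_abs = max(entry.abs_peaks) if entry.abs_peaks else None
    lambda_em = None
    if entry.em_peaks:
        # max over (intensity, wavelength): intensity first, red-shift tiebreak
        lambda_em = max(entry.em_peaks, key=lambda p: (p[1], p[0]))[0]
    return SpectralRecord(
        molecule_smiles=canonicalize(entry.molecule_smiles),
        solvent_smiles=canonicalize(entry.solvent_smiles) if entry.solvent_smiles else None,
        solvent_name=entry.solvent_name,
        lambda_abs=lambda_abs,
        lambda_em=lambda_em,
        source_id=entry.source_id,
    )


@dataclass
class Dataset:
    """Ordered collection of validated spectral records."""

    records: list[SpectralRecord]
    provenance: dict = field(default_factory=dict)
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "molecule_smiles": r.molecule_smiles,
                "solvent_smiles": r.solvent_smiles,
                "solvent_name": r.solvent_name,
                "lambda_abs_nm": r.lambda_abs,
                "lambda_em_nm": r.lambda_em,
                "source_id": r.source_id,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))

    def targets(self, target: str) -> np.ndarray:
        """Wavelength array for ``target`` in {'absorption', 'emission'}.

        Raises if any record lacks the requested value.
        """
        attr = _TARGET_ATTR[target]
        values = [getattr(r, attr) for r in self.records]
        if any(v is None for v in values):
            raise ValueError(f"some records lack {target} values")
        return np.asarray(values, dtype=float)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(records=[self.records[i] for i in indices], provenance=dict(self.provenance))

    def with_target(self, target: str) -> "Dataset":
        """Records that carry the requested target value, order preserved."""
        attr = _TARGET_ATTR[target]
        return Dataset(
            records=[r for r in self.records if getattr(r, attr) is not None],
            provenance=dict(self.provenance),
        )


_TARGET_ATTR = {"absorption": "lambda_abs", "emission": "lambda_em"}


def _parse_row(row: pd.Series) -> SpectralRecord:
    def _get(col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        if isinstance(v, str) and not v.strip():
            return None
        return v

    mol = _get("molecule_smiles")
    if mol is None:
        raise SmilesParseError("missing molecule_smiles")
    lam_abs = _get("lambda_abs_nm")
    lam_em = _get("lambda_em_nm")
    solvent_smiles = _get("solvent_smiles")
    return SpectralRecord(
        molecule_smiles=canonicalize(str(mol)),
        solvent_smiles=canonicalize(str(solvent_smiles)) if solvent_smiles is not None else None,
        solvent_name=str(_get("solvent_name")).strip().lower() if _get("solvent_name") is not None else None,
        lambda_abs=float(lam_abs) if lam_abs is not None else None,
        lambda_em=float(lam_em) if lam_em is not None else None,
        source_id=str(_get("source_id")) if _get("source_id") is not None else None,
    )


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    dedupe: bool = False,
) -> Dataset:
    """Read and validate a CSV/TSV table of spectral records.

    Every row either yields a validated :class:`SpectralRecord` or is
    rejected with a logged reason (kept on ``Dataset.rejected``); row
    order is preserved.  Unknown columns are ignored with a warning.
    With ``dedupe=True``, repeated (canonical molecule, solvent) pairs
    are averaged into one record per target.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if fmt not in {"csv", "tsv"}:
        raise ValueError(f"unsupported format {fmt!r}")
    frame = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"missing required columns: {missing}")
    extra = [c for c in frame.columns if c not in COLUMNS]
    if extra:
        logger.warning("ignoring unknown columns: %s", extra)

    records: list[SpectralRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(_parse_row(row))
        except (ValueError, TypeError) as exc:
            reason = "unparseable SMILES" if isinstance(exc, SmilesParseError) else str(exc)
            logger.warning("row %d rejected: %s", i, reason)
            rejected.append((i, reason))
    if not records:
        raise EmptyDatasetError(f"no valid records in {path}")
    ds = Dataset(records=records, provenance={"path": str(path), "format": fmt, "dedupe": dedupe}, rejected=rejected)
    if dedupe:
        ds = _dedupe(ds)
    return ds


def _dedupe(ds: Dataset) -> Dataset:
    """Average targets over repeated (molecule, solvent) pairs."""
    groups: dict[tuple[str, str], list[SpectralRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in ds.records:
        key = (r.molecule_smiles, r.solvent_key)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    merged = []
    for key in order:
        grp = groups[key]
        if len(grp) == 1:
            merged.append(grp[0])
            continue
        abs_vals = [r.lambda_abs for r in grp if r.lambda_abs is not None]
        em_vals = [r.lambda_em for r in grp if r.lambda_em is not None]
        merged.append(
            replace(
                grp[0],
                lambda_abs=float(np.mean(abs_vals)) if abs_vals else None,
                lambda_em=float(np.mean(em_vals)) if em_vals else None,
            )
        )
    return Dataset(records=merged, provenance=ds.provenance, rejected=ds.rejected)


def write_dataset(ds: Dataset, path: str | Path, fmt: str | None = None) -> None:
    """Write a dataset back to CSV/TSV with the fixed column header."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    ds.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)


@dataclass(frozen=True)
class DatasetSummary:
    n_records: int
    n_distinct_molecules: int
    n_distinct_solvents: int
    lambda_abs_range: tuple[float, float] | None
    lambda_em_range: tuple[float, float] | None


def summarize(ds: Dataset) -> DatasetSummary:
    """Counts over canonical identities plus wavelength ranges.

    Counts are invariant to record order and SMILES spelling because all
    stored SMILES are canonical.
    """
    if len(ds) == 0:
        raise EmptyDatasetError("cannot summarize an empty dataset")
    abs_vals = [r.lambda_abs for r in ds if r.lambda_abs is not None]
    em_vals = [r.lambda_em for r in ds if r.lambda_em is not None]
    return DatasetSummary(
        n_records=len(ds),
        n_distinct_molecules=len({r.molecule_smiles for r in ds}),
        n_distinct_solvents=len({r.solvent_key for r in ds}),
        lambda_abs_range=(min(abs_vals), max(abs_vals)) if abs_vals else None,
        lambda_em_range=(min(em_vals), max(em_vals)) if em_vals else None,
    )


def from_records(records: Iterable[SpectralRecord], **provenance) -> Dataset:
    """Build a dataset from already-validated records."""
    return Dataset(records=list(records), provenance=provenance)
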