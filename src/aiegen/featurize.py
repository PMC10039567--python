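"""Featurization of (molecule, solvent) pairs.

A record is turned into one fixed-length numeric vector assembled from
named blocks: a pinned list of 196 quantitative physicochemical /
graph-theoretic descriptors, and four hashed fingerprint families —
Morgan circular environments, daylight-type linear bond paths, atom
pairs (typed atoms at a topological distance) and topological torsions
(typed linear 4-atom paths).  "Multi-modal" descriptors are built by
stitching several fingerprint blocks together into one longer bit
vector; molecule blocks always precede solvent blocks.

Fingerprints are binary (one bit per hashed feature, no count
simulation) so that a block is exactly the indicator of its feature set,
and the daylight family hashes *linear* paths only — properties that
make the set-bit count of a small molecule equal to its number of
distinct substructural features and therefore directly checkable against
brute-force enumeration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

# the classic atom-pair API logs a C++-side deprecation warning per call;
# it is used deliberately (injective feature codes), so silence the channel
RDLogger.DisableLog("rdApp.warning")

from .dataset import Dataset, SmilesParseError, SpectralRecord, canonicalize

__all__ = [
    "FingerprintSpec",
    "DescriptorSpec",
    "FeatureVector",
    "FeatureMatrix",
    "FeaturizationError",
    "SolventVocabularyError",
    "quantitative_descriptor_names",
    "quantitative_descriptors",
    "fingerprint",
    "morgan_fp",
    "daylight_fp",
    "atompair_fp",
    "torsion_fp",
    "resolve_solvent",
    "solvent_table",
    "encode_solvent",
    "fuse",
    "featurize_record",
    "featurize_dataset",
    "preset",
    "PRESETS",
    "QuantitativeScaler",
]

logger = logging.getLogger(__name__)

N_QUANTITATIVE = 196


class FeaturizationError(ValueError):
    """A molecule or solvent could not be featurized."""


class SolventVocabularyError(KeyError):
    """A solvent name is outside the configured vocabulary."""


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class FingerprintSpec:
    """Recipe for one hashed-fingerprint block.

    kind: morgan | daylight | atompair | torsion
    n_bits: folded length (power of two, default 2048)
    radius: maximum circular-environment radius (morgan only)
    max_path: maximum bond-path length (daylight only)
    """

    kind: Literal["morgan", "daylight", "atompair", "torsion"]
    n_bits: int = 2048
    radius: int = 2
    max_path: int = 7

    def __post_init__(self) -> None:
        if self.kind not in {"morgan", "daylight", "atompair", "torsion"}:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.n_bits <= 0 or self.n_bits & (self.n_bits - 1):
            raise ValueError(f"n_bits must be a power of two, got {self.n_bits}")
        if not 0 <= self.radius <= 6:
            raise ValueError(f"radius must be in [0, 6], got {self.radius}")
        if self.max_path < 1:
            raise ValueError(f"max_path must be >= 1, got {self.max_path}")

    @property
    def length(self) -> int:
        return self.n_bits

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_bits": self.n_bits, "radius": self.radius, "max_path": self.max_path}


BlockRecipe = Union[Literal["quantitative"], FingerprintSpec]


def _recipe_name(recipe: BlockRecipe) -> str:
    return "quantitative" if recipe == "quantitative" else recipe.kind


def _recipe_from_dict(d) -> BlockRecipe:
    if d == "quantitative":
        return "quantitative"
    return FingerprintSpec(**d)


@dataclass(frozen=True)
class DescriptorSpec:
    """Declarative featurization recipe for (molecule, solvent) pairs.

    ``molecule_blocks`` lists block recipes applied to the molecule;
    solvent features follow, controlled by ``solvent_encoding``:

    - ``same_as_molecule``: every molecule block recipe is applied to the
      solvent structure as well (default);
    - ``quantitative_only``: the solvent contributes one 196-descriptor
      block regardless of the molecule blocks;
    - ``one_hot``: the solvent contributes an indicator over
      ``solvent_vocabulary``.
    """

    molecule_blocks: tuple[BlockRecipe, ...]
    solvent_encoding: Literal["same_as_molecule", "quantitative_only", "one_hot"] = "same_as_molecule"
    solvent_vocabulary: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.molecule_blocks:
            raise ValueError("at least one molecule block is required")
        names = [_recipe_name(b) for b in self.molecule_blocks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate block kinds in {names}")
        if self.solvent_encoding == "one_hot" and not self.solvent_vocabulary:
            raise ValueError("one_hot solvent encoding needs a solvent_vocabulary")

    @property
    def block_names(self) -> list[str]:
        names = [f"mol:{_recipe_name(b)}" for b in self.molecule_blocks]
        if self.solvent_encoding == "same_as_molecule":
            names += [f"solv:{_recipe_name(b)}" for b in self.molecule_blocks]
        elif self.solvent_encoding == "quantitative_only":
            names += ["solv:quantitative"]
        else:
            names += ["solv:one_hot"]
        return names

    @property
    def length(self) -> int:
        def _len(r: BlockRecipe) -> int:
            return N_QUANTITATIVE if r == "quantitative" else r.length

        n = sum(_len(b) for b in self.molecule_blocks)
        if self.solvent_encoding == "same_as_molecule":
            n *= 2
        elif self.solvent_encoding == "quantitative_only":
            n += N_QUANTITATIVE
        else:
            n += len(self.solvent_vocabulary)
        return n

    def to_dict(self) -> dict:
        return {
            "molecule_blocks": [b if b == "quantitative" else b.to_dict() for b in self.molecule_blocks],
            "solvent_encoding": self.solvent_encoding,
            "solvent_vocabulary": list(self.solvent_vocabulary),
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorSpec":
        return cls(
            molecule_blocks=tuple(_recipe_from_dict(b) for b in d["molecule_blocks"]),
            solvent_encoding=d.get("solvent_encoding", "same_as_molecule"),
            solvent_vocabulary=tuple(d.get("solvent_vocabulary", ())),
            name=d.get("name", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DescriptorSpec":
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_yaml(cls, text: str) -> "DescriptorSpec":
        return cls.from_dict(yaml.safe_load(text))


def preset(name: str) -> DescriptorSpec:
    """A named descriptor configuration.

    Single families: ``quantitative``, ``morgan``, ``daylight``,
    ``atompair``, ``toptorsion``.  Fused ("multi-modal") presets stitch a
    second family onto the daylight paths: ``morgan-daylight``,
    ``atompair-daylight``, ``toptorsion-daylight``.
    """
    try:
        blocks = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return DescriptorSpec(molecule_blocks=blocks, name=name)


_FP = {
    "morgan": FingerprintSpec("morgan"),
    "daylight": FingerprintSpec("daylight"),
    "atompair": FingerprintSpec("atompair"),
    "toptorsion": FingerprintSpec("torsion"),
}

PRESETS: dict[str, tuple[BlockRecipe, ...]] = {
    "quantitative": ("quantitative",),
    "morgan": (_FP["morgan"],),
    "daylight": (_FP["daylight"],),
    "atompair": (_FP["atompair"],),
    "toptorsion": (_FP["toptorsion"],),
    "morgan-daylight": (_FP["morgan"], _FP["daylight"]),
    "atompair-daylight": (_FP["atompair"], _FP["daylight"]),
    "toptorsion-daylight": (_FP["toptorsion"], _FP["daylight"]),
}

#: Constituent single-family presets of each fused preset.
FUSED_CONSTITUENTS = {
    "morgan-daylight": ("morgan", "daylight"),
    "atompair-daylight": ("atompair", "daylight"),
    "toptorsion-daylight": ("toptorsion", "daylight"),
}


# --------------------------------------------------------------------------
# quantitative descriptors


@lru_cache(maxsize=1)
def _descriptor_table() -> pd.DataFrame:
    with resources.files("aiegen.data").joinpath("quantitative_descriptors.csv").open() as fh:
        table = pd.read_csv(fh)
    missing = [n for n in table["name"] if not hasattr(Descriptors, n)]
    if missing:
        raise RuntimeError(f"pinned descriptors absent from RDKit: {missing}")
    return table


def quantitative_descriptor_names() -> list[str]:
    """The pinned, ordered 196-descriptor list (106 one-dim + 90 two-dim)."""
    return list(_descriptor_table()["name"])


@lru_cache(maxsize=4096)
def _quantitative_cached(canonical: str) -> tuple[float, ...]:
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical input always parses
        raise FeaturizationError(f"unparseable SMILES: {canonical!r}")
    values = []
    for name in quantitative_descriptor_names():
        try:
            v = float(getattr(Descriptors, name)(mol))
        except Exception:
            v = float("nan")
        if not np.isfinite(v):
            logger.warning("descriptor %s non-finite for %s; substituting 0", name, canonical)
            v = 0.0
        values.append(v)
    return tuple(values)


def quantitative_descriptors(smiles: str) -> np.ndarray:
    """The pinned 196-entry quantitative descriptor vector of a molecule."""
    try:
        canonical = canonicalize(smiles)
    except SmilesParseError as exc:
        raise FeaturizationError(str(exc)) from exc
    return np.asarray(_quantitative_cached(canonical), dtype=float)


# --------------------------------------------------------------------------
# fingerprints


@lru_cache(maxsize=64)
def _generator(spec: FingerprintSpec):
    if spec.kind == "morgan":
        return rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius, fpSize=spec.n_bits)
    if spec.kind == "daylight":
        # linear heavy-atom bond paths of 1..max_path bonds, one bit per path
        return rdFingerprintGenerator.GetRDKitFPGenerator(
            minPath=1,
            maxPath=spec.max_path,
            fpSize=spec.n_bits,
            numBitsPerFeature=1,
            branchedPaths=False,
        )
    if spec.kind == "atompair":
        return None  # classic injective pair codes, folded by modulo; see below
    return rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=spec.n_bits, countSimulation=False)


@lru_cache(maxsize=65536)
def _fingerprint_cached(canonical: str, spec: FingerprintSpec) -> bytes:
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover
        raise FeaturizationError(f"unparseable SMILES: {canonical!r}")
    arr = np.zeros(spec.n_bits, dtype=np.uint8)
    if spec.kind == "atompair":
        # classic atom-pair codes pack (type, type, distance) injectively;
        # fold to n_bits by modulo so one feature sets one bit
        sparse = rdMolDescriptors.GetAtomPairFingerprint(mol)
        for code in sparse.GetNonzeroElements():
            arr[code % spec.n_bits] = 1
    else:
        bv = _generator(spec).GetFingerprint(mol)
        arr[list(bv.GetOnBits())] = 1
    return arr.tobytes()


def fingerprint(smiles: str, spec: FingerprintSpec) -> np.ndarray:
    """Binary fingerprint vector of ``smiles`` under ``spec``.

    Deterministic for a fixed spec and invariant to SMILES spelling
    (input is canonicalized first).
    """
    try:
        canonical = canonicalize(smiles)
    except SmilesParseError as exc:
        raise FeaturizationError(str(exc)) from exc
    return np.frombuffer(_fingerprint_cached(canonical, spec), dtype=np.uint8).copy()


def morgan_fp(smiles: str, spec: FingerprintSpec | None = None) -> np.ndarray:
    """Morgan circular fingerprint (radius 2, 2048 bits by default)."""
    spec = spec or FingerprintSpec("morgan")
    if spec.kind != "morgan":
        raise ValueError("spec.kind must be 'morgan'")
    return fingerprint(smiles, spec)


def daylight_fp(smiles: str, spec: FingerprintSpec | None = None) -> np.ndarray:
    """Daylight-type path fingerprint: linear bond paths of 1..max_path bonds."""
    spec = spec or FingerprintSpec("daylight")
    if spec.kind != "daylight":
        raise ValueError("spec.kind must be 'daylight'")
    return fingerprint(smiles, spec)


def atompair_fp(smiles: str, spec: FingerprintSpec | None = None) -> np.ndarray:
    """Atom-pair fingerprint: (typed atom, typed atom, shortest-path distance)."""
    spec = spec or FingerprintSpec("atompair")
    if spec.kind != "atompair":
        raise ValueError("spec.kind must be 'atompair'")
    return fingerprint(smiles, spec)


def torsion_fp(smiles: str, spec: FingerprintSpec | None = None) -> np.ndarray:
    """Topological torsion fingerprint: typed linear 4-heavy-atom paths."""
    spec = spec or FingerprintSpec("torsion")
    if spec.kind != "torsion":
        raise ValueError("spec.kind must be 'torsion'")
    return fingerprint(smiles, spec)


# --------------------------------------------------------------------------
# solvents


@lru_cache(maxsize=1)
def solvent_table() -> pd.DataFrame:
    """Packaged solvent name -> SMILES table (24 common solvents)."""
    with resources.files("aiegen.data").joinpath("solvents.csv").open() as fh:
        table = pd.read_csv(fh, keep_default_na=False)
    return table


@lru_cache(maxsize=1)
def _solvent_lookup() -> dict[str, str]:
    lookup: dict[str, str] = {}
    for _, row in solvent_table().iterrows():
        lookup[row["name"].strip().lower()] = row["smiles"]
        for syn in str(row["synonyms"]).split(";"):
            syn = syn.strip().lower()
            if syn:
                lookup[syn] = row["smiles"]
    return lookup


def resolve_solvent(record_or_name: SpectralRecord | str) -> str:
    """Resolve a record's solvent fields (or a bare name) to a SMILES."""
    if isinstance(record_or_name, SpectralRecord):
        if record_or_name.solvent_smiles:
            return record_or_name.solvent_smiles
        name = record_or_name.solvent_name or ""
    else:
        name = record_or_name
    key = name.strip().lower()
    try:
        return _solvent_lookup()[key]
    except KeyError:
        raise SolventVocabularyError(f"unknown solvent name {name!r}") from None


# --------------------------------------------------------------------------
# fusion


@dataclass(frozen=True)
class BlockSlice:
    name: str
    offset: int
    length: int


@dataclass(frozen=True)
class FeatureVector:
    """One fused feature vector with its block layout."""

    values: np.ndarray
    layout: tuple[BlockSlice, ...]

    def __post_init__(self) -> None:
        if sum(b.length for b in self.layout) != self.values.shape[-1]:
            raise ValueError("layout lengths do not sum to vector length")

    def block(self, name: str) -> np.ndarray:
        for b in self.layout:
            if b.name == name:
                return self.values[b.offset : b.offset + b.length]
        raise KeyError(name)


def fuse(blocks: Sequence[tuple[str, np.ndarray]]) -> FeatureVector:
    """Concatenate named blocks into one vector, recording the layout."""
    if not blocks:
        raise ValueError("cannot fuse an empty block list")
    layout = []
    offset = 0
    for name, values in blocks:
        n = int(np.asarray(values).shape[-1])
        layout.append(BlockSlice(name=name, offset=offset, length=n))
        offset += n
    values = np.concatenate([np.asarray(v, dtype=float) for _, v in blocks])
    return FeatureVector(values=values, layout=tuple(layout))


def layout_fingerprint(layout: Sequence[BlockSlice]) -> str:
    """Stable hash identifying a block layout (model/feature contract)."""
    payload = json.dumps([(b.name, b.offset, b.length) for b in layout]).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# --------------------------------------------------------------------------
# record / dataset featurization


def _molecule_blocks(smiles: str, spec: DescriptorSpec, prefix: str) -> list[tuple[str, np.ndarray]]:
    out = []
    for recipe in spec.molecule_blocks:
        name = f"{prefix}:{_recipe_name(recipe)}"
        if recipe == "quantitative":
            out.append((name, quantitative_descriptors(smiles)))
        else:
            out.append((name, fingerprint(smiles, recipe).astype(float)))
    return out


def encode_solvent(record: SpectralRecord, spec: DescriptorSpec) -> list[tuple[str, np.ndarray]]:
    """Solvent feature blocks for one record under ``spec``."""
    if spec.solvent_encoding == "one_hot":
        name = (record.solvent_name or "").strip().lower()
        if name not in spec.solvent_vocabulary:
            raise SolventVocabularyError(f"solvent {name!r} not in vocabulary")
        vec = np.zeros(len(spec.solvent_vocabulary))
        vec[spec.solvent_vocabulary.index(name)] = 1.0
        return [("solv:one_hot", vec)]
    solvent_smiles = resolve_solvent(record)
    if spec.solvent_encoding == "quantitative_only":
        return [("solv:quantitative", quantitative_descriptors(solvent_smiles))]
    return _molecule_blocks(solvent_smiles, spec, prefix="solv")


def featurize_record(record: SpectralRecord, spec: DescriptorSpec) -> FeatureVector:
    """Fused feature vector for one record: molecule blocks then solvent blocks."""
    blocks = _molecule_blocks(record.molecule_smiles, spec, prefix="mol")
    blocks += encode_solvent(record, spec)
    return fuse(blocks)


@dataclass
class FeatureMatrix:
    """Feature matrix for a dataset; row i corresponds to record i."""

    X: np.ndarray
    layout: tuple[BlockSlice, ...]
    spec: DescriptorSpec

    @property
    def fingerprint(self) -> str:
        return layout_fingerprint(self.layout)

    def __len__(self) -> int:
        return self.X.shape[0]

    def block_slice(self, name: str) -> slice:
        for b in self.layout:
            if b.name == name:
                return slice(b.offset, b.offset + b.length)
        raise KeyError(name)

    def quantitative_columns(self) -> np.ndarray:
        """Column indices belonging to quantitative blocks (for scaling)."""
        cols: list[int] = []
        for b in self.layout:
            if b.name.endswith(":quantitative"):
                cols.extend(range(b.offset, b.offset + b.length))
        return np.asarray(cols, dtype=int)


def featurize_dataset(ds: Dataset, spec: DescriptorSpec) -> FeatureMatrix:
    """Featurize every record of ``ds`` under ``spec``.

    Identical (molecule, solvent) pairs yield identical rows.  Any record
    that fails featurization aborts with an error listing the offending
    row indices.
    """
    rows: list[np.ndarray] = []
    layout: tuple[BlockSlice, ...] | None = None
    failures: list[tuple[int, str]] = []
    for i, record in enumerate(ds):
        try:
            fv = featurize_record(record, spec)
        except (FeaturizationError, SolventVocabularyError) as exc:
            failures.append((i, str(exc)))
            continue
        if layout is None:
            layout = fv.layout
        rows.append(fv.values)
    if failures:
        raise FeaturizationError(f"failed to featurize rows: {failures}")
    assert layout is not None
    return FeatureMatrix(X=np.asarray(rows, dtype=np.float32), layout=layout, spec=spec)


# --------------------------------------------------------------------------
# scaling


@dataclass
class QuantitativeScaler:
    """Z-scores quantitative blocks only, with training-set statistics.

    Fingerprint bits are left untouched.  Fitting on training folds only
    keeps held-out folds free of information leakage.
    """

    columns: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    @classmethod
    def fit(cls, fm: FeatureMatrix, train_idx: np.ndarray | None = None) -> "QuantitativeScaler":
        cols = fm.quantitative_columns()
        scaler = cls(columns=cols)
        if cols.size == 0:
            return scaler
        X = fm.X if train_idx is None else fm.X[train_idx]
        sub = X[:, cols].astype(float)
        scaler.mean_ = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        scaler.scale_ = sd
        return scaler

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.columns.size == 0:
            return X
        out = np.array(X, dtype=np.float32, copy=True)
        out[:, self.columns] = (out[:, self.columns] - self.mean_) / self.scale_
        return out
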