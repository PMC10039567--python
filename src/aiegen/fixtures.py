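"""Synthetic solvated-luminogen datasets with a planted, recoverable
structure-property relationship.

Molecules are built by decorating a small library of pi-conjugated
rotor-like cores (tetraphenylethylene-, triphenylamine-, stilbene-,
biphenyl- and pyrazine-based scaffolds) with donor/acceptor substituents
at enumerated attachment points.  Wavelengths follow an additive model:

    lambda_abs = intercept + sum(effect x substructure count) + solvent shift
    lambda_em  = lambda_abs + Stokes base + solvent-dependent Stokes increment

with independent Gaussian noise on each observed target.  Effects act on
substructure occurrence counts, so the planted relationship is exactly
representable from fingerprint features: recovering it tests the
learning pipeline, not the photophysics.  The defaults emulate the
statistical shape of curated experimental databases — hundreds of
distinct chromophores in a small solvent panel, wavelengths mostly in
the visible 400-700 nm window, red shifts with solvent polarity — and
are not a physical model.  Noiseless ground truth is stored alongside
the observations, so every downstream module can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from rdkit import Chem

from .dataset import Dataset, SpectralRecord, canonicalize

__all__ = [
    "PlantedModel",
    "SyntheticDataset",
    "generate_molecules",
    "enumerate_decorations",
    "plant_targets",
    "make_benchmark_fixture",
    "default_planted_model",
    "split_signal_planted_model",
]


# --------------------------------------------------------------------------
# molecule generator

#: Scaffold templates; {r*} slots accept a parenthesized substituent branch
#: or an empty string (hydrogen).  Substituents use ring-closure digit 9 to
#: stay clear of the core's digits.
CORE_TEMPLATES: tuple[tuple[str, str, int], ...] = (
    ("tpe", "C(=C(c1ccccc1)c1ccc{r2}cc1)(c1ccccc1)c1ccc{r1}cc1", 2),
    ("tpa", "N(c1ccc{r3}cc1)(c1ccc{r1}cc1)c1ccc{r2}cc1", 3),
    ("stilbene", "C(=Cc1ccc{r1}cc1)c1ccc{r2}cc1", 2),
    ("biphenyl", "c1cc{r1}ccc1-c1ccc{r2}cc1", 2),
    ("tpa-thienylvinyl", "N(c1ccccc1)(c1ccccc1)c1ccc(-c2ccc(C=Cc3ccc{r1}cc3)s2)cc1", 1),
    ("pyrazine", "c1ccc(-c2nc(-c3ccccc3)c(-c3ccc{r1}cc3)nc2-c2ccc{r2}cc2)cc1", 2),
    ("phenylthiophene", "c1ccc(-c2ccc(-c3ccc{r1}cc3)s2)cc1", 1),
)

SUBSTITUENTS: tuple[tuple[str, str], ...] = (
    ("H", ""),
    ("F", "(F)"),
    ("Me", "(C)"),
    ("OMe", "(OC)"),
    ("NMe2", "(N(C)C)"),
    ("CN", "(C#N)"),
    ("NO2", "([N+](=O)[O-])"),
    ("CF3", "(C(F)(F)F)"),
    ("vinyl", "(C=C)"),
    ("thienyl", "(-c9cccs9)"),
    ("Br", "(Br)"),
    ("OH", "(O)"),
)


def enumerate_decorations() -> list[tuple[str, str, tuple[str, ...]]]:
    """All (canonical SMILES, core name, substituent names) decorations,
    in deterministic enumeration order, deduplicated by canonical SMILES."""
    seen: set[str] = set()
    out: list[tuple[str, str, tuple[str, ...]]] = []
    sub_lookup = dict(SUBSTITUENTS)
    for core_name, template, n_sites in CORE_TEMPLATES:
        for combo in product([name for name, _ in SUBSTITUENTS], repeat=n_sites):
            fields = {f"r{i + 1}": sub_lookup[name] for i, name in enumerate(combo)}
            smiles = template.format(**fields)
            canonical = canonicalize(smiles)
            if canonical in seen:
                continue
            seen.add(canonical)
            out.append((canonical, core_name, combo))
    return out


def generate_molecules(n: int, seed: int = 0) -> list[str]:
    """n unique, valid, canonical SMILES drawn from the decoration space.

    Deterministic per seed.  Raises if n exceeds the enumerable unique
    space (the error states the maximum).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    space = [smiles for smiles, _, _ in enumerate_decorations()]
    if n > len(space):
        raise ValueError(
            f"requested {n} molecules but the decoration space holds only {len(space)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(space))
    return [space[i] for i in order[:n]]


# --------------------------------------------------------------------------
# planted wavelength model


@dataclass(frozen=True)
class PlantedModel:
    """Additive ground-truth wavelength model.

    ``fragment_effects`` maps SMARTS patterns to a red shift in nm per
    occurrence; ``solvent_shifts`` shifts the absorption per solvent;
    the emission sits a Stokes term above the absorption, itself made of
    a constant plus a solvent-dependent increment (a stand-in for the
    polarity dependence of charge-transfer emission).  ``noise_sd`` is
    the sd of independent Gaussian noise added to each observed target.
    """

    intercept: float
    fragment_effects: dict[str, float]
    solvent_shifts: dict[str, float]
    stokes_base: float
    stokes_solvent: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        values = [self.intercept, self.stokes_base, *self.fragment_effects.values(),
                  *self.solvent_shifts.values(), *self.stokes_solvent.values()]
        if not np.all(np.isfinite(values)):
            raise ValueError("all planted effects must be finite")

    def true_wavelengths(self, smiles: str, solvent: str) -> tuple[float, float]:
        """Noiseless (lambda_abs, lambda_em) in nm for one record."""
        if solvent not in self.solvent_shifts:
            raise KeyError(f"solvent {solvent!r} has no planted shift")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {smiles!r}")
        lam = self.intercept + self.solvent_shifts[solvent]
        for smarts, effect in self.fragment_effects.items():
            patt = _pattern(smarts)
            lam += effect * len(mol.GetSubstructMatches(patt, uniquify=True))
        stokes = self.stokes_base + self.stokes_solvent.get(solvent, 0.0)
        return float(lam), float(lam + stokes)


_PATTERN_CACHE: dict[str, Chem.Mol] = {}


def _pattern(smarts: str) -> Chem.Mol:
    if smarts not in _PATTERN_CACHE:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"bad SMARTS {smarts!r}")
        _PATTERN_CACHE[smarts] = patt
    return _PATTERN_CACHE[smarts]


#: Default solvent panel for planted fixtures.
SOLVENT_PANEL = ("tetrahydrofuran", "ethyl acetate", "chloroform", "acetonitrile", "dimethyl sulfoxide")


def default_planted_model(noise_sd: float = 5.0) -> PlantedModel:
    """The standard fixture: substituent effects spanning the families
    all four fingerprints can see, with polarity-ordered solvent shifts."""
    return PlantedModel(
        intercept=412.0,
        fragment_effects={
            "cN(C)C": 45.0,            # dialkylamino donor
            "[N+](=O)[O-]": 50.0,      # nitro acceptor
            "C#N": 28.0,               # cyano acceptor
            "c[OX2][CH3]": 12.0,       # aryl methoxy
            "C(F)(F)F": 8.0,           # trifluoromethyl
            "cF": 4.0,                 # aryl fluoride
            "c1cccs1": 22.0,           # thiophene
            "C=C": 16.0,               # vinylene / ethylenic bridge
            "[NX3](c)(c)c": 30.0,      # triarylamine nitrogen
            "c1cnccn1": 15.0,          # pyrazine core
            "cBr": 6.0,                # aryl bromide
            "c[OX2H]": 10.0,           # phenol
        },
        solvent_shifts={
            "ethyl acetate": 2.0,
            "tetrahydrofuran": 6.0,
            "chloroform": 10.0,
            "acetonitrile": 16.0,
            "dimethyl sulfoxide": 24.0,
        },
        stokes_base=72.0,
        stokes_solvent={
            "ethyl acetate": 3.0,
            "tetrahydrofuran": 8.0,
            "chloroform": 12.0,
            "acetonitrile": 20.0,
            "dimethyl sulfoxide": 30.0,
        },
        noise_sd=noise_sd,
    )


def split_signal_planted_model(noise_sd: float = 5.0) -> PlantedModel:
    """A planted model whose signal is split across descriptor families:
    half the effects sit on short branched motifs (within a torsion or
    circular window), half on long linear motifs spanning 5-8 bonds that
    only path- or pair-type features capture as a unit.  Fusing families
    is then genuinely informative."""
    return PlantedModel(
        intercept=410.0,
        fragment_effects={
            # short-range, branched
            "cN(C)C": 40.0,
            "c[OX2][CH3]": 22.0,
            "C(F)(F)F": 18.0,
            # long-range, linear
            "C=Cc1ccc([OX2][CH3])cc1": 30.0,
            "C=Cc1ccc(C#N)cc1": 35.0,
            "c1ccc(-c2ccc([N+](=O)[O-])cc2)cc1": 30.0,
        },
        solvent_shifts={
            "ethyl acetate": 2.0,
            "tetrahydrofuran": 6.0,
            "chloroform": 10.0,
            "acetonitrile": 16.0,
            "dimethyl sulfoxide": 24.0,
        },
        stokes_base=72.0,
        stokes_solvent={
            "ethyl acetate": 3.0,
            "tetrahydrofuran": 8.0,
            "chloroform": 12.0,
            "acetonitrile": 20.0,
            "dimethyl sulfoxide": 30.0,
        },
        noise_sd=noise_sd,
    )


# --------------------------------------------------------------------------
# dataset assembly


@dataclass
class SyntheticDataset:
    """Observed dataset plus row-aligned noiseless ground truth."""

    dataset: Dataset
    truth: pd.DataFrame
    planted: PlantedModel
    seed: int

    def __len__(self) -> int:
        return len(self.dataset)


def plant_targets(
    molecules: list[str],
    solvents: list[str],
    planted: PlantedModel,
    seed: int = 0,
) -> SyntheticDataset:
    """Build one record per (molecule, solvent) pair with planted targets.

    Observed wavelengths are the noiseless truth plus independent
    Gaussian noise of sd ``planted.noise_sd`` per target; the truth
    table aligns row for row with the records.
    """
    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []
    for smiles in molecules:
        for solvent in solvents:
            t_abs, t_em = planted.true_wavelengths(smiles, solvent)
            o_abs = t_abs + rng.normal(0.0, planted.noise_sd)
            o_em = t_em + rng.normal(0.0, planted.noise_sd)
            records.append(
                SpectralRecord(
                    molecule_smiles=smiles,
                    solvent_name=solvent,
                    lambda_abs=float(o_abs),
                    lambda_em=float(o_em),
                    source_id="synthetic",
                )
            )
            truth_rows.append(
                {
                    "molecule_smiles": smiles,
                    "solvent_name": solvent,
                    "true_lambda_abs_nm": t_abs,
                    "true_lambda_em_nm": t_em,
                }
            )
    ds = Dataset(records=records, provenance={"generator": "aiegen.fixtures", "seed": seed})
    return SyntheticDataset(
        dataset=ds, truth=pd.DataFrame(truth_rows), planted=planted, seed=seed
    )


PRESET_SIZES = {"small": (60, 3), "default": (600, 5)}


def make_benchmark_fixture(
    preset: str = "default",
    seed: int = 0,
    noise_sd: float = 5.0,
    planted: PlantedModel | None = None,
) -> SyntheticDataset:
    """The standard synthetic benchmark.

    ``small`` = 60 molecules x 3 solvents (fast tests); ``default`` =
    600 molecules x 5 solvents, emission wavelengths mostly within the
    visible 400-700 nm window.  All randomness (molecule draw, noise)
    flows from ``seed`` via stream splitting.
    """
    try:
        n_mols, n_solvents = PRESET_SIZES[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESET_SIZES)}") from None
    mol_seed, noise_seed = (int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2))
    molecules = generate_molecules(n_mols, seed=mol_seed)
    model = planted if planted is not None else default_planted_model(noise_sd=noise_sd)
    return plant_targets(molecules, list(SOLVENT_PANEL[:n_solvents]), model, seed=noise_seed)
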