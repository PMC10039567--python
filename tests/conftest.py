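"""Shared fixtures: small molecules and synthetic datasets.

Everything is generated programmatically; heavyweight objects are
session-scoped so the suite featurizes and simulates once.
"""

from __future__ import annotations

import pytest

from aiegen.featurize import solvent_table
from aiegen.fixtures import make_benchmark_fixture


def small_molecule_catalogue() -> list[str]:
    """All packaged solvent structures with <= 8 heavy atoms, plus a few
    classic hydrocarbons exercising degenerate fingerprint cases."""
    from rdkit import Chem

    packaged = [
        smi
        for smi in solvent_table()["smiles"]
        if Chem.MolFromSmiles(smi).GetNumHeavyAtoms() <= 8
    ]
    extras = ["C", "CC", "CCC", "CCCC", "CC(C)C", "C=CC=C", "CC=O", "c1ccsc1", "CC#N"]
    seen: set[str] = set()
    out = []
    for smi in packaged + extras:
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        if canonical not in seen:
            seen.add(canonical)
            out.append(smi)
    return out


@pytest.fixture(scope="session")
def tiny_molecules() -> list[str]:
    return small_molecule_catalogue()


@pytest.fixture(scope="session")
def small_fixture():
    """60 molecules x 3 solvents, noise sd 5 nm."""
    return make_benchmark_fixture("small", seed=11)


@pytest.fixture(scope="session")
def small_noiseless_fixture():
    """Same shape as small_fixture but observed == truth exactly."""
    return make_benchmark_fixture("small", seed=13, noise_sd=0.0)
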