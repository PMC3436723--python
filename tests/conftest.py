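"""Shared fixtures: small seeded corpora and a SMILES->record helper."""

import pytest
from rdkit import Chem

from nplikeness.chem_io import from_rdkit
from nplikeness.fixtures import (
    FixtureConfig,
    generate_np_like,
    generate_synthetic_like,
)


def record_from_smiles(smiles: str, uuid: str = "test"):
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"bad test SMILES: {smiles}"
    return from_rdkit(mol, uuid=uuid)


@pytest.fixture
def rec():
    return record_from_smiles


@pytest.fixture(scope="session")
def np_corpus():
    """100 NP-like molecules, fixed seed."""
    return generate_np_like(FixtureConfig(seed=11, n_np=100, n_sm=0))


@pytest.fixture(scope="session")
def sm_corpus():
    """100 synthetic-like molecules, fixed seed, no metals/counter-ions."""
    return generate_synthetic_like(
        FixtureConfig(seed=11, n_np=0, n_sm=100,
                      counterion_fraction=0.0, metal_fraction=0.0)
    )


@pytest.fixture(scope="session")
def mixed_50(np_corpus, sm_corpus):
    """50 structurally varied molecules for round-trip style properties."""
    return np_corpus[:25] + sm_corpus[:25]
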