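"""Shared fixtures: small drug sets, graphs and a panel of real drug SMILES."""

from __future__ import annotations

import numpy as np
import pytest

from lamfp.data_model import Drug, DrugSet, InteractionGraph

# Twenty well-known small molecules (non-canonical forms are fine; the
# string measures act on the text as given).
REAL_DRUG_SMILES = [
    ("aspirin", "CC(=O)OC1=CC=CC=C1C(=O)O"),
    ("paracetamol", "CC(=O)NC1=CC=C(C=C1)O"),
    ("ibuprofen", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O"),
    ("caffeine", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("ethanol", "CCO"),
    ("glycerol", "OCC(O)CO"),
    ("urea", "NC(N)=O"),
    ("acetone", "CC(C)=O"),
    ("acetic_acid", "CC(=O)O"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("benzoic_acid", "OC(=O)c1ccccc1"),
    ("salicylic_acid", "OC(=O)c1ccccc1O"),
    ("pyridine", "c1ccncc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("cyclohexane", "C1CCCCC1"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
]


@pytest.fixture(scope="session")
def real_drugs() -> DrugSet:
    return DrugSet(Drug(name, smi) for name, smi in REAL_DRUG_SMILES)


@pytest.fixture()
def toy_drugs() -> DrugSet:
    return DrugSet(
        [
            Drug("a", "CCO"),
            Drug("b", "CCN"),
            Drug("c", "CCCO"),
            Drug("d", "OCCN"),
            Drug("e", "CCCCC"),
            Drug("f", "NCCO"),
        ]
    )


@pytest.fixture()
def toy_graph(toy_drugs) -> InteractionGraph:
    return InteractionGraph(
        toy_drugs, [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("e", "f")]
    )


def random_chain_smiles(rng: np.random.Generator, max_len: int = 20) -> str:
    """Random parseable heteroatom-chain SMILES over C/N/O."""
    length = int(rng.integers(1, max_len + 1))
    return "".join(str(rng.choice(["C", "N", "O"], p=[0.7, 0.15, 0.15])) for _ in range(length))
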