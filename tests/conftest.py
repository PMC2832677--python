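import numpy as np
import pytest

import ppiprofiler as pp
from ppiprofiler.fixtures import DeckSpec, make_deck


@pytest.fixture(scope="session")
def aspirin():
    return pp.parse_smiles("CC(=O)Oc1ccccc1C(=O)O aspirin")


@pytest.fixture(scope="session")
def benzene():
    return pp.parse_smiles("c1ccccc1 benzene")


@pytest.fixture(scope="session")
def methane():
    return pp.parse_smiles("C methane")


@pytest.fixture(scope="session")
def small_deck():
    """24 synthetic molecules with known multiple-bond counts + ground truth."""
    return make_deck(DeckSpec(n=24, seed=11))


@pytest.fixture(scope="session")
def wide_deck():
    """60 molecules spanning multiple-bond counts 0..30 (graph descriptors only)."""
    return make_deck(DeckSpec(n=60, b_range=(0, 30), seed=5))


def random_point_molecule(rng: np.random.Generator, n_atoms: int = 20) -> pp.Molecule:
    """Disconnected point set with random masses/coordinates for RDF oracles."""
    atoms = [
        pp.Atom(element="C", mass=float(rng.uniform(1.0, 35.0)),
                coords=rng.uniform(-6.0, 6.0, size=3))
        for _ in range(n_atoms)
    ]
    return pp.Molecule(id="points", atoms=atoms, bonds=[])
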