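"""Descriptor values against closed forms, hand counts and brute-force oracles."""

import math

import numpy as np
import pytest
from rdkit import Chem

import ppiprofiler as pp
from ppiprofiler.chemgraph import Molecule
from ppiprofiler.descriptors import CARBON_MASS, RDF070M, RdfParams
from ppiprofiler.errors import DescriptorError
from conftest import random_point_molecule


def strip_hydrogens(mol: Molecule) -> Molecule:
    return Molecule.from_rdkit(Chem.RemoveHs(mol.to_rdkit()), mol_id=mol.id)


class TestUnsaturation:
    @pytest.mark.parametrize("smiles,expected_b", [
        ("CC(=O)Oc1ccccc1C(=O)O", 8),   # aspirin: 6 aromatic + 2 double
        ("CC", 0),                       # ethane
        ("C#C", 2),                      # ethyne: pi* sum 5, B 3
        ("c1ccccc1", 6),                 # benzene
        ("C=CC=C", 2),                   # butadiene
    ])
    def test_multiple_bond_count(self, smiles, expected_b):
        mol = pp.parse_smiles(smiles)
        assert pp.multiple_bond_count(mol) == expected_b

    def test_ui_aspirin_two_decimals(self, aspirin):
        assert round(pp.unsaturation_index(aspirin), 2) == 3.17

    def test_ui_saturated_alkane_is_zero(self):
        assert pp.unsaturation_index(pp.parse_smiles("CCCCCCCC")) == 0.0

    def test_ui_benzene(self, benzene):
        assert pp.unsaturation_index(benzene) == pytest.approx(math.log2(7), abs=1e-9)

    def test_ui_equals_log2_of_count(self, small_deck):
        records, _ = small_deck
        for _, smi in records[:10]:
            mol = pp.parse_smiles(smi)
            b = pp.multiple_bond_count(mol)
            assert pp.unsaturation_index(mol) == pytest.approx(math.log2(1 + b))

    @pytest.mark.parametrize("smiles", [
        "CC(=O)Oc1ccccc1C(=O)O", "c1ccccc1", "C#N", "O=C=O", "CC(C)=CC",
    ])
    def test_ui_hydrogen_invariance(self, smiles):
        mol = pp.parse_smiles(smiles)
        assert pp.unsaturation_index(strip_hydrogens(mol)) == \
            pytest.approx(pp.unsaturation_index(mol))

    def test_threshold_to_multiple_bond_correspondence(self):
        assert pp.min_multiple_bonds_for_ui(3.95) == 15
        assert pp.min_multiple_bonds_for_ui(4.13) == 17


def rdf_bruteforce(mol: Molecule, params: RdfParams) -> float:
    """Independent double-loop oracle for the RDF descriptor."""
    total = 0.0
    atoms = [a for a in mol.atoms if params.include_h or not a.is_hydrogen]
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            r_ij = math.dist(atoms[i].coords, atoms[j].coords)
            total += atoms[i].mass * atoms[j].mass * math.exp(
                -params.b_smooth * (params.radius_r - r_ij) ** 2)
    return params.f * total


def two_atom_molecule(distance: float, mass: float = CARBON_MASS) -> Molecule:
    return Molecule(id="pair", atoms=[
        pp.Atom("C", mass, coords=[0.0, 0.0, 0.0]),
        pp.Atom("C", mass, coords=[distance, 0.0, 0.0]),
    ], bonds=[])


class TestRdf:
    def test_single_atom_zero(self):
        mol = Molecule(id="one", atoms=[pp.Atom("C", 12.011, coords=[0, 0, 0])], bonds=[])
        assert pp.rdf_descriptor(mol, RDF070M) == 0.0

    def test_pair_at_radius_closed_form(self):
        # 0.007 * 12.011^2 at the exact radius
        val = pp.rdf_descriptor(two_atom_molecule(7.0), RDF070M)
        assert val == pytest.approx(0.007 * 12.011**2, rel=1e-12)
        assert val == pytest.approx(1.0098, abs=5e-5)

    def test_pair_gaussian_falloff(self):
        # 0.1 Å off the radius: factor exp(-100 * 0.01) = e^-1
        at_r = pp.rdf_descriptor(two_atom_molecule(7.0), RDF070M)
        off_r = pp.rdf_descriptor(two_atom_molecule(7.1), RDF070M)
        assert off_r == pytest.approx(at_r * math.exp(-1.0), rel=1e-9)
        assert off_r == pytest.approx(0.3715, abs=5e-5)

    def test_monotone_toward_radius(self):
        vals = [pp.rdf_descriptor(two_atom_molecule(d), RDF070M) for d in (6.4, 6.7, 7.0)]
        assert vals[0] < vals[1] < vals[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mol = random_point_molecule(rng, n_atoms=20)
        for params in (RDF070M, RdfParams(radius_r=8.0)):
            assert pp.rdf_descriptor(mol, params) == \
                pytest.approx(rdf_bruteforce(mol, params), abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(42)
        mol = random_point_molecule(rng, n_atoms=15)
        base = pp.rdf_descriptor(mol, RDF070M)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-50, 50, size=3)
        moved = Molecule(id="moved", atoms=[
            pp.Atom(a.element, a.mass, coords=q @ a.coords + shift) for a in mol.atoms
        ], bonds=[])
        assert pp.rdf_descriptor(moved, RDF070M) == pytest.approx(base, rel=1e-9)

    def test_atom_reorder_invariance(self):
        rng = np.random.default_rng(7)
        mol = random_point_molecule(rng, n_atoms=12)
        perm = rng.permutation(12)
        shuffled = Molecule(id="perm", atoms=[mol.atoms[i] for i in perm], bonds=[])
        assert pp.rdf_descriptor(shuffled, RDF070M) == \
            pytest.approx(pp.rdf_descriptor(mol, RDF070M), rel=1e-12)

    def test_missing_coordinates_error_names_molecule(self, aspirin):
        with pytest.raises(DescriptorError, match="aspirin"):
            pp.rdf_descriptor(aspirin, RDF070M)

    def test_include_h_flag_changes_value(self, aspirin):
        m3 = pp.embed_3d(aspirin, seed=42)
        with_h = pp.rdf_descriptor(m3, RdfParams(radius_r=7.0, include_h=True))
        without = pp.rdf_descriptor(m3, RdfParams(radius_r=7.0, include_h=False))
        assert with_h != without


class TestAts8m:
    def test_nonane_single_lag8_pair(self):
        assert pp.ats8m(pp.parse_smiles("CCCCCCCCC nonane")) == pytest.approx(1.0)

    def test_methane_zero(self, methane):
        assert pp.ats8m(methane) == 0.0

    def test_decane_two_lag8_pairs(self):
        assert pp.ats8m(pp.parse_smiles("CCCCCCCCCC decane")) == pytest.approx(2.0)

    def test_hydrogens_do_not_contribute(self):
        # topological ATS is a heavy-atom quantity
        mol = pp.parse_smiles("CCCCCCCCC nonane")
        assert pp.ats8m(strip_hydrogens(mol)) == pytest.approx(pp.ats8m(mol))


class TestBondCounts:
    @pytest.mark.parametrize("smiles,expected", [
        ("c1ccccc1", (6, 6, 1)),                 # benzene
        ("CC(=O)Oc1ccccc1C(=O)O", (8, 6, 1)),    # aspirin
        ("C1CCCCC1", (0, 0, 0)),                 # cyclohexane
        ("c1ccncc1", (6, 6, 0)),                 # pyridine: aromatic but not carbocyclic
        ("C#CC=C", (2, 0, 0)),                   # one triple + one double
    ])
    def test_counts(self, smiles, expected):
        assert pp.bond_counts(pp.parse_smiles(smiles)) == expected

    def test_ui_tracks_multiple_bond_count_on_deck(self, wide_deck):
        records, _ = wide_deck
        ui, nbm = [], []
        for _, smi in records:
            mol = pp.parse_smiles(smi)
            ui.append(pp.unsaturation_index(mol))
            nbm.append(pp.bond_counts(mol)[0])
        r = np.corrcoef(ui, nbm)[0, 1]
        assert r > 0.9


class TestPhyschem:
    def test_aspirin_profile(self, aspirin):
        p = pp.physchem_profile(aspirin)
        assert p.MW == pytest.approx(180.2, abs=0.05)
        assert p.HBD == 1
        assert p.HBA == 4
        assert p.TPSA == pytest.approx(63.6, abs=0.05)
        assert p.nROT + p.nRIG == 13  # heavy-atom bond count is conserved

    def test_methane_profile(self, methane):
        p = pp.physchem_profile(methane)
        assert p.MW == pytest.approx(16.04, abs=0.01)
        assert (p.TPSA, p.HBD, p.HBA, p.nROT, p.nRIG) == (0.0, 0, 0, 0, 0)

    def test_pluggable_logp_estimator(self, aspirin):
        p = pp.physchem_profile(aspirin, logp_estimator=lambda m: -1.23)
        assert p.logP == -1.23


class TestDescriptorTable:
    def test_row_has_all_names_and_is_finite(self, aspirin):
        row = pp.descriptor_row(aspirin, seed=42)
        from ppiprofiler.descriptors import DESCRIPTOR_NAMES
        for name in DESCRIPTOR_NAMES:
            assert np.isfinite(row[name])
        assert row["UI"] == pytest.approx(3.17, abs=0.005)

    def test_input_coordinates_take_priority(self, aspirin):
        m3 = pp.embed_3d(aspirin, seed=123)
        row_a = pp.descriptor_row(m3, seed=1)
        row_b = pp.descriptor_row(m3, seed=2)  # seed ignored: coords present
        assert row_a["RDF070m"] == row_b["RDF070m"]
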