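"""Molecular graph model and file I/O.

The package works on a light-weight, hydrogen-explicit molecular graph:
atoms carry their chemical symbol, standard atomic weight and (optionally)
3D coordinates; bonds carry one of four orders (single, double, triple,
aromatic).  Aromatic rings are always represented with explicit aromatic
bond order rather than a Kekulé alternation — the unsaturation index counts
every aromatic bond as a multiple bond, which a Kekulé representation would
break (benzene must contribute six multiple bonds, not three).

RDKit does the heavy lifting (SMILES/SDF parsing, aromaticity perception,
distance-geometry embedding); :class:`Molecule` is the stable surface the
descriptor and profiling code is written against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import EmbeddingError, DataError, RecordError

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # RDKit is chatty on stderr; we log ourselves


class BondOrder(Enum):
    """Bond order with its conventional numeric value π*.

    Single bonds count 1, double and aromatic bonds 2, triple bonds 3.
    The aromatic value of 2 is what makes the unsaturation index treat every
    aromatic bond as one multiple bond.
    """

    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"

    @property
    def pi_star(self) -> int:
        return _PI_STAR[self]


_PI_STAR = {
    BondOrder.SINGLE: 1,
    BondOrder.DOUBLE: 2,
    BondOrder.AROMATIC: 2,
    BondOrder.TRIPLE: 3,
}

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: BondOrder.SINGLE,
    Chem.BondType.DOUBLE: BondOrder.DOUBLE,
    Chem.BondType.TRIPLE: BondOrder.TRIPLE,
    Chem.BondType.AROMATIC: BondOrder.AROMATIC,
}
_TO_RDKIT_ORDER = {
    BondOrder.SINGLE: Chem.BondType.SINGLE,
    BondOrder.DOUBLE: Chem.BondType.DOUBLE,
    BondOrder.TRIPLE: Chem.BondType.TRIPLE,
    BondOrder.AROMATIC: Chem.BondType.AROMATIC,
}


@dataclass
class Atom:
    """One atom: element symbol, standard atomic weight (amu), optional 3D position (Å)."""

    element: str
    mass: float
    coords: np.ndarray | None = None
    is_hydrogen: bool = False

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atomic mass must be positive, got {self.mass}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
                raise ValueError("coords must be a finite 3-vector")


@dataclass
class Bond:
    """An edge between two atom indices with a :class:`BondOrder`."""

    i: int
    j: int
    order: BondOrder

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond endpoints must be distinct")


@dataclass
class Molecule:
    """Hydrogen-explicit molecular graph.

    ``B = len(mol.bonds)`` is the total bond count of the H-explicit graph,
    the quantity the unsaturation index subtracts from the bond-order sum.
    """

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    source: str = ""
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if not a.is_hydrogen)

    @property
    def has_coords(self) -> bool:
        return bool(self.atoms) and all(a.coords is not None for a in self.atoms)

    def coords_array(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array; raises if any atom lacks coordinates."""
        if not self.has_coords:
            raise DataError(f"molecule {self.id!r} has no 3D coordinates")
        return np.vstack([a.coords for a in self.atoms])

    @classmethod
    def from_rdkit(cls, rdmol: Chem.Mol, mol_id: str = "", source: str = "") -> "Molecule":
        """Build from a sanitized, hydrogen-explicit RDKit mol."""
        conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
        atoms = []
        for a in rdmol.GetAtoms():
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(a.GetIdx())
                xyz = np.array([p.x, p.y, p.z])
            atoms.append(
                Atom(
                    element=a.GetSymbol(),
                    mass=a.GetMass(),
                    coords=xyz,
                    is_hydrogen=a.GetAtomicNum() == 1,
                )
            )
        bonds = [
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RDKIT_ORDER[b.GetBondType()])
            for b in rdmol.GetBonds()
        ]
        return cls(id=mol_id, atoms=atoms, bonds=bonds, source=source, _rdmol=rdmol)

    def to_rdkit(self) -> Chem.Mol:
        """The underlying RDKit mol (reconstructed from the graph if needed)."""
        if self._rdmol is None:
            self._rdmol = self._build_rdmol()
        return self._rdmol

    def _build_rdmol(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            rw.AddAtom(ra)
        for b in self.bonds:
            rw.AddBond(b.i, b.j, _TO_RDKIT_ORDER[b.order])
            if b.order is BondOrder.AROMATIC:
                rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
                rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
                rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        if self.has_coords:
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, a in enumerate(self.atoms):
                conf.SetAtomPosition(i, a.coords.tolist())
            mol.AddConformer(conf)
        return mol


def _largest_fragment(rdmol: Chem.Mol, mol_id: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return rdmol
    best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), f.GetNumAtoms()))
    log.info(
        "molecule %r: %d fragments, keeping largest (%d heavy atoms)",
        mol_id, len(frags), best.GetNumHeavyAtoms(),
    )
    return best


def parse_smiles(line: str, line_number: int | None = None) -> Molecule:
    """Parse one ``SMILES [name]`` record into a hydrogen-explicit Molecule.

    Aromaticity is perceived by the parser (aromatic rings carry aromatic
    bond order) and explicit hydrogens are added.  Multi-fragment records
    (salts) keep only the largest covalent component.
    """
    parts = line.split(None, 1)
    if not parts:
        raise RecordError("empty SMILES record", line_number)
    smiles = parts[0]
    name = parts[1].strip() if len(parts) > 1 else smiles
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise RecordError(f"unparsable SMILES {smiles!r}", line_number)
    rdmol = _largest_fragment(rdmol, name)
    Chem.SanitizeMol(rdmol)
    rdmol = Chem.AddHs(rdmol)
    return Molecule.from_rdkit(rdmol, mol_id=name, source="smiles")


def read_smiles(path: str | Path, on_error: str = "raise") -> Iterator[Molecule]:
    """Stream molecules from a SMILES file (one record per line, ``#`` comments).

    ``on_error='skip'`` logs and skips unparsable records instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                yield parse_smiles(line, line_number=lineno)
            except RecordError:
                if on_error == "skip":
                    log.warning("skipping unparsable record at line %d of %s", lineno, path)
                    continue
                raise


def read_sdf(path: str | Path, on_error: str = "raise") -> Iterator[Molecule]:
    """Stream molecules from a V2000 SDF.

    3D coordinates are preserved when present; aromaticity is re-perceived
    from the ring system so Kekulé-encoded aromatic rings come out with
    aromatic bond order.  Hydrogens are made explicit (placed from the
    existing geometry when the record is 3D).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            if on_error == "skip":
                log.warning("skipping malformed SDF record %d of %s", idx, path)
                continue
            raise RecordError(f"malformed SDF record in {path}", idx)
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"record_{idx}"
        name = name or f"record_{idx}"
        rdmol = _largest_fragment(rdmol, name)
        Chem.SanitizeMol(rdmol)
        has_conf = rdmol.GetNumConformers() > 0
        rdmol = Chem.AddHs(rdmol, addCoords=has_conf)
        yield Molecule.from_rdkit(rdmol, mol_id=name, source="sdf")


def write_smiles(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write canonical SMILES, one ``SMILES name`` record per line."""
    with open(path, "w") as fh:
        for m in mols:
            smi = Chem.MolToSmiles(Chem.RemoveHs(m.to_rdkit()))
            fh.write(f"{smi} {m.id}\n")


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write V2000 SDF; coordinates round-trip to 4 decimals (file precision)."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rdmol = Chem.Mol(m.to_rdkit())
            rdmol.SetProp("_Name", m.id)
            if rdmol.GetNumConformers() == 0:
                AllChem.Compute2DCoords(rdmol)
            writer.write(rdmol)
    finally:
        writer.close()


def embed_3d(mol: Molecule, seed: int = 42) -> Molecule:
    """Generate one deterministic low-energy conformer.

    Distance-geometry embedding (ETKDG) followed by MMFF94 relaxation (UFF
    fallback for atoms outside MMFF coverage).  The same molecule and seed
    always give the same coordinates; different seeds may give different
    conformers, which matters for conformer-dependent descriptors such as
    the radial distribution function family.
    """
    rdmol = Chem.Mol(mol.to_rdkit())
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_id = AllChem.EmbedMolecule(rdmol, params)
    if conf_id < 0:
        raise EmbeddingError(f"3D embedding failed for molecule {mol.id!r}")
    try:
        if AllChem.MMFFHasAllMoleculeParams(rdmol):
            AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(rdmol, maxIters=500)
    except Exception as exc:  # pragma: no cover - rare force-field failures
        raise EmbeddingError(f"force-field relaxation failed for {mol.id!r}: {exc}")
    return Molecule.from_rdkit(rdmol, mol_id=mol.id, source=mol.source)


def read_any(path: str | Path, on_error: str = "raise") -> Iterator[Molecule]:
    """Dispatch on file extension: ``.sdf``/``.sd`` → SDF, anything else → SMILES."""
    suffix = Path(path).suffix.lower()
    if suffix in {".sdf", ".sd", ".mol"}:
        return read_sdf(path, on_error=on_error)
    return read_smiles(path, on_error=on_error)


def write_any(mols: Sequence[Molecule], path: str | Path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in {".sdf", ".sd", ".mol"}:
        write_sdf(mols, path)
    else:
        write_smiles(mols, path)
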