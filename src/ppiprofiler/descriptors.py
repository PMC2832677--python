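"""Molecular descriptors used by the PPI-inhibitor profile.

Two descriptors carry the profile itself:

* **UI**, the unsaturation index: ``UI = log2(1 + b)`` where *b* is the
  multiple-bond count, ``b = Σ_bonds π* − B`` with conventional bond orders
  π* (single 1, double/aromatic 2, triple 3) and B the total bond count of
  the hydrogen-explicit graph.  Every single bond contributes π* = 1 and is
  cancelled by B, so *b* depends only on the multiple bonds and UI is
  invariant to explicit-hydrogen addition.

* **RDF(r)m**, a mass-weighted radial distribution function evaluated at a
  single sphere radius r:

      RDF(r) = f · Σ_{i<j} A_i A_j exp(−B_s (r − r_ij)²)

  with A the atomic weights in amu, r_ij the Euclidean inter-atomic
  distance in Å, scaling factor f = 0.007 and smoothing factor
  B_s = 100 Å⁻².  RDF070m (r = 7 Å) is sensitive to branched, star-, L- or
  T-shaped molecules that place heavy atom pairs ~7 Å apart.

The remaining functions compute supporting descriptors: the Broto–Moreau
autocorrelation ATS8m, simple bond counts (nBM/nAB/nBnz) and the seven
physico-chemical properties used by the drug-likeness filter and the PCA
overlap check (MW, logP, TPSA, HBD, HBA, nROT, nRIG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, Lipinski, rdMolDescriptors
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist

from .chemgraph import BondOrder, Molecule, embed_3d
from .errors import DescriptorError

CARBON_MASS = 12.011  # standard atomic weight of carbon, amu

#: Column order of a full descriptor row / table.
DESCRIPTOR_NAMES = [
    "UI", "RDF070m", "RDF080m", "ATS8m", "nBM", "nAB", "nBnz",
    "MW", "logP", "TPSA", "HBD", "HBA", "nROT", "nRIG",
]

PHYSCHEM_NAMES = ["MW", "logP", "TPSA", "HBD", "HBA", "nROT", "nRIG"]


@dataclass(frozen=True)
class RdfParams:
    """Constants of the radial distribution function descriptor.

    f : overall scaling factor (default 0.007 ≈ 1/12.011², which puts
        mass-weighted values on the scale the profile thresholds assume).
    b_smooth : Gaussian smoothing factor in Å⁻² (default 100).
    radius_r : sphere radius in Å (7.0 for RDF070m, 8.0 for RDF080m).
    weight : atomic property scheme; only "mass" is shipped.
    include_h : whether explicit hydrogens contribute to the atom pairs.
    """

    f: float = 0.007
    b_smooth: float = 100.0
    radius_r: float = 7.0
    weight: str = "mass"
    include_h: bool = True

    def __post_init__(self):
        if self.f <= 0 or self.b_smooth <= 0 or self.radius_r <= 0:
            raise ValueError("RdfParams constants must be positive")
        if self.weight != "mass":
            raise ValueError(f"unsupported weighting scheme {self.weight!r}")


RDF070M = RdfParams(radius_r=7.0)
RDF080M = RdfParams(radius_r=8.0)


def multiple_bond_count(mol: Molecule) -> int:
    """Multiple-bond count ``b = Σ π* − B``.

    Equals n_double + n_aromatic + 2·n_triple; invariant to explicit-H
    addition because every H bond contributes π* = 1, cancelled by B.
    """
    return sum(b.order.pi_star for b in mol.bonds) - mol.n_bonds


def unsaturation_index(mol: Molecule) -> float:
    """Unsaturation index ``UI = log2(1 + b)``; 0 iff the molecule is saturated."""
    return math.log2(1 + multiple_bond_count(mol))


def min_multiple_bonds_for_ui(ui_threshold: float) -> int:
    """Smallest integer multiple-bond count b with log2(1+b) ≥ the threshold.

    Maps the profile's float UI thresholds back to a discrete number of
    privileged multiple bonds (3.95 → 15, 4.13 → 17).
    """
    return math.ceil(2.0 ** ui_threshold - 1.0)


def rdf_descriptor(mol: Molecule, params: RdfParams = RDF070M) -> float:
    """Mass-weighted radial distribution function at ``params.radius_r``.

    Requires 3D coordinates on every atom.  The value is a sum over
    unordered atom pairs and is therefore invariant under rigid motion of
    the coordinates and under atom reordering.
    """
    if not mol.has_coords:
        raise DescriptorError(
            f"molecule {mol.id!r}: RDF descriptor requires 3D coordinates"
        )
    keep = [i for i, a in enumerate(mol.atoms) if params.include_h or not a.is_hydrogen]
    if len(keep) < 2:
        return 0.0
    coords = mol.coords_array()[keep]
    masses = np.array([mol.atoms[i].mass for i in keep])
    d = pdist(coords)  # unordered pairs, same (i<j) order as triu_indices
    w = np.outer(masses, masses)[np.triu_indices(len(masses), k=1)]
    return float(params.f * np.sum(w * np.exp(-params.b_smooth * (params.radius_r - d) ** 2)))


def _heavy_topological_distances(mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
    """Shortest-path (bond count) matrix over the heavy-atom graph, plus masses."""
    heavy = [i for i, a in enumerate(mol.atoms) if not a.is_hydrogen]
    index = {atom: k for k, atom in enumerate(heavy)}
    n = len(heavy)
    rows, cols = [], []
    for b in mol.bonds:
        if b.i in index and b.j in index:
            rows += [index[b.i], index[b.j]]
            cols += [index[b.j], index[b.i]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True)
    masses = np.array([mol.atoms[i].mass for i in heavy])
    return dist, masses


def ats8m(mol: Molecule, lag: int = 8, geometric: bool = False) -> float:
    """Broto–Moreau autocorrelation at lag 8, weighted by carbon-scaled mass.

    Default is the standard topological form: sum over heavy-atom pairs at
    bond-path distance ``lag`` of (m_i/12.011)·(m_j/12.011).  With
    ``geometric=True`` the pair set is instead atoms whose Euclidean
    distance is within 0.5 Å of ``lag`` (a Dirac window at 8 Å), which
    requires 3D coordinates.
    """
    if geometric:
        if not mol.has_coords:
            raise DescriptorError(f"molecule {mol.id!r}: geometric ATS needs coordinates")
        heavy = [i for i, a in enumerate(mol.atoms) if not a.is_hydrogen]
        coords = mol.coords_array()[heavy]
        masses = np.array([mol.atoms[i].mass for i in heavy]) / CARBON_MASS
        if len(heavy) < 2:
            return 0.0
        d = pdist(coords)
        w = np.outer(masses, masses)[np.triu_indices(len(masses), k=1)]
        return float(np.sum(w[np.abs(d - lag) <= 0.5]))
    dist, masses = _heavy_topological_distances(mol)
    if dist.size == 0:
        return 0.0
    scaled = masses / CARBON_MASS
    iu = np.triu_indices_from(dist, k=1)
    at_lag = dist[iu] == lag
    return float(np.sum(scaled[iu[0][at_lag]] * scaled[iu[1][at_lag]]))


def bond_counts(mol: Molecule) -> tuple[int, int, int]:
    """(nBM, nAB, nBnz): multiple bonds, aromatic bonds, benzene-like rings.

    nBM counts each double, aromatic and triple bond once; nBnz counts
    six-membered all-carbon aromatic rings.
    """
    n_double = sum(1 for b in mol.bonds if b.order is BondOrder.DOUBLE)
    n_arom = sum(1 for b in mol.bonds if b.order is BondOrder.AROMATIC)
    n_triple = sum(1 for b in mol.bonds if b.order is BondOrder.TRIPLE)
    rdmol = mol.to_rdkit()
    n_bnz = 0
    for ring in rdmol.GetRingInfo().AtomRings():
        if len(ring) == 6 and all(
            rdmol.GetAtomWithIdx(i).GetSymbol() == "C"
            and rdmol.GetAtomWithIdx(i).GetIsAromatic()
            for i in ring
        ):
            n_bnz += 1
    return n_double + n_arom + n_triple, n_arom, n_bnz


class PhyschemProfile(NamedTuple):
    MW: float
    logP: float
    TPSA: float
    HBD: int
    HBA: int
    nROT: int
    nRIG: int


def physchem_profile(
    mol: Molecule,
    logp_estimator: Callable[[object], float] | None = None,
) -> PhyschemProfile:
    """The seven physico-chemical properties used for drug-likeness and PCA.

    MW is the sum of atomic masses including hydrogens; HBD/HBA are the
    N–H/O–H donor and N+O acceptor counts; nROT counts non-ring single
    bonds between non-terminal heavy atoms with amide C–N excluded; nRIG is
    the heavy-atom bond count minus nROT.  logP defaults to the Crippen
    atom-contribution estimator and is pluggable.
    """
    # standard property definitions are heavy-atom-graph notions; explicit Hs
    # would make e.g. hydroxyl oxygens look non-terminal to the nROT pattern
    rdmol = Chem.RemoveHs(mol.to_rdkit())
    logp = (logp_estimator or Crippen.MolLogP)(rdmol)
    n_rot = Lipinski.NumRotatableBonds(rdmol)
    n_heavy_bonds = sum(
        1 for b in mol.bonds
        if not mol.atoms[b.i].is_hydrogen and not mol.atoms[b.j].is_hydrogen
    )
    return PhyschemProfile(
        MW=RDDescriptors.MolWt(rdmol),
        logP=float(logp),
        TPSA=rdMolDescriptors.CalcTPSA(rdmol),
        HBD=Lipinski.NumHDonors(rdmol),
        HBA=Lipinski.NOCount(rdmol),
        nROT=n_rot,
        nRIG=n_heavy_bonds - n_rot,
    )


@dataclass
class DescriptorRow:
    """One molecule's named descriptor values (all finite)."""

    id: str
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise DescriptorError(f"molecule {self.id!r}: missing descriptor {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.values


def descriptor_row(
    mol: Molecule,
    seed: int = 42,
    include_h: bool = True,
    logp_estimator: Callable[[object], float] | None = None,
) -> DescriptorRow:
    """Full descriptor row for one molecule, embedding a 3D conformer if needed.

    Input 3D coordinates take priority; otherwise a deterministic conformer
    is generated from ``seed`` for the RDF descriptors.
    """
    if not mol.has_coords:
        mol3d = embed_3d(mol, seed=seed)
    else:
        mol3d = mol
    rdf_p70 = RdfParams(radius_r=7.0, include_h=include_h)
    rdf_p80 = RdfParams(radius_r=8.0, include_h=include_h)
    nbm, nab, nbnz = bond_counts(mol)
    phys = physchem_profile(mol, logp_estimator=logp_estimator)
    values = {
        "UI": unsaturation_index(mol),
        "RDF070m": rdf_descriptor(mol3d, rdf_p70),
        "RDF080m": rdf_descriptor(mol3d, rdf_p80),
        "ATS8m": ats8m(mol),
        "nBM": float(nbm),
        "nAB": float(nab),
        "nBnz": float(nbnz),
        **{k: float(v) for k, v in phys._asdict().items()},
    }
    return DescriptorRow(id=mol.id, values=values)


def descriptor_table(
    mols: Iterable[Molecule],
    seed: int = 42,
    include_h: bool = True,
    logp_estimator: Callable[[object], float] | None = None,
) -> pd.DataFrame:
    """Descriptor table, one row per molecule, indexed by molecule id."""
    rows = []
    for m in mols:
        r = descriptor_row(m, seed=seed, include_h=include_h, logp_estimator=logp_estimator)
        rows.append({"id": r.id, **r.values})
    df = pd.DataFrame(rows, columns=["id"] + DESCRIPTOR_NAMES)
    return df.set_index("id")
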