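"""Deterministic synthetic test material: molecules with controlled
multiple-bond counts and labeled descriptor tables with planted rules.

Molecules are assembled from a small fragment grammar on an sp3-carbon
scaffold: each benzene ring contributes exactly 6 to the multiple-bond
count *b*, each carbonyl contributes 1, alkyl linkers contribute 0 — so
``multiple_bond_count`` of the result equals the requested target exactly
and the UI value is known in closed form.  Scaffold shapes (linear /
branched / star) vary how fragments are arranged in space, which moves the
conformer-dependent RDF descriptors without touching UI: star-shaped
scaffolds tend to place heavy atom pairs near 7 Å and score higher RDF070m
than equally sized linear chains.  RDF ground truth is therefore never
planted; decks carry exact UI-node expectations and only statistical
RDF-node expectations.

Labeled tables plant a two-descriptor OR rule (X ≥ x_thr OR Y ≥ y_thr)
with optional label-flip noise, emulating the structure the profiler's
two-node trees are meant to discover: X plays the role of a continuous
shape descriptor (RDF-like, gamma-distributed), Y an unsaturation-like
descriptor on a coarse grid (log2(1 + count)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import DataError
from .profiler import UI_THRESHOLD_DT1, UI_THRESHOLD_DT2
from .tree import LabeledTable

SHAPES = ("linear", "branched", "star")


@dataclass(frozen=True)
class DeckSpec:
    """Parameters of a synthetic molecule deck."""

    n: int = 60
    b_range: tuple[int, int] = (0, 30)            # inclusive target multiple-bond counts
    shape_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # linear, branched, star
    seed: int = 42

    def __post_init__(self):
        if self.n <= 0:
            raise DataError("deck size must be positive")
        if abs(sum(self.shape_mix) - 1.0) > 1e-9:
            raise DataError("shape fractions must sum to 1")
        if self.b_range[0] < 0 or self.b_range[1] < self.b_range[0]:
            raise DataError("invalid multiple-bond count range")


def make_molecule(target_b: int, shape: str = "linear", seed: int = 0) -> str:
    """SMILES of a molecule whose multiple-bond count equals ``target_b``.

    ``target_b // 6`` benzene rings plus ``target_b % 6`` carbonyls are
    attached to an alkane scaffold of the requested shape.  Deterministic
    for a (target_b, shape, seed) triple.
    """
    if target_b < 0:
        raise DataError("target multiple-bond count must be non-negative")
    if shape not in SHAPES:
        raise DataError(f"unknown shape {shape!r}; expected one of {SHAPES}")
    rng = np.random.default_rng(seed)
    n_benz, n_carbonyl = divmod(target_b, 6)
    n_attach = n_benz + n_carbonyl

    rw = Chem.RWMol()

    def add_c() -> int:
        return rw.AddAtom(Chem.Atom(6))

    def single(i: int, j: int) -> None:
        rw.AddBond(i, j, Chem.BondType.SINGLE)

    sites: list[int] = []  # one entry per available attachment (repeats = capacity)
    if shape == "linear":
        length = max(2, n_attach) + int(rng.integers(1, 4))
        chain = [add_c() for _ in range(length)]
        for a, b in zip(chain, chain[1:]):
            single(a, b)
        sites = [chain[0], chain[-1]] + chain[1:-1]        # ends first, 1 per atom
    elif shape == "branched":
        length = max(3, (n_attach + 1) // 2 + int(rng.integers(1, 3)))
        chain = [add_c() for _ in range(length)]
        for a, b in zip(chain, chain[1:]):
            single(a, b)
        sites = [chain[0], chain[-1]]
        for c in chain[1:-1]:
            sites += [c, c]                                # interior capacity 2
    else:  # star
        center = add_c()
        tips = []
        for _ in range(4):
            prev = center
            for _ in range(1 + int(rng.integers(0, 2))):   # arm length 1-2
                nxt = add_c()
                single(prev, nxt)
                prev = nxt
            tips.append(prev)
        sites = [tip for _ in range(3) for tip in tips]    # tip capacity 3

    while len(sites) < n_attach:                           # very unsaturated targets
        extra = add_c()
        single(sites[-1], extra)
        sites.append(extra)

    fragments = ["benzene"] * n_benz + ["carbonyl"] * n_carbonyl
    rng.shuffle(fragments)
    for site, frag in zip(sites, fragments):
        if frag == "benzene":
            ring = [add_c() for _ in range(6)]
            for k in range(6):
                i, j = ring[k], ring[(k + 1) % 6]
                rw.AddBond(i, j, Chem.BondType.AROMATIC)
                rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
            for idx in ring:
                rw.GetAtomWithIdx(idx).SetIsAromatic(True)
            single(site, ring[0])
        else:
            c = add_c()
            o = rw.AddAtom(Chem.Atom(8))
            rw.AddBond(c, o, Chem.BondType.DOUBLE)
            single(site, c)

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def make_deck(spec: DeckSpec = DeckSpec()) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Deck of (id, SMILES) records plus a ground-truth table.

    The truth table records each molecule's target multiple-bond count,
    scaffold shape, exact UI value and the expected outcome of the UI node
    under both shipped profiles.
    """
    rng = np.random.default_rng(spec.seed)
    # deterministic shape counts from the mix, remainder to the largest share
    counts = [int(f * spec.n) for f in spec.shape_mix]
    counts[int(np.argmax(spec.shape_mix))] += spec.n - sum(counts)
    shapes = [s for s, c in zip(SHAPES, counts) for _ in range(c)]
    rng.shuffle(shapes)

    records, truth = [], []
    for i, shape in enumerate(shapes):
        target_b = int(rng.integers(spec.b_range[0], spec.b_range[1] + 1))
        mol_seed = int(rng.integers(0, 2**31 - 1))
        smiles = make_molecule(target_b, shape, seed=mol_seed)
        mol_id = f"syn_{i:04d}"
        ui = math.log2(1 + target_b)
        records.append((mol_id, smiles))
        truth.append({
            "id": mol_id,
            "smiles": smiles,
            "target_b": target_b,
            "shape": shape,
            "UI": ui,
            "dt1_ui_pass": ui >= UI_THRESHOLD_DT1,
            "dt2_ui_pass": ui >= UI_THRESHOLD_DT2,
        })
    return records, pd.DataFrame(truth)


def write_deck(spec: DeckSpec, smiles_path: str | Path, truth_path: str | Path) -> None:
    records, truth = make_deck(spec)
    with open(smiles_path, "w") as fh:
        fh.write("# synthetic deck, seed %d\n" % spec.seed)
        for mol_id, smi in records:
            fh.write(f"{smi} {mol_id}\n")
    truth.to_csv(truth_path, sep="\t", index=False)


@dataclass(frozen=True)
class PlantedRuleSpec:
    """Labeled descriptor table with a planted OR rule.

    X is a continuous gamma-distributed shape-like descriptor, Y an
    unsaturation-like descriptor on the log2(1 + count) grid; the label is
    (X ≥ x_threshold) OR (Y ≥ y_threshold), then flipped at the noise
    rate.  Two irrelevant uniform descriptors (N1, N2) are included so
    preprocessing and induction have something to discard.
    """

    n: int = 600
    x_threshold: float = 10.0
    y_threshold: float = 4.0
    gamma_shape: float = 4.0       # X ~ Gamma(shape, scale): mean 10, sd 5
    gamma_scale: float = 2.5
    count_lambda: float = 10.0     # Y = log2(1 + Poisson(lambda))
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise < 0.5:
            raise DataError("label-noise rate must be in [0, 0.5)")
        if self.n <= 0:
            raise DataError("table size must be positive")


def make_labeled_table(spec: PlantedRuleSpec = PlantedRuleSpec()) -> LabeledTable:
    """Generate the planted-rule table; identical spec + seed ⇒ identical table."""
    rng = np.random.default_rng(spec.seed)
    x = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=spec.n)
    y = np.log2(1.0 + rng.poisson(spec.count_lambda, size=spec.n))
    n1 = rng.uniform(0.0, 1.0, size=spec.n)
    n2 = rng.normal(0.0, 1.0, size=spec.n)
    labels = ((x >= spec.x_threshold) | (y >= spec.y_threshold)).astype(int)
    flips = rng.random(spec.n) < spec.noise
    labels = np.where(flips, 1 - labels, labels)
    if len(np.unique(labels)) < 2:  # pathological draw; reroll deterministically
        labels[0], labels[1] = 0, 1
    X = pd.DataFrame({"X": x, "Y": y, "N1": n1, "N2": n2})
    return LabeledTable(X=X, y=labels, ids=[f"row_{i:04d}" for i in range(spec.n)])
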