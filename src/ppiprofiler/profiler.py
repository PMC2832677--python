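"""Apply descriptor-threshold decision trees to compound collections.

The two shipped profiles share one structure: a molecule is accepted when
its RDF070m value reaches 13.31, or failing that when its unsaturation
index reaches a profile-specific threshold (3.95 for DT1, 4.13 for DT2).
Both comparisons use ≥, so a row exactly at a threshold is accepted.
DT2's higher UI cut makes its accepted set a subset of DT1's on any deck.

Custom rule trees (e.g. the output of the enrichment-tree learner) run on
the same engine via a small JSON node format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

from .chemgraph import Molecule
from .descriptors import DescriptorRow, descriptor_row
from .errors import DescriptorError, EmbeddingError, PPIProfilerError

log = logging.getLogger(__name__)

RDF_THRESHOLD = 13.31
UI_THRESHOLD_DT1 = 3.95
UI_THRESHOLD_DT2 = 4.13


@dataclass
class RuleNode:
    """Binary threshold node: descriptor ≥ threshold goes to pass_child.

    Leaves have ``accept`` set and no descriptor.
    """

    descriptor: str | None = None
    threshold: float | None = None
    pass_child: "RuleNode | None" = None
    fail_child: "RuleNode | None" = None
    accept: bool | None = None

    @property
    def is_leaf(self) -> bool:
        return self.accept is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "accept": bool(self.accept)}
        return {
            "descriptor": self.descriptor,
            "threshold": self.threshold,
            "pass": self.pass_child.to_dict(),
            "fail": self.fail_child.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleNode":
        if d.get("leaf"):
            return cls(accept=bool(d["accept"]))
        return cls(
            descriptor=str(d["descriptor"]),
            threshold=float(d["threshold"]),
            pass_child=cls.from_dict(d["pass"]),
            fail_child=cls.from_dict(d["fail"]),
        )


@dataclass
class ProfilerModel:
    """Named rule tree applied to descriptor rows."""

    name: str
    root: RuleNode

    @classmethod
    def two_rule(cls, name: str, root_descriptor: str, root_threshold: float,
                 fallback_descriptor: str, fallback_threshold: float) -> "ProfilerModel":
        """OR of two threshold rules: root ≥ t1, else fallback ≥ t2."""
        root = RuleNode(
            descriptor=root_descriptor,
            threshold=root_threshold,
            pass_child=RuleNode(accept=True),
            fail_child=RuleNode(
                descriptor=fallback_descriptor,
                threshold=fallback_threshold,
                pass_child=RuleNode(accept=True),
                fail_child=RuleNode(accept=False),
            ),
        )
        return cls(name=name, root=root)

    @classmethod
    def dt1(cls) -> "ProfilerModel":
        return cls.two_rule("DT1", "RDF070m", RDF_THRESHOLD, "UI", UI_THRESHOLD_DT1)

    @classmethod
    def dt2(cls) -> "ProfilerModel":
        return cls.two_rule("DT2", "RDF070m", RDF_THRESHOLD, "UI", UI_THRESHOLD_DT2)

    @classmethod
    def load(cls, name_or_path: str) -> "ProfilerModel":
        """Resolve 'dt1'/'dt2' or load a custom-model JSON file."""
        key = name_or_path.lower()
        if key == "dt1":
            return cls.dt1()
        if key == "dt2":
            return cls.dt2()
        path = Path(name_or_path)
        with open(path) as fh:
            d = json.load(fh)
        return cls(name=d.get("name", path.stem), root=RuleNode.from_dict(d["tree"]))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "tree": self.root.to_dict()}, fh, indent=2)


@dataclass
class ProfileDecision:
    molecule_id: str
    accepted: bool
    flagged_by: str = "none"  # "RDF" (root rule), "UI" (fallback rule), or "none"


def profile_one(row: Union[DescriptorRow, Mapping[str, float]], model: ProfilerModel) -> ProfileDecision:
    """Walk the rule tree for one descriptor row.

    ``flagged_by`` records which rule admitted the molecule: "RDF" when the
    root (depth-0) threshold fired, "UI" when a deeper node did.
    """
    mol_id = row.id if isinstance(row, DescriptorRow) else str(row.get("id", "?"))
    node = model.root
    depth = 0
    last_pass_depth = None
    while not node.is_leaf:
        try:
            value = row[node.descriptor]
        except (KeyError, DescriptorError):
            raise DescriptorError(
                f"molecule {mol_id!r}: missing descriptor {node.descriptor!r}"
            )
        if value >= node.threshold:
            last_pass_depth = depth
            node = node.pass_child
        else:
            node = node.fail_child
        depth += 1
    accepted = bool(node.accept)
    if not accepted:
        flag = "none"
    else:
        flag = "RDF" if last_pass_depth == 0 else "UI"
    return ProfileDecision(molecule_id=mol_id, accepted=accepted, flagged_by=flag)


@dataclass
class ProfileReport:
    """Per-run bookkeeping: stage counts and flag attribution."""

    n_input: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_failed: int = 0
    flag_counts: dict = field(default_factory=lambda: {"RDF": 0, "UI": 0})

    @property
    def flag_ratio(self) -> tuple[float, float]:
        """(RDF, UI) share of accepted molecules, as fractions summing to 1."""
        total = self.flag_counts["RDF"] + self.flag_counts["UI"]
        if total == 0:
            return (0.0, 0.0)
        return (self.flag_counts["RDF"] / total, self.flag_counts["UI"] / total)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "n_failed": self.n_failed,
            "flagged_RDF": self.flag_counts["RDF"],
            "flagged_UI": self.flag_counts["UI"],
        }


def profile_collection(
    mols: Iterable[Molecule],
    model: ProfilerModel,
    seed: int = 42,
    include_h: bool = True,
) -> tuple[list[Molecule], list[ProfileDecision], ProfileReport]:
    """Descriptor pipeline + rule tree over a molecule stream.

    Molecules without coordinates get a deterministic conformer from
    ``seed``.  Per-molecule failures (embedding, descriptors) are logged
    and counted but never abort the stream; output order follows input
    order.
    """
    accepted: list[Molecule] = []
    decisions: list[ProfileDecision] = []
    report = ProfileReport()
    for mol in mols:
        report.n_input += 1
        try:
            row = descriptor_row(mol, seed=seed, include_h=include_h)
            decision = profile_one(row, model)
        except (EmbeddingError, DescriptorError, PPIProfilerError) as exc:
            log.warning("molecule %r failed: %s", mol.id, exc)
            report.n_failed += 1
            continue
        decisions.append(decision)
        if decision.accepted:
            accepted.append(mol)
            report.n_accepted += 1
            report.flag_counts[decision.flagged_by] += 1
        else:
            report.n_rejected += 1
    return accepted, decisions, report
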