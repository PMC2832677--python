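"""Soft drug-likeness (ADMET) pre-filter.

Property ranges are deliberately permissive — the filter is meant to remove
clearly non-drug-like material from a screening collection before
profiling, not to enforce strict oral-drug rules.  A molecule passes when
every property range holds AND it has at most one Lipinski rule-of-five
violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .descriptors import PhyschemProfile
from .errors import DataError


@dataclass(frozen=True)
class AdmetRules:
    """Permissive property ranges.

    MW and logP bounds are strict (open intervals); the count ranges admit
    zero (a drug with no H-bond donors is perfectly plausible) and HBA runs
    to 12 inclusive.
    """

    mw_range: tuple[float, float] = (100.0, 900.0)      # open interval
    hbd_range: tuple[int, int] = (0, 8)                 # 0 <= HBD < 8
    hba_range: tuple[int, int] = (0, 12)                # 0 <= HBA <= 12
    logp_range: tuple[float, float] = (-5.0, 6.0)       # open interval
    nrot_range: tuple[int, int] = (0, 20)               # 0 <= nROT < 20
    tpsa_range: tuple[float, float] = (0.0, 160.0)      # 0 <= TPSA < 160
    max_lipinski_violations: int = 1

    def __post_init__(self):
        for lo, hi in (self.mw_range, self.hbd_range, self.hba_range,
                       self.logp_range, self.nrot_range, self.tpsa_range):
            if not lo < hi:
                raise ValueError("range lower bound must be below upper bound")


DEFAULT_RULES = AdmetRules()


@dataclass
class FilterVerdict:
    molecule_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    lipinski_violations: int = 0


_REQUIRED = ("MW", "logP", "TPSA", "HBD", "HBA", "nROT")


def _as_mapping(props, molecule_id: str) -> Mapping[str, float]:
    if isinstance(props, PhyschemProfile):
        props = props._asdict()
    for name in _REQUIRED:
        if name not in props:
            raise DataError(f"molecule {molecule_id!r}: missing property {name!r}")
    return props


def lipinski_violations(props, molecule_id: str = "?") -> int:
    """Count of rule-of-five violations: MW>500, logP>5, HBD>5, HBA>10."""
    p = _as_mapping(props, molecule_id)
    return sum([p["MW"] > 500, p["logP"] > 5, p["HBD"] > 5, p["HBA"] > 10])


def apply_soft_filter(
    props, rules: AdmetRules = DEFAULT_RULES, molecule_id: str = "?"
) -> FilterVerdict:
    """Check one property profile against the soft ranges + Lipinski cap.

    The verdict lists every failed rule, not just the first.
    """
    p = _as_mapping(props, molecule_id)
    failed = []
    if not rules.mw_range[0] < p["MW"] < rules.mw_range[1]:
        failed.append("MW")
    if not rules.hbd_range[0] <= p["HBD"] < rules.hbd_range[1]:
        failed.append("HBD")
    if not rules.hba_range[0] <= p["HBA"] <= rules.hba_range[1]:
        failed.append("HBA")
    if not rules.logp_range[0] < p["logP"] < rules.logp_range[1]:
        failed.append("logP")
    if not rules.nrot_range[0] <= p["nROT"] < rules.nrot_range[1]:
        failed.append("nROT")
    if not rules.tpsa_range[0] <= p["TPSA"] < rules.tpsa_range[1]:
        failed.append("TPSA")
    viol = lipinski_violations(p, molecule_id)
    if viol > rules.max_lipinski_violations:
        failed.append("lipinski")
    return FilterVerdict(
        molecule_id=molecule_id,
        passed=not failed,
        failed_rules=failed,
        lipinski_violations=viol,
    )


def filter_profiles(
    profiles: Iterable[tuple[str, object]], rules: AdmetRules = DEFAULT_RULES
) -> list[FilterVerdict]:
    """Vectorised convenience: verdicts for (id, properties) pairs, input order kept."""
    return [apply_soft_filter(p, rules, molecule_id=i) for i, p in profiles]
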