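"""Efficiency of plaquing (EOP) and phagogram assembly.

EOP is the titer of a phage on a test strain divided by its titer on its
reference host (titrated in parallel).  The classification bands are the
commonly used ones: EOP >= 0.1 highly virulent, 0.001 <= EOP < 0.1
moderately virulent, EOP < 0.001 weakly or avirulent.  Band boundaries are
half-open so every positive EOP is classifiable; EOP > 1 (better plaquing on
the test strain than on the reference) is still highly virulent.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .assay import TitrationResult, TitrationStatus

__all__ = [
    "VirulenceClass",
    "PotencyRecord",
    "Phagogram",
    "efficiency_of_plaquing",
    "classify_eop",
    "build_phagogram",
]

logger = logging.getLogger(__name__)

HIGH_THRESHOLD = 0.1
MODERATE_THRESHOLD = 0.001


class VirulenceClass(str, enum.Enum):
    HIGHLY_VIRULENT = "highly_virulent"
    MODERATELY_VIRULENT = "moderately_virulent"
    WEAKLY_OR_AVIRULENT = "weakly_or_avirulent"
    NOT_ACTIVE = "not_active"
    NOT_EVALUABLE = "not_evaluable"


_VIRULENCE_GRADES = frozenset({
    VirulenceClass.HIGHLY_VIRULENT,
    VirulenceClass.MODERATELY_VIRULENT,
    VirulenceClass.WEAKLY_OR_AVIRULENT,
})


@dataclass(frozen=True)
class PotencyRecord:
    phage_id: str
    strain_id: str
    reference_strain_id: str | None
    eop: float | None
    virulence_class: VirulenceClass

    def __post_init__(self) -> None:
        if self.virulence_class in _VIRULENCE_GRADES:
            if self.eop is None or self.eop <= 0:
                raise ValueError("virulence grade requires eop > 0")
        elif self.eop is not None:
            raise ValueError(f"{self.virulence_class.value} must not carry an eop")


def efficiency_of_plaquing(titer_test: float, titer_reference: float) -> float:
    """EOP = titer on the test strain / titer on the reference host."""
    if titer_reference <= 0:
        raise ValueError("reference titer must be > 0")
    if titer_test <= 0:
        raise ValueError("test titer must be > 0")
    return titer_test / titer_reference


def classify_eop(eop: float) -> VirulenceClass:
    """Map a positive EOP to its virulence band (monotone step function)."""
    if eop <= 0:
        raise ValueError("eop must be > 0")
    if eop >= HIGH_THRESHOLD:
        return VirulenceClass.HIGHLY_VIRULENT
    if eop >= MODERATE_THRESHOLD:
        return VirulenceClass.MODERATELY_VIRULENT
    return VirulenceClass.WEAKLY_OR_AVIRULENT


@dataclass(frozen=True)
class Phagogram:
    """Phage x strain potency matrix, one record per pair."""

    phage_ids: tuple[str, ...]
    strain_ids: tuple[str, ...]
    records: Mapping[tuple[str, str], PotencyRecord]

    def record(self, phage_id: str, strain_id: str) -> PotencyRecord:
        return self.records[(phage_id, strain_id)]

    def class_tallies(self) -> dict[str, int]:
        tallies: dict[str, int] = {c.value: 0 for c in VirulenceClass}
        for rec in self.records.values():
            tallies[rec.virulence_class.value] += 1
        return tallies


def build_phagogram(
    titrations: Sequence[TitrationResult],
    reference_hosts: Mapping[str, str],
) -> Phagogram:
    """Assemble the potency matrix from titration results.

    Each phage's EOPs are referenced to its quantified titer on its reference
    host; the reference cell itself gets eop exactly 1.  Pairs with no
    activity map to not_active, excluded pairs (and every pair of a phage
    whose reference titration is missing or not quantified) to not_evaluable.
    """
    by_pair: dict[tuple[str, str], TitrationResult] = {}
    for t in titrations:
        key = (t.phage_id, t.strain_id)
        if key in by_pair:
            raise ValueError(f"duplicate titration for pair {key}")
        by_pair[key] = t
    phage_ids = tuple(dict.fromkeys(t.phage_id for t in titrations))
    strain_ids = tuple(dict.fromkeys(t.strain_id for t in titrations))

    ref_titer: dict[str, float | None] = {}
    for phage in phage_ids:
        ref_strain = reference_hosts.get(phage)
        ref = by_pair.get((phage, ref_strain)) if ref_strain is not None else None
        if ref is None or ref.status is not TitrationStatus.QUANTIFIED:
            logger.warning(
                "phage %s: reference host titration missing or not quantified; "
                "its column is not evaluable", phage)
            ref_titer[phage] = None
        else:
            ref_titer[phage] = ref.mean_titer

    records: dict[tuple[str, str], PotencyRecord] = {}
    for phage in phage_ids:
        ref_strain = reference_hosts.get(phage)
        for strain in strain_ids:
            t = by_pair.get((phage, strain))
            if t is None or ref_titer[phage] is None:
                rec = PotencyRecord(phage, strain, ref_strain, None,
                                    VirulenceClass.NOT_EVALUABLE)
            elif t.status is TitrationStatus.NO_ACTIVITY:
                rec = PotencyRecord(phage, strain, ref_strain, None,
                                    VirulenceClass.NOT_ACTIVE)
            elif t.status is not TitrationStatus.QUANTIFIED:
                rec = PotencyRecord(phage, strain, ref_strain, None,
                                    VirulenceClass.NOT_EVALUABLE)
            elif strain == ref_strain:
                rec = PotencyRecord(phage, strain, ref_strain, 1.0,
                                    VirulenceClass.HIGHLY_VIRULENT)
            else:
                eop = efficiency_of_plaquing(t.mean_titer, ref_titer[phage])
                rec = PotencyRecord(phage, strain, ref_strain, eop, classify_eop(eop))
            records[(phage, strain)] = rec
    return Phagogram(phage_ids=phage_ids, strain_ids=strain_ids, records=records)
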