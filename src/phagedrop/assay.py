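"""Spot-level domain types and the titration pipeline.

A drop-off (direct spot test) titration deposits small drops of ten-fold
serial phage dilutions, in triplicate, onto a bacterial lawn and counts the
plaque-forming units (PFU) in each spot after incubation.  This module turns
raw spot observations into titers: it resolves plate anomalies (merged
adjacent drops, missing drops), selects the countable dilution, converts
counts to PFU/mL, and aggregates replicates into mean / SD / CV with the
precision flag.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "SpotStatus",
    "TitrationStatus",
    "AnomalyFlag",
    "SpotObservation",
    "QuantificationRules",
    "ResolvedTriplicate",
    "TitrationResult",
    "titer_from_count",
    "resolve_anomalies",
    "select_quantifiable_dilution",
    "aggregate_replicates",
    "titrate",
]

MAX_DILUTION_EXPONENT_DEFAULT = 7


class SpotStatus(str, enum.Enum):
    """Outcome of a single drop on the lawn."""

    COUNTED = "counted"          # individual plaques, countable
    CONFLUENT = "confluent"      # lysis too dense to count (TNTC / clearance)
    NO_LYSIS = "no_lysis"        # intact lawn, zero plaques
    NO_DROP = "no_drop"          # the drop never landed (robot anomaly)
    MERGED = "merged"            # coalesced with an adjacent replicate drop


class TitrationStatus(str, enum.Enum):
    QUANTIFIED = "quantified"
    NO_ACTIVITY = "no_activity"
    EXCLUDED_NO_PFU = "excluded_no_pfu"
    EXCLUDED_UNRELIABLE_COUNT = "excluded_unreliable_count"


class AnomalyFlag(str, enum.Enum):
    MERGED_RESOLVED = "merged_resolved"
    MISSING_REPLICATE = "missing_replicate"


_COUNTLESS = frozenset({SpotStatus.NO_DROP, SpotStatus.NO_LYSIS, SpotStatus.CONFLUENT})


@dataclass(frozen=True)
class SpotObservation:
    """One drop of one phage dilution on one bacterial lawn.

    ``plaque_count`` is meaningful only for ``counted`` and ``merged`` spots;
    for a merged pair both partners carry the combined count of the fused
    drop.  ``dilution_exponent`` k means the drop came from a 10**-k dilution
    of the stock; 0 is undiluted.
    """

    phage_id: str
    strain_id: str
    dilution_exponent: int
    replicate_index: int
    drop_volume_ul: float
    status: SpotStatus
    plaque_count: float | None = None
    merge_partner: int | None = None

    def __post_init__(self) -> None:
        if self.drop_volume_ul <= 0:
            raise ValueError(f"drop_volume_ul must be > 0, got {self.drop_volume_ul}")
        if self.dilution_exponent < 0:
            raise ValueError("dilution_exponent must be >= 0")
        if self.replicate_index < 1:
            raise ValueError("replicate_index is 1-based")
        status = SpotStatus(self.status)
        object.__setattr__(self, "status", status)
        if status in _COUNTLESS and self.plaque_count is not None:
            raise ValueError(f"status {status.value!r} must not carry a plaque count")
        if status in (SpotStatus.COUNTED, SpotStatus.MERGED):
            if self.plaque_count is None or self.plaque_count < 0:
                raise ValueError(f"status {status.value!r} requires a nonnegative plaque count")
        if status is SpotStatus.MERGED and self.merge_partner is None:
            raise ValueError("merged spot requires merge_partner")
        if status is not SpotStatus.MERGED and self.merge_partner is not None:
            raise ValueError("merge_partner only valid for merged spots")


@dataclass(frozen=True)
class QuantificationRules:
    """Countability and precision thresholds for plate reading.

    ``max_countable`` is the ceiling above which individual plaques cannot be
    reliably distinguished (~50 per spot); ``min_reliable_pfu`` is the count
    below which replicate CVs degrade (precision guideline, not an exclusion);
    ``cv_acceptable_percent`` is the precision-acceptance threshold.
    """

    min_countable: int = 1
    max_countable: int = 50
    cv_acceptable_percent: float = 15.0
    min_reliable_pfu: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.min_countable <= self.max_countable):
            raise ValueError("require 0 < min_countable <= max_countable")
        if self.cv_acceptable_percent <= 0 or self.min_reliable_pfu <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ResolvedTriplicate:
    """Effective per-replicate counts after anomaly resolution.

    ``counts`` maps replicate index -> effective plaque count (merged pairs
    contribute half of their combined count each; intact-lawn spots count 0).
    Confluent spots have no usable count and are flagged instead.
    """

    counts: dict[int, float]
    flags: frozenset[AnomalyFlag]
    has_confluent: bool

    @property
    def n_usable(self) -> int:
        return len(self.counts)

    @property
    def mean_count(self) -> float | None:
        if not self.counts:
            return None
        return sum(self.counts.values()) / len(self.counts)


@dataclass(frozen=True)
class TitrationResult:
    """Titer of one phage on one strain with replicate statistics."""

    phage_id: str
    strain_id: str
    status: TitrationStatus
    selected_dilution_exponent: int | None = None
    replicate_titers: tuple[float, ...] | None = None
    mean_titer: float | None = None
    sd_titer: float | None = None
    cv_percent: float | None = None
    n_replicates_used: int | None = None
    precision_acceptable: bool | None = None
    anomaly_flags: frozenset[AnomalyFlag] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.status is TitrationStatus.QUANTIFIED:
            if self.mean_titer is None or self.mean_titer <= 0:
                raise ValueError("quantified result requires mean_titer > 0")
            if self.n_replicates_used is None or self.n_replicates_used < 2:
                raise ValueError("quantified result requires >= 2 replicates")
        else:
            numeric = (self.mean_titer, self.sd_titer, self.cv_percent,
                       self.replicate_titers, self.selected_dilution_exponent)
            if any(v is not None for v in numeric):
                raise ValueError("non-quantified result must not carry numeric fields")


def titer_from_count(plaque_count: float, drop_volume_ul: float,
                     dilution_exponent: int) -> float:
    """PFU/mL of the undiluted stock from one spot count.

    titer = count / (drop volume in mL) * 10**dilution_exponent.
    """
    if drop_volume_ul <= 0:
        raise ValueError(f"drop_volume_ul must be > 0, got {drop_volume_ul}")
    if dilution_exponent < 0:
        raise ValueError("dilution_exponent must be >= 0")
    if plaque_count < 0:
        raise ValueError("plaque_count must be >= 0")
    return plaque_count / (drop_volume_ul * 1e-3) * 10.0 ** dilution_exponent


def resolve_anomalies(triplicate: Sequence[SpotObservation]) -> ResolvedTriplicate:
    """Turn one dilution's replicate spots into effective counts.

    Merged pairs each contribute half of the fused drop's combined count
    (flag ``merged_resolved``); missing drops contribute nothing and reduce n
    (flag ``missing_replicate``); intact-lawn spots count as 0; confluent
    spots are unusable and only recorded as present.
    """
    if not triplicate:
        raise ValueError("empty triplicate")
    keys = {(s.phage_id, s.strain_id, s.dilution_exponent) for s in triplicate}
    if len(keys) != 1:
        raise ValueError(f"triplicate mixes phage/strain/dilution: {sorted(keys)}")
    by_rep = {s.replicate_index: s for s in triplicate}
    if len(by_rep) != len(triplicate):
        raise ValueError("duplicate replicate indices in triplicate")

    counts: dict[int, float] = {}
    flags: set[AnomalyFlag] = set()
    has_confluent = False
    for rep, spot in sorted(by_rep.items()):
        if spot.status is SpotStatus.COUNTED:
            counts[rep] = float(spot.plaque_count)
        elif spot.status is SpotStatus.MERGED:
            partner = by_rep.get(spot.merge_partner)
            if (partner is None or partner.status is not SpotStatus.MERGED
                    or partner.merge_partner != rep):
                raise ValueError(
                    f"merged spot (replicate {rep}) lacks a symmetric partner")
            if partner.plaque_count != spot.plaque_count:
                raise ValueError(
                    f"merged partners {rep}/{spot.merge_partner} disagree on combined count")
            counts[rep] = float(spot.plaque_count) / 2.0
            flags.add(AnomalyFlag.MERGED_RESOLVED)
        elif spot.status is SpotStatus.NO_LYSIS:
            counts[rep] = 0.0
        elif spot.status is SpotStatus.NO_DROP:
            flags.add(AnomalyFlag.MISSING_REPLICATE)
        elif spot.status is SpotStatus.CONFLUENT:
            has_confluent = True
    return ResolvedTriplicate(counts=counts, flags=frozenset(flags),
                              has_confluent=has_confluent)


def _group_by_dilution(series: Iterable[SpotObservation]) -> dict[int, list[SpotObservation]]:
    groups: dict[int, list[SpotObservation]] = {}
    for spot in series:
        groups.setdefault(spot.dilution_exponent, []).append(spot)
    return groups


def select_quantifiable_dilution(
    series: Sequence[SpotObservation],
    rules: QuantificationRules = QuantificationRules(),
) -> int | TitrationStatus:
    """Pick the dilution to read, or an exclusion status.

    A dilution qualifies when it has no confluent spot, at least two usable
    replicates, and every effective count within [min_countable,
    max_countable]; among qualifiers the one with the largest mean count wins
    (most counting information; ties break toward the lower exponent).

    Failure modes: ``no_activity`` when the lawn is intact everywhere;
    ``excluded_unreliable_count`` when even the highest tested dilution is
    still above the countable ceiling (or too few usable replicates remain
    anywhere); ``excluded_no_pfu`` when clearance occurs but no dilution ever
    shows countable individual plaques (lysis-from-without pattern).
    """
    if not series:
        raise ValueError("empty series")
    pairs = {(s.phage_id, s.strain_id) for s in series}
    if len(pairs) != 1:
        raise ValueError(f"series mixes phage/strain pairs: {sorted(pairs)}")

    groups = _group_by_dilution(series)
    resolved = {exp: resolve_anomalies(spots) for exp, spots in groups.items()}

    candidates: list[tuple[float, int]] = []
    for exp, res in resolved.items():
        if res.has_confluent or res.n_usable < 2:
            continue
        counts = list(res.counts.values())
        if all(rules.min_countable <= c <= rules.max_countable for c in counts):
            candidates.append((res.mean_count, exp))
    if candidates:
        # largest mean count; ties toward the lower exponent
        best_mean = max(m for m, _ in candidates)
        return min(exp for m, exp in candidates if m == best_mean)

    any_confluent = any(res.has_confluent for res in resolved.values())
    max_effective = max((c for res in resolved.values()
                         for c in res.counts.values()), default=0.0)
    if not any_confluent and max_effective < rules.min_countable:
        return TitrationStatus.NO_ACTIVITY

    highest = max(exp for exp, res in resolved.items() if res.n_usable or res.has_confluent)
    res = resolved[highest]
    mean = res.mean_count
    if res.has_confluent or (mean is not None and mean > rules.max_countable):
        return TitrationStatus.EXCLUDED_UNRELIABLE_COUNT
    if any(res.counts and max(res.counts.values()) >= rules.min_countable
           for res in resolved.values()):
        # countable plaques existed somewhere but never with >= 2 usable replicates
        return TitrationStatus.EXCLUDED_UNRELIABLE_COUNT
    return TitrationStatus.EXCLUDED_NO_PFU


def aggregate_replicates(titers: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator), and CV% of replicate titers."""
    if len(titers) < 2:
        raise ValueError(f"need >= 2 replicate titers, got {len(titers)}")
    if any(t <= 0 for t in titers):
        raise ValueError("replicate titers must be > 0")
    n = len(titers)
    mean = sum(titers) / n
    var = sum((t - mean) ** 2 for t in titers) / (n - 1)
    sd = math.sqrt(var)
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return mean, sd, 100.0 * sd / mean


def titrate(
    series: Sequence[SpotObservation],
    rules: QuantificationRules = QuantificationRules(),
) -> TitrationResult:
    """Full pipeline for one phage-strain pair: select dilution, resolve
    anomalies, convert counts to titers, aggregate, and flag precision."""
    selection = select_quantifiable_dilution(series, rules)
    phage_id = series[0].phage_id
    strain_id = series[0].strain_id
    if isinstance(selection, TitrationStatus):
        return TitrationResult(phage_id=phage_id, strain_id=strain_id, status=selection)

    spots = [s for s in series if s.dilution_exponent == selection]
    res = resolve_anomalies(spots)
    by_rep = {s.replicate_index: s for s in spots}
    titers = tuple(
        titer_from_count(count, by_rep[rep].drop_volume_ul, selection)
        for rep, count in sorted(res.counts.items())
    )
    mean, sd, cv = aggregate_replicates(titers)
    return TitrationResult(
        phage_id=phage_id,
        strain_id=strain_id,
        status=TitrationStatus.QUANTIFIED,
        selected_dilution_exponent=selection,
        replicate_titers=titers,
        mean_titer=mean,
        sd_titer=sd,
        cv_percent=cv,
        n_replicates_used=len(titers),
        precision_acceptable=cv < rules.cv_acceptable_percent,
        anomaly_flags=res.flags,
    )
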