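"""Synthetic plate-assay generator for the automated drop-off method.

Emulates what the liquid-handling robot produces: ten-fold serial dilutions
with multiplicative pipetting error, 5 uL drops in triplicate, Poisson
plaque counts per drop, a countability ceiling above which spots read as
confluent lysis, missed drops ("no drop-off") and coalescence of adjacent
replicate drops.  Every run is reproducible from a seed, and the generator
returns the realized ground truth alongside the spot table so downstream
estimates can be scored.

Also provides the run-plan arithmetic of the robot (spots per plate, plates,
runs, aspiration volume per tip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .assay import SpotObservation, SpotStatus

__all__ = [
    "SimulationConfig",
    "AssayTruth",
    "RunPlan",
    "AnomalyRateEstimate",
    "simulate_dilution_series",
    "simulate_spot",
    "apply_coalescence",
    "simulate_assay",
    "plan_run",
    "estimate_anomaly_rates",
    "study_panel_config",
]

_MERGEABLE = frozenset({SpotStatus.COUNTED, SpotStatus.NO_LYSIS})
_LANDED = frozenset({SpotStatus.COUNTED, SpotStatus.NO_LYSIS, SpotStatus.MERGED})


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic assay.

    ``susceptibility`` maps (phage, strain) to the true stock titer in
    PFU/mL of that phage's productive infection on that strain; absent pairs
    are not susceptible.  The anomaly rates default to the observed robot
    behavior: 0.93% missed drops and 1.97% coalescence per adjacent
    replicate pair; pipetting error is multiplicative lognormal (median 1)
    per ten-fold transfer.
    """

    susceptibility: Mapping[tuple[str, str], float]
    phage_ids: tuple[str, ...] | None = None
    strain_ids: tuple[str, ...] | None = None
    n_dilutions: int = 8
    n_replicates: int = 3
    drop_volume_ul: float = 5.0
    pipetting_cv: float = 0.05
    drop_volume_cv: float = 0.02
    p_no_drop: float = 0.0093
    p_coalescence: float = 0.0197
    max_countable: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_no_drop", "p_coalescence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.drop_volume_ul <= 0:
            raise ValueError("drop_volume_ul must be > 0")
        if self.n_dilutions < 1 or self.n_replicates < 1:
            raise ValueError("n_dilutions and n_replicates must be >= 1")
        if self.pipetting_cv < 0 or self.drop_volume_cv < 0:
            raise ValueError("CVs must be >= 0")
        if any(t <= 0 for t in self.susceptibility.values()):
            raise ValueError("stock titers must be > 0")
        if self.phage_ids is None:
            object.__setattr__(self, "phage_ids",
                               tuple(dict.fromkeys(p for p, _ in self.susceptibility)))
        if self.strain_ids is None:
            object.__setattr__(self, "strain_ids",
                               tuple(dict.fromkeys(s for _, s in self.susceptibility)))


@dataclass(frozen=True)
class AssayTruth:
    """Realized ground truth of one simulated assay."""

    concentrations: Mapping[tuple[str, str], tuple[float, ...]]  # per dilution
    realized_volumes_ul: Mapping[tuple[str, str, int, int], float]
    events: tuple[dict, ...]  # {"kind": "no_drop"|"coalescence", ...}


@dataclass(frozen=True)
class RunPlan:
    """Throughput arithmetic of the robot layout."""

    n_strains: int
    n_phage_wells: int
    n_dilutions: int
    n_replicates: int
    phages_per_run: int
    plates_per_run_max: int
    plates_per_strain: int
    spots_per_plate: int
    spots_per_run: int
    total_spots: int
    total_plates: int
    total_runs: int
    aspiration_volume_per_tip_ul: float


@dataclass(frozen=True)
class AnomalyRateEstimate:
    no_drop_rate: float
    no_drop_ci: tuple[float, float]
    n_spots: int
    n_no_drop: int
    coalescence_rate: float
    coalescence_ci: tuple[float, float]
    n_opportunities: int
    n_coalescence_events: int


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def simulate_dilution_series(stock: float, pipetting_cv: float,
                             n_dilutions: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Realized concentrations of a ten-fold serial dilution series.

    c_0 is the stock; each transfer divides by 10 and multiplies by a
    lognormal error with median 1 and coefficient of variation
    ``pipetting_cv`` (errors compound down the series).
    """
    if stock <= 0:
        raise ValueError("stock must be > 0")
    if n_dilutions < 1:
        raise ValueError("n_dilutions must be >= 1")
    sigma = _lognormal_sigma(pipetting_cv)
    if sigma == 0:
        eps = np.ones(n_dilutions - 1)
    else:
        eps = rng.lognormal(mean=0.0, sigma=sigma, size=n_dilutions - 1)
    series = np.empty(n_dilutions)
    series[0] = stock
    for k in range(1, n_dilutions):
        series[k] = series[k - 1] / 10.0 * eps[k - 1]
    return series


def _draw_spot(concentration: float, drop_volume_ul: float,
               config: SimulationConfig,
               rng: np.random.Generator) -> tuple[SpotStatus, int | None, float | None]:
    """(status, count, realized volume); volume is None for a missed drop."""
    if rng.random() < config.p_no_drop:
        return SpotStatus.NO_DROP, None, None
    sigma = _lognormal_sigma(config.drop_volume_cv)
    volume = drop_volume_ul * (rng.lognormal(0.0, sigma) if sigma > 0 else 1.0)
    lam = concentration * volume * 1e-3
    count = int(rng.poisson(lam)) if lam > 0 else 0
    if count == 0:
        return SpotStatus.NO_LYSIS, None, volume
    if count > config.max_countable:
        return SpotStatus.CONFLUENT, None, volume
    return SpotStatus.COUNTED, count, volume


def simulate_spot(concentration: float, drop_volume_ul: float,
                  config: SimulationConfig, rng: np.random.Generator,
                  phage_id: str = "phage", strain_id: str = "strain",
                  dilution_exponent: int = 0,
                  replicate_index: int = 1) -> SpotObservation:
    """Simulate one drop.  The emitted record carries the nominal drop
    volume (what the protocol targets); the realized volume only perturbs
    the Poisson intensity, as it does on a real plate."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    status, count, _ = _draw_spot(concentration, drop_volume_ul, config, rng)
    return SpotObservation(
        phage_id=phage_id, strain_id=strain_id,
        dilution_exponent=dilution_exponent, replicate_index=replicate_index,
        drop_volume_ul=drop_volume_ul, status=status,
        plaque_count=None if count is None else float(count),
    )


def apply_coalescence(triplicate: Sequence[SpotObservation], p_coalescence: float,
                      rng: np.random.Generator) -> list[SpotObservation]:
    """Merge adjacent replicate drops, each pair with probability
    ``p_coalescence``; a spot merges with at most one partner.  Both partners
    of a merged pair carry the combined plaque count; totals are conserved."""
    spots = sorted(triplicate, key=lambda s: s.replicate_index)
    out = list(spots)
    merged: set[int] = set()
    for i in range(len(spots) - 1):
        a, b = out[i], out[i + 1]
        if i in merged:
            continue
        if a.status not in _MERGEABLE or b.status not in _MERGEABLE:
            continue
        if rng.random() < p_coalescence:
            combined = float(a.plaque_count or 0) + float(b.plaque_count or 0)
            out[i] = SpotObservation(
                phage_id=a.phage_id, strain_id=a.strain_id,
                dilution_exponent=a.dilution_exponent,
                replicate_index=a.replicate_index,
                drop_volume_ul=a.drop_volume_ul, status=SpotStatus.MERGED,
                plaque_count=combined, merge_partner=b.replicate_index)
            out[i + 1] = SpotObservation(
                phage_id=b.phage_id, strain_id=b.strain_id,
                dilution_exponent=b.dilution_exponent,
                replicate_index=b.replicate_index,
                drop_volume_ul=b.drop_volume_ul, status=SpotStatus.MERGED,
                plaque_count=combined, merge_partner=a.replicate_index)
            merged.update((i, i + 1))
    return out


def simulate_assay(config: SimulationConfig) -> tuple[list[SpotObservation], AssayTruth]:
    """Simulate the full phage x strain x dilution x replicate spot table.

    Deterministic given ``config.seed``: each (strain, phage) series draws
    from its own child stream of the seed, so the table is reproducible and
    independent of evaluation order.
    """
    spots: list[SpotObservation] = []
    concentrations: dict[tuple[str, str], tuple[float, ...]] = {}
    volumes: dict[tuple[str, str, int, int], float] = {}
    events: list[dict] = []

    for si, strain in enumerate(config.strain_ids):
        for pi, phage in enumerate(config.phage_ids):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, si, pi]))
            stock = config.susceptibility.get((phage, strain))
            if stock is not None:
                series = simulate_dilution_series(
                    stock, config.pipetting_cv, config.n_dilutions, rng)
            else:
                series = np.zeros(config.n_dilutions)
            concentrations[(phage, strain)] = tuple(series)

            for exponent in range(config.n_dilutions):
                triplicate = []
                for rep in range(1, config.n_replicates + 1):
                    status, count, volume = _draw_spot(
                        series[exponent], config.drop_volume_ul, config, rng)
                    if volume is not None:
                        volumes[(phage, strain, exponent, rep)] = volume
                    else:
                        events.append({"kind": "no_drop", "phage_id": phage,
                                       "strain_id": strain,
                                       "dilution_exponent": exponent,
                                       "replicate_index": rep})
                    triplicate.append(SpotObservation(
                        phage_id=phage, strain_id=strain,
                        dilution_exponent=exponent, replicate_index=rep,
                        drop_volume_ul=config.drop_volume_ul, status=status,
                        plaque_count=None if count is None else float(count)))
                if config.n_replicates >= 2 and config.p_coalescence > 0:
                    triplicate = apply_coalescence(
                        triplicate, config.p_coalescence, rng)
                for spot in triplicate:
                    if (spot.status is SpotStatus.MERGED
                            and spot.replicate_index < spot.merge_partner):
                        events.append({"kind": "coalescence", "phage_id": phage,
                                       "strain_id": strain,
                                       "dilution_exponent": exponent,
                                       "replicates": (spot.replicate_index,
                                                      spot.merge_partner)})
                spots.extend(triplicate)
    truth = AssayTruth(concentrations=concentrations,
                       realized_volumes_ul=volumes, events=tuple(events))
    return spots, truth


def plan_run(n_strains: int, n_phage_wells: int, *,
             drop_volume_ul: float = 5.0, n_dilutions: int = 8,
             n_replicates: int = 3, phages_per_run: int = 4,
             plates_per_run_max: int = 10) -> RunPlan:
    """Throughput arithmetic: spots, plates, runs, aspiration volume.

    One plate holds one strain's lawn spotted with up to ``phages_per_run``
    phages x dilutions x replicates; a run handles up to
    ``plates_per_run_max`` plates; each tip aspirates 3*v*n + 10 uL where n
    is the number of plates served in the run.
    """
    if n_strains < 1 or n_phage_wells < 1:
        raise ValueError("n_strains and n_phage_wells must be >= 1")
    spots_per_plate = min(n_phage_wells, phages_per_run) * n_dilutions * n_replicates
    plates_per_strain = math.ceil(n_phage_wells / phages_per_run)
    total_plates = n_strains * plates_per_strain
    plates_per_run = min(total_plates, plates_per_run_max)
    return RunPlan(
        n_strains=n_strains,
        n_phage_wells=n_phage_wells,
        n_dilutions=n_dilutions,
        n_replicates=n_replicates,
        phages_per_run=phages_per_run,
        plates_per_run_max=plates_per_run_max,
        plates_per_strain=plates_per_strain,
        spots_per_plate=spots_per_plate,
        spots_per_run=spots_per_plate * plates_per_run,
        total_spots=n_strains * n_phage_wells * n_dilutions * n_replicates,
        total_plates=total_plates,
        total_runs=math.ceil(total_plates / plates_per_run_max),
        aspiration_volume_per_tip_ul=3.0 * drop_volume_ul * plates_per_run + 10.0,
    )


def estimate_anomaly_rates(spots: Sequence[SpotObservation]) -> AnomalyRateEstimate:
    """Empirical no-drop and coalescence rates with exact binomial CIs.

    The no-drop rate is per attempted spot.  The coalescence rate is
    estimated on the subset of adjacent replicate pairs whose examination is
    decided by drop placement alone: the first pair of each replicate set
    whose two drops both landed with a readable-or-blank lawn, or a later
    pair when every earlier pair had a missing or confluent drop.  Pairs
    that are only examined because an earlier pair happened not to merge are
    excluded — including them makes the trial count depend on the merge
    outcomes and the exact binomial interval loses its coverage guarantee.
    On the retained trials merging is i.i.d. Bernoulli, so the
    Clopper-Pearson interval is exact for ``p_coalescence``.
    """
    spots = list(spots)
    if not spots:
        raise ValueError("empty spot table")
    n_spots = len(spots)
    n_no_drop = sum(1 for s in spots if s.status is SpotStatus.NO_DROP)

    groups: dict[tuple[str, str, int], list[SpotObservation]] = {}
    for s in spots:
        groups.setdefault((s.phage_id, s.strain_id, s.dilution_exponent), []).append(s)

    n_opp = 0
    n_events = 0
    for group in groups.values():
        reps = sorted(group, key=lambda s: s.replicate_index)
        previous_eligible = False
        for i in range(len(reps) - 1):
            a, b = reps[i], reps[i + 1]
            eligible = a.status in _LANDED and b.status in _LANDED
            if eligible and not previous_eligible:
                n_opp += 1
                if (a.status is SpotStatus.MERGED
                        and a.merge_partner == b.replicate_index):
                    n_events += 1
            previous_eligible = eligible

    def exact_ci(k: int, n: int) -> tuple[float, float]:
        if n == 0:
            return (0.0, 1.0)
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95,
                                                 method="exact")
        return (float(ci.low), float(ci.high))

    return AnomalyRateEstimate(
        no_drop_rate=n_no_drop / n_spots,
        no_drop_ci=exact_ci(n_no_drop, n_spots),
        n_spots=n_spots,
        n_no_drop=n_no_drop,
        coalescence_rate=n_events / n_opp if n_opp else 0.0,
        coalescence_ci=exact_ci(n_events, n_opp),
        n_opportunities=n_opp,
        n_coalescence_events=n_events,
    )


def study_panel_config(seed: int = 0, n_strains: int = 126, n_phages: int = 10,
                       include_cocktail: bool = True,
                       n_positive_interactions: int = 151,
                       **overrides) -> SimulationConfig:
    """A panel mirroring a realistic screening study: ``n_phages`` single
    phages plus an optional cocktail against ``n_strains`` strains, the
    first ``n_phages`` strains being the phages' reference hosts, with
    sparse additional positives up to ``n_positive_interactions`` in total.

    Host stocks are drawn log-uniform around 10**8.5-10**10 PFU/mL; non-host
    positives carry a log-uniform efficiency penalty, spreading effective
    titers over roughly 10**4-10**10 PFU/mL.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 987654321]))
    phages = [f"phage_{i:02d}" for i in range(1, n_phages + 1)]
    strains = [f"strain_{i:03d}" for i in range(1, n_strains + 1)]
    hosts = {phages[i]: strains[i] for i in range(min(n_phages, n_strains))}

    susceptibility: dict[tuple[str, str], float] = {}
    stocks = {p: 10.0 ** rng.uniform(8.3, 10.0) for p in phages}
    for p, h in hosts.items():
        susceptibility[(p, h)] = stocks[p]
    if include_cocktail:
        phages.append("cocktail")
        for h in hosts.values():
            susceptibility[("cocktail", h)] = 10.0 ** rng.uniform(8.3, 10.0)

    n_extra = n_positive_interactions - len(susceptibility)
    all_pairs = [(p, s) for p in phages for s in strains
                 if (p, s) not in susceptibility]
    idx = rng.choice(len(all_pairs), size=max(n_extra, 0), replace=False)
    for i in idx:
        p, s = all_pairs[i]
        stock = stocks.get(p, 10.0 ** rng.uniform(8.3, 10.0))
        susceptibility[(p, s)] = stock * 10.0 ** rng.uniform(-4.5, 0.0)

    return SimulationConfig(
        susceptibility=susceptibility,
        phage_ids=tuple(phages),
        strain_ids=tuple(strains),
        seed=seed,
        **overrides,
    )
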