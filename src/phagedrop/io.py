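"""Readers, writers, configuration, and the end-to-end pipeline glue.

All on-disk interfaces are plain text: spot tables and paired titers as
CSV, phagograms as a TSV matrix plus a long-format CSV, reports and ground
truth as JSON carrying a ``schema_version`` field.  Scientific notation in
CSV output is fixed to ``%.6e`` so diffs are stable across platforms.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .assay import (AnomalyFlag, QuantificationRules, SpotObservation, SpotStatus,
                    TitrationResult, TitrationStatus, titrate)
from .agreement import AgreementReport, PairedTiters
from .potency import Phagogram, build_phagogram
from .simulate import AssayTruth, SimulationConfig

__all__ = [
    "SCHEMA_VERSION",
    "AnalysisConfig",
    "ParseError",
    "read_spot_table",
    "write_spot_table",
    "read_paired_titers",
    "write_paired_titers",
    "write_titration_results",
    "write_phagogram",
    "agreement_report_dict",
    "write_agreement_report",
    "write_truth",
    "load_analysis_config",
    "load_simulation_config",
    "run_pipeline",
    "PipelineOutput",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

SPOT_COLUMNS = ("phage_id", "strain_id", "dilution_exponent", "replicate",
                "drop_volume_ul", "status", "plaque_count", "merge_partner")
PAIRED_COLUMNS = ("group", "label", "reference_titer", "evaluated_titer")


class ParseError(ValueError):
    """Input file violates the documented schema; names the offending row."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the titration + potency + agreement pipeline."""

    rules: QuantificationRules = field(default_factory=QuantificationRules)
    reference_hosts: Mapping[str, str] = field(default_factory=dict)
    ccc_scale: str = "log10"
    equal_variance_t: bool = True
    max_dilution_exponent: int = 7
    log_level: str = "INFO"


def _fmt_count(count: float | None) -> str:
    if count is None:
        return ""
    if float(count).is_integer():
        return str(int(count))
    return f"{count:.6g}"


def write_spot_table(spots: Iterable[SpotObservation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPOT_COLUMNS)
        for s in spots:
            writer.writerow([
                s.phage_id, s.strain_id, s.dilution_exponent, s.replicate_index,
                f"{s.drop_volume_ul:g}", s.status.value, _fmt_count(s.plaque_count),
                "" if s.merge_partner is None else s.merge_partner,
            ])


def read_spot_table(path: str | Path,
                    max_dilution_exponent: int = 7) -> list[SpotObservation]:
    """Parse and validate a spot-table CSV; merge-partner symmetry is
    enforced across the file and errors name the offending row."""
    path = Path(path)
    spots: list[SpotObservation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != SPOT_COLUMNS:
            raise ParseError(
                f"{path}: header must be {','.join(SPOT_COLUMNS)}, "
                f"got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                status = SpotStatus(row["status"])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unknown status {row['status']!r}") from None
            count = row["plaque_count"].strip()
            partner = row["merge_partner"].strip()
            try:
                exponent = int(row["dilution_exponent"])
                if exponent > max_dilution_exponent:
                    raise ValueError(
                        f"dilution_exponent {exponent} exceeds bound "
                        f"{max_dilution_exponent}")
                spot = SpotObservation(
                    phage_id=row["phage_id"],
                    strain_id=row["strain_id"],
                    dilution_exponent=exponent,
                    replicate_index=int(row["replicate"]),
                    drop_volume_ul=float(row["drop_volume_ul"]),
                    status=status,
                    plaque_count=float(count) if count else None,
                    merge_partner=int(partner) if partner else None,
                )
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            spots.append(spot)

    by_key = {(s.phage_id, s.strain_id, s.dilution_exponent, s.replicate_index): s
              for s in spots}
    for s in spots:
        if s.status is SpotStatus.MERGED:
            partner = by_key.get(
                (s.phage_id, s.strain_id, s.dilution_exponent, s.merge_partner))
            if (partner is None or partner.status is not SpotStatus.MERGED
                    or partner.merge_partner != s.replicate_index):
                raise ParseError(
                    f"{path}: merged spot ({s.phage_id}, {s.strain_id}, "
                    f"dilution {s.dilution_exponent}, replicate "
                    f"{s.replicate_index}) lacks a symmetric partner")
    return spots


def write_paired_titers(pairs: PairedTiters, grouping: Sequence[str],
                        path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PAIRED_COLUMNS)
        for group, label, ref, ev in zip(grouping, pairs.labels,
                                         pairs.reference_values,
                                         pairs.evaluated_values):
            writer.writerow([group, label, f"{ref:.6e}", f"{ev:.6e}"])


def read_paired_titers(path: str | Path) -> tuple[PairedTiters, tuple[str, ...]]:
    path = Path(path)
    labels, groups, ref, ev = [], [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != PAIRED_COLUMNS:
            raise ParseError(
                f"{path}: header must be {','.join(PAIRED_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ref.append(float(row["reference_titer"]))
                ev.append(float(row["evaluated_titer"]))
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            labels.append(row["label"])
            groups.append(row["group"])
    return (PairedTiters(labels=tuple(labels), reference_values=tuple(ref),
                         evaluated_values=tuple(ev)), tuple(groups))


def _titration_row(t: TitrationResult) -> dict:
    return {
        "phage_id": t.phage_id,
        "strain_id": t.strain_id,
        "status": t.status.value,
        "selected_dilution_exponent": t.selected_dilution_exponent,
        "replicate_titers": (None if t.replicate_titers is None
                             else list(t.replicate_titers)),
        "mean_titer": t.mean_titer,
        "sd_titer": t.sd_titer,
        "cv_percent": t.cv_percent,
        "n_replicates_used": t.n_replicates_used,
        "precision_acceptable": t.precision_acceptable,
        "anomaly_flags": sorted(f.value for f in t.anomaly_flags),
    }


def write_titration_results(results: Sequence[TitrationResult],
                            csv_path: str | Path | None = None,
                            json_path: str | Path | None = None) -> None:
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["phage_id", "strain_id", "status",
                             "selected_dilution_exponent", "mean_titer",
                             "sd_titer", "cv_percent", "n_replicates_used",
                             "precision_acceptable", "anomaly_flags"])
            for t in results:
                writer.writerow([
                    t.phage_id, t.strain_id, t.status.value,
                    "" if t.selected_dilution_exponent is None
                    else t.selected_dilution_exponent,
                    "" if t.mean_titer is None else f"{t.mean_titer:.6e}",
                    "" if t.sd_titer is None else f"{t.sd_titer:.6e}",
                    "" if t.cv_percent is None else f"{t.cv_percent:.4f}",
                    "" if t.n_replicates_used is None else t.n_replicates_used,
                    "" if t.precision_acceptable is None else t.precision_acceptable,
                    ";".join(sorted(f.value for f in t.anomaly_flags)),
                ])
    if json_path is not None:
        payload = {"schema_version": SCHEMA_VERSION,
                   "titrations": [_titration_row(t) for t in results]}
        Path(json_path).write_text(json.dumps(payload, indent=1))


def write_phagogram(phagogram: Phagogram,
                    matrix_tsv: str | Path | None = None,
                    long_csv: str | Path | None = None,
                    report_json: str | Path | None = None) -> None:
    """TSV matrix (strains as rows, phages as columns; cells are the EOP,
    ``not_active`` or ``NA``), long-format CSV, and a JSON tally report."""
    if matrix_tsv is not None:
        with open(matrix_tsv, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["strain_id", *phagogram.phage_ids])
            for strain in phagogram.strain_ids:
                row = [strain]
                for phage in phagogram.phage_ids:
                    rec = phagogram.record(phage, strain)
                    if rec.eop is not None:
                        row.append(f"{rec.eop:.6e}")
                    elif rec.virulence_class.value == "not_active":
                        row.append("not_active")
                    else:
                        row.append("NA")
                writer.writerow(row)
    if long_csv is not None:
        with open(long_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["phage_id", "strain_id", "reference_strain_id",
                             "eop", "virulence_class"])
            for phage in phagogram.phage_ids:
                for strain in phagogram.strain_ids:
                    rec = phagogram.record(phage, strain)
                    writer.writerow([
                        rec.phage_id, rec.strain_id,
                        rec.reference_strain_id or "",
                        "" if rec.eop is None else f"{rec.eop:.6e}",
                        rec.virulence_class.value,
                    ])
    if report_json is not None:
        payload = {"schema_version": SCHEMA_VERSION,
                   "n_phages": len(phagogram.phage_ids),
                   "n_strains": len(phagogram.strain_ids),
                   "class_tallies": phagogram.class_tallies()}
        Path(report_json).write_text(json.dumps(payload, indent=1))


def agreement_report_dict(report: AgreementReport) -> dict:
    ba = report.bland_altman
    return {
        "schema_version": SCHEMA_VERSION,
        "n_pairs": report.n_pairs,
        "bias_ratio": ba.bias_ratio,
        "bias_ci": list(ba.bias_ci),
        "limits_of_agreement": list(ba.limits_of_agreement),
        "ccc": {"value": report.ccc.ccc, "ci": list(report.ccc.ci),
                "pearson_r": report.ccc.pearson_r, "scale": report.ccc.scale},
        "variability_test": {
            "name": report.variability.test_name,
            "statistic": report.variability.statistic,
            "p_value": report.variability.p_value,
            "normality_p": list(report.variability.normality_p),
        },
        "per_method_cv_summary": {
            "reference": {"mean": report.variability.mean_a,
                          "sd": report.variability.sd_a},
            "evaluated": {"mean": report.variability.mean_b,
                          "sd": report.variability.sd_b},
        },
        "reference_groups": [
            {"group": g.group, "mean": g.mean, "sd": g.sd, "cv_percent": g.cv_percent}
            for g in report.reference_groups],
        "evaluated_groups": [
            {"group": g.group, "mean": g.mean, "sd": g.sd, "cv_percent": g.cv_percent}
            for g in report.evaluated_groups],
        "log_differences": dict(report.log_differences),
        "mean_abs_log_difference": report.mean_abs_log_difference,
    }


def write_agreement_report(report: AgreementReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(agreement_report_dict(report), indent=1))


def write_truth(truth: AssayTruth, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "concentrations": [
            {"phage_id": p, "strain_id": s, "per_dilution": list(c)}
            for (p, s), c in truth.concentrations.items()],
        "realized_volumes_ul": [
            {"phage_id": p, "strain_id": s, "dilution_exponent": d,
             "replicate": r, "volume_ul": v}
            for (p, s, d, r), v in truth.realized_volumes_ul.items()],
        "events": [dict(e, replicates=list(e["replicates"]))
                   if "replicates" in e else dict(e)
                   for e in truth.events],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


_ANALYSIS_KEYS = {"min_countable", "max_countable", "cv_acceptable_percent",
                  "min_reliable_pfu", "reference_hosts", "ccc_scale",
                  "equal_variance_t", "max_dilution_exponent", "log_level"}


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load and validate an analysis configuration (JSON); unknown keys are
    rejected rather than silently ignored."""
    data = json.loads(Path(path).read_text())
    unknown = set(data) - _ANALYSIS_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    rule_keys = {"min_countable", "max_countable", "cv_acceptable_percent",
                 "min_reliable_pfu"}
    rules = QuantificationRules(**{k: data[k] for k in rule_keys if k in data})
    other = {k: v for k, v in data.items() if k not in rule_keys}
    return AnalysisConfig(rules=rules, **other)


_SIM_KEYS = {"susceptibility", "phage_ids", "strain_ids", "n_dilutions",
             "n_replicates", "drop_volume_ul", "pipetting_cv", "drop_volume_cv",
             "p_no_drop", "p_coalescence", "max_countable", "seed"}


def load_simulation_config(path: str | Path, seed: int | None = None) -> SimulationConfig:
    """Load a simulation configuration (JSON mirroring SimulationConfig
    field names; ``susceptibility`` is a list of [phage, strain, stock]
    triples).  ``seed`` overrides the file's value when given."""
    data = json.loads(Path(path).read_text())
    unknown = set(data) - _SIM_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        susceptibility = {(p, s): float(t) for p, s, t in data.pop("susceptibility")}
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: susceptibility must be a list of "
                         f"[phage, strain, stock_titer] triples ({exc})") from None
    for key in ("phage_ids", "strain_ids"):
        if key in data:
            data[key] = tuple(data[key])
    if seed is not None:
        data["seed"] = seed
    return SimulationConfig(susceptibility=susceptibility, **data)


@dataclass(frozen=True)
class PipelineOutput:
    titrations: tuple[TitrationResult, ...]
    phagogram: Phagogram | None
    report: dict


def run_pipeline(spots: Sequence[SpotObservation],
                 config: AnalysisConfig = AnalysisConfig()) -> PipelineOutput:
    """Titrate every phage-strain series, build the phagogram when reference
    hosts are configured, and assemble a JSON-ready summary report."""
    series: dict[tuple[str, str], list[SpotObservation]] = {}
    for s in spots:
        series.setdefault((s.phage_id, s.strain_id), []).append(s)

    titrations = []
    for (phage, strain), group in series.items():
        result = titrate(group, config.rules)
        if result.status is not TitrationStatus.QUANTIFIED:
            logger.info("pair (%s, %s): %s", phage, strain, result.status.value)
        elif result.anomaly_flags:
            logger.info("pair (%s, %s): quantified at dilution %d with flags %s",
                        phage, strain, result.selected_dilution_exponent,
                        sorted(f.value for f in result.anomaly_flags))
        titrations.append(result)

    phagogram = (build_phagogram(titrations, config.reference_hosts)
                 if config.reference_hosts else None)

    status_tally = {s.value: 0 for s in TitrationStatus}
    flag_tally = {f.value: 0 for f in AnomalyFlag}
    for t in titrations:
        status_tally[t.status.value] += 1
        for f in t.anomaly_flags:
            flag_tally[f.value] += 1
    report = {
        "schema_version": SCHEMA_VERSION,
        "n_pairs": len(titrations),
        "status_tally": status_tally,
        "anomaly_flag_tally": flag_tally,
        "n_precision_acceptable": sum(1 for t in titrations if t.precision_acceptable),
        "class_tallies": phagogram.class_tallies() if phagogram else None,
    }
    return PipelineOutput(titrations=tuple(titrations), phagogram=phagogram,
                          report=report)
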