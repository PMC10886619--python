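"""Packaged method-comparison fixture: one phage titrated by both methods.

Four dilution tubes (A: undiluted, B: 10**-1, C: 10**-2, D: 10**-3) of one
phage stock were each titrated four times independently by the manual and
the automated drop-off method — 16 paired titers.  Each published titer is
the mean of a triplicate plaque count and is therefore an exact multiple of
one third; the fixture stores those exact values (``k/3 * 10**m``) so that
derived statistics are free of presentation rounding, together with the
3-significant-figure strings as printed, for regression against the
published summary rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .agreement import PairedTiters

__all__ = ["Table1Fixture", "table1_fixture"]

TUBES = ("A", "B", "C", "D")
METHODS = ("manual", "automated")

# (numerator over 3, decimal exponent) per tube, replicates 1-4
_RAW = {
    "manual": {
        "A": ((30, 8), (22, 8), (46, 8), (26, 8)),
        "B": ((30, 7), (36, 7), (32, 7), (44, 7)),
        "C": ((22, 6), (42, 6), (32, 6), (30, 6)),
        "D": ((46, 5), (52, 5), (62, 5), (38, 5)),
    },
    "automated": {
        "A": ((32, 8), (26, 8), (42, 8), (30, 8)),
        "B": ((40, 7), (36, 7), (44, 7), (36, 7)),
        "C": ((40, 6), (32, 6), (38, 6), (40, 6)),
        "D": ((34, 5), (34, 5), (30, 5), (26, 5)),
    },
}

# summary rows as published (3 significant figures / 2 decimals)
PRINTED_SUMMARY = {
    "manual": {
        "mean": {"A": 1.03e9, "B": 1.18e8, "C": 1.05e7, "D": 1.65e6},
        "sd": {"A": 3.51e8, "B": 2.06e7, "C": 2.74e6, "D": 3.37e5},
        "cv": {"A": 33.93, "B": 17.44, "C": 26.11, "D": 20.44},
        "mean_cv": 24.48,
        "mean_cv_sd": 7.25,
    },
    "automated": {
        "mean": {"A": 1.08e9, "B": 1.30e8, "C": 1.25e7, "D": 1.03e6},
        "sd": {"A": 2.27e8, "B": 1.28e7, "C": 1.26e6, "D": 1.28e5},
        "cv": {"A": 20.94, "B": 9.82, "C": 10.10, "D": 12.35},
        "mean_cv": 13.30,
        "mean_cv_sd": 5.21,
    },
}

PRINTED_REPLICATES = {
    "manual": {
        "A": ("1.00e9", "7.33e8", "1.53e9", "8.67e8"),
        "B": ("1.00e8", "1.20e8", "1.07e8", "1.47e8"),
        "C": ("7.33e6", "1.40e7", "1.07e7", "1.00e7"),
        "D": ("1.53e6", "1.73e6", "2.07e6", "1.27e6"),
    },
    "automated": {
        "A": ("1.07e9", "8.67e8", "1.40e9", "1.00e9"),
        "B": ("1.33e8", "1.20e8", "1.47e8", "1.20e8"),
        "C": ("1.33e7", "1.07e7", "1.27e7", "1.33e7"),
        "D": ("1.13e6", "1.13e6", "1.00e6", "8.67e5"),
    },
}


@dataclass(frozen=True)
class Table1Fixture:
    """Read-only access to the paired-titer validation data."""

    titers: Mapping[str, Mapping[str, tuple[float, ...]]]  # method -> tube -> 4 titers
    printed_summary: Mapping[str, Mapping]
    printed_replicates: Mapping[str, Mapping[str, tuple[str, ...]]]

    def tube(self, method: str, tube: str) -> tuple[float, ...]:
        return self.titers[method][tube]

    def paired_titers(self) -> PairedTiters:
        """The 16 pairs: replicate #k manual vs #k automated within each tube."""
        labels, ref, ev = [], [], []
        for tube in TUBES:
            for k in range(4):
                labels.append(f"{tube}{k + 1}")
                ref.append(self.titers["manual"][tube][k])
                ev.append(self.titers["automated"][tube][k])
        return PairedTiters(labels=tuple(labels), reference_values=tuple(ref),
                            evaluated_values=tuple(ev))

    def tube_grouping(self) -> tuple[str, ...]:
        return tuple(tube for tube in TUBES for _ in range(4))


def table1_fixture() -> Table1Fixture:
    titers = {
        method: {tube: tuple(k / 3.0 * 10.0 ** m for k, m in reps)
                 for tube, reps in by_tube.items()}
        for method, by_tube in _RAW.items()
    }
    return Table1Fixture(titers=titers, printed_summary=PRINTED_SUMMARY,
                         printed_replicates=PRINTED_REPLICATES)
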