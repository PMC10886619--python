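"""Method-comparison statistics for paired titers.

Agreement between a reference (manual) and an evaluated (automated)
titration method is assessed on the ratio scale: per-pair ratios
r_i = evaluated_i / reference_i are log10-transformed, the Bland-Altman bias
is the geometric mean ratio 10**mean(l) with 95% limits of agreement
10**(mean(l) +/- 1.96 sd(l)), and concordance is summarised by Lin's
concordance correlation coefficient.  Replicate precision of the two
methods is compared on per-group CVs through a normality-gated two-sample
test (Kolmogorov-Smirnov gate; Student's t when both groups pass, otherwise
Mann-Whitney).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .assay import aggregate_replicates

__all__ = [
    "PairedTiters",
    "BlandAltmanResult",
    "CCCResult",
    "VariabilityComparison",
    "MethodGroupSummary",
    "AgreementReport",
    "abs_log10_difference",
    "bland_altman_ratio",
    "lins_ccc",
    "compare_variability",
    "method_comparison_report",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class PairedTiters:
    """Paired measurements of the same tubes by two methods (PFU/mL)."""

    labels: tuple[str, ...]
    reference_values: tuple[float, ...]
    evaluated_values: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (n == len(self.reference_values) == len(self.evaluated_values)):
            raise ValueError("labels and value lists must have equal length")
        if n < 2:
            raise ValueError("need >= 2 pairs")
        if any(v <= 0 for v in self.reference_values + self.evaluated_values):
            raise ValueError("all titers must be > 0")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias_ratio: float
    bias_ci: tuple[float, float]
    limits_of_agreement: tuple[float, float]
    ratios: tuple[float, ...]
    averages_log10: tuple[float, ...]   # mean of the two log10 measurements, per pair


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    ci: tuple[float, float]
    pearson_r: float
    scale: str  # "log10" or "raw"


@dataclass(frozen=True)
class VariabilityComparison:
    test_name: str            # "student_t" or "mann_whitney"
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    normality_p: tuple[float, float]


@dataclass(frozen=True)
class MethodGroupSummary:
    """Per-group (tube) replicate statistics for one method."""

    group: str
    mean: float
    sd: float
    cv_percent: float


@dataclass(frozen=True)
class AgreementReport:
    n_pairs: int
    bland_altman: BlandAltmanResult
    ccc: CCCResult
    variability: VariabilityComparison
    reference_groups: tuple[MethodGroupSummary, ...]
    evaluated_groups: tuple[MethodGroupSummary, ...]
    log_differences: Mapping[str, float]  # per-group |delta log10| of method means
    mean_abs_log_difference: float

    def __post_init__(self) -> None:
        lo, hi = self.bland_altman.bias_ci
        if not (lo <= self.bland_altman.bias_ratio <= hi):
            raise ValueError("bias CI must contain the bias")
        lo, hi = self.bland_altman.limits_of_agreement
        if not (lo <= self.bland_altman.bias_ratio <= hi):
            raise ValueError("limits of agreement must bracket the bias")


def abs_log10_difference(mean_a: float, mean_b: float) -> float:
    """|log10(a) - log10(b)|, the decade-scale gap between two titers."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("titers must be > 0")
    return abs(math.log10(mean_a) - math.log10(mean_b))


def bland_altman_ratio(pairs: PairedTiters) -> BlandAltmanResult:
    """Bland-Altman ratio analysis on log10-transformed paired titers.

    Bias is the geometric mean of evaluated/reference ratios; the 95% CI of
    the bias uses the t distribution (n-1 df) on the log scale; the limits of
    agreement are the conventional +/- 1.96 sd(log ratio).
    """
    ref = np.asarray(pairs.reference_values, dtype=float)
    ev = np.asarray(pairs.evaluated_values, dtype=float)
    ratios = ev / ref
    logs = np.log10(ratios)
    n = len(logs)
    mean_l = float(logs.mean())
    sd_l = float(logs.std(ddof=1))
    half_ci = stats.t.ppf(0.975, n - 1) * sd_l / math.sqrt(n)
    return BlandAltmanResult(
        bias_ratio=10.0 ** mean_l,
        bias_ci=(10.0 ** (mean_l - half_ci), 10.0 ** (mean_l + half_ci)),
        limits_of_agreement=(10.0 ** (mean_l - 1.96 * sd_l),
                             10.0 ** (mean_l + 1.96 * sd_l)),
        ratios=tuple(ratios),
        averages_log10=tuple((np.log10(ref) + np.log10(ev)) / 2.0),
    )


def lins_ccc(x: Sequence[float], y: Sequence[float],
             scale: str = "raw") -> CCCResult:
    """Lin's concordance correlation coefficient with its 95% CI.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population
    (n-denominator) moments.  The CI is computed by Fisher z-transforming the
    coefficient with the large-sample variance of Lin (1989) and
    back-transforming.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    if scale == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log10 scale requires positive values")
        x, y = np.log10(x), np.log10(y)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")

    sx2 = float(x.var())      # population moments
    sy2 = float(y.var())
    if sx2 == 0 and sy2 == 0:
        raise ValueError("degenerate input: both sequences constant")
    sxy = float(((x - x.mean()) * (y - y.mean())).mean())
    shift = float(x.mean() - y.mean())
    ccc = 2.0 * sxy / (sx2 + sy2 + shift ** 2)

    if sx2 == 0 or sy2 == 0:
        r = 0.0
    else:
        r = sxy / math.sqrt(sx2 * sy2)

    if abs(ccc) >= 1.0 - 1e-12 or r == 0.0:
        ci = (ccc, ccc)  # perfect agreement (or undefined accuracy): degenerate CI
    else:
        u = shift / (sx2 * sy2) ** 0.25
        c2 = ccc ** 2
        var_z = (
            (1 - r ** 2) * c2 / ((1 - c2) * r ** 2)
            + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (r * (1 - c2) ** 2)
            - ccc ** 4 * u ** 4 / (2 * r ** 2 * (1 - c2) ** 2)
        ) / (n - 2)
        z = math.atanh(ccc)
        half = 1.959963984540054 * math.sqrt(max(var_z, 0.0))
        ci = (math.tanh(z - half), math.tanh(z + half))
    return CCCResult(ccc=ccc, ci=ci, pearson_r=r, scale=scale)


def compare_variability(cvs_a: Sequence[float], cvs_b: Sequence[float],
                        alpha_normality: float = 0.05,
                        equal_var: bool = True) -> VariabilityComparison:
    """Compare two groups of replicate CVs with a normality-gated test.

    Each group is screened with a one-sample Kolmogorov-Smirnov test against
    a normal with sample-estimated moments (anti-conservative at small n, but
    it is the gate the assay-validation convention uses).  Both normal ->
    Student's t-test (equal variance by default); otherwise Mann-Whitney.
    """
    a = np.asarray(cvs_a, dtype=float)
    b = np.asarray(cvs_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")

    def ks_p(v: np.ndarray) -> float:
        if len(v) < 3 or v.std(ddof=1) == 0:
            return 1.0  # too small / degenerate to reject normality
        return float(stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue)

    pa, pb = ks_p(a), ks_p(b)
    if pa > alpha_normality and pb > alpha_normality:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return VariabilityComparison(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        normality_p=(pa, pb),
    )


def _group_summaries(pairs: PairedTiters, grouping: Sequence[str],
                     which: str) -> tuple[MethodGroupSummary, ...]:
    values = (pairs.reference_values if which == "reference"
              else pairs.evaluated_values)
    out = []
    for group in dict.fromkeys(grouping):
        vals = [v for v, g in zip(values, grouping) if g == group]
        mean, sd, cv = aggregate_replicates(vals)
        out.append(MethodGroupSummary(group=group, mean=mean, sd=sd, cv_percent=cv))
    return tuple(out)


def method_comparison_report(pairs: PairedTiters,
                             grouping: Sequence[str] | None = None,
                             ccc_scale: str = "log10",
                             equal_var: bool = True) -> AgreementReport:
    """Full agreement analysis of paired titers, grouped into replicate sets.

    ``grouping`` assigns each pair to its tube/replicate group (defaults to
    the pair labels).  Per-group means feed the |delta log10| summaries, the
    per-group CVs feed the variability test, and the raw pairs feed the
    Bland-Altman ratio analysis and the CCC (log10 scale by default, since
    titers typically span several decades).
    """
    if grouping is None:
        grouping = pairs.labels
    if len(grouping) != len(pairs):
        raise ValueError("grouping must assign every pair to a group")

    ref_groups = _group_summaries(pairs, grouping, "reference")
    ev_groups = _group_summaries(pairs, grouping, "evaluated")
    ev_by_group = {g.group: g for g in ev_groups}
    log_diffs = {
        g.group: abs_log10_difference(ev_by_group[g.group].mean, g.mean)
        for g in ref_groups
    }
    return AgreementReport(
        n_pairs=len(pairs),
        bland_altman=bland_altman_ratio(pairs),
        ccc=lins_ccc(pairs.reference_values, pairs.evaluated_values, scale=ccc_scale),
        variability=compare_variability(
            [g.cv_percent for g in ref_groups],
            [g.cv_percent for g in ev_groups],
            equal_var=equal_var,
        ),
        reference_groups=ref_groups,
        evaluated_groups=ev_groups,
        log_differences=log_diffs,
        mean_abs_log_difference=float(np.mean(list(log_diffs.values()))),
    )


def bland_altman_plot(result: BlandAltmanResult, path: str) -> None:
    """Ratio-vs-average plot: solid bias line, dashed 95% agreement limits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.averages_log10, result.ratios, color="k", zorder=3)
    ax.axhline(result.bias_ratio, color="k", lw=1.5)
    for limit in result.limits_of_agreement:
        ax.axhline(limit, color="k", lw=1.0, ls="--")
    ax.set_xlabel("average titer, log10(PFU/mL)")
    ax.set_ylabel("ratio evaluated / reference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
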