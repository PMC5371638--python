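"""Condition-level statistics for positioning, volumes and ploidy.

Shell distributions (territory counts per sub-shell I–V) are compared
between conditions with both a 2x5 chi-square contingency test and
per-shell 2x2 Fisher's exact tests (in-shell vs not); both are always
reported because neither test is canonical for this comparison.  Unbinned
distance distributions are compared with the two-sample Kolmogorov–Smirnov
test, and volume samples across shells with the Kruskal–Wallis rank test.

Interphase ploidy is called per nucleus from the number of retained
territory objects in a paint channel (2 = diploid, >2 = aneuploid gain,
<2 = loss); metaphase spreads are classified from their chromosome count
(45–46 pseudo-diploid, <45 loss, >46 gain).

Raw p-values are reported (no multiple-testing correction by default); an
optional Benjamini–Hochberg adjustment is available for the per-shell
Fisher p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import RadialMeasurement, ShellIndex, shell_of
from .segmentation import SegmentedObject

__all__ = [
    "ShellDistribution",
    "ShellComparison",
    "PloidyCall",
    "MetaphaseClass",
    "compare_shell_distributions",
    "ks_two_sample",
    "kruskal_wallis",
    "call_ploidy",
    "ploidy_cohort_summary",
    "classify_metaphase",
    "median_iqr",
    "benjamini_hochberg",
]

ALPHA = 0.05


@dataclass
class ShellDistribution:
    """Territory counts per sub-shell I–V for one condition."""

    condition: str
    counts: dict[ShellIndex, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {s: int(self.counts.get(s, 0)) for s in ShellIndex}
        if any(v < 0 for v in full.values()):
            raise ValueError("negative shell count")
        self.counts = full

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[s] for s in ShellIndex], dtype=int)

    @classmethod
    def from_rd_percent(cls, condition: str, rd_values) -> "ShellDistribution":
        counts: dict[ShellIndex, int] = {}
        for rd in rd_values:
            s = shell_of(float(rd))
            counts[s] = counts.get(s, 0) + 1
        return cls(condition=condition, counts=counts)

    @classmethod
    def from_measurements(
        cls, condition: str, measurements: list[RadialMeasurement]
    ) -> "ShellDistribution":
        return cls.from_rd_percent(condition, [m.rd_percent for m in measurements])

    def __add__(self, other: "ShellDistribution") -> "ShellDistribution":
        """Pooling across replicates is additive."""
        merged = {s: self.counts[s] + other.counts[s] for s in ShellIndex}
        return ShellDistribution(condition=self.condition, counts=merged)


@dataclass
class ShellComparison:
    """Report of a two-condition shell-distribution comparison."""

    condition_a: str
    condition_b: str
    chi2_statistic: float
    chi2_p: float
    fisher_p_per_shell: dict[ShellIndex, float]
    dropped_shells: list[ShellIndex]
    method: str

    @property
    def primary_p(self) -> float:
        if self.method == "fisher_per_shell":
            return min(self.fisher_p_per_shell.values())
        return self.chi2_p

    @property
    def significant(self) -> bool:
        return self.primary_p < ALPHA

    @property
    def tests_disagree(self) -> bool:
        fisher_sig = any(p < ALPHA for p in self.fisher_p_per_shell.values())
        return (self.chi2_p < ALPHA) != fisher_sig


def compare_shell_distributions(
    a: ShellDistribution,
    b: ShellDistribution,
    method: str = "chi2",
) -> ShellComparison:
    """Compare two shell distributions; both test families always computed.

    chi2: one 2x5 contingency test over the shell counts (shells empty in
    both conditions are dropped with a warning).  fisher_per_shell: for
    each shell, a 2x2 Fisher's exact test of in-shell vs not-in-shell
    counts.  ``method`` only selects which p-value ``primary_p`` reports.
    """
    if method not in ("chi2", "fisher_per_shell"):
        raise ValueError(f"unknown method {method!r}")
    if a.n == 0 or b.n == 0:
        raise ValueError("both conditions need at least one territory")

    arr_a, arr_b = a.as_array(), b.as_array()
    keep = (arr_a + arr_b) > 0
    dropped = [s for s, k in zip(ShellIndex, keep) if not k]
    if dropped:
        warnings.warn(
            f"shell(s) {[s.name for s in dropped]} empty in both conditions; "
            "dropped from the chi-square table",
            stacklevel=2,
        )
    table = np.stack([arr_a[keep], arr_b[keep]])
    if table.shape[1] < 2:
        chi2_stat, chi2_p = 0.0, 1.0
    elif np.array_equal(arr_a, arr_b):
        # identical distributions: statistic is exactly 0, p exactly 1
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table)

    fisher = {}
    for s, ca, cb in zip(ShellIndex, arr_a, arr_b):
        contingency = [[int(ca), int(a.n - ca)], [int(cb), int(b.n - cb)]]
        fisher[s] = float(stats.fisher_exact(contingency)[1])

    return ShellComparison(
        condition_a=a.condition,
        condition_b=b.condition,
        chi2_statistic=float(chi2_stat),
        chi2_p=float(chi2_p),
        fisher_p_per_shell=fisher,
        dropped_shells=dropped,
        method=method,
    )


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on raw (unbinned) distances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("KS test needs >= 5 samples per group")
    res = stats.ks_2samp(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal–Wallis H across >= 2 groups, midranks for ties.

    Implemented directly (rank sums with tie correction, chi-square
    reference distribution) so it can be cross-checked against an
    independent reference implementation.  All-identical values return
    H = 0, p = 1 with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Kruskal-Wallis H = 0", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(pooled)  # midranks
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


@dataclass
class PloidyCall:
    """Copy-number call for one chromosome in one nucleus."""

    nucleus_id: str
    chromosome_label: str
    copy_count: int
    flagged_qc: bool = False  # zero objects: possible hybridization failure

    @property
    def ploidy_class(self) -> str:
        if self.copy_count == 2:
            return "diploid"
        if self.copy_count > 2:
            return "aneuploid_gain"
        return "loss"


def call_ploidy(
    nucleus_id: str,
    chromosome_label: str,
    territory_objects: list[SegmentedObject],
) -> PloidyCall:
    """Copy count = number of retained territory objects in the channel."""
    count = len(territory_objects)
    return PloidyCall(
        nucleus_id=nucleus_id,
        chromosome_label=chromosome_label,
        copy_count=count,
        flagged_qc=(count == 0),
    )


def ploidy_cohort_summary(calls: list[PloidyCall]) -> dict[str, dict[str, float]]:
    """Per chromosome: % of nuclei in each ploidy class."""
    summary: dict[str, dict[str, float]] = {}
    by_chrom: dict[str, list[PloidyCall]] = {}
    for call in calls:
        by_chrom.setdefault(call.chromosome_label, []).append(call)
    for chrom, chrom_calls in by_chrom.items():
        n = len(chrom_calls)
        classes = [c.ploidy_class for c in chrom_calls]
        summary[chrom] = {
            "n_nuclei": n,
            "pct_loss": 100.0 * classes.count("loss") / n,
            "pct_diploid": 100.0 * classes.count("diploid") / n,
            "pct_aneuploid_gain": 100.0 * classes.count("aneuploid_gain") / n,
        }
    return summary


def classify_metaphase(count: int) -> str:
    """Metaphase-spread class from a chromosome count.

    45–46 -> pseudo_diploid, <45 -> loss, >46 -> gain.
    """
    if count < 0:
        raise ValueError("chromosome count must be >= 0")
    if count < 45:
        return "loss"
    if count <= 46:
        return "pseudo_diploid"
    return "gain"


def median_iqr(values) -> tuple[float, float]:
    """Median and IQR (Q3 - Q1, linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default report)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adjusted[idx] = running
    return adjusted
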