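"""Per-chromosome transcriptional deregulation statistics.

Given a table of per-gene fold changes and p-values from a knockdown vs
control comparison, this module applies the deregulation filter
(|fold change| >= 2.0 and p < 0.05), computes the per-chromosome
deregulation burden

    % deregulation = 100 * (deregulated genes on chromosome)
                          / (coding genes on chromosome),

flags chromosomes exceeding the 0.7 % significance cut (strict), compares
deregulated gene sets between knockdowns (set overlap), and regresses
% deregulation on gene density (genes/Mbp) reporting r².

Boundary conventions are deliberate and unit-tested: the fold-change cutoff
is inclusive on |fc|, the p cutoff is strict, and the 0.7 % significance
threshold is strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging_io import canonical_chromosome

__all__ = [
    "GeneRecord",
    "ChromosomeAnnotation",
    "DeregulationProfile",
    "filter_deregulated",
    "overlap",
    "percent_deregulation",
    "density_correlation",
    "gene_ids",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """One gene's differential-expression summary.

    ``fold_change`` is a signed *linear* fold change (+2.96 means 2.96-fold
    up, −2.0 means 2-fold down); zero is invalid.
    """

    gene_id: str
    chromosome: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError(f"gene {self.gene_id}: fold_change must be nonzero")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"gene {self.gene_id}: p_value {self.p_value} outside [0,1]")

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 0 else "down"


@dataclass(frozen=True)
class ChromosomeAnnotation:
    """Coding-gene count and length of one chromosome."""

    chromosome: str
    coding_genes: int
    length_mbp: float

    def __post_init__(self) -> None:
        if self.coding_genes <= 0:
            raise ValueError(f"chr{self.chromosome}: coding_genes must be > 0")
        if self.length_mbp <= 0:
            raise ValueError(f"chr{self.chromosome}: length_mbp must be > 0")

    @property
    def gene_density(self) -> float:
        """Coding genes per Mbp."""
        return self.coding_genes / self.length_mbp


#: Strict significance threshold on % deregulation per chromosome.
DEREG_SIGNIFICANCE_PCT = 0.7


@dataclass
class DeregulationProfile:
    """Per-chromosome deregulation burden for one knockdown condition."""

    condition: str
    n_deregulated: dict[str, int] = field(default_factory=dict)
    percent_dereg: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)

    @property
    def significant_chromosomes(self) -> list[str]:
        return [c for c, s in self.significant.items() if s]


def filter_deregulated(
    table: list[GeneRecord],
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split a gene table into (up, down) deregulated gene lists.

    A gene is deregulated when |fold_change| >= ``fc_cutoff`` (inclusive)
    and p_value < ``p_cutoff`` (strict).  The two returned lists are
    disjoint by construction (sign of the fold change).
    """
    if not table:
        raise ValueError("empty gene table")
    up = [g for g in table if g.fold_change >= fc_cutoff and g.p_value < p_cutoff]
    down = [g for g in table if -g.fold_change >= fc_cutoff and g.p_value < p_cutoff]
    return up, down


def gene_ids(records: list[GeneRecord]) -> set[str]:
    return {g.gene_id for g in records}


def overlap(set_a: set[str], set_b: set[str]) -> tuple[int, int, int]:
    """Set overlap between two deregulated gene-id sets.

    Returns ``(unique_to_a, unique_to_b, common)`` with
    ``unique_to_a + common == |A|`` and
    ``unique_to_a + unique_to_b + common == |A ∪ B|``.
    """
    a, b = set(set_a), set(set_b)
    common = len(a & b)
    return len(a) - common, len(b) - common, common


def percent_deregulation(
    dereg: list[GeneRecord],
    annotation: list[ChromosomeAnnotation],
    condition: str = "",
    significance_pct: float = DEREG_SIGNIFICANCE_PCT,
) -> DeregulationProfile:
    """Compute the per-chromosome % deregulation profile.

    Every chromosome in ``annotation`` gets an entry (zero deregulated genes
    → 0 %).  A deregulated gene on a chromosome absent from the annotation
    is an error naming the gene.  Significance is strict (> threshold).
    """
    ann = {a.chromosome: a for a in annotation}
    counts: dict[str, int] = {c: 0 for c in ann}
    seen: dict[str, set[str]] = {}
    for g in dereg:
        chrom = canonical_chromosome(g.chromosome)
        if chrom not in ann:
            raise KeyError(
                f"gene {g.gene_id}: chromosome {g.chromosome!r} not in annotation"
            )
        # A gene id may legitimately map to several chromosomes; count it once
        # per mapped chromosome but warn.
        if g.gene_id in seen and chrom not in seen[g.gene_id]:
            log.warning(
                "gene %s maps to multiple chromosomes; counted on each", g.gene_id
            )
        seen.setdefault(g.gene_id, set()).add(chrom)
        counts[chrom] += 1

    profile = DeregulationProfile(condition=condition)
    for chrom, a in ann.items():
        pct = 100.0 * counts[chrom] / a.coding_genes
        profile.n_deregulated[chrom] = counts[chrom]
        profile.percent_dereg[chrom] = pct
        profile.significant[chrom] = pct > significance_pct
    return profile


def density_correlation(
    profile: DeregulationProfile,
    annotation: list[ChromosomeAnnotation],
) -> float:
    """r² of OLS of % deregulation on gene density across chromosomes."""
    ann = {a.chromosome: a for a in annotation}
    chroms = [c for c in profile.percent_dereg if c in ann]
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes for the density regression")
    x = np.array([ann[c].gene_density for c in chroms], dtype=float)
    y = np.array([profile.percent_dereg[c] for c in chroms], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in gene density or % deregulation")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)
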