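"""Analytical-validation statistics for the targeted panel.

Covers the assay's validation suite: dilution-series design and limit of
detection, intra-run replicate reproducibility, cross-platform concordance,
and prospective-cohort summarisation.

Conventions (documented because they are easy to get wrong):

* Replicate dispersion is the population standard deviation (divisor n,
  not n-1) of the replicate values in fraction units; recomputing the
  printed replicate tables reproduces their dispersion column only under
  this reading.
* Reported percentages round half away from zero.  Cohort per-gene
  percentages use alteration-positive patients as the denominator; category
  percentages use all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from ._util import population_sd, round_half_away
from .kb import CATEGORY_LEVEL1, CATEGORY_LEVEL2, ClinicalReport


@dataclass(frozen=True)
class DilutionPoint:
    """One point of the positive-stock / wild-type mixing design."""

    target_vaf: float
    mix_fraction: float
    stock_vaf: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.mix_fraction <= 1.0):
            raise ValueError("mix_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ReplicateStats:
    mean_vaf: float        # percent, 2 decimals
    dispersion: float      # population SD of fractional vafs, 3 decimals
    sensitivity: float     # detected/expected as percent
    mean_depth: float      # reads, 2 decimals
    depth_dispersion: float  # population SD of depths, 3 decimals

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 100.0):
            raise ValueError("sensitivity must lie in [0, 100]")
        if self.dispersion < 0 or self.depth_dispersion < 0:
            raise ValueError("dispersions must be >= 0")


@dataclass(frozen=True)
class ConcordanceRow:
    label: str      # mutation type / gene
    platform: str   # comparator platform
    expected: int
    detected: int
    pct: float

    def __post_init__(self) -> None:
        if self.expected < 0 or self.detected < 0:
            raise ValueError("counts must be >= 0")
        if self.detected > self.expected:
            raise ValueError(
                f"detected ({self.detected}) exceeds expected ({self.expected}) "
                f"for {self.label}/{self.platform}"
            )


@dataclass(frozen=True)
class ConcordanceResult:
    rows: tuple[ConcordanceRow, ...]
    expected: int
    detected: int
    pct: float


@dataclass(frozen=True)
class LodRow:
    vtype: str
    vaf: float
    tested: int
    detected: int

    def __post_init__(self) -> None:
        if self.detected > self.tested:
            raise ValueError("detected must not exceed tested")


@dataclass(frozen=True)
class LodTable:
    rows: tuple[LodRow, ...]


@dataclass(frozen=True)
class CohortSummary:
    total_samples: int
    positive_patients: int
    gene_counts: dict[str, int]
    gene_pct: dict[str, int]           # of alteration-positive patients
    category_counts: dict[str, int]    # level-1 / level-2 / negative
    category_pct: dict[str, int]       # of all samples

    @property
    def actionable_pct(self) -> int:
        """Percent of samples carrying a level-1 or level-2 variant."""
        n = self.category_counts.get(CATEGORY_LEVEL1, 0) + \
            self.category_counts.get(CATEGORY_LEVEL2, 0)
        return int(round_half_away(100.0 * n / self.total_samples))


def dilution_design(
    stock_vaf: float, target_vafs: Sequence[float]
) -> list[DilutionPoint]:
    """Mixing fractions of positive stock needed to hit each target VAF.

    target = stock × mix, solved with exact rational arithmetic where the
    inputs are exactly representable.
    """
    if not (0.0 < stock_vaf <= 1.0):
        raise ValueError("stock_vaf must lie in (0, 1]")
    points = []
    for target in target_vafs:
        if target > stock_vaf:
            raise ValueError(
                f"target VAF {target} exceeds stock VAF {stock_vaf}"
            )
        mix = Fraction(str(target)) / Fraction(str(stock_vaf))
        points.append(
            DilutionPoint(
                target_vaf=target, mix_fraction=float(mix), stock_vaf=stock_vaf
            )
        )
    return points


def replicate_stats(
    vafs: Sequence[float], depths: Sequence[float], expected: int
) -> ReplicateStats:
    """Reproducibility statistics over replicate libraries of one variant.

    ``vafs`` are the detected allele fractions (fraction units) over the
    replicates in which the variant was seen; ``expected`` is the number of
    replicates in which it should have been seen.
    """
    if len(vafs) == 0 or len(vafs) != len(depths):
        raise ValueError("need equal, non-empty vaf and depth lists")
    if expected < len(vafs):
        raise ValueError("expected replicate count below detected count")
    mean_vaf = round_half_away(100.0 * sum(vafs) / len(vafs), 2)
    return ReplicateStats(
        mean_vaf=mean_vaf,
        dispersion=round_half_away(population_sd(list(vafs)), 3),
        sensitivity=round_half_away(100.0 * len(vafs) / expected, 2),
        mean_depth=round_half_away(sum(depths) / len(depths), 2),
        depth_dispersion=round_half_away(population_sd(list(depths)), 3),
    )


def concordance(
    rows: Iterable[tuple[str, str, int, int]]
) -> ConcordanceResult:
    """Per-row and overall concordance of the assay against comparators.

    Each row is (label, platform, expected, detected); percentages are to
    one decimal place and the overall figure is over summed counts, so it
    is invariant to row splitting/merging that preserves totals.
    """
    out_rows = tuple(
        ConcordanceRow(
            label=label, platform=platform, expected=exp, detected=det,
            pct=round_half_away(100.0 * det / exp, 1) if exp else 100.0,
        )
        for label, platform, exp, det in rows
    )
    total_exp = sum(r.expected for r in out_rows)
    total_det = sum(r.detected for r in out_rows)
    return ConcordanceResult(
        rows=out_rows,
        expected=total_exp,
        detected=total_det,
        pct=round_half_away(100.0 * total_det / total_exp, 1) if total_exp else 100.0,
    )


def lod_estimate(table: LodTable) -> dict[str, float | None]:
    """Limit of detection per mutation type from a detection-count grid.

    The LOD is the lowest VAF such that every grid point at that VAF or
    above shows full detection; None when no such VAF exists.
    """
    by_type: dict[str, list[LodRow]] = {}
    for row in table.rows:
        by_type.setdefault(row.vtype, []).append(row)
    lods: dict[str, float | None] = {}
    for vtype, rows in by_type.items():
        rows = sorted(rows, key=lambda r: r.vaf)
        lod = None
        for i, row in enumerate(rows):
            if all(r.detected == r.tested for r in rows[i:]):
                lod = row.vaf
                break
        lods[vtype] = lod
    return lods


def cohort_summary(reports: Sequence[ClinicalReport]) -> CohortSummary:
    """Per-gene alteration frequencies and category proportions of a cohort.

    A patient counts once per gene regardless of how many variants of that
    gene they carry; fusion findings count for the joined gene pair as one
    label.  Gene percentages are relative to alteration-positive patients,
    category percentages to all samples, both rounded half away from zero
    to integers.
    """
    if not reports:
        raise ValueError("cohort_summary requires at least one report")
    total = len(reports)
    gene_counts: dict[str, int] = {}
    positive = 0
    category_counts = {CATEGORY_LEVEL1: 0, CATEGORY_LEVEL2: 0, "negative": 0}
    for report in reports:
        category_counts[report.category] += 1
        genes = set()
        for f in report.findings:
            label = f.variant_key.split(":")[0] if f.vtype == "Fusion" else f.gene
            genes.add(label)
        if genes:
            positive += 1
        for g in genes:
            gene_counts[g] = gene_counts.get(g, 0) + 1
    gene_pct = {
        g: int(round_half_away(100.0 * n / positive)) if positive else 0
        for g, n in gene_counts.items()
    }
    category_pct = {
        c: int(round_half_away(100.0 * n / total))
        for c, n in category_counts.items()
    }
    return CohortSummary(
        total_samples=total,
        positive_patients=positive,
        gene_counts=dict(sorted(gene_counts.items())),
        gene_pct=dict(sorted(gene_pct.items())),
        category_counts=category_counts,
        category_pct=category_pct,
    )
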