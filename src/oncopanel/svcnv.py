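"""Simplified copy-number calling and split-read fusion detection.

Copy number: per-target mean depths for a sample are median-scaled against a
diploid baseline profile, and per-region log2 ratios are thresholded
(default gain >= 0.45, loss <= -0.6, chosen so a single-copy gain at the
closed-form ratio log2(3/2) = 0.585 is called while diploid depth noise
rarely is).  The integer copy-number estimate is round(2 * 2^ratio).

Fusions: split-read evidence records (two clipped segments per read) are
grouped transitively — two records are consistent when both clip positions
agree within a window and the strand pattern matches — and clusters with
enough support whose breakpoints fall in the panel's fusion-target genes
become fusion calls.  The cluster breakpoint is the modal clip position on
each side (ties to the smallest coordinate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .panel import Panel, TargetRegion
from .caller import VariantCall, CNV, FUSION

log = logging.getLogger(__name__)

DEFAULT_GAIN_THRESHOLD = 0.45
DEFAULT_LOSS_THRESHOLD = -0.6
DEFAULT_WINDOW = 5
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MIN_BASELINE_DEPTH = 50.0


@dataclass(frozen=True)
class DepthProfile:
    """Per-region mean deduplicated depth for one sample."""

    regions: tuple[TargetRegion, ...]
    depths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.depths):
            raise ValueError("regions and depths must be the same length")
        if any(d < 0 for d in self.depths):
            raise ValueError("depths must be >= 0")


@dataclass(frozen=True)
class RegionRatio:
    region: TargetRegion
    log2_ratio: float
    excluded: bool = False  # baseline too shallow to be informative


@dataclass(frozen=True)
class CnvCall:
    chrom: str
    start: int
    end: int
    genes: tuple[str, ...]
    log2_ratio: float  # mean over merged regions
    copy_number: int
    direction: str  # "gain" | "loss"
    n_regions: int

    def to_variant_call(self) -> VariantCall:
        return VariantCall(
            chrom=self.chrom, pos=self.start, ref="N",
            alt="<DUP>" if self.direction == "gain" else "<DEL>",
            vtype=CNV, alt_count=0, depth=0, vaf=0.0, p_value=0.0,
            gene=self.genes[0],
            info={
                "end": self.end, "copy_number": self.copy_number,
                "log2_ratio": self.log2_ratio, "direction": self.direction,
            },
        )


@dataclass(frozen=True)
class SplitReadEvidence:
    """One read aligning in two clipped segments across a breakpoint."""

    read_id: str
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str

    def __post_init__(self) -> None:
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError("clip positions must be >= 0")
        if self.strand_a not in "+-" or self.strand_b not in "+-":
            raise ValueError("strands must be '+' or '-'")


@dataclass(frozen=True)
class SplitReadCluster:
    chrom_a: str
    breakpoint_a: int
    strand_a: str
    chrom_b: str
    breakpoint_b: int
    strand_b: str
    support: int
    records: tuple[SplitReadEvidence, ...] = field(compare=False, default=())


@dataclass(frozen=True)
class FusionCall:
    gene_a: str
    chrom_a: str
    breakpoint_a: int
    gene_b: str
    chrom_b: str
    breakpoint_b: int
    orientation: str  # joined strand pattern, e.g. "+/-" (reverse-joined partner)
    support: int

    def to_variant_call(self) -> VariantCall:
        return VariantCall(
            chrom=self.chrom_a, pos=self.breakpoint_a, ref="N", alt="<BND>",
            vtype=FUSION, alt_count=self.support, depth=self.support,
            vaf=1.0, p_value=0.0, gene=self.gene_a,
            info={
                "partner_gene": self.gene_b, "partner_chrom": self.chrom_b,
                "partner_pos": self.breakpoint_b, "orientation": self.orientation,
            },
        )


def normalize_and_ratio(
    sample: DepthProfile,
    baseline: DepthProfile,
    min_baseline_depth: float = DEFAULT_MIN_BASELINE_DEPTH,
) -> list[RegionRatio]:
    """Median-scale both profiles and return per-region log2(sample/baseline).

    Both profiles are scaled so their median region depth equals 1, which
    removes library-size differences; regions whose baseline depth is below
    ``min_baseline_depth`` are flagged excluded (uninformative) and get a
    NaN ratio.
    """
    if sample.regions != baseline.regions:
        raise ValueError("sample and baseline must cover the same region set")
    s = np.asarray(sample.depths, dtype=float)
    b = np.asarray(baseline.depths, dtype=float)
    s_med, b_med = float(np.median(s)), float(np.median(b))
    if s_med <= 0 or b_med <= 0:
        raise ValueError("profiles must have positive median depth")
    s_norm, b_norm = s / s_med, b / b_med
    out: list[RegionRatio] = []
    for region, sn, bn, raw_b in zip(sample.regions, s_norm, b_norm, b):
        if raw_b < min_baseline_depth:
            out.append(RegionRatio(region, float("nan"), excluded=True))
        elif sn <= 0:
            out.append(RegionRatio(region, float("-inf")))
        else:
            out.append(RegionRatio(region, float(np.log2(sn / bn))))
    return out


def call_cnv(
    ratios: Sequence[RegionRatio],
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    min_regions: int = 2,
) -> list[CnvCall]:
    """Threshold per-region log2 ratios into merged copy-number calls.

    Contiguous regions (profile order, same chromosome) in the same
    direction merge into one call whose copy number is round(2 * 2^mean
    ratio).  Runs shorter than ``min_regions`` are suppressed unless the
    gene involved is a single-region target in the profile (a focal
    single-exon event cannot recruit neighbours).
    """
    if not (loss_threshold < 0 < gain_threshold):
        raise ValueError("thresholds must satisfy loss < 0 < gain")
    regions_per_gene = Counter(r.region.gene for r in ratios)
    calls: list[CnvCall] = []
    run: list[RegionRatio] = []
    run_dir = ""

    def flush() -> None:
        if not run:
            return
        genes = tuple(dict.fromkeys(r.region.gene for r in run))
        single_region_gene = all(regions_per_gene[g] == 1 for g in genes)
        if len(run) >= min_regions or single_region_gene:
            mean_ratio = float(np.mean([r.log2_ratio for r in run]))
            calls.append(
                CnvCall(
                    chrom=run[0].region.chrom,
                    start=run[0].region.start,
                    end=run[-1].region.end,
                    genes=genes,
                    log2_ratio=mean_ratio,
                    copy_number=max(int(round(2.0 * 2.0 ** mean_ratio)), 0),
                    direction=run_dir,
                    n_regions=len(run),
                )
            )

    for rr in ratios:
        if rr.excluded:
            flush(); run, run_dir = [], ""
            continue
        if rr.log2_ratio >= gain_threshold:
            direction = "gain"
        elif rr.log2_ratio <= loss_threshold:
            direction = "loss"
        else:
            direction = ""
        if direction and direction == run_dir and run and \
                run[-1].region.chrom == rr.region.chrom:
            run.append(rr)
        else:
            flush()
            run = [rr] if direction else []
            run_dir = direction
    flush()
    return calls


def _consistent(
    a: SplitReadEvidence, b: SplitReadEvidence, window: int
) -> bool:
    return (
        a.chrom_a == b.chrom_a
        and a.chrom_b == b.chrom_b
        and a.strand_a == b.strand_a
        and a.strand_b == b.strand_b
        and abs(a.pos_a - b.pos_a) <= window
        and abs(a.pos_b - b.pos_b) <= window
    )


def _modal_position(positions: Iterable[int]) -> int:
    counts = Counter(positions)
    best = max(counts.values())
    return min(p for p, c in counts.items() if c == best)


def cluster_split_reads(
    evidence: Sequence[SplitReadEvidence], window: int = DEFAULT_WINDOW
) -> list[SplitReadCluster]:
    """Transitively group mutually consistent split-read records.

    Union-find over the pairwise consistency relation (both clip positions
    within ``window``, identical strand pattern and chromosomes); the
    result is the set of connected components, each summarised by its modal
    clip positions.  Clusters are sorted by support descending, then
    coordinates.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    n = len(evidence)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if _consistent(evidence[i], evidence[j], window):
                union(i, j)

    groups: dict[int, list[SplitReadEvidence]] = {}
    for i, rec in enumerate(evidence):
        groups.setdefault(find(i), []).append(rec)

    clusters = [
        SplitReadCluster(
            chrom_a=recs[0].chrom_a,
            breakpoint_a=_modal_position(r.pos_a for r in recs),
            strand_a=recs[0].strand_a,
            chrom_b=recs[0].chrom_b,
            breakpoint_b=_modal_position(r.pos_b for r in recs),
            strand_b=recs[0].strand_b,
            support=len(recs),
            records=tuple(recs),
        )
        for recs in groups.values()
    ]
    clusters.sort(
        key=lambda c: (-c.support, c.chrom_a, c.breakpoint_a, c.chrom_b, c.breakpoint_b)
    )
    return clusters


def fusion_target_genes(panel: Panel) -> frozenset[str]:
    """Genes with intron-level capture — the panel's fusion targets."""
    return frozenset(
        r.gene for r in panel.regions if r.label.lower().startswith("intron")
    )


def call_fusion(
    clusters: Sequence[SplitReadCluster],
    panel: Panel,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[FusionCall]:
    """Promote well-supported clusters in fusion-target genes to calls.

    A cluster becomes a FusionCall when its support reaches ``min_support``
    and both breakpoints lie inside panel regions of fusion-target genes
    (genes captured at intron level); others are dropped with a logged
    reason.  Output is sorted by support descending.
    """
    targets = fusion_target_genes(panel)
    if not targets:
        raise ValueError("panel has no intron-level fusion-target regions")
    calls: list[FusionCall] = []
    for cl in clusters:
        if cl.support < min_support:
            continue
        gene_a = panel.gene_of(cl.chrom_a, cl.breakpoint_a)
        gene_b = panel.gene_of(cl.chrom_b, cl.breakpoint_b)
        if gene_a is None or gene_b is None:
            log.info(
                "dropping cluster %s:%d/%s:%d: breakpoint outside panel",
                cl.chrom_a, cl.breakpoint_a, cl.chrom_b, cl.breakpoint_b,
            )
            continue
        if gene_a not in targets or gene_b not in targets:
            log.info(
                "dropping cluster %s/%s: not a fusion-target gene pair",
                gene_a, gene_b,
            )
            continue
        calls.append(
            FusionCall(
                gene_a=gene_a, chrom_a=cl.chrom_a, breakpoint_a=cl.breakpoint_a,
                gene_b=gene_b, chrom_b=cl.chrom_b, breakpoint_b=cl.breakpoint_b,
                orientation=f"{cl.strand_a}/{cl.strand_b}",
                support=cl.support,
            )
        )
    calls.sort(key=lambda c: (-c.support, c.chrom_a, c.breakpoint_a))
    return calls


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

DEPTH_COLUMNS = ("chrom", "start", "end", "gene", "label", "depth")
SPLIT_COLUMNS = (
    "read_id", "chrom_a", "pos_a", "strand_a", "chrom_b", "pos_b", "strand_b"
)


def write_depth_profile(profile: DepthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DEPTH_COLUMNS) + "\n")
        for r, d in zip(profile.regions, profile.depths):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{r.label}\t{d:.4f}\n")


def read_depth_profile(path: str | Path) -> DepthProfile:
    regions: list[TargetRegion] = []
    depths: list[float] = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != DEPTH_COLUMNS:
            raise ValueError(f"{path}: unexpected depth-profile header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            regions.append(TargetRegion(f[0], int(f[1]), int(f[2]), f[3], f[4]))
            depths.append(float(f[5]))
    return DepthProfile(tuple(regions), tuple(depths))


def write_split_reads(
    records: Iterable[SplitReadEvidence], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SPLIT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.chrom_a}\t{r.pos_a}\t{r.strand_a}\t"
                f"{r.chrom_b}\t{r.pos_b}\t{r.strand_b}\n"
            )


def read_split_reads(path: str | Path) -> list[SplitReadEvidence]:
    out: list[SplitReadEvidence] = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != SPLIT_COLUMNS:
            raise ValueError(f"{path}: unexpected split-read header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            out.append(
                SplitReadEvidence(f[0], f[1], int(f[2]), f[3], f[4], int(f[5]), f[6])
            )
    return out
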