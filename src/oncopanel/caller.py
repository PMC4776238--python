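"""Hotspot SNV/InDel calling from pileup summaries under a binomial error model.

The unit of input is a deduplicated, base-quality-filtered pileup summary per
site (the upstream aligner/duplicate-marker is out of scope).  At each site,
each non-reference allele with k supporting reads out of depth n is scored
with the binomial tail p-value P(X >= k | X ~ Binomial(n, e)), where e is
the substitution or indel error rate of the error model.  A call PASSes when
the p-value is at or below the configured per-site alpha and the supporting
reads and allele fraction clear their absolute floors.

The defaults (e_sub = 1e-3, matching a Q30 base-quality floor; e_indel =
1e-4; alpha = 1e-5; >= 4 supporting reads; VAF >= 0.005; depth >= 50) give
closed-form sensitivity and specificity above 99% for variants at allele
fraction 0.03 and ~450x depth; ``detection_power`` computes that power
exactly.

Pileup allele tokens: a single base (``A``) for substitutions,
``ins<SEQ>`` for insertions, ``del<N>`` for deletions of N bases, with the
site's ``ref`` base acting as the anchor base for indels (left-aligned
upstream representation assumed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from scipy.special import bdtrc

from ._util import round_half_away

log = logging.getLogger(__name__)

SNV = "SNV"
INDEL = "InDel"
CNV = "CNV"
FUSION = "Fusion"


def is_indel_allele(allele: str) -> bool:
    return allele.startswith("ins") or allele.startswith("del")


@dataclass(frozen=True)
class PileupSite:
    """Deduplicated, quality-filtered allele counts at one genomic position."""

    chrom: str
    pos: int  # 0-based
    ref: str
    depth: int
    allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        for allele, count in self.allele_counts.items():
            if count < 0:
                raise ValueError(f"negative count for allele {allele}")
            if count > self.depth:
                raise ValueError(
                    f"allele {allele} count {count} exceeds depth {self.depth}"
                )


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution and per-site indel error probabilities."""

    e_sub: float = 1e-3
    e_indel: float = 1e-4

    def __post_init__(self) -> None:
        for e in (self.e_sub, self.e_indel):
            if not (0.0 < e < 0.5):
                raise ValueError("error rates must lie in (0, 0.5)")

    def rate_for(self, allele: str) -> float:
        return self.e_indel if is_indel_allele(allele) else self.e_sub


@dataclass(frozen=True)
class CallerConfig:
    alpha: float = 1e-5
    min_vaf: float = 0.005
    min_alt_reads: int = 4
    min_depth: int = 50
    mode: str = "hotspot"  # "hotspot" | "panel-wide"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf must lie in [0, 1]")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if self.mode not in ("hotspot", "panel-wide"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class VariantCall:
    """A detected variant with allele fraction and support evidence.

    SNV/InDel calls come from the pileup caller; CNV and fusion calls are
    adapted into this shape for annotation and reporting (``info`` carries
    type-specific extras such as the fusion partner or copy number).
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    vtype: str  # SNV | InDel | CNV | Fusion
    alt_count: int
    depth: int
    vaf: float
    p_value: float
    filter: str = "PASS"
    gene: str = ""
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError("vaf must lie in [0, 1]")
        if self.alt_count > self.depth:
            raise ValueError("alt_count must not exceed depth")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def is_pass(self) -> bool:
        return self.filter == "PASS"


def binom_sf(k_minus_1: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), given k-1 (survival function)."""
    return float(bdtrc(k_minus_1, n, p))


def min_supporting_reads(depth: int, error_rate: float, alpha: float) -> int:
    """Smallest read count k with P(X >= k | Binomial(depth, e)) <= alpha.

    Returns depth + 1 if no attainable count is significant.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 < error_rate < 1.0):
        raise ValueError("error_rate must lie in (0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    # P(X >= k) is non-increasing in k: binary search the crossing point.
    lo, hi = 1, depth + 1
    if binom_sf(depth - 1, depth, error_rate) > alpha:
        return depth + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if binom_sf(mid - 1, depth, error_rate) <= alpha:
            hi = mid
        else:
            lo = mid + 1
    return lo


def detection_power(
    depth: int, vaf: float, error_rate: float, alpha: float
) -> float:
    """Probability that a true variant at the given allele fraction is called.

    Closed form: P(X >= k* | X ~ Binomial(depth, vaf)) with k* from
    ``min_supporting_reads``.  Exactly monotone in vaf at fixed depth; in
    depth it is monotone between the depths at which k* increments (the
    usual discrete-test sawtooth).
    """
    if not (0.0 < vaf <= 1.0):
        raise ValueError("vaf must lie in (0, 1]")
    k = min_supporting_reads(depth, error_rate, alpha)
    if k > depth:
        return 0.0
    return binom_sf(k - 1, depth, vaf)


def call_site(
    site: PileupSite,
    model: ErrorModel = ErrorModel(),
    config: CallerConfig = CallerConfig(),
    alpha: float | None = None,
) -> list[VariantCall]:
    """Score every observed non-reference allele at one site.

    Returns one candidate VariantCall per non-reference allele with at
    least one supporting read; calls that fail a threshold carry the failed
    filter names instead of PASS.  Sites below ``config.min_depth`` are
    skipped with a logged reason (empty result, no exception).
    ``alpha`` overrides the per-test significance level (used for
    multiple-testing correction in panel-wide mode).
    """
    if site.depth < config.min_depth:
        log.info(
            "skipping %s:%d: depth %d below min_depth %d",
            site.chrom, site.pos, site.depth, config.min_depth,
        )
        return []
    a = config.alpha if alpha is None else alpha
    calls: list[VariantCall] = []
    for allele in sorted(site.allele_counts):
        count = site.allele_counts[allele]
        if count <= 0 or allele == site.ref:
            continue
        e = model.rate_for(allele)
        p_value = binom_sf(count - 1, site.depth, e)
        vaf = round_half_away(count / site.depth, 4)
        failed = []
        if p_value > a:
            failed.append("sig")
        if count < config.min_alt_reads:
            failed.append("min_alt_reads")
        if vaf < config.min_vaf:
            failed.append("min_vaf")
        calls.append(
            VariantCall(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=allele,
                vtype=INDEL if is_indel_allele(allele) else SNV,
                alt_count=count,
                depth=site.depth,
                vaf=vaf,
                p_value=min(p_value, 1.0),
                filter="PASS" if not failed else ";".join(failed),
            )
        )
    return calls


def call_sample(
    sites: Iterable[PileupSite],
    model: ErrorModel = ErrorModel(),
    config: CallerConfig = CallerConfig(),
    hotspots: Sequence[tuple[str, int]] | None = None,
) -> list[VariantCall]:
    """Call variants across a sample's pileup sites.

    In hotspot mode only hotspot (chrom, pos) entries are tested, each at
    the per-site alpha (tumour-only interpretation restricted to known
    somatic hotspots).  In panel-wide mode every site is tested and alpha
    is Bonferroni-divided by the number of tested (position, alternate)
    pairs: three substitution alternates per site plus any observed indel
    alleles.  Output is sorted by (chrom, pos, alt).
    """
    sites = list(sites)
    if config.mode == "hotspot":
        if not hotspots:
            raise ValueError("hotspot mode requires a non-empty hotspot list")
        wanted = set(hotspots)
        tested = [s for s in sites if (s.chrom, s.pos) in wanted]
        alpha = config.alpha
    else:
        tested = sites
        n_tests = sum(
            3 + sum(1 for a in s.allele_counts if is_indel_allele(a))
            for s in tested
        )
        alpha = config.alpha / max(n_tests, 1)
    out: list[VariantCall] = []
    for site in tested:
        out.extend(call_site(site, model, config, alpha=alpha))
    out.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return out


def strand_bias_pvalue(fwd: int, rev: int) -> float:
    """Two-sided binomial p-value for forward/reverse support imbalance.

    Optional post-filter for pileups that carry per-strand support; not
    applied by default.
    """
    from scipy.stats import binomtest

    if fwd < 0 or rev < 0 or fwd + rev == 0:
        raise ValueError("strand counts must be non-negative with positive total")
    return float(binomtest(fwd, fwd + rev, 0.5).pvalue)


# ---------------------------------------------------------------------------
# Pileup TSV I/O (documented dialect: chrom, pos, ref, depth, alleles with
# "allele:count" pairs comma-joined, "." when none)
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ("chrom", "pos", "ref", "depth", "alleles")


def write_pileup_tsv(sites: Iterable[PileupSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for s in sites:
            pairs = ",".join(
                f"{a}:{c}" for a, c in sorted(s.allele_counts.items()) if c > 0
            )
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.depth}\t{pairs or '.'}\n")


def read_pileup_tsv(path: str | Path) -> list[PileupSite]:
    sites: list[PileupSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PILEUP_COLUMNS:
            raise ValueError(
                f"{path}: expected pileup header {PILEUP_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            counts: dict[str, int] = {}
            if fields[4] != ".":
                for pair in fields[4].split(","):
                    allele, _, num = pair.rpartition(":")
                    if not allele:
                        raise ValueError(f"{path}:{lineno}: malformed allele pair {pair!r}")
                    counts[allele] = int(num)
            sites.append(
                PileupSite(fields[0], int(fields[1]), fields[2], int(fields[3]), counts)
            )
    return sites


# ---------------------------------------------------------------------------
# Calls TSV I/O
# ---------------------------------------------------------------------------

CALL_COLUMNS = (
    "chrom", "pos", "ref", "alt", "vtype", "alt_count", "depth",
    "vaf", "p_value", "filter", "gene",
)


def write_calls_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.vtype}\t{c.alt_count}\t"
                f"{c.depth}\t{c.vaf:.4f}\t{c.p_value:.6g}\t{c.filter}\t{c.gene}\n"
            )


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != CALL_COLUMNS:
            raise ValueError(f"{path}: unexpected calls header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            calls.append(
                VariantCall(
                    chrom=f[0], pos=int(f[1]), ref=f[2], alt=f[3], vtype=f[4],
                    alt_count=int(f[5]), depth=int(f[6]), vaf=float(f[7]),
                    p_value=float(f[8]), filter=f[9], gene=f[10],
                )
            )
    return calls
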