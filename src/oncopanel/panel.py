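"""Targeted-panel model: regions, loading/merging, and capture QC metrics.

The panel is a set of exon/intron target regions on a hybrid-capture chip.
Coordinates follow the BED convention (0-based, half-open) both on disk and
in memory; 1-based coordinates appear only at VCF emission.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetRegion:
    """One captured target: an exon or intron of a panel gene.

    ``part`` distinguishes actionable-now genes ("I") from prognostic /
    frequently-mutated genes ("II"); it is descriptive metadata only.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    gene: str
    label: str = ""
    part: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("TargetRegion chrom must be non-empty")
        if not self.gene:
            raise ValueError("TargetRegion gene must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"TargetRegion requires 0 <= start < end, got {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Panel:
    """An ordered, non-overlapping collection of target regions."""

    regions: tuple[TargetRegion, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        prev: TargetRegion | None = None
        for r in self.regions:
            if prev is not None and prev.chrom == r.chrom:
                if r.start < prev.start:
                    raise ValueError("Panel regions must be sorted by (chrom, start)")
                if r.start < prev.end:
                    raise ValueError(
                        f"Panel regions overlap: {prev.chrom}:{prev.start}-{prev.end} "
                        f"and {r.chrom}:{r.start}-{r.end}"
                    )
            elif prev is not None and r.chrom < prev.chrom:
                raise ValueError("Panel regions must be sorted by (chrom, start)")
            prev = r

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({r.gene for r in self.regions}))

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.regions)

    def gene_of(self, chrom: str, pos: int) -> str | None:
        """Gene whose region contains (chrom, pos), else None."""
        r = self.region_at(chrom, pos)
        return r.gene if r is not None else None

    def region_at(self, chrom: str, pos: int) -> TargetRegion | None:
        idx = self._index()
        starts, regs = idx.get(chrom, ((), ()))
        i = bisect_right(starts, pos) - 1
        if i >= 0 and regs[i].end > pos:
            return regs[i]
        return None

    def contains(self, chrom: str, pos: int) -> bool:
        return self.region_at(chrom, pos) is not None

    def _index(self):
        # lazy per-chrom (starts, regions) index; frozen dataclass, so cache
        # via object.__setattr__
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {}
            for r in self.regions:
                idx.setdefault(r.chrom, ([], []))
                idx[r.chrom][0].append(r.start)
                idx[r.chrom][1].append(r)
            idx = {c: (tuple(s), tuple(g)) for c, (s, g) in idx.items()}
            object.__setattr__(self, "_idx", idx)
        return idx


@dataclass(frozen=True)
class PanelStats:
    genes: int
    regions: int
    total_bases: int


@dataclass(frozen=True)
class CoverageQC:
    """Capture/coverage QC for one sample over the panel."""

    mean_depth: float
    frac_ge_threshold: float
    on_target_fraction: float
    threshold: int

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        for f in (self.frac_ge_threshold, self.on_target_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("QC fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "mean_depth": self.mean_depth,
            "frac_ge_threshold": self.frac_ge_threshold,
            "on_target_fraction": self.on_target_fraction,
            "threshold": self.threshold,
        }


def _parse_name_field(name: str) -> tuple[str, str, str]:
    parts = (name.split("|") + ["", "", ""])[:3]
    gene = parts[0] or "NA"
    return gene, parts[1], parts[2]


def load_panel(path: str | Path, name: str | None = None) -> Panel:
    """Read a BED file (>=4 columns: chrom, start, end, name) into a Panel.

    The name column is ``gene|label|part`` with missing fields defaulted.
    Regions are sorted; overlapping regions on the same chromosome are
    merged, keeping gene/label/part of the first, with a logged warning.
    """
    path = Path(path)
    raw: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            gene, label, part = _parse_name_field(fields[3])
            raw.append(TargetRegion(fields[0], start, end, gene, label, part))
    merged = merge_regions(raw)
    return Panel(regions=tuple(merged), name=name or path.stem)


def merge_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Sort regions and merge same-chromosome overlaps (first wins metadata)."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    out: list[TargetRegion] = []
    for r in ordered:
        if out and out[-1].chrom == r.chrom and r.start < out[-1].end:
            prev = out[-1]
            log.warning(
                "merging overlapping regions %s:%d-%d (%s) and %s:%d-%d (%s)",
                prev.chrom, prev.start, prev.end, prev.gene,
                r.chrom, r.start, r.end, r.gene,
            )
            out[-1] = TargetRegion(
                prev.chrom, prev.start, max(prev.end, r.end),
                prev.gene, prev.label, prev.part,
            )
        else:
            out.append(r)
    return out


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a Panel back to 4-column BED (name = gene|label|part)."""
    with open(path, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}|{r.label}|{r.part}\n")


def panel_stats(panel: Panel) -> PanelStats:
    """Gene count, region count, and total targeted bases."""
    return PanelStats(
        genes=len(panel.genes), regions=panel.n_regions, total_bases=panel.total_bases
    )


def coverage_qc(
    panel: Panel,
    per_base_depths: Mapping[tuple[str, int], int],
    total_effective_bases: int,
    threshold: int = 20,
) -> CoverageQC:
    """Coverage QC over the panel from per-base depths.

    ``per_base_depths`` maps (chrom, 0-based position) -> deduplicated depth;
    positions absent from the map count as depth 0.  Off-panel positions in
    the map are ignored.  ``total_effective_bases`` is the sample's total
    sequenced base count after filtering (on- plus off-target); the
    on-target fraction is Σ on-target depth / total_effective_bases, i.e.
    computed on base counts.
    """
    if panel.n_regions == 0:
        raise ValueError("coverage_qc requires a non-empty panel")
    target_size = panel.total_bases
    on_target = 0
    n_ge = 0
    for (chrom, pos), depth in per_base_depths.items():
        if depth < 0:
            raise ValueError(f"negative depth at {chrom}:{pos}")
        if not panel.contains(chrom, pos):
            continue
        on_target += depth
        if depth >= threshold:
            n_ge += 1
    if total_effective_bases < on_target:
        raise ValueError(
            "total_effective_bases must be >= total on-target base count"
        )
    frac = 1.0 if threshold <= 0 else n_ge / target_size
    return CoverageQC(
        mean_depth=on_target / target_size,
        frac_ge_threshold=frac,
        on_target_fraction=(on_target / total_effective_bases)
        if total_effective_bases > 0
        else 0.0,
        threshold=threshold,
    )
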