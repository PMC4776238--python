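"""Drug–variant knowledge base, evidence-level tiering and clinical reports.

Evidence for drug sensitivity or resistance in lung adenocarcinoma is
organised in two patterns with ordered levels: sensitivity {1A, 1B, 2A, 2B,
2C} and resistance {1A, 1B, 2A, 2B}.  1A/1B reflect approved/clinically
validated evidence in lung cancer ("level 1"); 2A/2B/2C reflect evidence
borrowed from other tumour types, case reports or pre-clinical work
("level 2").  A call's tier is the highest-priority level among its
knowledge-base matches under the ordering 1A > 1B > 2A > 2B > 2C; both
patterns are retained in the match list and the ordinal maximum is used
only for sample-level rollup.

Variant keys are normalized descriptors: ``GENE:L858R`` (protein change),
``GENE:c.2573T>G`` (cDNA fallback), ``GENE:ex19del`` (exon-level class for
recurrent deletion/insertion families), ``GENEA-GENEB:fusion`` (gene pair,
alphabetical), and ``GENE:amp`` (amplification).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .caller import VariantCall, SNV, INDEL, CNV, FUSION
from .panel import Panel, CoverageQC

log = logging.getLogger(__name__)

SENSITIVITY = "sensitivity"
RESISTANCE = "resistance"
LEVELS = ("1A", "1B", "2A", "2B", "2C")
LEVEL_ORDER = {lvl: i for i, lvl in enumerate(LEVELS)}
LEVELS_BY_PATTERN = {
    SENSITIVITY: frozenset(LEVELS),
    RESISTANCE: frozenset(("1A", "1B", "2A", "2B")),
}
LEVEL1 = frozenset(("1A", "1B"))
CATEGORY_LEVEL1 = "level-1"
CATEGORY_LEVEL2 = "level-2"
CATEGORY_UNCLASSIFIED = "unclassified"

VARIANT_TYPES = (SNV, INDEL, FUSION, "Amplification")


# ---------------------------------------------------------------------------
# Bundled transcript map (hg19) for the panel's reportable hotspot genes.
# Exon tuples are (genomic start, genomic end, cDNA coordinate of the exon's
# first base), genomic coordinates 1-based inclusive; minus-strand genes
# count cDNA from the exon's right edge and complement alleles.
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class Transcript:
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int, int], ...]
    protein: Mapping[str, str] = field(default_factory=dict)
    # (genomic start, genomic end, indel kind "del"/"ins", class key suffix)
    classes: tuple[tuple[int, int, str, str], ...] = ()

    def g_to_c(self, gpos: int) -> int | None:
        """Map a 1-based genomic position to a cDNA coordinate, or None."""
        for gstart, gend, cstart in self.exons:
            if gstart <= gpos <= gend:
                if self.strand == "+":
                    return cstart + (gpos - gstart)
                return cstart + (gend - gpos)
        return None

    def to_cdna_allele(self, base: str) -> str:
        return base if self.strand == "+" else base.translate(_COMPLEMENT)


BUNDLED_TRANSCRIPTS: dict[str, Transcript] = {
    "EGFR": Transcript(
        gene="EGFR", chrom="chr7", strand="+",
        exons=(
            (55241614, 55241736, 2062),  # exon 18
            (55242415, 55242513, 2185),  # exon 19
            (55248986, 55249171, 2284),  # exon 20
            (55259412, 55259567, 2470),  # exon 21
        ),
        protein={
            "c.2573T>G": "L858R",
            "c.2369C>T": "T790M",
            "c.2582T>A": "L861Q",
            "c.2156G>C": "G719A",
            "c.2303G>T": "S768I",
        },
        classes=(
            (55242415, 55242513, "del", "ex19del"),
            (55248986, 55249171, "ins", "ex20ins"),
        ),
    ),
    "KRAS": Transcript(
        gene="KRAS", chrom="chr12", strand="-",
        exons=((25398208, 25398329, -10),),  # exon 2 (includes 5'UTR)
        protein={
            "c.34G>T": "G12C",
            "c.34G>A": "G12S",
            "c.35G>A": "G12D",
            "c.35G>T": "G12V",
            "c.38G>A": "G13D",
        },
    ),
    "BRAF": Transcript(
        gene="BRAF", chrom="chr7", strand="-",
        exons=(
            (140453075, 140453193, 1742),  # exon 15
            (140481375, 140481493, 1324),  # exon 11
        ),
        protein={
            "c.1799T>A": "V600E",
            "c.1406G>C": "G469A",
            "c.1781A>G": "D594G",
        },
    ),
    "PIK3CA": Transcript(
        gene="PIK3CA", chrom="chr3", strand="+",
        exons=(
            (178936001, 178936132, 1543),  # exon 10
            (178951880, 178952152, 2935),  # exon 21
        ),
        protein={
            "c.1624G>A": "E542K",
            "c.1633G>A": "E545K",
            "c.1636C>A": "Q546K",
            "c.3140A>G": "H1047R",
            "c.3140A>T": "H1047L",
        },
    ),
    "PTEN": Transcript(
        gene="PTEN", chrom="chr10", strand="+",
        exons=((89692769, 89693008, 254),),  # exon 5
        protein={"c.389G>A": "R130Q"},
    ),
    "AKT1": Transcript(
        gene="AKT1", chrom="chr14", strand="-",
        exons=((105246425, 105246560, 40),),  # exon 3
        protein={"c.49G>A": "E17K"},
    ),
    "ERBB2": Transcript(
        gene="ERBB2", chrom="chr17", strand="+",
        exons=((37880979, 37881164, 2263),),  # exon 20
        protein={},
        classes=((37880979, 37881164, "ins", "ex20ins"),),
    ),
}


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KbEntry:
    gene: str
    variant_key: str
    variant_type: str  # SNV | InDel | Fusion | Amplification
    drug: str
    pattern: str  # sensitivity | resistance
    level: str
    evidence: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.variant_key:
            raise ValueError("variant_key must be non-empty")
        if self.pattern not in LEVELS_BY_PATTERN:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.level not in LEVELS_BY_PATTERN[self.pattern]:
            raise ValueError(
                f"level {self.level} not valid for pattern {self.pattern}"
            )
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant_type {self.variant_type!r}")


@dataclass(frozen=True)
class KnowledgeBase:
    entries: tuple[KbEntry, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.gene, e.variant_key, e.drug, e.pattern)
            if key in seen:
                raise ValueError(f"duplicate knowledge-base entry {key}")
            seen.add(key)

    def composition(self) -> dict:
        """Entry counts by variant type plus distinct gene and drug counts."""
        by_type = {t: 0 for t in VARIANT_TYPES}
        for e in self.entries:
            by_type[e.variant_type] += 1
        return {
            "total": len(self.entries),
            "by_type": by_type,
            "genes": len({e.gene for e in self.entries}),
            "drugs": len({e.drug for e in self.entries}),
        }


_KB_REQUIRED = ("gene", "variant_key", "variant_type", "drug", "pattern", "level")


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base from versioned JSON."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ValueError(f"{path}: knowledge base JSON must have an 'entries' list")
    entries = []
    for i, raw in enumerate(doc["entries"]):
        missing = [k for k in _KB_REQUIRED if k not in raw]
        if missing:
            raise ValueError(f"{path}: entry {i} missing fields {missing}")
        try:
            entries.append(
                KbEntry(
                    gene=raw["gene"], variant_key=raw["variant_key"],
                    variant_type=raw["variant_type"], drug=raw["drug"],
                    pattern=raw["pattern"], level=raw["level"],
                    evidence=raw.get("evidence", ""), source=raw.get("source", ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: entry {i}: {exc}") from exc
    return KnowledgeBase(tuple(entries), version=doc.get("version", "unversioned"))


def write_kb(kb: KnowledgeBase, path: str | Path) -> None:
    doc = {
        "version": kb.version,
        "entries": [
            {
                "gene": e.gene, "variant_key": e.variant_key,
                "variant_type": e.variant_type, "drug": e.drug,
                "pattern": e.pattern, "level": e.level,
                "evidence": e.evidence, "source": e.source,
            }
            for e in kb.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Variant-key normalization
# ---------------------------------------------------------------------------


def left_align_indel(pos: int, ref: str, alt: str, context: str = "") -> tuple[int, str, str]:
    """Trim shared flanking bases of an explicit ref/alt pair (left alignment).

    Removes the common suffix then the common prefix (keeping one anchor
    base), the usual VCF-style minimal representation.  ``context`` is
    unused here but kept for callers that later supply reference sequence
    for full left shifting.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _indel_span(call: VariantCall) -> tuple[str, int, int] | None:
    """(kind, 1-based genomic start, length) of an indel call, if parseable."""
    alt = call.alt
    if alt.startswith("del"):
        try:
            length = int(alt[3:])
        except ValueError:
            length = len(alt) - 3
        return "del", call.pos + 2, length  # first deleted base, after anchor
    if alt.startswith("ins"):
        return "ins", call.pos + 1, len(alt) - 3
    # explicit ref/alt sequence representation
    pos, ref, a = left_align_indel(call.pos, call.ref, alt)
    if len(ref) > len(a):
        return "del", pos + 2, len(ref) - len(a)
    if len(a) > len(ref):
        return "ins", pos + 1, len(a) - len(ref)
    return None


def variant_key_set(
    call: VariantCall,
    transcripts: Mapping[str, Transcript] = BUNDLED_TRANSCRIPTS,
    panel: Panel | None = None,
) -> tuple[str, ...]:
    """All keys under which a call can match the knowledge base.

    Most specific first: protein / exact descriptor, then any exon-level
    class key.  Calls that cannot be placed in a panel gene get a
    genomic-fallback key (never matched by the bundled KB) with a warning.
    """
    if call.vtype == FUSION:
        partner = call.info.get("partner_gene", "")
        pair = "-".join(sorted(g for g in (call.gene, partner) if g))
        return (f"{pair}:fusion",)
    if call.vtype == CNV:
        if call.info.get("direction", "gain") == "gain" or call.alt == "<DUP>":
            return (f"{call.gene}:amp",)
        return (f"{call.gene}:loss",)

    gene = call.gene
    if not gene and panel is not None:
        gene = panel.gene_of(call.chrom, call.pos) or ""
    tx = transcripts.get(gene)
    if tx is None or tx.chrom != call.chrom:
        if not gene:
            log.warning(
                "call %s:%d outside panel genes; unmatchable key",
                call.chrom, call.pos,
            )
            gene = "?"
        return (f"{gene}:g.{call.pos + 1}{call.ref}>{call.alt}",)

    keys: list[str] = []
    if call.vtype == SNV:
        c = tx.g_to_c(call.pos + 1)
        if c is not None:
            cdna = f"c.{c}{tx.to_cdna_allele(call.ref)}>{tx.to_cdna_allele(call.alt)}"
            protein = tx.protein.get(cdna)
            if protein:
                keys.append(f"{gene}:{protein}")
            keys.append(f"{gene}:{cdna}")
        else:
            keys.append(f"{gene}:g.{call.pos + 1}{call.ref}>{call.alt}")
        return tuple(keys)

    # InDel
    span = _indel_span(call)
    if span is None:
        return (f"{gene}:g.{call.pos + 1}{call.ref}>{call.alt}",)
    kind, gstart, length = span
    gend = gstart + length - 1 if kind == "del" else gstart
    c1, c2 = tx.g_to_c(gstart), tx.g_to_c(gend)
    if c1 is not None and c2 is not None:
        lo, hi = sorted((c1, c2))
        if kind == "del":
            keys.append(f"{gene}:c.{lo}_{hi}del{length}")
        else:
            keys.append(f"{gene}:c.{lo}ins{length}")
    else:
        keys.append(f"{gene}:g.{gstart}{kind}{length}")
    for cstart, cend, ckind, suffix in tx.classes:
        if ckind == kind and cstart <= gstart <= cend:
            keys.append(f"{gene}:{suffix}")
    return tuple(keys)


def normalize_variant_key(
    call: VariantCall,
    transcripts: Mapping[str, Transcript] = BUNDLED_TRANSCRIPTS,
    panel: Panel | None = None,
) -> str:
    """Canonical reportable key for a call.

    Protein change when mappable, else cDNA change; indels falling in a
    recurrent exon-level family report the class key (e.g. the exon-19
    deletion class); fusions an alphabetical gene pair; copy gains
    ``GENE:amp``.  Idempotent for a fixed call.
    """
    keys = variant_key_set(call, transcripts, panel)
    if call.vtype == INDEL:
        # exon-level class descriptor preferred for recurrent families
        for k in keys:
            if ":c." not in k and ":g." not in k:
                return k
    return keys[0]


# ---------------------------------------------------------------------------
# Tiering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TierAssignment:
    call: VariantCall
    variant_key: str
    matches: tuple[KbEntry, ...]
    best_level: str | None
    category: str

    def __post_init__(self) -> None:
        if (self.best_level is None) != (len(self.matches) == 0):
            raise ValueError("best_level present iff matches non-empty")


def _category_for(level: str | None) -> str:
    if level is None:
        return CATEGORY_UNCLASSIFIED
    return CATEGORY_LEVEL1 if level in LEVEL1 else CATEGORY_LEVEL2


def classify(
    call: VariantCall,
    kb: KnowledgeBase,
    transcripts: Mapping[str, Transcript] = BUNDLED_TRANSCRIPTS,
    panel: Panel | None = None,
) -> TierAssignment:
    """Match a call against the knowledge base and assign its tier.

    Matching accepts the exact normalized key or any class key; the best
    level is the highest-priority level among matches (1A > 1B > 2A > 2B >
    2C), independent of entry order.  No match yields an unclassified
    assignment, never an error.
    """
    keys = set(variant_key_set(call, transcripts, panel))
    matches = tuple(
        sorted(
            (e for e in kb.entries if e.variant_key in keys),
            key=lambda e: (LEVEL_ORDER[e.level], e.pattern, e.gene, e.drug),
        )
    )
    best = min((e.level for e in matches), key=LEVEL_ORDER.get, default=None)
    return TierAssignment(
        call=call,
        variant_key=normalize_variant_key(call, transcripts, panel),
        matches=matches,
        best_level=best,
        category=_category_for(best),
    )


def sample_category(assignments: Sequence[TierAssignment]) -> str:
    """Sample-level rollup: level-1 beats level-2 beats negative."""
    cats = {a.category for a in assignments}
    if CATEGORY_LEVEL1 in cats:
        return CATEGORY_LEVEL1
    if CATEGORY_LEVEL2 in cats:
        return CATEGORY_LEVEL2
    return "negative"


# ---------------------------------------------------------------------------
# Clinical report
# ---------------------------------------------------------------------------

_CATEGORY_SORT = {CATEGORY_LEVEL1: 0, CATEGORY_LEVEL2: 1, CATEGORY_UNCLASSIFIED: 2}


@dataclass(frozen=True)
class Finding:
    gene: str
    variant_key: str
    vtype: str
    vaf: float
    category: str
    best_level: str | None
    drugs: tuple[tuple[str, str, str], ...]  # (drug, pattern, level)


@dataclass(frozen=True)
class ClinicalReport:
    sample_id: str
    findings: tuple[Finding, ...]
    negative_genes: tuple[str, ...]
    qc: CoverageQC | None = None

    @property
    def category(self) -> str:
        cats = {f.category for f in self.findings}
        if CATEGORY_LEVEL1 in cats:
            return CATEGORY_LEVEL1
        if CATEGORY_LEVEL2 in cats:
            return CATEGORY_LEVEL2
        return "negative"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "category": self.category,
            "findings": [
                {
                    "gene": f.gene,
                    "variant": f.variant_key,
                    "type": f.vtype,
                    "vaf": f.vaf,
                    "category": f.category,
                    "best_level": f.best_level,
                    "drugs": [
                        {"drug": d, "pattern": p, "level": lvl}
                        for d, p, lvl in f.drugs
                    ],
                }
                for f in self.findings
            ],
            "negative_genes": list(self.negative_genes),
            "qc": self.qc.to_dict() if self.qc is not None else "unavailable",
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"Sample {self.sample_id} — targeted panel report",
                 f"Overall category: {self.category}", ""]
        if self.findings:
            lines.append("Positive findings:")
            for f in self.findings:
                lvl = f.best_level or "unclassified"
                lines.append(
                    f"  {f.gene} {f.variant_key} ({f.vtype}, VAF {f.vaf:.4f}) — {lvl}"
                )
                for d, p, l in f.drugs:
                    lines.append(f"    {d}: {p} (level {l})")
        else:
            lines.append("Positive findings: none")
        lines.append("")
        lines.append("Negative genes (no reportable alteration): "
                     + (", ".join(self.negative_genes) or "none"))
        if self.qc is None:
            lines.append("QC: unavailable")
        else:
            lines.append(
                f"QC: mean depth {self.qc.mean_depth:.1f}x, "
                f">= {self.qc.threshold}x fraction {self.qc.frac_ge_threshold:.4f}, "
                f"on-target {self.qc.on_target_fraction:.4f}"
            )
        return "\n".join(lines) + "\n"


def _finding_genes(finding: Finding) -> tuple[str, ...]:
    # a fusion finding marks both partner genes positive
    if finding.vtype == FUSION and "-" in finding.variant_key.split(":")[0]:
        return tuple(finding.variant_key.split(":")[0].split("-"))
    return (finding.gene,)


def generate_report(
    sample_id: str,
    calls: Sequence[VariantCall],
    kb: KnowledgeBase,
    panel: Panel,
    qc: CoverageQC | None = None,
    transcripts: Mapping[str, Transcript] = BUNDLED_TRANSCRIPTS,
) -> ClinicalReport:
    """Assemble the automatic clinical report for one sample.

    Every PASS call becomes a finding (classified or explicitly
    unclassified — nothing is silently dropped); every actionable-now
    (Part I) panel gene appears exactly once, either through a finding or
    in the negative-gene list.  Output serialisation is deterministic.
    """
    findings: list[Finding] = []
    for call in calls:
        if not call.is_pass:
            continue
        assignment = classify(call, kb, transcripts, panel)
        gene = call.gene or panel.gene_of(call.chrom, call.pos) or "?"
        findings.append(
            Finding(
                gene=gene,
                variant_key=assignment.variant_key,
                vtype=call.vtype,
                vaf=call.vaf,
                category=assignment.category,
                best_level=assignment.best_level,
                drugs=tuple(dict.fromkeys(
                    (e.drug, e.pattern, e.level) for e in assignment.matches
                )),
            )
        )
    findings.sort(key=lambda f: (_CATEGORY_SORT[f.category], f.gene, f.variant_key))
    part1 = sorted({r.gene for r in panel.regions if r.part == "I"})
    positive = {g for f in findings for g in _finding_genes(f)}
    negative = tuple(g for g in part1 if g not in positive)
    return ClinicalReport(
        sample_id=sample_id,
        findings=tuple(findings),
        negative_genes=negative,
        qc=qc,
    )
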