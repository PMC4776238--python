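"""Seeded generators for every input the toolkit consumes.

Everything the other modules read — pileups with controlled truth VAFs,
depth profiles with copy-number events, split-read evidence with positional
jitter, the panel itself, the drug–variant knowledge base and the
prospective cohort — is generated here, deterministically under a seed, so
the whole test surface runs without any external data.

The knowledge base and cohort produced here are explicitly SYNTHETIC,
non-clinical fixtures: well-known lung-adenocarcinoma entries (EGFR
L858R / exon-19 deletions / T790M, ALK and ROS1 fusions, BRAF V600E, MET
amplification, KRAS resistance) padded with realistic filler to match the
panel's published-style composition (115 entries: 49 SNV + 45 InDel + 19
fusion + 2 amplification over 15 genes and 27 drugs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import round_half_away
from .caller import (
    CNV, FUSION, INDEL, SNV, ErrorModel, PileupSite, VariantCall, binom_sf,
    is_indel_allele,
)
from .kb import KbEntry, KnowledgeBase
from .panel import Panel, TargetRegion
from .svcnv import DepthProfile, SplitReadEvidence


# ---------------------------------------------------------------------------
# Synthetic panel (436 exons + 13 introns, 145 genes, 249,000 targeted bases)
# ---------------------------------------------------------------------------

# (chrom, start, end, gene, label) — hg19 anchors for genes with bundled
# transcripts, hotspots, the copy-number worked example and fusion introns
_ANCHOR_EXONS = (
    ("chr7", 55241613, 55241736, "EGFR", "exon18"),
    ("chr7", 55242414, 55242513, "EGFR", "exon19"),
    ("chr7", 55248985, 55249171, "EGFR", "exon20"),
    ("chr7", 55259411, 55259567, "EGFR", "exon21"),
    ("chr12", 25398207, 25398329, "KRAS", "exon2"),
    ("chr7", 140453074, 140453193, "BRAF", "exon15"),
    ("chr7", 140481374, 140481493, "BRAF", "exon11"),
    ("chr3", 178936000, 178936132, "PIK3CA", "exon10"),
    ("chr3", 178951879, 178952152, "PIK3CA", "exon21"),
    ("chr10", 89692768, 89693008, "PTEN", "exon5"),
    ("chr14", 105246424, 105246560, "AKT1", "exon3"),
    ("chr7", 116435940, 116436719, "MET", "exon14"),
    ("chr8", 38271000, 38271500, "FGFR1", "exon4"),
    ("chr17", 37880978, 37881164, "ERBB2", "exon20"),
    ("chr1", 115256420, 115256720, "NRAS", "exon3"),
    ("chr15", 66727454, 66727754, "MAP2K1", "exon2"),
    ("chr4", 55593383, 55593683, "KIT", "exon11"),
    ("chr1", 162741788, 162742088, "DDR2", "exon18"),
    # one exon each for the fusion-target genes
    ("chr2", 29415640, 29415940, "ALK", "exon1"),
    ("chr2", 42396490, 42396790, "EML4", "exon1"),
    ("chr6", 117609463, 117609763, "ROS1", "exon1"),
    ("chr10", 43572517, 43572817, "RET", "exon1"),
    ("chr4", 55095264, 55095564, "PDGFRA", "exon1"),
)

_ANCHOR_INTRONS = (
    ("chr2", 29446207, 29446744, "ALK", "intron19"),
    ("chr2", 29447500, 29448100, "ALK", "intron18"),
    ("chr2", 29449000, 29449600, "ALK", "intron17"),
    ("chr2", 29450500, 29451100, "ALK", "intron16"),
    ("chr2", 42522655, 42523949, "EML4", "intron6"),
    ("chr2", 42527000, 42527600, "EML4", "intron13"),
    ("chr6", 117645000, 117645600, "ROS1", "intron31"),
    ("chr6", 117650000, 117650600, "ROS1", "intron32"),
    ("chr6", 117655000, 117655600, "ROS1", "intron33"),
    ("chr10", 43609000, 43609600, "RET", "intron10"),
    ("chr10", 43612000, 43612600, "RET", "intron11"),
    ("chr4", 55140000, 55140600, "PDGFRA", "intron22"),
    ("chr4", 55144000, 55144600, "PDGFRA", "intron23"),
)

PART1_GENES = frozenset(
    {
        "EGFR", "KRAS", "BRAF", "PIK3CA", "PTEN", "AKT1", "MET", "FGFR1",
        "ERBB2", "NRAS", "MAP2K1", "KIT", "DDR2", "ALK", "ROS1", "RET",
        "PDGFRA",
    }
)

# frequently mutated / prognostic filler genes (Part II)
_FILLER_GENES = (
    "TP53 STK11 KEAP1 NF1 NF2 RB1 CDKN2A CDKN2B SMARCA4 SMARCB1 "
    "ARID1A ARID1B ARID2 ATM ATR APC MDM2 MDM4 CCND1 CCND2 "
    "CCND3 CCNE1 CDK4 CDK6 FGFR2 FGFR3 FGFR4 NTRK1 NTRK2 NTRK3 "
    "ERBB3 ERBB4 IGF1R JAK1 JAK2 JAK3 STAT3 SMAD2 SMAD4 TGFBR1 "
    "TGFBR2 BRCA1 BRCA2 PALB2 CHEK1 CHEK2 FANCA FANCC MLH1 MSH2 "
    "MSH6 PMS2 POLE POLD1 PTCH1 SMO GLI1 NOTCH1 NOTCH2 NOTCH3 "
    "FBXW7 CTNNB1 AXIN1 AXIN2 GNAS GNAQ GNA11 HRAS RIT1 RAF1 "
    "ARAF MAP2K2 MAPK1 MTOR RICTOR RPTOR TSC1 TSC2 PIK3R1 PIK3CB "
    "INPP4B AKT2 AKT3 RHEB SRC ABL1 ABL2 KDR FLT1 FLT3 "
    "FLT4 CSF1R ESR1 AR VHL HIF1A EPAS1 SETD2 PBRM1 BAP1 "
    "KMT2A KMT2C KMT2D KDM5C KDM6A CREBBP EP300 NSD1 EZH2 DNMT3A "
    "TET2 IDH1 IDH2 SF3B1 U2AF1 SRSF2 ZRSR2 RBM10 MYC MYCN "
    "MYCL NKX2-1 SOX2 TERT CDH1 NFE2L2 CUL3 "
).split()

PANEL_TOTAL_BASES = 249_000
PANEL_EXONS = 436
PANEL_INTRONS = 13
PANEL_GENES = 145


def synthetic_panel(name: str = "lung-145") -> Panel:
    """The bundled 145-gene lung panel: 436 exons + 13 introns, 249 kb.

    Anchor regions carry real hg19 coordinates for the genes used in the
    worked examples; filler exons are laid out deterministically on
    synthetic coordinates and sized so the panel totals exactly 249,000
    targeted bases.  No randomness.
    """
    n_anchor_genes = len({r[3] for r in _ANCHOR_EXONS})
    n_filler_genes = PANEL_GENES - n_anchor_genes
    if len(_FILLER_GENES) != len(set(_FILLER_GENES)) or len(
        _FILLER_GENES
    ) < n_filler_genes:
        raise AssertionError("filler gene list must be unique and long enough")
    filler = _FILLER_GENES[:n_filler_genes]

    regions = [
        TargetRegion(c, s, e, g, lab, "I" if g in PART1_GENES else "II")
        for c, s, e, g, lab in _ANCHOR_EXONS
    ]
    regions += [
        TargetRegion(c, s, e, g, lab, "I" if g in PART1_GENES else "II")
        for c, s, e, g, lab in _ANCHOR_INTRONS
    ]
    anchor_bases = sum(len(r) for r in regions)

    n_filler_exons = PANEL_EXONS - len(_ANCHOR_EXONS)
    filler_bases = PANEL_TOTAL_BASES - anchor_bases
    base_len, extra = divmod(filler_bases, n_filler_exons)
    n_four = n_filler_exons - 3 * n_filler_genes  # genes given a 4th exon

    exon_idx = 0
    for gi, gene in enumerate(filler):
        chrom = f"chr{(gi % 22) + 1}"
        gene_start = 1_000_000 + gi * 50_000
        n_exons = 4 if gi < n_four else 3
        for j in range(n_exons):
            length = base_len + (1 if exon_idx < extra else 0)
            start = gene_start + j * 2_000
            regions.append(
                TargetRegion(chrom, start, start + length, gene, f"exon{j + 1}", "II")
            )
            exon_idx += 1

    panel = Panel(regions=tuple(sorted(regions, key=lambda r: (r.chrom, r.start))), name=name)
    if panel.total_bases != PANEL_TOTAL_BASES or panel.n_regions != PANEL_EXONS + PANEL_INTRONS:
        raise AssertionError("synthetic panel arithmetic is inconsistent")
    return panel


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one simulated site (vaf 0 = wild type)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError("truth vaf must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    """Depth/error model plus a truth set for pileup simulation."""

    seed: int
    sites: tuple[SiteTruth, ...]
    depth_mean: float = 450.0
    depth_sd: float = 0.0  # 0 -> constant depth
    e_sub: float = 1e-3
    e_indel: float = 1e-4

    def error_model(self) -> ErrorModel:
        return ErrorModel(e_sub=self.e_sub, e_indel=self.e_indel)


def _draw_depths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Discretised lognormal depths with the requested mean and spread."""
    if sd <= 0:
        return np.full(n, int(round(mean)), dtype=int)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    depths = np.rint(rng.lognormal(mu, np.sqrt(sigma2), size=n)).astype(int)
    return np.maximum(depths, 1)


def simulate_pileups(spec: SimulationSpec) -> list[PileupSite]:
    """Simulate deduplicated, quality-filtered pileups for a truth set.

    Alt support is Binomial(depth, vaf + e·(1−vaf)) at mutant sites and
    Binomial(depth, e) at wild-type sites — error reads may coincide with
    the variant allele, which is the conservative reading.  Byte-identical
    for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.sites)
    depths = _draw_depths(rng, n, spec.depth_mean, spec.depth_sd)
    e = np.array(
        [spec.e_indel if is_indel_allele(t.alt) else spec.e_sub for t in spec.sites]
    )
    vafs = np.array([t.vaf for t in spec.sites])
    p = vafs + e * (1.0 - vafs)
    alt_counts = rng.binomial(depths, p)
    out = []
    for truth, depth, alt in zip(spec.sites, depths, alt_counts):
        counts = {truth.alt: int(alt)} if alt > 0 else {}
        out.append(
            PileupSite(truth.chrom, truth.pos, truth.ref, int(depth), counts)
        )
    return out


# Dilution-series truth variants: two substitution hotspots at run-average
# depth and the recurrent exon-19 deletion on its deeper amplicon.
DILUTION_VARIANTS = (
    ("chr7", 55249070, "C", "T", 450.0),       # EGFR T790M
    ("chr7", 55259514, "T", "G", 450.0),       # EGFR L858R
    ("chr7", 55242463, "A", "del15", 750.0),   # EGFR c.2235_2249del15
)


def simulate_dilution_series(
    stock_vaf: float = 0.5,
    mix_fractions: Sequence[float] = (0.02, 0.06, 0.10, 0.20),
    replicates: Sequence[int] = (4, 3, 8, 3),
    seed: int = 0,
    variants: Sequence[tuple[str, int, str, str, float]] = DILUTION_VARIANTS,
    depth_sd: float = 0.0,
    e_sub: float = 1e-3,
    e_indel: float = 1e-4,
) -> dict[float, list[list[PileupSite]]]:
    """Simulate the mixing-experiment grid.

    Positive stock at ``stock_vaf`` is virtually mixed into wild-type DNA at
    each ``mix_fraction`` (truth VAF = stock × mix), with the listed number
    of replicate libraries per point.  Returns target VAF -> replicates ->
    pileup sites (one per truth variant).
    """
    if len(mix_fractions) != len(replicates):
        raise ValueError("mix_fractions and replicates must align")
    series: dict[float, list[list[PileupSite]]] = {}
    master = np.random.default_rng(seed)
    for mix, n_rep in zip(mix_fractions, replicates):
        target = stock_vaf * mix
        reps = []
        for _ in range(n_rep):
            rep_sites: list[PileupSite] = []
            for chrom, pos, ref, alt, depth in variants:
                spec = SimulationSpec(
                    seed=int(master.integers(0, 2**31 - 1)),
                    sites=(SiteTruth(chrom, pos, ref, alt, target),),
                    depth_mean=depth,
                    depth_sd=depth_sd,
                    e_sub=e_sub,
                    e_indel=e_indel,
                )
                rep_sites.extend(simulate_pileups(spec))
            reps.append(rep_sites)
        series[target] = reps
    return series


# ---------------------------------------------------------------------------
# Depth profiles and split reads
# ---------------------------------------------------------------------------


def simulate_depth_profile(
    panel: Panel,
    cn_events: Mapping[str, int] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    baseline_depth: float = 450.0,
) -> tuple[DepthProfile, DepthProfile]:
    """Sample and diploid-baseline depth profiles over a panel.

    ``cn_events`` maps gene -> integer copy number (all that gene's
    regions).  ``noise_sigma`` is the standard deviation of per-base
    ln-depth; a region's profile value is the mean over its bases, so
    longer targets are quieter — the profile analogue of read-count
    averaging.  The baseline is the exact diploid mean.
    """
    cn_events = dict(cn_events or {})
    unknown = set(cn_events) - set(panel.genes)
    if unknown:
        raise ValueError(f"cn_events reference genes outside the panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    sample: list[float] = []
    base: list[float] = []
    for region in panel.regions:
        cn = cn_events.get(region.gene, 2)
        mean = baseline_depth * (cn / 2.0)
        if noise_sigma > 0:
            factors = np.exp(rng.normal(0.0, noise_sigma, size=len(region)))
            sample.append(float(mean * factors.mean()))
        else:
            sample.append(mean)
        base.append(baseline_depth)
    return (
        DepthProfile(panel.regions, tuple(sample)),
        DepthProfile(panel.regions, tuple(base)),
    )


def simulate_split_reads(
    breakpoint_a: tuple[str, int, str] = ("chr2", 29446561, "+"),
    breakpoint_b: tuple[str, int, str] = ("chr2", 42523152, "-"),
    support: int = 50,
    jitter_bp: int = 2,
    noise_records: int = 0,
    panel: Panel | None = None,
    seed: int = 0,
    p_exact: float = 0.6,
) -> list[SplitReadEvidence]:
    """Split-read evidence for one fusion breakpoint plus scattered noise.

    Each supporting record clips exactly at the breakpoint with probability
    ``p_exact`` and otherwise slips uniformly by ±1..``jitter_bp`` bases
    (independent per side), so the modal clip position stays the true
    breakpoint.  Noise records pair uniform random panel positions with
    random strands.  Defaults reproduce the ALK/EML4 worked example
    (ALK clipped at chr2:29446561 joined to the EML4 minus strand at
    chr2:42523152).
    """
    if support < 0 or noise_records < 0:
        raise ValueError("record counts must be >= 0")
    if noise_records > 0 and panel is None:
        raise ValueError("noise records require a panel to scatter over")
    rng = np.random.default_rng(seed)
    chrom_a, pos_a, strand_a = breakpoint_a
    chrom_b, pos_b, strand_b = breakpoint_b

    def jitter() -> int:
        if jitter_bp <= 0 or rng.random() < p_exact:
            return 0
        off = int(rng.integers(1, jitter_bp + 1))
        return off if rng.random() < 0.5 else -off

    records = [
        SplitReadEvidence(
            read_id=f"r{i:04d}",
            chrom_a=chrom_a, pos_a=pos_a + jitter(), strand_a=strand_a,
            chrom_b=chrom_b, pos_b=pos_b + jitter(), strand_b=strand_b,
        )
        for i in range(support)
    ]
    if noise_records:
        regions = panel.regions
        for i in range(noise_records):
            ra = regions[int(rng.integers(len(regions)))]
            rb = regions[int(rng.integers(len(regions)))]
            records.append(
                SplitReadEvidence(
                    read_id=f"n{i:04d}",
                    chrom_a=ra.chrom,
                    pos_a=int(rng.integers(ra.start, ra.end)),
                    strand_a="+" if rng.random() < 0.5 else "-",
                    chrom_b=rb.chrom,
                    pos_b=int(rng.integers(rb.start, rb.end)),
                    strand_b="+" if rng.random() < 0.5 else "-",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Knowledge-base fixture
# ---------------------------------------------------------------------------

# (gene, key, type, drug, pattern, level) — synthetic, non-clinical fixture
_S, _R = "sensitivity", "resistance"
_KB_ROWS: tuple[tuple[str, str, str, str, str, str], ...] = (
    # --- SNVs (49) ---
    ("EGFR", "EGFR:L858R", SNV, "gefitinib", _S, "1A"),
    ("EGFR", "EGFR:L858R", SNV, "erlotinib", _S, "1A"),
    ("EGFR", "EGFR:L858R", SNV, "afatinib", _S, "1A"),
    ("EGFR", "EGFR:L858R", SNV, "icotinib", _S, "1A"),
    ("EGFR", "EGFR:L861Q", SNV, "afatinib", _S, "1B"),
    ("EGFR", "EGFR:G719A", SNV, "afatinib", _S, "1B"),
    ("EGFR", "EGFR:G719S", SNV, "afatinib", _S, "1B"),
    ("EGFR", "EGFR:G719C", SNV, "afatinib", _S, "1B"),
    ("EGFR", "EGFR:T790M", SNV, "gefitinib", _R, "1A"),
    ("EGFR", "EGFR:T790M", SNV, "erlotinib", _R, "1A"),
    ("EGFR", "EGFR:T790M", SNV, "icotinib", _R, "1A"),
    ("EGFR", "EGFR:T790M", SNV, "osimertinib", _S, "1B"),
    ("EGFR", "EGFR:S768I", SNV, "afatinib", _S, "1B"),
    ("KRAS", "KRAS:G12C", SNV, "gefitinib", _R, "1A"),
    ("KRAS", "KRAS:G12C", SNV, "erlotinib", _R, "1A"),
    ("KRAS", "KRAS:G12D", SNV, "gefitinib", _R, "1A"),
    ("KRAS", "KRAS:G12D", SNV, "erlotinib", _R, "1A"),
    ("KRAS", "KRAS:G12V", SNV, "gefitinib", _R, "1A"),
    ("KRAS", "KRAS:G12V", SNV, "erlotinib", _R, "1A"),
    ("KRAS", "KRAS:G13D", SNV, "gefitinib", _R, "1A"),
    ("KRAS", "KRAS:G13D", SNV, "erlotinib", _R, "1A"),
    ("KRAS", "KRAS:G12C", SNV, "selumetinib", _S, "2C"),
    ("BRAF", "BRAF:V600E", SNV, "dabrafenib", _S, "1B"),
    ("BRAF", "BRAF:V600E", SNV, "vemurafenib", _S, "1B"),
    ("BRAF", "BRAF:V600E", SNV, "trametinib", _S, "2A"),
    ("BRAF", "BRAF:G469A", SNV, "sorafenib", _S, "2C"),
    ("BRAF", "BRAF:D594G", SNV, "sorafenib", _S, "2C"),
    ("PIK3CA", "PIK3CA:E545K", SNV, "everolimus", _S, "2B"),
    ("PIK3CA", "PIK3CA:E545K", SNV, "buparlisib", _S, "2B"),
    ("PIK3CA", "PIK3CA:E542K", SNV, "everolimus", _S, "2B"),
    ("PIK3CA", "PIK3CA:H1047R", SNV, "everolimus", _S, "2B"),
    ("PIK3CA", "PIK3CA:H1047R", SNV, "temsirolimus", _S, "2B"),
    ("PIK3CA", "PIK3CA:H1047L", SNV, "everolimus", _S, "2B"),
    ("NRAS", "NRAS:Q61K", SNV, "trametinib", _S, "2C"),
    ("NRAS", "NRAS:Q61R", SNV, "trametinib", _S, "2C"),
    ("MAP2K1", "MAP2K1:K57N", SNV, "trametinib", _S, "2C"),
    ("MAP2K1", "MAP2K1:K57N", SNV, "selumetinib", _S, "2C"),
    ("MET", "MET:Y1230C", SNV, "crizotinib", _S, "2C"),
    ("MET", "MET:D1228N", SNV, "crizotinib", _S, "2C"),
    ("ERBB2", "ERBB2:L755S", SNV, "lapatinib", _S, "2B"),
    ("ERBB2", "ERBB2:V842I", SNV, "trastuzumab", _S, "2C"),
    ("KIT", "KIT:D816V", SNV, "imatinib", _R, "2B"),
    ("KIT", "KIT:L576P", SNV, "imatinib", _S, "2B"),
    ("DDR2", "DDR2:S768R", SNV, "dasatinib", _S, "2B"),
    ("PDGFRA", "PDGFRA:D842V", SNV, "imatinib", _R, "2B"),
    ("PDGFRA", "PDGFRA:D842V", SNV, "sunitinib", _S, "2C"),
    ("ROS1", "ROS1:G2032R", SNV, "crizotinib", _R, "2A"),
    ("RET", "RET:M918T", SNV, "cabozantinib", _S, "2C"),
    ("RET", "RET:M918T", SNV, "vandetanib", _S, "2C"),
    # --- InDels (45) ---
    ("EGFR", "EGFR:ex19del", INDEL, "gefitinib", _S, "1A"),
    ("EGFR", "EGFR:ex19del", INDEL, "erlotinib", _S, "1A"),
    ("EGFR", "EGFR:ex19del", INDEL, "afatinib", _S, "1A"),
    ("EGFR", "EGFR:ex19del", INDEL, "icotinib", _S, "1A"),
    ("EGFR", "EGFR:ex20ins", INDEL, "gefitinib", _R, "1B"),
    ("EGFR", "EGFR:ex20ins", INDEL, "erlotinib", _R, "1B"),
    ("EGFR", "EGFR:ex20ins", INDEL, "afatinib", _R, "1B"),
    ("EGFR", "EGFR:ex20ins", INDEL, "icotinib", _R, "1B"),
    ("EGFR", "EGFR:ex20ins", INDEL, "ponatinib", _S, "2C"),
    ("ERBB2", "ERBB2:ex20ins", INDEL, "trastuzumab", _S, "2B"),
    ("ERBB2", "ERBB2:ex20ins", INDEL, "lapatinib", _S, "2B"),
    ("ERBB2", "ERBB2:ex20ins", INDEL, "afatinib", _S, "2B"),
    ("ERBB2", "ERBB2:ex20ins", INDEL, "dacomitinib", _S, "2C"),
    ("MET", "MET:ex14del", INDEL, "crizotinib", _S, "2A"),
    ("MET", "MET:ex14del", INDEL, "cabozantinib", _S, "2C"),
    ("KIT", "KIT:ex11del", INDEL, "imatinib", _S, "2B"),
    ("KIT", "KIT:ex11del", INDEL, "sunitinib", _S, "2B"),
    # --- Fusions (19) ---
    ("ALK", "ALK-EML4:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ALK", "ALK-EML4:fusion", FUSION, "ceritinib", _S, "1A"),
    ("ALK", "ALK-EML4:fusion", FUSION, "alectinib", _S, "1B"),
    ("ALK", "ALK-EML4:fusion", FUSION, "brigatinib", _S, "2A"),
    ("ALK", "ALK-KIF5B:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ALK", "ALK-TFG:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ALK", "ALK-KLC1:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ROS1", "CD74-ROS1:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ROS1", "ROS1-SLC34A2:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ROS1", "EZR-ROS1:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ROS1", "GOPC-ROS1:fusion", FUSION, "crizotinib", _S, "1A"),
    ("ROS1", "ROS1-SDC4:fusion", FUSION, "crizotinib", _S, "1A"),
    ("RET", "KIF5B-RET:fusion", FUSION, "cabozantinib", _S, "2A"),
    ("RET", "KIF5B-RET:fusion", FUSION, "vandetanib", _S, "2A"),
    ("RET", "CCDC6-RET:fusion", FUSION, "cabozantinib", _S, "2A"),
    ("RET", "CCDC6-RET:fusion", FUSION, "vandetanib", _S, "2A"),
    ("RET", "NCOA4-RET:fusion", FUSION, "cabozantinib", _S, "2C"),
    ("RET", "RET-TRIM33:fusion", FUSION, "vandetanib", _S, "2A"),
    ("FGFR1", "BAG4-FGFR1:fusion", FUSION, "lucitanib", _S, "2C"),
    # --- Amplifications (2) ---
    ("MET", "MET:amp", "Amplification", "crizotinib", _S, "2A"),
    ("FGFR1", "FGFR1:amp", "Amplification", "lucitanib", _S, "2C"),
)

# the specific exon-19 deletion alleles carried alongside the class entry
_EX19DEL_ALLELES = (
    "c.2235_2249del15", "c.2236_2250del15", "c.2240_2254del15",
    "c.2239_2247del9", "c.2237_2255del19", "c.2239_2256del18",
    "c.2236_2253del18",
)


def generate_kb_fixture(version: str = "fixture-1.0") -> KnowledgeBase:
    """Deterministic synthetic knowledge base matching the documented
    composition: 115 entries (49 SNV, 45 InDel, 19 fusion, 2 amplification)
    in 15 genes with 27 targeted drugs.  NOT for clinical use."""
    rows = list(_KB_ROWS)
    for allele in _EX19DEL_ALLELES:
        for drug in ("gefitinib", "erlotinib", "afatinib", "icotinib"):
            rows.append(("EGFR", f"EGFR:{allele}", INDEL, drug, _S, "1A"))
    entries = tuple(
        KbEntry(
            gene=g, variant_key=k, variant_type=t, drug=d, pattern=p, level=lvl,
            evidence="synthetic fixture entry", source="fixture",
        )
        for g, k, t, d, p, lvl in rows
    )
    return KnowledgeBase(entries=entries, version=version)


# ---------------------------------------------------------------------------
# Prospective cohort fixture
# ---------------------------------------------------------------------------

# descriptor -> VariantCall template (SNV/InDel: chrom, 0-based pos, ref, alt)
_VARIANT_TEMPLATES: dict[str, tuple] = {
    "EGFR:L858R": ("chr7", 55259514, "T", "G", SNV, "EGFR"),
    "EGFR:L861Q": ("chr7", 55259523, "T", "A", SNV, "EGFR"),
    "EGFR:ex19del": ("chr7", 55242463, "A", "del15", INDEL, "EGFR"),
    "KRAS:G12C": ("chr12", 25398284, "C", "A", SNV, "KRAS"),
    "KRAS:G12D": ("chr12", 25398283, "C", "T", SNV, "KRAS"),
    "KRAS:G12V": ("chr12", 25398283, "C", "A", SNV, "KRAS"),
    "KRAS:G13D": ("chr12", 25398280, "C", "T", SNV, "KRAS"),
    "PIK3CA:H1047L": ("chr3", 178952084, "A", "T", SNV, "PIK3CA"),
    "PIK3CA:H1047R": ("chr3", 178952084, "A", "G", SNV, "PIK3CA"),
    "PIK3CA:E545K": ("chr3", 178936090, "G", "A", SNV, "PIK3CA"),
    "PIK3CA:Q546K": ("chr3", 178936093, "C", "A", SNV, "PIK3CA"),
    "PIK3CA:c.1558C>T": ("chr3", 178936015, "C", "T", SNV, "PIK3CA"),
    "BRAF:V600E": ("chr7", 140453135, "A", "T", SNV, "BRAF"),
    "BRAF:G469A": ("chr7", 140481410, "C", "G", SNV, "BRAF"),
    "BRAF:D594G": ("chr7", 140453153, "T", "C", SNV, "BRAF"),
    "PTEN:R130Q": ("chr10", 89692903, "G", "A", SNV, "PTEN"),
    "AKT1:E17K": ("chr14", 105246550, "C", "T", SNV, "AKT1"),
}


@dataclass(frozen=True)
class CohortSpec:
    """Composition of the synthetic prospective cohort.

    The default reproduces the study-style breakdown over 58 lung
    adenocarcinoma samples: 48 alteration-positive patients, one alteration
    each — EGFR 22 (11 L858R, 10 exon-19 deletions, 1 L861Q), KRAS 11,
    PIK3CA 6, BRAF 3, ALK-EML4 fusions 2, MET gain 1, PTEN 1, AKT1 1,
    FGFR1 gain 1 — and 10 alteration-free samples.
    """

    total_samples: int = 58
    variant_plan: tuple[tuple[str, int], ...] = (
        ("EGFR:L858R", 11),
        ("EGFR:ex19del", 10),
        ("EGFR:L861Q", 1),
        ("KRAS:G12C", 4),
        ("KRAS:G12D", 3),
        ("KRAS:G12V", 2),
        ("KRAS:G13D", 2),
        ("PIK3CA:H1047L", 1),
        ("PIK3CA:H1047R", 1),
        ("PIK3CA:E545K", 1),
        ("PIK3CA:Q546K", 2),
        ("PIK3CA:c.1558C>T", 1),
        ("BRAF:V600E", 1),
        ("BRAF:G469A", 1),
        ("BRAF:D594G", 1),
        ("ALK-EML4:fusion", 2),
        ("MET:amp", 1),
        ("FGFR1:amp", 1),
        ("PTEN:R130Q", 1),
        ("AKT1:E17K", 1),
    )

    def __post_init__(self) -> None:
        n = sum(c for _, c in self.variant_plan)
        if n > self.total_samples:
            raise ValueError(
                f"variant plan covers {n} patients but cohort has only "
                f"{self.total_samples} samples"
            )


@dataclass(frozen=True)
class SampleCalls:
    sample_id: str
    calls: tuple[VariantCall, ...]


def _build_call(descriptor: str, rng: np.random.Generator) -> VariantCall:
    if descriptor.endswith(":fusion"):
        pair = descriptor.split(":")[0]
        gene_a, gene_b = pair.split("-")
        support = int(rng.integers(10, 60))
        return VariantCall(
            chrom="chr2", pos=29446561, ref="N", alt="<BND>", vtype=FUSION,
            alt_count=support, depth=support, vaf=1.0, p_value=0.0,
            gene=gene_a, info={"partner_gene": gene_b, "orientation": "+/-"},
        )
    if descriptor.endswith(":amp"):
        gene = descriptor.split(":")[0]
        chrom, pos = ("chr7", 116435940) if gene == "MET" else ("chr8", 38271000)
        return VariantCall(
            chrom=chrom, pos=pos, ref="N", alt="<DUP>", vtype=CNV,
            alt_count=0, depth=0, vaf=0.0, p_value=0.0, gene=gene,
            info={"direction": "gain", "copy_number": 3},
        )
    chrom, pos, ref, alt, vtype, gene = _VARIANT_TEMPLATES[descriptor]
    depth = int(rng.integers(300, 700))
    vaf_truth = float(rng.uniform(0.05, 0.45))
    alt_count = max(int(round(vaf_truth * depth)), 6)
    e = 1e-4 if is_indel_allele(alt) else 1e-3
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, vtype=vtype,
        alt_count=alt_count, depth=depth,
        vaf=round_half_away(alt_count / depth, 4),
        p_value=binom_sf(alt_count - 1, depth, e),
        gene=gene,
    )


def generate_cohort_fixture(
    spec: CohortSpec | None = None, seed: int = 0
) -> list[SampleCalls]:
    """Per-sample PASS call sets for the synthetic prospective cohort.

    The composition is satisfied exactly (not in expectation); the seed
    only randomises allele fractions, depths and the order in which
    variants land on sample identifiers.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    descriptors: list[str | None] = []
    for descriptor, count in spec.variant_plan:
        descriptors.extend([descriptor] * count)
    descriptors.extend([None] * (spec.total_samples - len(descriptors)))
    order = rng.permutation(len(descriptors))
    samples = []
    for i, slot in enumerate(order):
        descriptor = descriptors[slot]
        calls = () if descriptor is None else (_build_call(descriptor, rng),)
        samples.append(SampleCalls(sample_id=f"S{i + 1:02d}", calls=calls))
    return samples
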