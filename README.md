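# oncopanel

A desk-scale toolkit for targeted-NGS somatic profiling of lung
adenocarcinoma panels. It implements the informatics half of a
hybrid-capture panel workflow — hotspot SNV/InDel calling from pileup
summaries under an explicit binomial sequencing-error model, simplified
per-target copy-number and split-read fusion detection, knowledge-base
driven actionability tiering with automatic clinical reports — together
with the full analytical-validation suite a clinical lab runs on such an
assay: dilution-series limit of detection, intra-run replicate
reproducibility, cross-platform concordance, and prospective-cohort
summarisation. Every input it needs (panel BED, pileups, depth profiles,
split-read evidence, knowledge base, cohort) can be generated by its
seeded synthetic-data module, so the whole surface runs offline.

It is aimed at method developers and bioinformaticians who want a
transparent, testable reference for how tumour-only hotspot calling and
reporting fit together — not at clinical production use. The bundled
knowledge base and cohort are synthetic fixtures.

## The error model

Upstream alignment, duplicate marking and base-quality filtering are out
of scope; the caller's unit of input is a deduplicated, Q30-filtered
pileup summary per site. At a site of depth *n*, an alternate allele with
*k* supporting reads is scored against the null that all support is
sequencing error:

    p = P(X ≥ k),  X ~ Binomial(n, e)

with *e* the substitution (default 10⁻³, the Q30 bound) or indel (default
10⁻⁴) error rate. A call PASSes when p ≤ α (default 10⁻⁵) and clears
absolute floors (≥ 4 supporting reads, VAF ≥ 0.005, depth ≥ 50). The
closed-form power of this test,

    power(n, f) = P(X ≥ k* | X ~ Binomial(n, f)),   k* = min{k : P(X ≥ k | n, e) ≤ α},

is exposed as `detection_power`; at 450× and allele fraction 0.03 the
defaults give k\* = 6 and power 0.993, i.e. sensitivity and specificity
both beyond 99% for variants above 3% allele fraction — the design
contract of the assay. In hotspot mode only known somatic hotspot
positions are tested at the per-site α (tumour-only interpretation);
panel-wide mode Bonferroni-divides α across all tested (position,
alternate) pairs.

Copy number is called from median-normalised per-target log2 depth ratios
(gain ≥ 0.45, loss ≤ −0.6; integer copy number `round(2·2^ratio)`), and
fusions from transitively clustered split-read records whose modal clip
positions fall in the panel's intron-captured fusion-target genes.

## Worked example

Calling a sample that carries an EGFR exon-19 deletion at 17.5% allele
fraction co-occurring with a lower-frequency PIK3CA H1047L (8.9%), then
tiering it against the bundled knowledge base:

```python
from oncopanel import *
from oncopanel.caller import PileupSite

panel = synthetic_panel()
kb = generate_kb_fixture()
sites = [
    PileupSite("chr7", 55242463, "A", 456, {"del15": 80}),
    PileupSite("chr3", 178952084, "A", 451, {"T": 40}),
]
calls = call_sample(sites, hotspots=[("chr7", 55242463), ("chr3", 178952084)])
for c in calls:
    print(f"{c.chrom}:{c.pos+1} {c.ref}>{c.alt} {c.vtype} VAF={c.vaf:.4f} p={c.p_value:.3g} {c.filter}")
print(generate_report("A21", calls, kb, panel).to_text())
```

prints

```
chr3:178952085 A>T SNV VAF=0.0887 p=2.03e-63 PASS
chr7:55242464 A>del15 InDel VAF=0.1754 p=4.41e-230 PASS

Sample A21 — targeted panel report
Overall category: level-1

Positive findings:
  EGFR EGFR:ex19del (InDel, VAF 0.1754) — 1A
    afatinib: sensitivity (level 1A)
    erlotinib: sensitivity (level 1A)
    gefitinib: sensitivity (level 1A)
    icotinib: sensitivity (level 1A)
  PIK3CA PIK3CA:H1047L (SNV, VAF 0.0887) — 2B
    everolimus: sensitivity (level 2B)

Negative genes (no reportable alteration): AKT1, ALK, BRAF, DDR2, ERBB2, ...
QC: unavailable
```

Both variants are detected at their input allele fractions (80/456 =
0.1754; 40/451 = 0.0887) with p-values far below α; the deletion
normalises to the exon-19 deletion class and matches the first-line
EGFR-TKI entries at evidence level 1A (drug approved for lung cancers
carrying the variant), so the sample rolls up to category level-1. The
actionable-now panel genes without a reportable call are listed
explicitly as negatives.

The same operations are available from a shell via the `oncopanel` CLI
(`panel stats`, `call`, `cnv`, `fusion`, `annotate`, `report`,
`validate replicates|concordance|lod`, `cohort summarize`,
`simulate ...`).

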