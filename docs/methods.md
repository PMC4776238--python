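# Methods

This note documents the models, defaults and design choices behind
oncopanel, and what the synthetic fixtures do and do not establish.

## Scope and input contract

The toolkit starts where alignment ends. Base calling, read trimming,
alignment, duplicate marking and local realignment are upstream; the unit
of input for small-variant calling is a per-site pileup summary
(chromosome, 0-based position, reference base, deduplicated
quality-filtered depth, and per-allele support counts). Coordinates are
BED-convention 0-based half-open everywhere in memory and on disk;
1-based coordinates appear only in emitted VCF.

## Variant calling

**Model.** Each non-reference allele at a site is tested against the null
that its support is sequencing error: p = P(X ≥ k | X ~ Binomial(n, e)),
with n the site depth, k the allele support, and e the per-read error
probability for that allele class. A call passes when p ≤ α and clears
absolute floors on support, allele fraction and depth.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| e_sub | 1e-3 | a Q30 base-quality floor bounds per-base substitution error at 10⁻³ |
| e_indel | 1e-4 | indel artefacts after deduplication are roughly an order rarer than substitutions on this class of data |
| α | 1e-5 | per-site false-positive bound; over a ~10²–10³-site hotspot list keeps the expected run-level false-positive count ≪ 1 |
| min_alt_reads | 4 | absolute floor against clustered artefacts that the binomial does not model |
| min_vaf | 0.005 | reporting floor well below the validated detection limit |
| min_depth | 50 | below this no variant at the 3% design point is callable anyway |

These defaults realise the assay's design contract: at 450× the rejection
threshold is k\* = 6 reads, giving closed-form specificity
P(X ≥ 6 | 450, 10⁻³) = 7.6×10⁻⁶ per site and sensitivity
P(X ≥ 6 | 450, 0.03) = 0.993 at allele fraction 0.03 — both beyond 99%.
All are overridable through `CallerConfig`/`ErrorModel`.

**Power is not exactly monotone in depth.** `detection_power` is exactly
monotone in allele fraction, but in depth it saw-tooths slightly wherever
the integer threshold k\* increments (e.g. 0.9953 at 470× vs 0.9897 at
480×, where k\* steps 6→7). This is the standard discreteness artefact of
binomial tests, not a bug; the property tests assert monotonicity in VAF,
monotonicity in depth between threshold increments, and that k\* itself
never decreases with depth.

**Multiple testing.** Hotspot mode (the tumour-only clinical
interpretation) tests only listed hotspot positions, each at the per-site
α. Panel-wide mode Bonferroni-divides α by the number of tested
(position, alternate) pairs, counted as three substitution alternates per
site plus observed indel alleles — tests that cannot reject are still
part of the substitution test space.

**Indels.** Insertions and deletions are keyed by (anchor position,
inserted sequence | deletion length), assumed left-aligned by the
upstream pileup generator; `left_align_indel` additionally trims explicit
ref/alt pairs to minimal representation. An optional two-sided binomial
strand-bias p-value is provided for pileups that carry strand counts but
is not applied by default.

## Copy number and fusions

These are deliberately minimal, transparent equivalents of production
CNV/SV callers, not reimplementations of them.

**CNV.** Sample and diploid-baseline per-target mean depths are each
scaled to unit median (removing library size), ratios are taken per
region, and log2 ratios are thresholded at gain ≥ 0.45 / loss ≤ −0.6.
The thresholds sit between diploid noise and the first integer states: a
single-copy gain has closed-form ratio log2(3/2) = 0.585 and a
single-copy loss −1. Copy number is round(2·2^ratio). Contiguous
same-direction regions merge; runs shorter than `min_regions` (default 2)
are suppressed except for genes with a single target region, which can
never recruit a neighbour. Baseline regions under 50× are flagged
uninformative and excluded. No GC correction or significance model is
attempted: at panel scale with a clean baseline the integer states are
separated by far more than the averaged noise.

**Fusions.** Split-read records (two clipped segments with strands) are
grouped by transitive closure of pairwise consistency — both clip
positions within a 5 bp window and identical strand pattern — and each
cluster is summarised by its modal clip position per side (ties to the
smallest coordinate). Clusters with ≥ 3 supporting reads whose
breakpoints both fall in intron-captured fusion-target genes become
calls; the orientation string is the joined strand pattern (`+/-` = the
partner's minus strand reverse-joined to the driver). The window,
support threshold and the cluster→gene rules are fixture-calibrated
defaults, not derived from any production SV caller.

## Knowledge base and tiering

Evidence entries pair a normalized variant key with a drug, a pattern
(sensitivity | resistance) and a level. Sensitivity uses {1A, 1B, 2A, 2B,
2C}, resistance {1A, 1B, 2A, 2B}; 1A/1B is lung-cancer-approved or
clinically validated evidence ("level 1"), 2A/2B/2C evidence borrowed
from other tumour types, case reports or pre-clinical work ("level 2").
Matching accepts the exact key (protein change, cDNA descriptor, gene
pair, amplification) or an exon-level class key — recurrent families such
as the EGFR exon-19 deletions are curated as a class as well as as
individual alleles. A call's tier is the ordinal maximum of its matches
(1A > 1B > 2A > 2B > 2C) across both patterns; both patterns are kept in
the match list, and the ordinal maximum is used only for the sample-level
rollup (level-1 if any 1A/1B, else level-2 if any 2A/2B/2C, else
negative). How sensitivity and resistance levels should interleave in a
single ordering is genuinely open; reporting both and rolling up on the
ordinal maximum is this package's choice.

The bundled transcript map covers the panel's reportable hotspot genes
with hg19 exon segments and a protein-change dictionary; minus-strand
genes complement alleles into cDNA space. It is intentionally tiny — just
enough to normalize the fixture variants — and falls back to cDNA or
genomic descriptors for anything else.

The **clinical report** lists every PASS call as a finding (classified or
explicitly unclassified — nothing is silently dropped), lists every
actionable-now (Part I) panel gene exactly once as positive or negative,
carries the coverage-QC block when supplied (marked unavailable
otherwise), and serialises deterministically.

## Validation statistics

* **Dilution design:** target VAF = stock VAF × mix fraction, exact
  rational arithmetic; the standard grid mixes a 50%-VAF positive stock
  to 1/3/5/10%.
* **Replicate statistics:** the dispersion column is the *population*
  standard deviation (divisor n) of the replicate values in fraction
  units — recomputing published-style replicate tables reproduces their
  printed dispersion (0.019/0.022/0.013; 92.816 for coverage) only under
  this reading, not as a standard error. Means are reported to 2
  decimals, dispersions to 3.
* **Concordance:** per-row and overall detected/expected percentages to
  one decimal; the overall figure is over summed counts, hence invariant
  to row merging and splitting.
* **LOD:** the lowest VAF such that every tested grid point at or above
  it shows full detection; undefined when none does.
* **Cohort summary:** a patient counts once per gene; per-gene
  percentages use alteration-positive patients as denominator (the only
  reading under which 22 EGFR patients among 48 positives print as 46%),
  category percentages use all samples. Percentages round half away from
  zero on the computed double; note 6/48 = 12.5 rounds to 13 under this
  rule, so assertions avoid exact-half cells.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (spec, seed); fixed inputs give
byte-identical serialised outputs, and cohort/KB compositions are
satisfied exactly, not in expectation.

* **Pileups** draw depth from a discretised lognormal (or a constant when
  the spread is 0) and alt support from Binomial(depth, f + e·(1−f)) — an
  error read may coincide with the variant allele, the conservative
  choice. The dilution simulator anchors substitution sites at the 450×
  run average and the exon-19 deletion amplicon at 750×, reflecting its
  deeper observed capture; replicate counts default to the validation
  grid (4/3/8/3). At these settings the closed-form per-replicate
  detection probability at 1% VAF is ~0.30 for substitutions and ~0.95
  for the deletion, so a simulated grid reproduces the qualitative
  pattern (full substitution detection from 3%, partial at 1%, deletions
  detectable at 1%) with high but not unit probability per replicate —
  the acceptance test therefore aggregates 30 simulated grids.
* **Depth profiles** set each region to baseline × (CN/2) and apply
  per-base lognormal noise whose region value is the mean over the
  region's bases; σ is the per-base ln-depth standard deviation, so a
  600 bp target at σ = 0.1 has region-level noise of ~0.4% and a CN = 3
  single-exon gain is recovered essentially always. The baseline is the
  exact diploid mean, mirroring a pooled-normal reference.
* **Split reads** clip exactly at the breakpoint with probability 0.6 and
  otherwise slip uniformly by ±1..jitter bases per side. The exact-clip
  majority is what makes the modal clip position a reliable breakpoint
  estimator; under pure uniform jitter the mode would be a coin toss,
  which does not describe real soft-clip behaviour at a clean breakpoint.
* **The panel** (436 exons + 13 introns, 145 genes, exactly 249,000
  targeted bases) uses real hg19 coordinates for the anchor genes and
  deterministic synthetic layout for filler genes. The 249 kb total is
  taken over exons and introns together. Part I (actionable-now) vs Part
  II (prognostic/frequently mutated) is carried as metadata and drives
  only the report's negative-gene list.
* **The knowledge base** is a synthetic, non-clinical 115-entry fixture
  (49 SNV, 45 InDel including per-allele exon-19 deletions, 19 fusions, 2
  amplifications; 15 genes, 27 drugs) built from well-known
  lung-adenocarcinoma associations plus realistic filler.
* **The cohort** is 58 samples with 48 alteration-positive patients (22
  EGFR — 11 L858R, 10 exon-19 del, 1 L861Q — 11 KRAS, 6 PIK3CA, 3 BRAF, 2
  ALK–EML4, 1 each MET gain, PTEN, AKT1, FGFR1 gain), one alteration per
  patient; under the bundled level map this yields 36 level-1, 7 level-2
  and 15 negative samples. The single EGFR patient beyond L858R and the
  exon-19 deletions is assigned L861Q; three PIK3CA patients carry
  variants deliberately absent from the knowledge base, and PTEN/AKT1 are
  kept outside its 15 genes, exercising the unclassified path. KRAS
  resistance markers are 1A and therefore count toward level-1 under the
  ordinal rollup.

Passing tests on these fixtures demonstrate the *computational* contracts
— error-model calibration, threshold logic, normalization, tiering,
statistics — under idealised noise. They do not demonstrate performance
on real FFPE libraries, whose deamination artefacts, fragment-length
effects, capture GC bias and flow-space indel error structure the
generators intentionally do not model.

## Numerical choices

* Binomial tails via `scipy.special.bdtrc` (exact regularised
  incomplete-beta evaluation, fast enough for 10⁵-site simulations); the
  threshold search is a binary search on the monotone tail.
* Reported percentages and VAFs round half away from zero via
  floor(|x|·10ⁿ + 0.5), applied to the computed double; VAFs to 4
  decimals, percent means to 2, dispersions to 3.
* Modal-breakpoint ties break to the smallest coordinate; cluster sort is
  support-descending with coordinate tie-breaks; report findings sort by
  category then gene, making every serialisation deterministic.
* Degenerate inputs: zero-median depth profiles, empty panels, empty
  hotspot lists in hotspot mode and over-full cohort plans raise
  `ValueError`; shallow sites and off-panel breakpoints are skipped with
  a logged reason rather than raised.

## Known limitations

* Tumour-only: no matched normal, no germline subtraction beyond the
  hotspot restriction.
* No read-level realignment, haplotype assembly or breakpoint contig
  assembly; fusion calls depend on upstream split-read extraction.
* The binomial error model assumes independent errors at a site;
  systematic FFPE artefacts violate this and are only partially absorbed
  by the min_alt_reads floor.
* CNV calling has no GC/mappability correction and assumes a clean
  diploid baseline; it is a worked-example-scale model.
* The transcript map covers only the panel's reportable hotspot genes;
  other calls fall back to genomic descriptors and will not match
  knowledge-base entries.
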