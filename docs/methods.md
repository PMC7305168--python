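# Methods

This note documents the models, conventions and numerical choices behind
`methtx`, and what the synthetic benchmark does and does not establish.

## Coordinates and call tables

All internal coordinates are 0-based half-open; GTF (1-based closed) and the
two methylation-call dialects are converted on read, BED/bedGraph are
native. A CpG is keyed by the position of its C on the plus strand. The
BSMAP-methratio dialect reports the two strands separately, so counts at the
G position of a minus-strand record are merged onto the plus-strand C by
summing methylated and total read counts; the Bismark-coverage dialect
carries no strand column and is taken as already CpG-resolved. Chromosome
names are matched by exact string equality — nothing is renamed silently
(`strip_chr_prefix` is an explicit option). Depth filtering (>= 8 reads for
RRBS-style input, >= 5 per replicate for WGBS-style input) happens at read
time via `min_depth`.

## Methylation summaries

Feature and window means weight each CpG equally (the mean of per-CpG
percentages), never read-weighted; replicate pooling, in contrast, sums raw
counts and recomputes the percentage, so deep replicates weigh more. Means
over fewer CpGs than the minimum (3 per 1 kb window by default) are
undefined and propagated as NaN — zero is a valid methylation level and is
never used as a missing-value sentinel. Window tilings anchor at coordinate
0 of each chromosome; the choice is arbitrary but deterministic. Window
classes use a closed medium interval [10, 50] with strict high (> 50) and
low (< 10) bounds, read literally from the class definitions. Gene
metaplots use 20 equal body bins oriented 5'→3' plus ten 1 kb flank bins per
side; the profile is the unweighted mean over genes of per-bin means, so
long genes do not dominate. Site metaplots use 40 strand-oriented 250 bp
bins over ±5 kb; CpG density counts CG dinucleotides whose C lies in the
bin, scaled to CpG/kb.

## DMR calling

The region caller enforces the published acceptance contract — at least
three differentially methylated CpGs (DMCs), mean difference above 20
percentage points, BH-adjusted region p below 0.001 — around a deliberately
simple engine: a two-sided Fisher exact test on pooled
(methylated, unmethylated) counts per CpG defines DMCs (p < 0.01 and
|difference| > 20), maximal runs of DMCs at most 250 bp apart form
candidates, and the region p combines the DMC p-values by Stouffer's
method before BH adjustment across candidates. The 250 bp regioning
distance and the Stouffer combination are this package's own choices; the
original analysis used a regioner whose internal model (bimodal
beta-binomial) is not described in enough detail to re-implement, so only
the three reported criteria are treated as the contract. Fisher p-values
are computed only for CpGs that already pass the difference filter — an
exact optimization, since a DMC must pass both.

## Promoter classes and gene groups

The CpG ratio is the standard observed/expected form,
`n_CpG * L / (n_C * n_G)`, over 500 bp windows advanced in 20 bp steps
across TSS ± 1 kb; windows are anchored at the promoter start and a
trailing partial window is not evaluated, because the thresholds (0.45,
0.65, GC 55%) are calibrated for 500 bp. N bases are excluded from all
counts and from the effective length; a window with no C or no G has ratio
0; an all-N promoter is an error. CpGs are counted on the given strand with
a CpG spanning a window boundary attributed to the window containing its C
(the counts are reverse-complement symmetric, so orientation does not
matter in practice). Gene groups follow the published rule with the 30%
boundary inclusive in group 3, and promoter methylation measured over
TSS −1000..+500 in transcription orientation; genes without a defined
promoter methylation are reported with a flag rather than dropped.

## Differential expression

The engine is a documented stand-in, not a re-implementation of a published
tool: median-of-ratios size factors (geometric-mean rescaled; library-size
fallback with a warning below 100 all-nonzero features), fold changes
`log2((m_b + 0.5) / (m_a + 0.5))` on normalized group means, and a Wald
z-test with the delta-method standard error under NB variance
`m + alpha m^2`. Two numerical choices matter:

* **Common dispersion.** `alpha` is a single moment estimate pooled across
  groups *and* features — a 5%-trimmed mean of per-feature moment
  estimates over features with mean > 1, floored at 0.01. Per-feature
  moment estimation at three replicates per group makes the Wald statistic
  behave like a t with ~4 degrees of freedom and inflates the nominal
  p < 0.001 rate roughly tenfold; the common estimate restores normal
  calibration (measured null rate ≈ 0.0012 at 50,000 features) without any
  trend or shrinkage machinery. The cost is that feature-specific
  dispersion differences are ignored; in the synthetic study all features
  share one true dispersion, so the simplification is exact there, but on
  real data heterogeneous features would be mis-calibrated in both
  directions.
* **Variance at the pseudo-counted mean.** The delta-method variance of
  `log2(m + 0.5)` is evaluated at `m + 0.5`, not `m`. The literal plug-in
  gives zero variance when a group mean is zero and declares any feature
  silent in one group significant; evaluating at the shifted mean is the
  consistent extension of the pseudo-count and suppresses exactly this
  failure mode.

There is no LFC shrinkage, no independent filtering and no outlier
handling. The published significance policies are applied verbatim:
genes/TE copies at fold change > 3 with BH-adjusted p < 0.001, TE families
at fold change > 2 (adjusted), exons at fold change > 3 with *raw*
p < 0.001 (taken at face value as printed). With a single replicate in a
group, fold changes are reported and p is missing.

For TE family and copy matrices, depth normalization is taken from the
gene count matrix rather than from the TE matrix itself: when one family
reactivates fifty-fold it dominates the TE library and median-of-ratios
(or library-size) factors computed within the TE matrix absorb real
signal into normalization.

## TE quantification

An alignment record contributes `1/n_hits` of a read's mass; a record
overlapping (>= 1 bp) copies of k distinct families splits that mass
equally among them, and records overlapping no TE accumulate in
`unassigned`, so total mass always equals the number of distinct reads.
Copy counts use uniquely mapping reads only; a unique read spanning two
adjacent copies increments both (documented, conservative). The > 400 bp
element filter applies only to the genomic-feature methylation panel, not
to counting. TSS-to-ERV distance is point-to-nearest-edge, strand-ignored,
strict at 20 kb. LTR metaplot elements merge below 8 kb gaps, keep the
leftmost member's strand, and anchor at the 5' start in that orientation.

## Cryptic intragenic initiation

Candidate isoforms need at least one upregulated exon at the exon policy.
Criteria, in transcription order per isoform: (i) < 100% of exons up;
(ii) exon 1 not up; (iii) no isoform of the gene 100% up (vetoes the whole
gene); (iv) < 5 up exons must be consecutive; (v) >= 5 up exons tolerate at
most one gap strictly inside the up span; (vi) the arithmetic mean *linear*
fold change of up exons exceeds 3x that of the other exons (the
aggregation is not specified upstream; the mean of linear fold changes is
the simplest reading and is configurable); (vii) the mean FPKM of up exons
in the upregulated condition exceeds that of the other exons (which
condition to use is likewise unspecified; the upregulated condition is the
default). The original workflow ended in manual curation — one isoform per
gene, removal of TE-driven sites, initiation positions read off coverage
tracks. Those steps are replaced by deterministic rules: per gene, the
isoform with most up exons wins (ties: longer spliced transcript, then
lexicographic id); a call is excluded when the initiation position ± 50 bp
overlaps a TE copy other than simple repeats/low-complexity, or an
annotated alternative promoter when provided; the initiation position is
the genomic 5' start of the 5'-most up exon and is flagged as inferred.
Every evaluated isoform keeps its full criterion trace so borderline calls
can be audited.

## The synthetic study

The generator's defaults are the benchmark's study conditions. Genome: two
5 Mb chromosomes, iid sequence at 42% GC with 80% of CpGs removed (≈ 9
CpG/kb, mimicking genomic CpG depletion). 300 genes (5–10 exons of 100–300
bp, introns 0.5–2.5 kb, 1–2 isoforms), promoters synthesized per intended
class — HCP at 60% GC with free CpGs, ICP at 50% GC with 45% CpG thinning,
LCP at 40% GC with 92% thinning — so that re-classification from sequence
reproduces the intent (300/300 at the default seed). Eleven TE families
(~500 copies, 1.3 Mb) emulate young ERVK/ERVL/LINE elements with
multi-mapping reads, plus SINEs and a simple repeat.

Methylation: WT latent level 0.85 outside CpG islands, 0.03 inside; the
ICM track is a per-kb block mixture (8% of blocks high at 0.80, the rest at
0.12 — chosen to land the ICM/DKO global mean near the published ~18%)
with CGIs low, gDMRs at 0.50, retained TE families at 0.85, planted de novo
windows at 0.01 and cryptic-site patches at 0.05. DKO copies the ICM track
(retained TEs and gDMRs explicitly held high); Dnmt1KO is WT scaled by
0.25, gDMRs included. Per CpG, depth is truncated NB (mean 12, the
realistic post-deduplication WGBS depth; minimum 1) and methylated counts
are beta-binomial with precision 30. Two replicates per genotype are pooled
by count summation.

Expression: log-normal baselines (log-mean 4, log-sd 1.5 → median ≈ 55
counts), NB counts with dispersion 0.05 and log-normal per-sample depth
factors; three replicates per genotype. Planted effects: 40 germline-like
genes (methylated HCP promoters; 8-fold in both mutants), 15 2C-like genes
(LCP; 8-fold in DKO only), 20 cryptic-initiation genes (single-isoform,
10-fold on exons from a planted index >= 3 onward, in DKO), reactivated TE
copies drawn from the longer half of their families (30-fold in Dnmt1KO;
18 of 60 IAPEz copies, so 30% of the family), and ERV-driven genes
(TSS < 20 kb from a reactivated copy; 2.5-fold in Dnmt1KO). Planted genes'
baselines are redrawn above 20 counts — derepression to readily
quantifiable expression, matching the strongly reactivated gene sets the
design emulates. Exon counts are drawn per exon proportional to exon
length (independent draws, not constrained to sum to the gene count).

What the benchmark does not show: the generator has no read-level
bisulfite chemistry, no mapping bias, no isoform switching, no dispersion
heterogeneity across features, and its TE "alignments" abstract mapping as
an `n_hits` multiplicity. Passing tests therefore demonstrate the
correctness and calibration of the analysis procedures under the stated
statistical model, not robustness to artefacts of real libraries.

Two consequences of honest sampling noise are documented rather than
hidden. First, the de novo window filter (<5% ICM / >50% WT) recovers every
planted window, but also selects germline-promoter CGIs and cryptic-site
patches — genuinely de novo methylated by construction — and, at a ~0.6%
rate, sparse-CpG background windows whose measured ICM mean crossed 5%;
exact set-equality with the planted list is not attainable at a realistic
ICM background level, and the filter's input-output behaviour is instead
proven against an exhaustive oracle. Second, genome-wide DMR calling
between WT and Dnmt1KO returns thousands of regions because the
hypomethylation truly is genome-wide; the targeted recovery check uses a
dedicated two-condition construction with one planted region.

## Problem sizes and determinism

Default scale (5 min end-to-end on one CPU): ~114,000 CpGs × 4 genotypes ×
2 replicates, 300 genes / ~3,200 exons × 9 samples, ~500 TE copies,
~150,000 alignment records. The test suite reuses one session-scale
simulation plus a reduced configuration (120 genes, 2.2 Mb) for structural
tests. All randomness flows from a single root seed through fixed, named
substreams (annotation, methylome latents, methylome draws, counts,
coverage), so any stage can be regenerated independently and byte-identical
outputs follow from equal seeds.
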