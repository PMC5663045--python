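# Methods

This note documents the models, parameters and numerical choices behind
`gliomapairs`, and what the synthetic-cohort results do and do not
demonstrate about real data.

## Read-count and cohort model (synthetic data)

A tumor sample is modelled as a mixture of tumor cells at purity p on a
diploid background. A heterozygous somatic variant carried by a fraction f
of tumor cells (its clonal fraction) is covered by `depth` reads with

    alt_reads ~ Binomial(depth, p · f / 2),

which is exactly the quantity the MAF filters act on; no sequencing-error,
mapping or trinucleotide-context structure is modelled. Germline variants
sit at BAF 0.5 in tumor and normal regardless of purity. Caller behavior is
reduced to a per-caller detection probability (default 0.95) plus uniform
false positives (default 2 per sample per caller) planted at MAF < 0.15 so
that the consensus and MAF rules are both exercised. With
`deterministic_reads=True`, read counts are rounded expectations; combined
with sensitivity 1 and false-positive rate 0 this defines the noise-free
regime in which every downstream stage must recover the planted truth
exactly — the basis of the end-to-end recovery tests.

The default cohort mirrors the emulated study design: 16 pairs split 7/7/2
across H3/IDH1 mutant, H3/IDH1 wildtype and NF1 germline; 69× mean
coverage (the study's reported average); purity 0.8; matched normals for
9 of 16 patients; 8 shared passengers, 3 primary-private and 5
recurrence-private per pair (a recurrence-ward trend); one hypermutator
pair with a 10× count multiplier. H3/IDH1 driver templates enforce the
co-occurrence rule (oncohistone/IDH1 always with TP53, HIST1H3B K27M with
ACVR1), K27M pairs are placed in the midline, and each pair's methylation
subgroup (K27M / G34R/V / IDH1 / WT) follows its driver. Driver variants
are placed inside approximate GRCh37 loci of the named genes; passengers
and false positives are uniform over the autosomes. Purity and per-sample
depth variability are unreported in the emulated design, so purity is a
single cohort-level constant — a simplification, not an inference.

Planted copy-number/AI segments occupy distinct arms within a sample
(guaranteeing the non-overlap invariant), spanning 30–60% of an arm.
Single-copy events and cnLOH shift BAF centers to 0.5 ± 0.3 (i.e. 0.2/0.8,
typical of 60–100% aberrant-cell fraction); amplifications use 0.5 ± 0.17
and coverage multiplier (2+p)/2; deletions (2−p)/2 (≈ log₂ −0.74 at
p = 0.8, −1 at p = 1). Two cohort-level flavors are available: 17q cnLOH in
NF1-germline recurrences and a genome-wide cnLOH recurrence.

What passing tests therefore show: the pipeline's logic, thresholds and
statistics behave as designed against data whose generative model matches
the pipeline's assumptions. What they do not show: robustness to alignment
artifacts, FFPE damage, GC/mappability bias, indel representation
ambiguity, subclonal phylogenies beyond the shared/private dichotomy, or
mutational signatures (e.g. temozolomide-driven hypermutation is modelled
only as a count multiplier).

## Variant consensus and filter cascade

Variants are keyed by exact (chrom, pos, ref, alt); no indel normalization
is performed (synthetic VCFs are emitted normalized; real data would need
left-alignment upstream). When callers disagree on read counts the caller
with maximum depth is representative (deterministic, favors best-covered
evidence; caller name breaks ties). Every rule appends a machine-readable
code to `filter_reasons` and reads only its own fields, so the final
status is order-independent — a property the suite checks directly.

Thresholds (FilterPolicy defaults): 2-of-3 callers; read support ≥ 0.10;
MAF ≥ 0.05 inclusive for the genes-of-interest panel vs > 0.15 exclusive
elsewhere (the inclusive/exclusive split follows the stated "minimum of
5% or greater" vs "> 15%" phrasing); population cutoffs 5·10⁻⁴
(1000G/EVS) and 5·10⁻⁵ (ExAC), inclusive, with absent annotations treated
as frequency 0 (novel); normal review threshold 2 reads. Variants with
exactly 1 alt read in the normal are `review_flagged` and retained in
outputs: the original workflow resolved these by manual alignment
inspection, which a pipeline cannot reproduce. The 10% read-support rule
is waived for genes-of-interest variants by default
(`waive_read_support_for_goi`), otherwise the 5% MAF tier would be
unreachable; the flag allows the stricter reading.

## Allelic-imbalance detection

Folded deviations |BAF − 0.5| are strictly positive at finite depth even
in balanced regions (≈ 0.034 median at depth 100), so windows are tested
against a baseline rather than against zero. The baseline is the
Hodges–Lehmann pseudo-median of folded deviations — the exact location
parameter the Wilcoxon signed-rank statistic tests, which keeps the
windowed test calibrated despite the skew of folded deviations (measured
per-window size 5.2% at nominal 5%). It is estimated from the matched
normal's folded deviations when normal read counts exist, else from the
tumor's own genome; the tumor-based estimate assumes most of the genome is
balanced and fails on genome-wide cnLOH, which is why the normal-based
baseline is preferred whenever available. The pseudo-median computation
thins inputs to ≤ 400 evenly spaced order statistics, bounding the
pairwise Walsh-average matrix.

Defaults: window 25 sites (non-overlapping, trailing remainder folded into
the last window; arms with < 25 sites yield no call), one-sided Wilcoxon
(greater), Benjamini–Hochberg at α = 0.05 across all windows of a sample.
Merged segments are trimmed to the first/last individually deviant site
(two-sided normal-approximate binomial test at ~5%) and discarded when
supported by fewer than `min_sites = 10` sites — genuine events span most
of a window, while marginal windows trim to short noise runs. Degenerate
windows (all deviations equal to the baseline) get p = 1. Under the null
the family-wise false-positive rate measured over 1000 simulations is
~4–6% at the nominal 5% (false positives are correlated within a sample
through the shared baseline estimate). Region sharedness between primary
and recurrence is any-overlap (≥ 1 bp, same chromosome) and counted per
list, so a region split across two partner regions contributes asymmetric
shared counts; per-pair reporting uses the primary-list count.

Coordinates are 0-based half-open internally and in BED output; VCF and
track TSVs are 1-based. Arm assignment uses a bundled GRCh37 table (hg19
chromosome lengths with approximate centromere midpoints); the generator
and the callers share it, so arm logic is internally consistent, but the
centromere positions should not be treated as reference-accurate.

## Joint CNV/cnLOH caller

Coverage is binned (default 10 consecutive targets), each sample scaled by
its genome-wide median depth (median, not mean, for robustness to focal
events), and bins with raw normal depth < 10 dropped. Note that the median
baseline presumes the majority of the genome is copy-neutral; a plant
covering ~half of the simulated genome visibly compresses log₂ ratios.
Binary segmentation splits at the point maximizing the pooled two-sample
t statistic and accepts a split when |t| > √(2·penalty·log n) (BIC-style;
penalty default 3, minimum segment 3 bins) — a deliberate, testable
stand-in for full circular binary segmentation, adequate at these scales.
GC correction is omitted (the generator has no GC bias); real data would
need it.

States: gain at mean log₂ ≥ +0.3, loss at ≤ −0.3 (detects single-copy
events at purity ≥ 0.6); a union-partition cell is imbalanced when inside
a detected AI segment; an interval-level classification treats an interval
as imbalanced when AI segments cover ≥ 50% of it. Event classes follow the
fixed mapping (gain→amplification, loss→deletion, neutral+imbalanced→
cnLOH). The union of coverage and AI breakpoints partitions each
chromosome (cells split at the centromere so every event lies on one arm);
cells uncovered by any coverage segment default to neutral. Arm-level
calls require one class to cover ≥ 70% of the arm's analyzable extent
(the bases covered by segment-level cells). In recovery scoring, detected
events shorter than a quarter of the planted segment are treated as
breakpoint imprecision at union-cell edges rather than false discoveries.

## Methylation clustering

Probe filtering removes chrX/chrY, SNP-overlapping and cross-reactive
probes. The top 3000 probes by across-sample SD (n−1 denominator) are
selected, ties broken lexicographically by probe id for determinism.
Distance is 1 − Pearson correlation between sample beta vectors — the
operative word in the emulated protocol is "Pearson", and beta values are
bounded continuous, so Pearson on betas is the default with a Spearman
switch (`method="spearman"`). Linkage is average (UPGMA); flat labels cut
the tree at k = 4, the canonical pHGG subgroup count, configurable.
Zero-variance samples make correlation undefined and raise an error naming
the sample. Pairs with a member missing from the clustering are skipped
and logged; the co-clustering fraction is over evaluable pairs. The
reference-cohort integration of the original protocol is out of scope: the
module validates co-clustering on synthetic cohorts and accepts any
external beta matrix the user supplies.

## Cohort statistics

Medians use the even-n average-of-middle-two convention and are reported
both raw (one decimal) and rounded to the nearest integer, since clinical
reports print integers while the underlying column medians are fractional
(the bundled table's TTP median is 12.9 → printed 13); ranges likewise
(3.8–45.2 → printed 4–45). Treatment counts tokenize the free-text
history on '+' and ',' against a small controlled vocabulary (RT,
temozolomide aliases); unrecognized tokens are kept lowercased and simply
not counted. The paired burden tests compare primary totals
(shared + primary-only) against recurrence totals per pair; zero-variance
differences raise rather than returning a meaningless statistic.

## Group assignment

Precedence is H3/IDH1 mutant > NF1 germline > wildtype: the three groups
are disjoint by construction and the precedence makes the residual
well-defined; a conflict (H3 driver plus germline NF1) is logged. Driver
matching uses normalized protein-change tokens (K27M, G34V/R, R132·
prefix); no transcript arithmetic. Pathway membership for the
conservation matrix ships as an editable YAML (curated groupings, not
computed). When a gene carries variants in several temporal categories
for one pair, the matrix reports the first of shared > primary_only >
recurrence_only.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is meaningfully exercised:
noise-free end-to-end recovery on 4-pair cohorts (600 BAF sites, 1200
probes) covering all three groups; AI recovery on 100 single-chromosome
simulations (400 sites, 40-site plants, depth 80); null calibration on
1000 balanced simulations; CNV recovery on 100 three-chromosome
simulations (≥ 50-bin plants); co-clustering on 8-pair cohorts spanning
all four methylation subgroups; 1000 random inputs for the t-test oracle
comparison. The full-size 16-pair cohort is exercised by the analysis
drivers and the pipeline smoke test.

## Known limitations

Exact-key variant matching (no indel normalization); no purity/ploidy
estimation (BAF shift magnitudes are configuration, not inference); binary
segmentation rather than CBS; no GC/mappability correction; the AI
statistic is a calibrated stand-in for the unpublished original; arm
boundaries are approximate; the hypermutator phenotype is a count
multiplier without signature structure.
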