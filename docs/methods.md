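# Methods

This note documents the models, numerical choices and limitations behind
`snpkaryo`, in the order the pipeline runs.

## Signal model and the synthetic generator

The generator emulates the marker-level output of a genotyping array after
vendor preprocessing: per probe a log-R-ratio (LRR) and, for SNP probes, a
B-allele frequency (BAF) and a genotype call.  The conventions:

* **LRR.** A region at total copy number CN has expected LRR = log2(CN/2).
  With tumor purity p < 1 the expectation becomes log2((p·CN + (1−p)·2)/2).
  CN = 0 is floored at −5 to avoid log(0); homozygous deletions at that depth
  are outside the copy-number range the calling thresholds are designed for,
  so the floor is purely numerical.  Additive Gaussian noise with sd 0.2
  (default) approximates a good-quality array after GC correction.
* **BAF.** Germline genotypes are drawn per SNP probe as AB with probability
  0.3 (the default heterozygous fraction; typical genome-wide SNP panels
  yield 25–35% heterozygous calls per sample), else AA/BB equiprobably.  In a
  lesion of copy number CN, a germline-AB SNP moves to nB/CN: with LOH one
  parental allele is lost (nB ∈ {0, CN}, chosen per SNP with equal
  probability, emulating phase); without LOH both alleles survive and nB is
  uniform on 1..CN−1.  Gaussian noise sd 0.03, clipped to [0, 1]
  (truncated-Gaussian), approximates cluster width.  Genotype calls derive
  from the observed BAF (≤ 0.2 AA, ≥ 0.8 BB, else AB; no-calls inside CN=0).
* **Probe map.** Probes sit at regular spacing with uniform jitter below half
  the spacing (so order is preserved); a configurable fraction are SNP
  probes, the rest copy-number-only.  The desk-scale default genome is 4
  autosomes × 10 Mb at 1 kb spacing (40,000 probes per sample), which keeps a
  full 20-sample cohort run under a minute while preserving ≥ 10-marker
  lesions down to ~10 kb.  Real arrays are ~50× denser and have strongly
  non-uniform spacing; conclusions about marker-poor regions therefore do not
  transfer from synthetic runs.

Cohorts implant one shared lesion in exactly round(carrier_fraction × n)
randomly chosen samples plus a fixed number of private lesions per sample
(`private_lesions_per_sample` is an exact count, not a Poisson mean, so the
study conditions are deterministic given the seed).  Private lesions never
overlap one another within a sample, nor the shared locus in any sample —
this keeps the truth-table carrier count at the shared locus exact, which is
what the recurrence stages are tested against.  Sizes are log-uniform
(20–200 kb for CNVs at CN ∈ {1, 3, 4}; 1–3 Mb for aUPD, drawn with
probability 0.15).  Identical (specification, seed) pairs produce
byte-identical output files.

What the generator does **not** emulate: raw probe intensities and
restriction-fragment/PCR bias, GC waves, genotyping-error structure,
subclonality (single purity value per cohort), X/Y/MT (the pipeline excludes
them anyway), and linkage structure in germline genotypes (SNPs are
exchangeable).  Passing tests therefore demonstrate algorithmic correctness
under the stated noise model, not performance on real arrays.

## Segmentation

The comparison signal is tumor LRR minus matched-normal LRR (paired) or
minus the per-probe median of a healthy panel (baseline).  Note the paired
ratio carries √2 × the single-sample noise sd (two independent arrays), which
is the operative noise level in all recovery figures.

Series are first split at inter-probe gaps strictly greater than `max_gap`
(default 100 kb) so no segment spans a marker desert; sub-series shorter than
`min_markers` are flagged excluded.  The default 100 kb is a choice, not a
published constant — real analyses tune it to the array's density profile.

**Recursive bisection** (`segment_series`): the candidate breakpoint
maximizes the pooled-variance two-sample t statistic between left and right
flanks (leftmost argmax on ties; computed for all cuts from prefix sums in
O(n) per level); the split is accepted when both sides hold ≥ `min_markers`
(10) probes and the two-sided t-distribution p-value is ≤ `split_alpha`
(0.001); recursion continues on accepted halves; adjacent leaves whose means
do not differ at `merge_alpha` (0.001, independently configurable; the split
and merge levels default equal) are re-merged to a fixpoint.  p-values come
from the t distribution rather than permutation — adequate at desk scale and
orders of magnitude faster; the statistic at the selected cut is a maximum
over many correlated cuts, so its pointwise p-value is anti-conservative,
which in practice drives deep fragmentation of long noise stretches that the
merge pass then largely undoes.  Degenerate flanks (zero pooled variance) map
to p = 0 when the means differ and p = 1 when they agree; mean differences at
or below 1e−9 are treated as zero so cumulative-sum rounding on constant
stretches cannot fabricate infinite statistics.

**Edge pre-scan** (`segment_with_precut`, the production path used by
`segment_sample`): pure bisection has a structural blind spot — a short
lesion deep inside a long flat series shifts the full-halves t at its
boundary by only ~w·h/√(n/4) (w markers, height h, series length n), which
for a 20-marker one-copy loss in a 10,000-probe chromosome is ~1.5, below the
noise maxima, so the recursion can terminate without ever isolating it.  The
driver therefore first computes a local two-window t statistic (adjacent
windows of `min_markers` probes, df = 2w−2) at every cut, keeps cuts reaching
the two-sided critical value at `split_alpha` (strongest first, suppressing
weaker candidates within w//2 probes), bisects each resulting block, and
finally applies the merge rule across the whole series.  False edges are
cheap — the merge pass removes any cut whose flanks do not differ at
`merge_alpha` — while true short lesions get isolated with the local
statistic ~w·h/√(2/w), e.g. ~16 for the example above.  `segment_series`
itself remains pure bisection so its first-split behaviour is exactly the
exhaustive single-cut maximizer, which the test suite verifies against a
brute-force oracle.

Segment bounds snap to member probes, end = last probe position + 1; all
internal coordinates are 1-based half-open so length = end − start.

## Lesion calling

* Copy-number state: gain iff mean ratio LRR ≥ +0.15, loss iff ≤ −0.2,
  neutral otherwise; cn_estimate = 2·2^LRR reported to one decimal.  The
  asymmetric defaults reflect the log-scale asymmetry of single-copy changes
  (CN 3 → +0.585, CN 1 → −1) and are configurable; they are calling
  conventions, not published constants.
* LOH: informative SNPs are those genotyped AB in the matched normal
  (paired) or heterozygous in at least half of the reference panel (baseline;
  a population proxy that is explicitly lower-confidence, since the tumor's
  own germline may be homozygous at a panel-het SNP).  LOH is called when ≥
  10 informative SNPs exist and ≥ 90% of their tumor BAFs fall in the
  homozygous bands (≤ 0.1 or ≥ 0.9); below 10 the segment is reported
  uninformative (loh = false).
* The five categories follow from (state, LOH); copy-neutral segments
  without LOH are not lesions.
* aUPD channel: copy-neutral LOH is invisible in LRR, so inside each
  copy-neutral segment the mirrored-BAF series |BAF − 0.5| of the informative
  SNPs is segmented with the same splitter; sub-regions that pass the LOH
  call and remain copy-neutral in mean ratio LRR become AUPD lesions.  A
  known limitation: under heavy LRR noise a long aUPD spanning several
  (spuriously fragmented) neutral LRR segments is detected piecewise, and
  pieces below the 1 Mb filter are lost; aUPD recall under noise is therefore
  lower than CNV recall.  Zero-noise recovery is exact.

Filters run in a fixed order per lesion (excluded chromosome → CNV < 1 kb →
aUPD < 1 Mb → blacklisted cytoband) and log the first matching rule;
filtering is idempotent.  The blacklist matches band *names* against the
lesion's overlapping bands from the supplied cytoband map, so entries that do
not exist in the map (for instance the T-cell-receptor set is sometimes
written "7p34" where UCSC nomenclature has the TRB locus at 7q34) are kept
verbatim and simply never match; both spellings may be listed in a config.

## Cohort analysis

* Density: counts per chromosome ÷ length in Mb; chi-square goodness-of-fit
  of the raw counts against length-proportional expectation (df = #chroms −
  1; reported not-applicable for a single chromosome); chromosomes above the
  median normalized value are flagged.
* Recurrence counts **distinct samples**, not lesions, per unit (cytoband, or
  maximal constant-count genomic runs from a sweep line over per-sample
  merged intervals).
* MAR: candidate regions are maximal constant-count runs whose
  distinct-sample count strictly exceeds cohort_size × min_fraction
  (min_fraction 0.5 ⇒ strict majority, so 11/20 qualifies and 10/20 does
  not); any imbalance category counts as support.  The MAR is the candidate
  with the highest count, ties broken by smallest length ("minimal" region)
  and then genomic order, which makes the result deterministic.  Its mean
  copy number averages cn_estimate per affected sample, then across samples;
  the dominant category is the modal category of the overlapping lesions
  (alphabetical on ties).  When no position reaches the majority the result
  is empty with an explanatory status, not an error.  The sweep line is
  verified against per-base brute-force counting on random mini-cohorts.
* Known/novel: a lesion is "known" when ≥ 50% of its length is covered by
  the union of database intervals (the threshold is a package convention,
  configurable); summary percentages are reported both exact and rounded to
  integers, and the exact pair always sums to 100.
* Training/test overlap: upper-tail hypergeometric P(X ≥ |A∩B|) drawing |B|
  from a universe with |A| marked; the percentage is relative to |A|.  The
  universe is whatever band set the user supplies (the bands of the loaded
  map, by default); published analyses of this shape rarely state their
  universe, so no attempt is made to match any particular printed p-value —
  the test is reported for the stated universe.

## qPCR quantitation

ΔCt per well = target Ct − reference Ct; per sample the mean and the n−1
standard deviation over replicates (small replicate counts, default 4 wells);
QC passes when σΔCt < 0.15 cycles.  Without a calibrator the scale is
anchored on the cohort itself: the median mean-ΔCt across QC-passing samples
is assumed to represent the reference copy number 2 — valid when more than
half the assayed samples are diploid at the target, which is the intended use
(a validation plate with controls).  CN_i = 2·2^(anchor − ΔCt_i); adding any
constant to both dyes' Ct values cancels, and one ΔCt cycle is exactly a
two-fold change.  Concordance with the array's binary "amplified" readout
(integer CN ≥ 3 by default) is reported both over all samples and restricted
to QC-passing ones, since it is ambiguous whether failing replicates should
count.

## Problem sizes and determinism

The reference synthetic study used throughout the tests and the acceptance
script is 20 tumor/normal pairs × 40,000 probes (4 × 10 Mb at 1 kb), LRR sd
0.2, one shared 50 kb CN=4 amplification in 11 samples, 5 private lesions per
sample — about 10–20 s end-to-end on one CPU.  Oracle suites run 100 random
instances each.  All randomness flows through numpy Generators seeded from a
single integer; identical seeds give identical outputs (manifests are equal
up to timestamps).

## Known limitations

* No GC-wave correction (the generator produces none; real data would need
  vendor or external correction upstream).
* No subclonal fraction estimation; a single cohort-wide purity parameter.
* Baseline-mode LOH is a population proxy and over-calls homozygosity at
  panel-het SNPs where the tumor germline is homozygous; its thresholds are
  tuned to remain conservative (0.9 hom fraction) rather than sensitive.
* Noisy aUPD spanning fragmented neutral segments is recovered piecewise
  (see above).
* The chi-square density test treats lesions as independent events, ignoring
  that one biological event can span several called lesions.
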