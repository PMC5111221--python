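# Methods

`shallowcn` estimates genome-wide DNA copy number from low-coverage
(~0.1–3×) whole-genome sequencing by read-depth analysis in fixed genomic
windows, the standard approach for profiling copy-number alterations (CNAs)
in degraded, low-input material such as formalin-fixed paraffin-embedded
(FFPE) tumor tissue. This note documents the model, the tunable parameters,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## Read-depth model and normalization

The genome is partitioned into bins of `bin_size` bp (default 50,000; the
terminal bin of each chromosome may be shorter). The per-bin read count of
a sample with tumor purity *p* carrying integer copy number *C* at a bin is
modeled as negative binomial with mean

    mu = r · (width / bin_size) · (p·C + (1−p)·2)/2 · g(gc)

where `r = mean_coverage · bin_size / read_length` converts fold coverage
to expected counts (read length defaults to 75 bp) and *g* is a unimodal
GC-response curve normalized to mean 1.

`gc_normalize` inverts this without a matched normal: a degree-2
polynomial of count on GC fraction is fitted to non-zero bins, bins outside
the 5th–95th percentile band of relative residuals (count/fit) are dropped,
and the polynomial is refitted. Trimming on *residuals* rather than on raw
counts matters: a raw-count percentile cut removes entire GC strata when GC
bias is strong and biases the curve, whereas the residual band removes only
outliers (CNA bins, artifacts). Ratios `count/expected` are divided by
their genome-wide median and log2-transformed, so the majority (assumed
diploid) state maps to log2 ratio 0, i.e. values estimate log2(CN/2) with
baseline ploidy fixed at 2. Zero-count bins are masked (reason
`zero-count`) rather than log-transformed with a pseudocount: at ~0.2×
amplified-library coverage a pseudocount would fabricate deep-loss signal
in the many empty bins. No mappability weighting is applied; supplying a
blacklist of unreliable regions is the supported mechanism for excluding
systematically misbehaving bins.

A caveat inherent to median-centering: when a large fraction of the genome
is aberrant in one direction, the genome-wide median no longer sits at the
diploid level and all ratios shift slightly. The majority-diploid
assumption should hold for the intended samples.

## Segmentation (CBS)

Segmentation is circular binary segmentation: per chromosome, the arc of
the circularized marker sequence maximizing

    T(i, j) = |mean_in − mean_out| / sqrt(1/k + 1/(n−k))

is located (the arc/complement symmetry of T means scanning all linear
windows covers every circular arc). No per-arc variance term is included;
any constant scale cancels in the permutation test, so significance — the
p-value from `n_permutations` random relabelings compared against `alpha` —
is calibrated without a variance model. The permutation loop stops early
once enough permuted maxima exceed the observed statistic to rule out
significance, which makes rejected splits (the recursion leaves) cheap.
Accepted splits recurse on each resulting piece. Afterwards adjacent
segments whose means differ by less than `prune_tol` are merged, closest
pair first.

Defaults: `alpha = 0.01`, `n_permutations = 1000`,
`min_bins_per_segment = 3`, `prune_tol = 0.05` log2 units — conventional
CBS settings, all exposed. Runs of more than `max_gap` (default 10)
consecutive missing bins break segments, so no segment bridges a
centromere-scale masked gap; shorter gaps are bridged. Segment extents run
from the first member bin's start to the last member bin's end, and each
segment's mean is the exact mean of its member bins. Constant
(zero-variance) stretches return a single segment without permutation
work.

Determinism: a single seed drives one generator through a fixed recursion
order, so identical inputs and seed give identical segmentations.

## Calling

Segments are called `gain` when the mean log2 ratio is strictly above
`gain_thr = 0.15`, `loss` when strictly below `loss_thr = −0.15`, else
`neutral`; boundary values are neutral by the strict inequality. A
three-state model is used throughout — no separate high-amplification or
homozygous-deletion classes, no allele-specific/LOH analysis (read depth at
these coverages cannot support genotyping), and no purity/ploidy search
beyond the fixed diploid baseline.

## MAPD

The noise metric is the median absolute pairwise difference
MAPD = median(|x_{i+1} − x_i|) over position-ordered per-bin log2 ratios.
Because a true CN breakpoint contributes only one large difference per
boundary, MAPD reflects bin-to-bin noise, not biology; for i.i.d. Gaussian
noise of sd σ it equals √2·Φ⁻¹(0.75)·σ ≈ 0.954σ. Pairs spanning a
chromosome boundary are excluded (not biological adjacencies), and the
metric is computed genome-wide on bin-level normalized values, not segment
means. Missing markers are skipped by default, pairing consecutive
non-missing markers within a chromosome; a `strict` mode dropping any pair
with a missing member is available for masking-sensitive comparisons.

## Profile comparison

For concordance, a profile is quantized onto the grid: each bin takes the
call of the segment containing its midpoint (bins in masked gaps are
masked). Two samples are compared over bins unmasked in both — masked
regions cannot be compared fairly, and the denominator choice is recorded
with the result. `shared_fraction` is the base-pair fraction with
identical three-state calls; `shared_cnv_fraction` restricts to bins where
at least one sample carries a CNA.

The compared base pairs partition exactly into five classes: shared CNA,
CNA in A only (B neutral), CNA in B only, *conflict* (gain in one sample,
loss in the other at the same bin), and shared neutral. The explicit
conflict term is required for the partition to be exact — event-type-matched
bookkeeping would otherwise count a conflicted bin once per event type —
and is zero in the common case. `shared_neutral_bp(total, shared_cna,
sample_only_cna)` implements the subtraction identity used to report shared
copy-neutral genome.

`shared_regions` works at base-pair resolution by sweeping segment
boundaries: for each event type independently, every interval is labeled
with the exact sample subset calling that event there; subsets of size ≥ 2
are shared regions, singletons sample-only. Because pipeline segments are
bin-aligned this coincides with the bin-quantized view, while remaining
exact for imported segment-level profiles.

`cna_bin_correlation` extracts normalized log2 values from bins inside the
union of CNA calls across the supplied profiles (minus any filter
regions), computes pairwise-complete Pearson correlations, and clusters
the correlation-matrix rows by Euclidean distance with complete linkage
(the classic hclust default for this analysis); the dendrogram is
exportable as Newick.

## Synthetic data: what it emulates, and what it does not

The generator emulates: segmental integer-CN events on a diploid
background diluted by purity; smooth (AR(1), lag-1 correlation 0.9) GC
landscapes in [0.3, 0.7] with a quadratic depth response; extra-Poisson
count noise; amplification-style degradation (mean-preserving variance
inflation by a gamma-Poisson multiplier plus independent bin dropout); and
binomial read thinning for down-sampling experiments. Events are snapped
to bin boundaries — the native resolution of the pipeline.

Chosen defaults: NB size (dispersion) 100, i.e. ~10% extra-Poisson CV per
50 kb bin, which yields MAPD ≈ 0.14–0.16 at 0.6–2.2× — the noise regime of
acceptable FFPE shallow-WGS libraries (array-style QC practice treats
MAPD ≲ 0.3 as usable). WGA-style degradation defaults to dropout 0.85 and
variance inflation ×4, matching libraries with under ~15% of the genome
covered and several-fold duplicate inflation. Purity defaults to 1 and is
a free parameter: cellularity of real specimens varies and is not modeled
further.

Not emulated: FFPE damage chemistry (deamination, fragment-length
effects), library/adaptor artifacts, mappability structure, and
read-level phenomena generally (counts are simulated at bin level; the
SAM fixture writer exists only to exercise the alignment adapter).
Passing recovery tests therefore demonstrate correctness of the
*analysis* under the stated noise model, not robustness to every
real-data artifact.

## Validation experiment sizes

The packaged experiments (`shallowcn.experiments`, also run by
`scripts/acceptance.py`) use desk-scale genomes chosen to keep a full run
in a few minutes while leaving events tens of bins long: titration runs
use 6 chromosomes × 12 Mb (1,440 bins) with 8 events of 2.5–3.5 Mb
(50–70 bins) and CN states {1, 3, 4} at 2.2× down-sampled to 1.3× and
0.6×; the WGA contrast uses 8 × 15 Mb so that 85% dropout still leaves
enough non-zero bins to normalize; oracle checks use 1,000 random MAPD
tracks and 200 single-changepoint chromosomes of ≤ 120 bins. All
experiment knobs are function arguments, so larger replications are one
call away.

## Known limitations

- Median-centering assumes a majority-diploid genome (see above).
- The GC fit is genome-wide; chromosome-specific GC artifacts are not
  modeled.
- CBS permutation p-values are conditional on the marker set after
  masking; heavy masking reduces power on short chromosomes.
- Bin-midpoint quantization makes sub-bin (< 50 kb) events invisible by
  construction; this is the window-size detection limit, not a defect of
  segmentation.
- Sex chromosomes are treated as autosomes (no ploidy adjustment for
  patient sex); exclude them from comparisons when that matters.
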