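# Methods

This note records the models, parameter choices and numerical conventions
behind `danorm`, and what the synthetic validation does and does not show.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED family).  Paired-end fragments
are 10-column BEDPE records; both mates must share a chromosome and carry
`+`/`-` strands.  The Tn5 correction moves each mate's 5' coordinate by
+4 bp (plus strand) or −5 bp (minus strand), compensating for the 9-bp
target-site duplication the transposase leaves at an insertion point.  It
is applied before minimal (fragment-span) conversion, exactly once; the
CLI enforces single application through a provenance flag in the output
manifest.  Blacklist filtering removes any record overlapping a
blacklisted interval by ≥ 1 bp, the strictest reading of overlap.
Extra BEDPE columns are preserved verbatim on write.

## Region definition

**Naive-overlap consensus.**  A pooled-replicate peak is kept when every
replicate contains a peak overlapping it by at least 50% of the shorter of
the two peaks (`mode="either"`, matching `bedtools intersect -e -f 0.5
-F 0.5`).  Measuring only against the pooled peak's length is available as
`mode="pooled"`; the either-peak rule is the default because it is what
widely used consensus scripts implement.

**Sliding windows.**  Fixed-width windows (default 300 bp, spacing =
width) tile each chromosome from 0; a window extending past the chromosome
end is dropped.  A window survives the local-background filter when its
pooled fragment count exceeds `fold_threshold` (default 3) times the count
of its surrounding neighborhood (default 2 kb centered on the window, own
fragments excluded) after scaling the neighborhood to the window's
footprint.  The 0.5-count continuity correction is added to both the
window count and the scaled background so the empty/empty case has ratio
exactly 1 and is dropped by any threshold above 1; applying the correction
before length-scaling would instead let empty windows pass, which is why
the scaled form is used.  The low-abundance floor defaults to the average
log2-CPM of a hypothetical region holding 5 fragments at the mean library
size — small enough to keep any plausibly testable region, large enough to
drop windows whose variance estimates would be meaningless.

**Window merging.**  After testing, windows within 100 bp on one
chromosome merge; each merged region receives the Simes combined p-value
min_i (k·p_(i)/i) over its k members — a valid p-value under independence,
verified by simulation — with the logFC of its most significant member as
the representative effect, and BH is applied across merged regions rather
than windows so the FDR applies at the region level.

## Library complexity

The duplicate-frequency histogram maps j to n_j, the number of distinct
fragment identities (chromosome, span, strand pair) seen exactly j times;
C = Σ n_j distinct identities from R = Σ j·n_j records.  Complexity is
estimated with the Lander–Waterman saturation model: N solves
C = N(1 − e^(−R/N)), by bisection on [C, 10^12·C] — a single transparent
equation that simulation can check directly (the histogram is retained so
a rational-function extrapolation estimator could be added behind the same
interface).  The estimate requires observed duplication; a fully unique
library has an unbounded estimate and is treated as an error rather than a
number.

Equalization thins libraries by seeded Bernoulli subsampling.  The matched
quantity is the **expected number of distinct fragments after thinning**,
E[C(p)] = Σ n_j(1 − (1−p)^j), solved for p against the smallest observed
distinct count among the libraries.  Matching the estimated underlying N
instead is not operationally possible — thinning reads does not change the
size of the molecule pool they were drawn from — so N is reported per
library but not used as the target.  One PRNG stream per library
(seed + library index) keeps thinning of one library invariant to adding
another.  Deduplication, when requested, follows thinning.

## Counting and abundance

A fragment increments every region it overlaps by ≥ 1 bp (midpoint
assignment is a flag); fragments are counted once per pair.  Library sizes
default to total post-filter fragments per library, not in-region column
sums, and both are available.  Abundance uses the log2-CPM transform
log2((y + 0.5)/(L + 1)·10^6) with the MA-plot A value as its per-region
row mean.

## Normalization methods

* **Library size / reads-in-peaks** — scale factors proportional to total
  fragments or to in-peak column sums, renormalized to geometric mean 1.
  The former trusts global differences as possibly biological; the latter
  removes overall efficiency (FRiP) differences.
* **TMM** — computed on large (10-kb) genomic bins.  Reference column:
  upper-quartile CPM closest to the mean upper-quartile.  Bins with a zero
  in either compared sample are excluded pairwise; the most extreme 30% of
  M values *on each side* and 5% of A values on each side are trimmed
  (edgeR's rank bounds), and the factor is the precision-weighted mean of
  surviving M with delta-method weights.  The per-tail trim is essential:
  it is what lets the factor ignore an asymmetric minority (up to ~30%) of
  truly changing bins.  Fewer than 10 surviving bins triggers a warning
  and an untrimmed fallback.
* **Loess** — per-sample robust local-linear regression of M_gi = y_gi −
  A_g on A_g over log2(count + 0.5), tricube weights, 3 robustifying
  iterations, fitted values taken as log2-scale offsets and row-centered.
  The span default is 0.7, the cyclic-loess normalization convention: the
  bias this method exists to remove is smooth in abundance, and a wide
  neighborhood prevents a truly-changing minority of regions from dragging
  the local fit, while the robust reweights preserve the trend's shape.
  (With span 0.5 the correction of an asymmetric composition is measurably
  incomplete — a systematic ~54% residual up-fraction in the direction-flip
  experiment below.)  Offsets are consumed by subtraction from log2-CPM.
* **Quantile** — classic quantile normalization of the log2-CPM matrix:
  target distribution is the across-column mean of order statistics; ties
  receive the mean of their target quantiles via interpolation at average
  ranks.  Output columns share identical sorted values exactly.

## Testing engines

**Moderated linear model (primary).**  Per region, weighted least squares
of (normalized) log2-CPM on a two-column design (intercept + condition
indicator).  Precision weights come from the mean–variance trend: lowess
of √(residual sd) on mean abundance, predicted at each observation's
fitted value, raised to the −4th power, clipped to [10^-6, 10^6].  The
residual variances are shrunk toward a pooled prior: with
e_g = log s_g² − ψ(d/2) + log(d/2), the prior df d0 solves
ψ'(d0/2) = var(e) − ψ'(d/2) (Newton on the trigamma inverse) and
s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)); the posterior variance is the
df-weighted average (d0·s0² + d·s_g²)/(d0 + d) and the moderated t has
d0 + d degrees of freedom (normal in the d0 → ∞ branch, reached when
variances are effectively identical; d0 = 0 recovers the ordinary t
exactly).  Regions with zero residual variance are excluded from
hyperparameter fitting.

**NB exact test (secondary).**  Counts are rescaled to the geometric-mean
effective library size and rounded.  With a method-of-moments common
dispersion φ (mean over regions of max(0, (s² − μ)/μ²)), the group-A sum
conditional on a region's total is beta-binomial with shapes n_A/φ and
n_B/φ (sums of i.i.d. NB variables sharing a success probability); φ = 0
degenerates to the binomial split.  Two-sided p doubles the smaller tail,
capped at 1; a mid-p variant that halves the boundary term is a flag.
This engine accepts factor-based normalizations only — per-observation
offsets and quantile-transformed values have no count-scale meaning.

**FDR.**  Benjamini–Hochberg step-up with monotonicity enforcement.
Default significance threshold 0.10 for discovery-style analyses, 0.05
for negative controls; both are parameters.

## Promoters, PR curves, enrichment

Promoter windows are strand-oriented [TSS − upstream, TSS + downstream)
(defaults ±3 kb; −2000/+200 suits compact genomes), a region is a promoter
on ≥ 1 bp overlap, a region overlapping several windows links to every
gene (nearest-TSS-only is a flag), and each gene's best promoter FDR is
the minimum over its linked regions.  The PR curve scores genes by
1 − FDR, sweeps descending with ties grouped, and integrates by steps
(Δrecall × precision — the average-precision convention, cross-checked
against scikit-learn).  Enrichment reports observed/expected and the
upper-tail cumulative hypergeometric p.

## Synthetic data: what it emulates

**Counts.**  count_gi ~ NB(mean = L_i·q_g·2^(x_i·(Δ_g + log2 c +
trend_g)), variance = μ + φμ²), with q_g a normalized log-normal baseline
(log2-mean 6.5, sd 1.0 → mean counts near 100), x_i the second-condition
indicator, Δ_g the planted log2 effect on a `frac_da` subset (up with
probability `up_fraction`), c a global efficiency multiplier, and trend_g
= amplitude·(a_g − ā) a linear-in-abundance M distortion — the minimal
bias shape that local regression can remove and linear factors cannot.
Default dispersion φ = 0.1, typical for replicated bulk ATAC-seq.  One
seed drives structure and counts through two documented substreams.

**Fragments.**  One chromosome with evenly spaced peaks carrying
log-normal accessibility weights; each library places N distinct molecules
(a `frip` fraction inside peaks, centers uniform within the peak,
lengths uniform 120–400 bp, 50-bp mates), then draws R reads with
replacement from them, so duplication — and therefore estimated
complexity — is controlled by R/N.  A condition effect multiplies the
weights of planted peaks.

What the generators do **not** emulate: sequence content and Tn5 sequence
bias, GC effects, fragment-length structure around nucleosomes, mappability
or blacklist artifacts, and within-condition biological heterogeneity
beyond NB dispersion.  Passing the validation experiments therefore shows
the machinery is correct and calibrated under its stated model, not that
any particular normalization is right for a given real data set.

## Validation experiments (study conditions)

Defined in `danorm.experiments`, seeded, and re-run both by
`tests/test_acceptance.py` and `scripts/acceptance.py`.

1. **Normalization oracles** — TMM on a 900-bin matrix against an
   independently written brute-force trimmed weighted mean (agreement to
   10^-6); the quantile sorted-column identity; loess reduction of an
   injected M(A) = 0.5·(A − Ā) trend to a residual trend below 0.1 over
   the central 90% abundance range (m = 5,000).
2. **Direction flip** — m = 10,000 regions, 3 vs 3, φ = 0.1, 20% of
   regions truly UP at log2 effect 4.5 (strong de-novo openings), no
   technical bias.  The effect size was fixed by a pilot power calibration
   in the moderate-power regime where conservative normalizations
   redistribute significance symmetrically; it was chosen once, before the
   validation was frozen.  Expected behavior: library-size and TMM keep a
   large majority of significant calls UP; loess and quantile yield sign
   counts statistically compatible with 50/50 (binomial p > 0.01).
3. **Null calibration** — 200 independent null experiments (m = 2,000,
   3 vs 3, no DA, no bias) per normalization route; discoveries at
   FDR < 0.05 are rare and the realized false-discovery rate stays within
   two Monte-Carlo standard errors of nominal.
4. **Complexity machinery** — estimator recovery of N = 10,000 from
   R = 50,000 reads (median error < 5% over 100 libraries); the closed-form
   thinning expectation against 1,000 empirical thinnings (< 1%); and DA
   call reproducibility across two subsampling seeds (Jaccard ≥ 0.9) on six
   deep libraries (60k molecules, 114–132k reads) with 20 of 200 peaks
   changing threefold.
5. **Small-instance oracles** — naive overlap vs an all-pairs checker;
   the NB exact test vs direct enumeration through an independent NB pmf
   (totals ≤ 30); Simes and BH vs their defining formulas; hypergeometric
   enrichment vs combinatorial enumeration on a 15-gene universe.
6. **End-to-end pipeline** — three simulated experiments (200 peaks, 20
   planted at 2.5-fold half up/half down, 3 vs 3 libraries of 30k molecules
   at unequal depths): shift → minimal → equalize → count → loess →
   moderated test keeps mean false-discovery proportion ≤ 2 × the nominal
   0.10 with high sensitivity.

Problem sizes were chosen so the whole validation completes in about a
minute on a single CPU while keeping Monte-Carlo error well below each
margin.

## Known limitations

* The moderated engine is a single common engine across all normalization
  routes; it is not a reimplementation of DESeq2 or edgeR's quasi-likelihood
  machinery, so DA counts on real data will not numerically match those
  tools even under matching normalization.
* The NB exact test uses a single common dispersion; strongly
  region-dependent dispersion will make it conservative in some regions and
  liberal in others.
* The complexity estimator assumes uniform sampling of molecules; strong
  amplification bias (GC, length) violates this and biases N downward.
* Loess/quantile normalization remove true global shifts by construction —
  the central interpretive caveat of the whole comparison, not an
  implementation defect.
* The fragment simulator draws reads i.i.d. from the molecule pool; real
  PCR duplicates cluster by cycle and are not exchangeable.
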