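# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the simulation-based tests demonstrate.

## Signals

**Read depth (RD).** The RD value of a bin is the arithmetic mean of
FORMAT/DP over the variant sites falling in it — not the sum — so the
signal estimates coverage independently of SNP density and is directly
comparable with alignment-derived binned depth. All variant records with a
usable depth contribute (het and hom-alt alike; DP is replaced by the AD
sum only when DP is absent or zero). Bins containing no variant are masked
and stay masked: they are excluded from, never interpolated into,
segmentation. Copy-number units divide by the genome-wide **median** of
unmasked autosomal bins and multiply by 2; the median (not the mean) keeps
the diploid baseline stable in cancer genomes where large CNAs would drag
a mean. Contigs whose basename is X/Y/M/MT are excluded from the baseline.

**GC correction.** Bins are stratified by GC fraction into classes of
width 1 percentage point; corrected(b) = raw(b) × (global mean)/(class
mean). Classes with fewer than 100 unmasked bins are pooled with the
nearest neighboring class until large enough, and bins with missing GC
keep their raw value. Class width and minimum occupancy are configurable;
by construction the correction preserves the global mean of unmasked bins.

**BAF likelihood.** Phase is unknown, so a het site with allele depths
(ad_ref, ad_alt) contributes the folded binomial
L(p) ∝ Binom(ad_alt; n, p) + Binom(ad_alt; n, 1−p) on the grid
p_k = k/(G−1), G = 101. Bin curves are per-site products computed in log
space (underflow-safe) and renormalized; the reported maximum-likelihood
BAF is folded into [0, ½], ties breaking toward ½. Sites with depth below
8 (configurable) are excluded from BAF; hom-alt sites never contribute.
Binomial log-pmfs are evaluated directly from `gammaln` plus outer
products, which is exact and orders of magnitude faster than per-site
distribution objects at whole-genome scale.

## RD caller (mean shift)

Per chromosome and per contiguous unmasked run, the shift at bin i is

    shift(i) = Σ_{0<|j−i|≤3h} (j−i) · exp(−(j−i)²/2h²) · exp(−(x_i−x_j)²/2σ²)

with σ the difference-based robust noise estimate
1.4826·median|Δx|/√2. Breakpoints fall strictly between shift(i) < 0 and
shift(i+1) > 0; the bandwidth sweep h = 2, 4, …, 128 accumulates
breakpoints, merging adjacent segments whose two-sample t-test (on the
original bin values) exceeds p = 0.01 before each next bandwidth, and
replacing values by segment means between sweeps. A perfectly constant run
yields exactly one segment (all shifts are zero; the inequality is
strict). Degenerate t-tests (combined n < 3 or zero pooled variance) merge
only when the means agree to machine precision, so noiseless steps
survive. Segments with |mean − 2| > 0.5 are called deletion/duplication
after a one-sample t-test against the global mean, Bonferroni-corrected
across segments; the cell fraction is |cn − 2| clamped to [0, 1] under a
single-copy assumption (larger amplifications keep their cn while f
saturates at 1). CNN-LOH is invisible to depth alone and never emitted by
this caller.

## 2D caller

### Merging

Starting from one segment per unmasked bin, the adjacent pair with the
smallest distance

    d(s,t) = (m_s − m_t)² / (σ²(1/n_s + 1/n_t)) − 2 ln BC(curve_s, curve_t)

merges first (leftmost on ties); a merged segment's curve is the
renormalized product of its constituents' curves. Three numerical
safeguards matter in practice:

* **Overlap smoothing.** BC is computed on curves convolved with a
  Gaussian of one grid step (sd 0.01). Product curves of long segments
  become narrower than the grid; without smoothing, two fragments of the
  same clonal duplication (true BAF 1/3, which lies between grid points)
  concentrate on adjacent grid points, their overlap collapses to zero,
  and they can never merge. Sub-grid overlap precision is an artifact of
  the discretization, so this loses no information.
* **Selection-aware stop.** Merging stops when the minimum distance
  exceeds d_max + 2 ln(k), k the chromosome's unmasked bin count and
  d_max = 9 the base threshold. The boundaries that survive inside a
  homogeneous region are the maxima of ~k null chi-square(1) contrasts,
  which grow like 2 ln k; a fixed threshold would strand spurious internal
  boundaries on long chromosomes and fragment genuine events.
* **Short-segment absorption.** After stopping, segments shorter than the
  minimum callable span are absorbed into their nearest-distance neighbor
  and merging resumes until stable. A single bin whose BAF fluctuated a
  few of its own widths away has near-zero overlap with a long neighbor's
  near-delta curve; left in place it splits one real event into two
  fragments separated by an uncallable sliver.

Bins with no usable het site participate with a flat (uninformative)
curve, so depth alone drives their assignment.

### Genotyping and significance

Each segment's (cn, baf) observation is fitted to

    deletion:    CN(f) = 2 − f,  BAF(f) = (1−f)/(2−f)
    duplication: CN(f) = 2 + f,  BAF(f) = 1/(2+f)
    cnn-LOH:     CN(f) = 2,      BAF(f) = (1−f)/2

minimizing ((cn−CN(f))/σ_m)² + ((baf−BAF(f))/σ_b)² over f on a 0.001 grid
followed by bounded local refinement; ties prefer smaller f (parsimony).
The segment is neutral when the best fit collapses to the f→0 boundary or
when the diploid model (CN 2, BAF ½) scores within 2.0 of the best model.

The uncertainties are deliberately conservative:

* σ_m² = σ²/n_bins + σ_baseline², with σ_baseline = 0.01 CN. The second
  term is the shared depth-calibration error of the global median; without
  it, long segments acquire arbitrarily confident means and a fraction of
  a percent of normalization error becomes "significant".
* σ_b is the curvature width of the segment's BAF curve at its peak,
  floored at 0.01 and at the **null-split scale** 0.35·R^(−1/4), R the
  segment's total het-site read count. The folded likelihood has vanishing
  Fisher information at p = ½, so under a diploid null its argmax drifts
  from ½ like R^(−1/4) (coefficient measured by simulation at 30–80×
  coverage) — much slower than the usual R^(−1/2). Without this floor,
  ordinary null "BAF splits" on long segments would be called as
  low-cell-fraction CNN-LOH.

Significance is a chi-square test (2 df) that (cn, baf) ≠ (2, ½),
Bonferroni-corrected across the number of **unmasked bins** — the number
of boundary hypotheses the agglomeration examined — rather than the final
segment count, because segment means are selected extremes and a
per-segment correction is anti-conservative (it produced false calls on
simulated flat diploid genomes). Calls additionally require at least
8 bins (`min_call_bins`): merging occasionally strands tiny segments at
joint RD+BAF noise extremes, which is precisely the statistic being
tested, so shorter calls are unreliable by construction.

### Parameter summary

| parameter | default | meaning |
|---|---|---|
| `bandwidths` | 2…128 bins | mean-shift sweep |
| `merge_alpha` | 0.01 | t-test threshold for mean-shift merging |
| `min_cn_shift` | 0.5 CN | minimum RD-only call amplitude |
| `alpha` | 0.05 | familywise significance level |
| `d_max` | 9.0 | base 2D merge threshold (plus 2 ln k) |
| `sigma_baseline` | 0.01 CN | shared depth-calibration uncertainty |
| `baf_sigma_floor` | 0.01 | minimum BAF uncertainty (one grid step) |
| `baf_split_coeff` | 0.35 | null-split scale coefficient (×R^(−1/4)) |
| `baf_overlap_smooth` | 0.01 | overlap-smoothing width |
| `min_call_bins` | 8 | minimum callable segment span |
| `f_grid_step` | 0.001 | cell-fraction search resolution |

## Simulator

The generator emulates a short-read WGS sample reduced to its variant
sites. Het positions arrive with exponential gaps (mean 1500 bp by
default, matching a typical human het density); one third of all variant
sites are hom-alt. Site depth is Poisson(coverage·CN/2) with the local
total copy number CN; an optional gamma-mixing knob adds overdispersion
for lower-quality data but is off by default. At het sites the alt allele
sits on either haplotype with probability ½ independently (unphased
realism), and ad_alt ~ Binomial(dp, q) with q the alt haplotype's read
fraction under the local event state — the same three formulas the caller
inverts. The alignment-like truth RD per bin is
Normal(μ, √(μ·read_length/bin_size)) truncated at zero with
μ = coverage·CN/2: reads tile a bin (effective sample ~bin_size/read_length)
whereas variants sample it sparsely, and that variance gap is exactly what
the VCF-vs-alignment comparison measures. Everything is reproducible from
the spec's single seed.

What the simulator does **not** model: mappability and reference-bias
artifacts, GC-coverage coupling (GC correction is exercised with synthetic
tables instead), sequencing error in genotype calls, overlapping or nested
events, and multi-subclone architectures. Passing tests therefore show the
method's statistical behavior under clean sampling noise, not robustness
to real-data artifacts.

## Concordance harness

Per-bin CN differences are summarized over bins unmasked in both tracks
(mean, SD, central quantiles). Call sets are matched one-to-one greedily
by decreasing overlap under a reciprocal-overlap criterion (default 50%,
the community convention); recall is the matched fraction of the reference
set and type concordance is reported separately over matched pairs, since
"matched" and "same type" are distinct questions. Fragmented hits count
once; the remainder stays unmatched, so recall never exceeds 1.

The reproduction script runs desk-scale versions of the comparison: five
neutral 50-Mb genomes at 30× for the CN-difference spread, ten 100-Mb
samples with ten clonal 1–9.5-Mb events each (types cycling
deletion/duplication/cnn-LOH, one per 10-Mb slot so events never overlap
and a majority of the genome stays at CN 2, which the median baseline
requires), and one 40-Mb sample at 80× carrying a 10-Mb duplication at 6%
cell fraction. These sizes keep every run under a minute while leaving
hundreds of bins per event.

## Known limitations

* Median normalization biases the baseline upward when a single event
  covers a large minority of the genome (the 25%-duplication sample shows
  ~0.01 CN inflation, i.e. the recovered 6% fraction reads ~5%); a
  mixture-model baseline would remove this.
* The RD caller's segmentation can split long events into adjacent
  same-type fragments; its calls are best consumed as covered regions.
  The 2D caller's absorption pass handles this, the mean-shift path keeps
  the classical behavior.
* CNN-LOH at low cell fraction (f ≲ 0.15) is intrinsically hard: its only
  signal is a BAF shift of f/2, which competes with the R^(−1/4) null
  split. The significance floor makes such calls conservative rather than
  wrong.
* The HDF5 layout (`pycnvlite-1`) is this package's own documented scheme;
  no byte-level compatibility with other tools' containers is claimed.
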