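# Methods

This note documents the models implemented in `ctfrac`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Electropherogram model and the mono-nucleosomal ratio

A trace is a pair of arrays (fragment size in bp, fluorescence), strictly
increasing in size, spanning at least 100–1000 bp, with internal alignment
markers at 25 and 1500 bp. The analysis regions are fixed half-open
intervals: mono-nucleosomal [100, 200) bp and total low-molecular-weight
[100, 1000) bp. Because both markers lie outside both regions, marker peaks
are excluded by construction rather than by peak detection — simpler and
exactly reproducible. Under trapezoidal integration of a piecewise-linear
signal the open/closed distinction at the endpoints carries zero measure,
so region areas are additive over adjacent regions to rounding error.

* **Baseline**: a constant equal to the 5th percentile of the off-peak
  signal (marker neighbourhoods excluded) is subtracted and negatives are
  clipped. The instrument vendor's smoothing/baseline algorithm is
  proprietary; a constant-percentile baseline keeps region areas invariant
  (to ~1%) under constant offsets, which is the property the ratio needs.
* **Integration**: trapezoidal rule with linear interpolation at region
  edges. The independent oracle in the tests is a fine-grid Riemann sum,
  and for Gaussian peaks the closed form A·σ·√(2π).
* **Ratio and call**: r = area[100,200)/area[100,1000); r ≥ 0.1 → tumor,
  with the tie at exactly 0.1 going to tumor (10% content is treated as
  sufficient). A zero total area yields an `indeterminate` flag rather than
  an exception so cohort runs survive a degenerate file. Whether the ratio
  is computed on raw area or calibrated mass is immaterial: both regions
  share one calibration constant, so the ratio is identical.
* **Mass**: mass_ng = area × one calibration constant (ng per unit area).
  The simulator fixes this constant at 1, so simulated window masses are
  read back directly.
* **Qubit discrepancy flag**: fluorometric quantification sees
  double-stranded DNA of any size; the trace window stops at 1000 bp.
  A fold ratio qubit/max(window mass, ε) ≥ 5 flags probable
  high-molecular-weight DNA (necrotic in origin rather than apoptotic).
  The fold threshold of 5 is a convention; the published discordant cases
  show fold differences well above 10.

## Synthetic trace generator

The generator writes a Gaussian ladder on a 1 bp grid over 15–1700 bp:
peaks at multiples of the nucleosome unit (167 bp, the center of the
100–200 bp mono-nucleosomal band), common peak width σ = 10 bp, with
mixture weights

* tumor compartment: f · decay^(k−1) for multimer k ≤ 3 (tumor ladders are
  dominated by the mono-nucleosomal peak and fade by the tri-nucleosome),
  decay = 0.5;
* normal compartment: (1−f) · growth^(k−1) for k ≤ 6 (normal cfDNA shows
  multimer peaks of increasing quantity out to the penta/hexa-nucleosome,
  ~600–1000 bp), growth = 1.3.

The noise-free ladder is scaled so its integral over 100–1000 bp equals
`total_mass` (default 24.2 ng, the cohort median per ml of plasma), then
marker peaks, an optional high-molecular-weight Gaussian hump centred at
1300 bp (invisible to the analysis window but counted in simulated Qubit
totals — this reproduces the discordance mechanism), and optional additive
Gaussian noise are added. With these defaults the expected ratio r(f) is
strictly increasing and crosses the 0.1 decision threshold near f ≈ 0.07,
so the ratio rule recovers the generator's labelling convention (tumor iff
f ≥ 0.1) exactly for any f at least 0.05 away from 0.1 in the noise-free
case. The 167/0.5/1.3/σ=10 constants are generator conventions chosen once
to reproduce the qualitative ladder shapes; they are not fitted to data.

Cohort simulation draws tumor fractions per timepoint — diagnosis
f ~ U(0.3, 0.9), relapse f ~ U(0, 0.3), reflecting that relapse samples
carry less ctDNA per ml of blood — and total in-window mass from one
log-normal (median 24.2 ng, log-sd 0.4) shared by both arms, so only the
mono-nucleosomal quantity differs systematically between arms (the pattern
the diagnosis-vs-relapse tests are designed to detect: mono significant,
totals not). High-molecular-weight DNA is added with probability 0.1 at
U(100, 900) ng. Paired patients share ids and tumor-genome event sets
across timepoints.

## Methylome model

Input is a post-calling per-CpG table (chrom, 0-based position, methylated
count, total informative count from both strands, Phred quality), as
produced by a whole-methylome caller after alignment. Alignment-level steps
(MAPQ filtering, duplicate removal, end trimming) are preconditions of the
input, not operations of this package.

* **Filtering**: keep sites with Phred ≥ 20 (genotype error ≤ 1%), total
  ≥ 6 informative reads, and total ≤ 500× (sites above 500× are dominated
  by centromeric/telomeric repeats). Idempotent; retained/discarded counts
  are attached to the result.
* **Binning**: 1 kb half-open bins, bedGraph coordinate convention. The bin
  level is pooled counts Σmeth/Σtotal (coverage-weighted), which is robust
  at low CpG density; bins with no retained CpG are omitted. "Averaged over
  1 kb bins" does not by itself prescribe weighting — the pooled-count
  choice is documented here as the package's convention.
* **Blocks**: a hypomethylation block is a maximal run of ≥ 10 consecutive
  emitted bins with beta < 0.5; a missing bin breaks the run. "Extending
  over many kb" is operationalized as ≥ 10 kb; both the 0.5 level and the
  minimum length are configurable.
* **Classification**: tumor iff (≥ 1 block) and (minimum bin beta ≤ 0.25);
  normal iff (no block) and (≥ 90% of bins above 0.7, operationalizing
  "predominantly above 0.7"); otherwise indeterminate — the two published
  rules do not partition all possible profiles, and a three-way label keeps
  the indeterminate middle out of concordance denominators. Whether the
  0.25 drop refers to single-bin minima or block means is ambiguous in the
  source description; it is implemented as the single-bin minimum combined
  with the block requirement, and the threshold is exposed for sensitivity
  analysis. The reported waviness range is the 5th–95th percentile of bin
  betas.

### Synthetic methylome

Observed methylation at a site is the linear mixture
β_obs = (1−f)·β_normal(site) + f·β_tumor(site); coverage is Poisson (mean
30), methylated counts Binomial, Phred scores ~ N(36, 6) clipped to [2, 60]
(so a realistic ~0.4% of calls fail the Phred filter). The default genome
is 4 chromosomes × 300 × 1 kb bins with ~8 CpGs per bin. Three territories
are planted:

* background: β_normal = 0.85, β_tumor = 0.75 (tumors are globally slightly
  hypomethylated);
* **blocks** (two 40-bin regions): β_tumor = 0.15 against a normal-plasma
  level of 0.52 — tumor hypomethylation blocks arise preferentially in
  partially-methylated-domain-like territory whose normal level is already
  intermediate, which is what lets the observed mixture dip below the 0.5
  block threshold at moderate tumor fractions (f ≳ 0.15) rather than only
  near purity;
* **deep cores** (two 5-bin regions): β_tumor = 0, β_normal = 0.32 — short,
  deeply unmethylated regions that produce the sharp single-bin drops to
  ≤ 0.25 characteristic of ctDNA-positive profiles. They are deliberately
  shorter than the 10-bin block minimum so a pure-normal sample never
  acquires a block, and small enough (≈ 0.8% of bins) that together with
  the block territory (≈ 7.5%) a pure-normal profile still keeps > 90% of
  bins above 0.7 and classifies as normal.

These territory levels (0.52, 0.32) are generator conventions chosen once
so that the generator reproduces the qualitative phenomenology the
classifier was designed against — sharp ≤ 0.25 drops in ctDNA-containing
samples at realistic tumor fractions, and a 0.75–1 waviness profile in
normal cfDNA — not values fitted to any dataset. A consequence worth
stating: under a genome-wide fully-methylated normal background the
single-bin-minimum rule would mathematically require f ≥ 0.86 to reach
0.25, so the classifier's sensitivity at moderate f depends on such
low-normal territory existing; this is a model assumption, not a finding.

## Copy-number model

Depth is consumed as a pre-binned BED-like table; the package neither reads
alignments nor corrects GC/mappability (the synthetic data carries no GC
bias; for real data an upstream correction should precede this module).
For real genomes a 100 kb bin size is a reasonable default; the synthetic
mini-genome uses 1 Mb bins.

* **Normalization**: log2(depth / median autosomal depth); zero-depth bins
  are masked; sex chromosomes are excluded from the median.
* **Segmentation**: exact per-chromosome dynamic programming minimizing
  within-segment squared error plus a per-segment penalty (O(n²), intended
  for desk-scale bin counts). The default penalty is 4·σ̂²·log n with σ̂
  estimated from the median absolute successive difference — twice the
  classical BIC rate, which keeps isolated noisy bins from becoming
  singleton segments while arm-scale steps remain easily detectable. The
  oracle in the tests is exhaustive enumeration of breakpoint sets on small
  instances.
* **Calling**: gain ≥ +0.3, loss ≤ −0.3 in log2 (standard conventions; the
  source analysis does not state its thresholds). MYCN amplification
  requires log2 ≥ 1.0 at the MYCN window, chosen so that clinically
  amplified loci (CN ≳ 8 at moderate f) trigger but simple gains do not.
  11q deletion requires ≥ 25% of the covered q arm in loss segments. Other
  non-neutral segments of ≥ 5 bins count as additional SCAs; the size floor
  keeps noise bins out of the SCA count. Windows default to GRCh38
  coordinates (MYCN at chr2 ≈ 15.9–16.1 Mb; 11q from the centromere) and
  are supplied explicitly for the synthetic genome.
* **Coverage breadth**: length-weighted fraction of bins at ≥ 10/15/20×,
  non-increasing in the threshold by construction.
* **Tumor fraction**: f̂ = (2·2^log2 − 2)/(CN − 2), clipped to [0, 1],
  undefined at CN = 2. Two routes are provided: from the segment overlapping
  a window (appropriate when segmentation has isolated the event, i.e. at
  high signal-to-noise), and from the per-bin mean inside a *known* aberrant
  window, re-centered on the out-of-window mean. The bin route is preferred
  for recovery measurement because at per-bin SNR near 1 the segmenter may
  legitimately not isolate the event, which would bias a segment-mean
  estimate toward 0; re-centering cancels the shift that the aberration
  itself induces in the global normalization median.

### Synthetic depth

Expected bin depth is mean_depth · ((1−f)·2 + f·CN)/2 with mean_depth = 30
(typical whole-methylome coverage for this application) and gamma-Poisson
counts at variance/mean = 1.5 (modest overdispersion beyond Poisson;
exposed as a parameter, not fitted). The mini-genome scales real chromosome
proportions to 1 Mb bins: chr1 120, chr2 120, chr11 100, chr17 80 bins.
The event menu is MYCN-like amplification (chr2 bins 14–18, CN 20), 11q-like
arm deletion (chr11 bins 30–100, CN 1) and 17q-like gain (chr17 bins 30–80,
CN 3); every simulated tumor genome carries at least one event, shared
between a patient's diagnosis and relapse samples.

## Cohort integration

* **Sequencing label**: tumor iff any SCA or a tumor methylome; normal iff
  no SCA and a normal methylome; indeterminate otherwise.
* **Concordance**: only samples with determinate labels on both sides are
  evaluable (mirroring a cohort restricted to samples with both CNV and
  methylation profiles); the success rate is reported in percent to one
  decimal; the failure table lists sample, ratio, both labels, Qubit total
  and the discrepancy flag.
* **PCA/clustering**: samples × common emitted bins (intersection — how the
  original analysis handled missing bins is unstated, so intersection is
  the convention here), top 10,000 bins by variance, column-centered, PCA,
  then k-means (k = 2, fixed seed) on the first two components. The cluster
  richer in methylome-tumor calls is named tumor, which makes the naming
  invariant to sample order and to component sign flips.
* **Diagnosis vs relapse**: two-tailed Student t-tests with pooled variance
  (classic Student rather than Welch, matching the stated test; Welch is a
  one-line change via scipy), unpaired on total and mono-nucleosomal mass,
  paired on complete diagnosis/relapse pairs. Degenerate zero-variance
  inputs return t = 0, p = 1 instead of NaN. No multiple-testing correction
  is applied across the three tests (none was applied in the source
  analysis).
* **Descriptives**: counts/percentages by stage, sex and relapse status and
  medians of age and time to relapse, from a one-row-per-patient table.

## Problem sizes and determinism

All simulation-based checks run at desk scale: methylome cohorts of 40
samples × ~9,600 CpGs, depth tables of 420 × 1 Mb bins, 500-replicate null
calibrations. Every generator is deterministic under a fixed seed, and the
acceptance script derives all sub-seeds from a single `--seed`.

## What passing tests do and do not show

The generators implement exactly the linear mixture assumptions the
analysis methods invert, with clean Gaussian/Poisson/Binomial noise. Real
traces carry instrument smoothing, calibration drift and overlapping peak
shapes; real methylomes carry GC- and mappability-correlated coverage,
incomplete conversion and biological variation between patients; real
depth profiles carry wave artefacts. Passing recovery tests therefore
demonstrates internal consistency of the pipeline under its own model —
not clinical performance. The published cohort-level numbers that depend on
the original patient data (the 95.1% concordance on real electropherograms,
the specific significance levels) are reproduced here as arithmetic on the
published tables plus qualitative pattern recovery on simulated cohorts.

## Known limitations

* No peak deconvolution: overlapping nucleosomal peaks are integrated, not
  fitted; the regions are fixed.
* No GC/mappability correction and no replication-timing wave removal in
  the CNV module.
* The segmentation DP is O(n²) per chromosome — fine for ≤ a few thousand
  bins, not for 10 kb-bin whole genomes.
* The tumor-fraction estimator assumes one clonal CN state per window and
  a diploid background; subclonality and ploidy shifts are not modelled.
* The methylome classifier's thresholds (0.25, 0.5, 0.7, 10 bins, 90%) are
  operational conventions, exposed as parameters; they are not calibrated
  against clinical outcomes.
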