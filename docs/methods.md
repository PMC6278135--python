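# Methods

## The classification problem

Posterior fossa ependymoma (PF-EPN) splits into two methylation subgroups,
PFA and PFB. PFA tumors are globally hypermethylated at CpG islands; PFB
tumors are not. The package implements four routes to the subgroup call,
from most data-hungry to most clinic-friendly: genome-wide clustering of
array beta values, copy-number evidence derived from the same array's
intensity channels, a three-gene pyrosequencing panel with per-gene
methylation thresholds, and an immunohistochemical H3K27me3 rule. A
synthetic-cohort generator supplies inputs with known ground truth for all
four.

## Probe selection

A beta value is the methylated fraction of a probe's signal, in [0, 1].
Three selection rules operate on a probes × samples beta matrix plus a probe
annotation (chromosome, position, arm, CpG-island flag):

- *Autosomal filter*: drop probes on chrX/chrY. Order-preserving; unknown
  chromosome labels are an error, not silently kept.
- *High-SD island probes*: CpG-island probes whose across-sample standard
  deviation strictly exceeds a threshold (default 0.25). The SD uses the
  unbiased n−1 estimator — the convention in array QC; means and SDs ignore
  missing values pairwise, and probes with fewer than two observations are
  dropped with a logged count rather than imputed. The SD is computed over
  exactly the samples passed in; subsetting to a tumor group is the
  caller's responsibility, since the relevant sample set differs between
  analyses.
- *Subgroup markers*: probes with mean beta ≥ 0.5 over PFA samples and
  ≤ 0.2 over PFB samples, both bounds inclusive.

Both the SD threshold and the marker mean bounds are monotone: tightening
them can only shrink the selected set, a property the test suite asserts.

## Clustering

Samples are clustered on the probe-restricted matrix by agglomerative
hierarchical clustering with Ward linkage on Euclidean distance, and the
tree is cut at k = 2. Ward/Euclidean is the common choice for beta-value
heatmaps; both are recorded in the assignment provenance and configurable.
Missing beta values are imputed by the probe mean before distance
computation (logged). The cluster with the higher mean beta over the
clustering probes is labeled PFA; exactly equal means raise an
unresolved-label error so the caller must decide — silently picking one
orientation would be worse. Labels are invariant to sample and probe order.

## Copy number from array intensities

The total (methylated + unmethylated) signal of a probe tracks local copy
number. "Summed value" means that per-probe total — the standard reading.

- *Probe QC* against ≥ 2 normal references: per probe, the across-control
  median summed signal and its MAD. Probes are retained when the median
  lies inside the [0.05, 0.95] quantile band over probes and the MAD is at
  or below the 0.8 quantile over probes. Quantiles use linear interpolation
  with inclusive bounds. The MAD is computed on summed values, consistent
  with the quantile filter it accompanies.
- *Profile*: per retained probe, log2((sample total + 1)/(control median
  total + 1)); the offset of 1 intensity unit keeps the ratio finite at
  zero signal and is negligible at realistic intensities (thousands of
  units). The profile is then centered by subtracting its own median, which
  makes it exactly invariant to global intensity scaling of the sample.
- *Arm calls*: an arm with ≥ 20 probes is called gain/loss when its median
  log2 ratio is ≥ +0.15 / ≤ −0.15, else neutral; fewer probes yield an
  explicit insufficient-probes call. The ±0.15 / 20-probe choice is a
  pipeline decision (the underlying study reports 1q gain without numeric
  criteria); both are configurable and logged in the run report.
- *Instability flag*: along a chromosome in position order, log2 ratios are
  median-smoothed (centered window of 5 probes), discretized to
  {−1, 0, +1} at ±0.3, and the number of state transitions counted; ≥ 10
  transitions flags the chromosome as unstable. This is a deliberate proxy
  for the oscillating profiles of chromothripsis, not a full chromothripsis
  caller (no breakpoint clustering, no two-state test); arm medians plus
  this flag cover the two copy-number outputs the analysis needs, so no
  segmentation algorithm is included.

## The three-gene classifier

Per-gene percent methylation in each subgroup is modeled as
100 × Beta(α, β). Fitting clips values to [10⁻³, 1 − 10⁻³] (configurable)
so boundary observations keep finite log-likelihood, then maximizes the
likelihood with method-of-moments initialization; identical values after
clipping are a degenerate-fit error. The per-gene threshold is the point
x\* where the two fitted densities are equal: the log-density difference is
scanned on a 0.01-percentage-point grid and each sign change is refined by
bisection. When several crossings exist, the one inside the inter-mean
interval is used; zero usable crossings raise an error. Below x\* the PFB
density dominates. For well-separated class densities the threshold falls
strictly between the two class means; this is not a theorem for arbitrary
beta pairs (mildly separated or non-unimodal densities can cross outside
the inter-mean interval), so the general contract is the defining one:
equal densities at the threshold, PFB dominating below.

A gene votes PFB when its value is strictly below its threshold — at
equality the case counts toward PFA, the conservative direction given that
PFB specificity is the selection objective. Three candidate rules combine
votes: *all* (3/3), *majority* (≥ 2/3), *any* (≥ 1/3); their PFB-call sets
nest, so specificity is monotone from *any* up to *all*. Rule selection
maximizes, lexicographically: the minimum PFB specificity over training and
validation, then the specificity sum, then conservativeness
(all ≻ majority ≻ any). Sensitivity and specificity are computed with PFB
as the positive class; an undefined rate (empty denominator) is reported as
absent, never as 0.

The stratified 1:2 split draws round(n/3) cases per class (half away from
zero) without replacement; membership depends only on the sorted sample ids
and the seed, so input order is irrelevant. With 90 PFA and 33 PFB this
yields exactly 41 training (30/11) and 82 validation (60/22) cases. A class
absent from either partition is an error unless explicitly allowed.

## The IHC rule

Strictly more than 80 % H3K27me3-labeled tumor nuclei → intact expression →
PFB; 0–80 % → reduced → PFA (the boundary belongs to reduced, per the
disjoint category definitions); a failed endothelial internal control makes
the slide not evaluable, which propagates rather than defaulting to either
class. Staining intensity is deliberately ignored; the rule consumes a
single percent-labeled scalar per case.

## The synthetic cohort

The generator's defaults are the package's study conditions: 45 PFA, 15 PFB
and 6 normal references; 2000 probes (a deliberately scaled-down array that
keeps every probe class represented — 100 sex-chromosome probes, 400 CpG
islands of which 40 are planted subgroup markers, and ~43 probes per
autosomal arm dealt round-robin across all 44 arms). Marker probes draw
from Beta(8, 6) in PFA (mean 0.571) and Beta(1, 15) in PFB (mean 0.0625);
background probes from Beta(5, 5) for everyone — so marker means straddle
the 0.5/0.2 selection bounds while background probes satisfy neither.
Gene-panel percentages use the same well-separated Beta(8, 6)/Beta(1, 15)
pair for each gene. IHC percentages are uniform mixtures mirroring the
observed categories: PFA = 0.38·U(0, 5) + 0.62·U(5, 50) (never above 50, so
IHC specificity for PFB is structurally 1); PFB = 0.867·U(81, 100) +
0.133·U(10, 60). 30 % of PFA samples carry a 1q gain.

Intensities follow a minimal multiplicative model: per probe and sample the
total signal is LogNormal(log(2000 · 2^s), 0.1), where s = 0.5 on 1q probes
of gained samples and 0 elsewhere; the methylated channel is the beta value
times the total, so beta = meth/(meth + unmeth) exactly. Ages are
log-normal with medians 4 y (PFA) and 30 y (PFB) — clinical flavor only.

One top-level seed feeds a `SeedSequence`; each data block (sample sheet,
betas, intensities, gene panel, IHC) uses its own spawned stream, so adding
a block never perturbs earlier draws, and identical config + seed gives a
bitwise-identical cohort.

What the generator does **not** emulate: raw IDAT files, probe
cross-hybridization, batch/FFPE effects, within-assay CpG heterogeneity,
correlated probes within an island, or intermediate/ambiguous cases.
Passing tests therefore demonstrate that the implementation recovers
planted structure under the stated statistical model — not that the
thresholds learned here transfer to clinical specimens.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation, inclusive bounds (pandas default).
- SD: ddof = 1 throughout.
- Split rounding: half away from zero per class.
- Beta-fit clipping: 10⁻³ on the unit scale, configurable.
- Threshold grid: 10⁻⁴ on [0, 1] (0.01 percentage points), bisection
  refinement; validated in tests against an independent exhaustive scan.
- Equal cluster means, identical fit values, missing classes, k > n,
  out-of-range values: all explicit errors naming the offending input, not
  silent fallbacks.

## Sampling variability of the learned thresholds

With only 11 PFB training cases, the likelihood-ratio threshold has an
intrinsic sampling SD of roughly 4 percentage points around the analytic
crossover of the generating densities (≈ 26.5 % for the default
Beta(8, 6)/Beta(1, 15) pair) — a property of any consistent estimator at
this n, not of the fitting method. The test suite therefore checks that the
threshold estimator is unbiased (mean over 20 seeded replicates within 3
percentage points of the analytic crossover) rather than demanding each
replicate land that close. Rule *selection* is far more stable than the
thresholds themselves: the all-genes rule attains specificity 1.0 on both
partitions across seeds because the class distributions barely overlap.

## Problem sizes

Tests and the acceptance script run cohorts of 60–123 tumor samples on
2000–8800 probes (200 probes per arm where arm-level recovery is measured),
sizes chosen so the planted effects are comfortably detectable while the
whole suite stays fast.
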