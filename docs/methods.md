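# Methods

This note documents the models, procedures, defaults, and numerical
choices behind `meicoc`, and what the simulation-based validation does and
does not establish.

## The point-process model of crossover-marker foci

Foci on one chromosome axis are modeled as a **stationary gamma-renewal
process** on the interval [0, L]: inter-focus gaps are iid Gamma with shape
ν and mean µ (scale µ/ν), and the first focus is drawn from the equilibrium
forward-recurrence distribution — sampled as U·G\* with G\* ~ Gamma(ν+1,
µ/ν), the length-biased gap, and U uniform. This makes the process
statistically homogeneous along the axis; placing the first gap at the
origin instead would thin foci near the marked end and distort CoC curves
there. At ν = 1 the two conventions coincide and the process is homogeneous
Poisson: focus counts are Poisson(L/µ) and the zero-focus frequency is
e^{−L/µ}, which the tests use as an analytic oracle. For any ν the
stationary renewal theorem fixes the expected count at L/µ, a property the
suite checks by simulation.

Axis lengths are lognormal with user-set mean and coefficient of variation
(positive support and CV-parameterization; the distributional family is a
modeling choice, not a claim about real spreads). Chromosomes within a
nucleus share the nucleus' axis length. One root seed spawns one child RNG
stream per nucleus (`numpy` `SeedSequence`), so identical configurations
are bit-reproducible and subsets of nuclei can be regenerated exactly.
Obligatory-crossover enforcement (resampling until ≥ 1 focus) exists as an
off-by-default flag, because the analyses treat the zero-focus frequency as
a readout rather than a constraint.

### Default study conditions

The validation experiments (`meicoc.experiments`) emulate a pooled
chromosome-XV-scale focus-mapping dataset: axis mean 3 µm (CV 15%), mean
focus spacing 0.5 µm (≈ 6 foci per axis), cohorts of 2000 chromosomes,
30 intervals. These sizes keep every check well inside interactive
runtimes while leaving counting errors small; they are stated here once
and reused by the analysis drivers, the test suite, and
`scripts/acceptance.py`.

## CoC curves

Positions are normalized per chromosome and binned into n half-open
intervals [k/n, (k+1)/n), with a focus at exactly the axis end assigned to
the last bin (the half-open convention would otherwise drop it; the
procedure's verbal description does not resolve this). Interval presence
is per chromosome (two foci in one bin count once). For each unordered
pair i &lt; j: ObsDCO = frequency of chromosomes with foci in both bins,
PredDCO = f_i·f_j, CoC = Obs/Pred. Pairs with PredDCO = 0 are flagged
undefined and excluded from curve averaging, with counts logged. Distances
are exact multiples of 1/n (midpoint-to-midpoint), so grouping by distance
needs no tolerance. When pairs from replicate experiments are pooled, the
curve reports the mean and SE across per-replicate means.

For hypothesis checks the package also provides a counting-error SE per
distance (`coc_curve_binomial_se`): each pair's CoC variance is the
first-order delta-method propagation of the binomial errors of the three
frequencies in Obs/(f_i·f_j) treated as independent, and pairs combine as
independent within a distance. Dropping the (negative, under the
no-interference null) covariances makes the SE deliberately conservative —
Monte Carlo calibration at the default study conditions shows the true
spread of the per-distance mean is 85–95% of this SE — and, unlike an SE
across pairs or replicates, it is defined even at the largest distance,
which only one pair represents. The null-behavior check "per-distance mean
within 3 SE of 1" is a 29-way simultaneous test; the conservatism is what
keeps its familywise false-alarm rate low.

## Gamma interference fit

Inter-adjacent distances are consecutive focus gaps within a chromosome
(fewer than two foci contribute nothing), by default normalized to the
chromosome's own axis length to match the CoC normalization; raw µm is an
option. Note the two conventions are not equivalent under axis-length
variability: dividing by each axis' own length mixes scales and attenuates
large shapes (≈ −17% at ν = 10 with 15% CV), while µm-unit gaps follow the
generating gap law regardless of L. Both are therefore exposed, and the
parameter-recovery validation uses a fixed axis length where the two
coincide.

The two-parameter MLE solves the profile score equation
ln k − ψ(k) = ln(mean) − mean(ln) by safeguarded Newton iteration
(method-of-moments-style closed form as the start, step-halving to keep
k &gt; 0, tolerance 1e−10 on the score; the left side is monotone so the
root is unique). Degenerate inputs raise: no gaps, or all gaps identical
(the sufficient statistic hits its boundary and the shape diverges). Fits
on fewer than 30 gaps succeed but warn that the CI will be wide. The
solver is cross-checked against an independent library implementation and
a brute-force likelihood grid in the tests.

### Edge censoring and the bootstrap CI

A gap is observed only if both of its foci fall inside the axis, which
under-samples long gaps; the plain MLE applied to observed gaps is
therefore biased upward, and the bias grows as the axis holds fewer foci
(measured by `analysis/03_gamma_interference.py`: ≈ +10% at 3 foci/axis,
≈ +3% at 6, &lt; 1% at 15, for ν = 1). At cohort sizes of 2000 chromosomes
this bias exceeds the MLE's sampling SE, so an iid parametric-bootstrap
percentile interval — which is centered on the biased estimate — cannot
cover the true shape. Two CI methods are provided:

* `percentile` (default): iid resamples from the fitted gamma, percentile
  interval, 1000 resamples. Appropriate when gaps are effectively
  uncensored (long axes, many foci per axis).
* `renewal`: each resample resimulates the fitted stationary renewal
  process on the observed per-chromosome windows and refits the observed
  gaps, so the bootstrap distribution carries the same censoring bias as
  the estimate; the basic (reverse-percentile) interval then cancels the
  bias to first order. The resimulation uses the rate-based spacing
  estimate µ̂ = Σ windows / Σ foci — unbiased under stationarity, unlike
  the censored mean gap — so the bootstrap world has the right focus
  density. The interval is clamped to contain the point estimate.

The recovery validation (100 replicate cohorts per true shape ν ∈ {1, 2,
5}, 300 resamples each) recovers the shape within ~3% of truth and the
renewal CI covers the truth in ≈ 95% of replicates; with the iid
percentile interval coverage collapses below 60% at ν = 1, which is why
the renewal method is the one used for validation. Bootstrap size 300 in
the validation (vs the 1000-resample default) trades tail resolution for
runtime across 300 replicate fits.

## Focus/axis metrics and tests

Per-nucleus summaries sum focus counts and axis lengths over chromosomes
(duplicate chromosome records are an error) and flag nuclei containing a
zero-focus chromosome. The closed-form helpers return exact, unrounded
values — the multiplicative independence expectation f_a·f_b for a double
mutant, conditional fractions as percentages, overlap percentages —
with display rounding left to callers (two decimals for overlap fractions,
integers for whole-culture percentages).

The t-test defaults to Welch (unequal variances), with pooled-variance
Student as an option; the two-proportion z-test uses the pooled variance;
both are two-sided. Degenerate cases are set by convention and flagged:
zero variance in both samples with equal means gives p = 1, and a pooled
proportion of 0 or 1 leaves the z statistic undefined. Stars follow
p ≥ 0.05 n.s. / &lt; 0.05 * / &lt; 0.01 ** / &lt; 0.001 ***.

Tetrad scoring: exactly 2 yellow + 2 red fluorescent spores is faithful;
any other color multiset with ≥ 1 fluorescent spore is one missegregation
event (no MI/MII sub-typing); all-dark tetrads are excluded from the
denominator before the frequency is formed.

## Immunofluorescence quantification

"The level at which the profile flattens" is operationalized as: smooth
the line profile with a moving average (window 3 by default; sums are
divided after convolution so exactly flat profiles stay exact), find the
maximal runs from each end over which the absolute discrete slope stays
below `slope_frac` (default 2%) of the smoothed peak-minus-minimum range,
require at least 3 pixels per tail, and average the smoothed intensities
over both tails. A profile flat end to end returns its mean; a profile
with no qualifying tail (e.g. a monotone ramp) raises with advice to draw
a longer line. Per nucleus, the background is the mean of exactly three
profile backgrounds. Integrated intensity counts masked pixels strictly
above background (ties excluded), and corrected = raw − background ×
n_above. Line sampling is nearest-pixel by default (linear interpolation
optional); line placement is supplied by the user or fixture, not
automated.

The synthetic validation scene is a 96×96 frame: 16 Gaussian foci
(amplitude 500, σ 3 px) inside a disk-masked nucleus on background 100
with pixel noise SD 8 (1.6% of amplitude), plus three isolated
reference fragments whose ±14 px profile lines feed the background
estimate; the scene's quantification uses window-5 smoothing and a 3%
slope tolerance, which makes tail detection essentially deterministic at
this noise level. Recovery of the recorded ground-truth signal is within
~3%. The dominant systematic is noise rectification — background pixels
whose noise puts them just above threshold each contribute ≈ 0.4·SD — so
accuracy depends on the mask area relative to total spot signal; the
procedure shares this property with the manual protocol it implements.

## Pipeline

`meicoc run config.yaml` executes stages (simulate, simulate_tetrads, coc,
gamma, metrics, missegregation) in fixed dependency order from a YAML
config, writes numeric TSVs as the canonical outputs, and records a
manifest (config snapshot, seeds, SHA-256 digests of inputs and outputs,
package version). Reruns of the same config are byte-identical, which the
tests assert. Plots are deliberately not part of the canonical outputs.

## What the synthetic validation does not show

The generator reproduces the statistical skeleton the analyses assume —
renewal spacing, proportional count scaling, binomial tetrad patterns,
Gaussian spot photometry — but not real cytology: no focus-detection
errors, no axis-tracing uncertainty, no chromatin-density background
structure, no optical blur correlated between channels, no biological
obligatory-crossover enforcement. Passing validation therefore
demonstrates correctness of the estimators under their stated model, not
robustness to measurement artifacts. The CoC pair machinery treats
same-interval double foci as single presences; sub-interval interference
is invisible at the 30-interval resolution.
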