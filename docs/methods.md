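# Methods

This note documents the models and procedures implemented in `palaeoveg`,
the defaults chosen where the methodological literature leaves the choice
open, and what the synthetic-data tests do and do not demonstrate about
real records.

## Data model and chronology

A `PollenCore` is an ordered stratigraphic table: depths strictly increase
downcore, counts are non-negative integers, and each sample carries the
exotic-marker bookkeeping (marker grains added per tablet: 20,848; marker
grains counted; processed volume in cm³) needed for concentration
estimates. Percentages use the **terrestrial pollen sum**: aquatics and
spores are carried but excluded from the denominator, and their
percentages are expressed relative to the same terrestrial sum — the
standard palynological convention, so terrestrial percentages close to
100 % while non-terrestrial ones do not enter the closure.

Age–depth models are piecewise linear between user-supplied tie points
(ages in ka BP increasing into the past). Tie points are data: orbital
tuning — the selection of tie points against a target curve — is a manual
interpretive step and is deliberately not automated. A depositional hiatus
is encoded as two tie points at the same depth with different ages; a
sample lying exactly at that depth takes the younger age, and the
sedimentation rate inside a hiatus is zero, which makes influx *undefined*
(NaN), never zero. Extrapolation beyond the tie-point range is refused.

The arboreal-pollen percentage (AP%) denominator is configurable: by
default AP% sums the `tree` group only; shrubs can be added by the caller
(whether shrub pollen counts as arboreal varies between studies, so the
package exposes the choice rather than hard-coding one).

## Biomization

Affinity scores follow the classical square-root-above-threshold form:
score(b) = Σₖ √max(0, pₖ − θ) over every taxon k linked to biome b through
at least one of its PFTs, each taxon counted once per biome regardless of
how many of that biome's PFTs contain it. θ defaults to 0.5 %, giving a
dead zone in which trace occurrences contribute nothing. Ties on the top
score go to the biome defined by fewer PFTs; any residual tie is broken
alphabetically so results are deterministic. Samples in which every biome
scores zero are labelled `unclassified`, logged, and excluded from
interval-proportion denominators.

Megabiome merging groups all forest biomes into *forest*; temperate
grassland and temperate xerophytic shrubland into *steppe*; the shrubby
tundra biomes into *shrubland*; graminoid/forb and cushion-forb tundra
into *meadow*. Samples whose winning biome is *desert* are relabelled
*desert-steppe*: in the alpine meadow–forest ecotone such spectra carry
abundant Cyperaceae/Poaceae rather than true desert indicators.

The shipped scheme (`schemes/zoige_default.yaml`) is an original
reconstruction assembled from assignments common in the Chinese
biomization literature. It is marked as such in the file and is **not**
any study's verbatim assignment table; users reconstructing real records
should supply their own scheme file.

A low-influx screen flags samples whose total influx falls below a
configurable quantile (default 5 %) for sensitivity re-analysis — spectra
deposited under very low influx can be dominated by long-distance
transport. The screen never alters assignments.

## Diversity

Rarefied richness is Hurlbert's E(Sₙ), evaluated with log-gamma arithmetic
because C(N, 300) overflows naive binomials; n > N raises (no
extrapolation). Pielou's J = H′/ln S is undefined for single-taxon samples
and returned as missing with a warning. Group-wise richness (tree vs
shrub/herb, to control for vegetation openness) standardizes within-group:
the default per-group constant is the minimum positive group total across
samples capped at 300, and samples whose group total falls below the
constant get missing values rather than extrapolated ones.

## Resilience

All residence/recovery logic runs forward in calendar time (old → young).
A transition boundary sits at the age midpoint of the two samples
bracketing a label change, so episodes tile the record exactly; the first
and last episodes are bounded by the first/last sample ages and flagged
edge-censored. Recovery is the elapsed time from the end of a maximal run
to the next sample with the same label; if the megabiome never returns
the interval is censored ("not recovering"). Means exclude censored
entries by default — a censored recovery has unbounded duration and would
bias any average — with an `include_censored` switch to inspect the
alternative.

LOESS trends are tricube-weighted local *linear* fits (degree 1, span
0.75 default, 1,000 case-resampling bootstrap replicates for the 95 %
percentile band). The band quantifies sampling variability of the
smoother; smoothing bias at high curvature is a property of the estimator
itself, which the coverage test acknowledges by targeting the smoother's
population value.

Climate matching interpolates the driver at the episode midpoint
(residence) or gap midpoint (recovery; a `start` option uses the gap's old
end instead, since the matching point is a convention). Normalization
within megabiome is z-score by default, min–max by flag. The GMST rate of
change is the consecutive first difference divided by the age step,
assigned to the younger point.

## Spectral and recurrence diagnostics

The continuous wavelet transform uses a Morlet mother with ω₀ = 6 — the
standard palaeoclimate choice, for which period ≈ 1.033 × scale — computed
by FFT with zero-padding to the next power of two, power normalized by
series variance, and a √2·scale e-folding cone of influence. Significance
is the pointwise chi-square test against the theoretical AR(1) spectrum
with lag-1 autocorrelation estimated from the series: normalized power is
distributed as P_k·χ²₂/2 under the red-noise null. Series must be
uniformly resampled (1-kyr default elsewhere in the package) and should
be detrended first.

The bandpass filter operates in the frequency domain: linear detrend,
FFT, a response of 1 inside the period band with raised-cosine transitions
of 10 % relative width at each edge, inverse FFT. Repeated application is
idempotent except inside the transition bands.

Recurrence determinism embeds the series (dimension 3, delay = first
autocorrelation zero, both configurable; the delay is capped so windows
retain enough state vectors), thresholds Euclidean distances at ε
(default 10 % of the embedded cloud's bounding-box diagonal) and reports
the fraction of recurrence points on diagonals of length ≥ 2, main
diagonal excluded. A constant series yields DET ≈ 1 (exactly 1 up to the
single length-1 corner diagonal), a clean periodic signal > 0.9, i.i.d.
noise near 0. Windowed evaluation slides a window (step = window/4
default) and returns DET at window centres.

Rate-of-change analysis z-scores the input, fits a cubic B-spline
(k = 20 basis functions, second-difference penalty) with the smoothing
parameter selected by restricted maximum likelihood, and takes the
trend's first derivative by central finite differences on a fine grid
inset by the stencil half-width. A simultaneous 95 % interval comes from
10,000 draws of the spline coefficients from their Bayesian posterior
N(β̂, σ̂²(XᵀX+λS)⁻¹); grid intervals where the band excludes zero are
flagged as periods of substantial change. The trend agrees with an
external penalized-spline REML fit to r ≈ 0.9996 on test data; residual
differences reflect basis and knot conventions.

## Regime shifts and ordination

CONISS merges only stratigraphically adjacent clusters, each step chosen
to minimize the increase in total within-cluster sum of squares
(nₐn_b/(nₐ+n_b)·‖x̄ₐ−x̄_b‖²), on square-root-transformed percentages — a
chord-like dissimilarity that stabilizes multinomial variance. The sum of
all merge increments equals the total dispersion (an ANOVA identity
asserted in tests). The default zone count compares merge increments,
largest scale first, against a broken-stick null: zones are added while
the observed increment exceeds its broken-stick share. Zone boundaries
are age midpoints between adjacent samples of different zones.

The multivariate regression tree splits recursively on age thresholds
minimizing multivariate within-node SSE (exact search via prefix sums),
and is pruned by K-fold cross-validated relative error with the 1-SE
rule. Split positions are invariant to affine transforms of age.

PCA retains taxa exceeding 2 % in at least one sample, square-root
transforms, centres (no variance scaling — a linear method is appropriate
for short compositional gradients), and fixes axis signs so the
largest-|loading| taxon loads positively.

## Driver attribution and calibration

The path model is recursive (acyclic) and contains only measured
variables, so it is estimated equation-by-equation: each endogenous node
is regressed by OLS on its parents after z-scoring, giving standardized
partial coefficients; exogenous correlations are reported as
covariances; indirect effects are products of coefficients along
directed paths, and in fully recursive chains the total effect equals
the simple standardized slope (tested as an identity). Significance
stars follow **(0.001 < P < 0.01) and ***(P < 0.001). Because
interpolation to a 1-kyr grid manufactures serial dependence, p-values
are additionally corrected with a lag-1 effective-sample-size adjustment
(n_eff = n(1−r₁r₂)/(1+r₁r₂)); both versions are reported and the
corrected one is the default for stars. Input preparation multiplies
δ¹⁸O by −1 (so low = low ice), optionally bandpasses the vegetation
proxy to 13–250 kyr for orbital-scale analysis, z-scores every column
and aligns all series by linear interpolation to a common 1-kyr grid.
Per-phase analysis is a loop over age windows.

Weighted-averaging calibration computes the abundance-weighted mean
(optimum) and weighted standard deviation (tolerance) of site climates
per taxon, requiring presence at ≥ 5 sites. Climate envelopes are
Gaussian KDEs with Silverman bandwidth, reporting the mode(s) and the
central 50 %/90 % equal-tail intervals; fewer than 30 values is refused.

## Synthetic data: what it emulates, and what it does not

A single latent "effective temperature" axis drives all taxa — in the
alpine ecotone temperature is the dominant control, and a moisture axis
is left as a configuration extension. The latent axis is the exported
linear combination of insolation (sum of 20/41/100-kyr sinusoids, the
41/100-kyr amplitudes ramping up toward the present), an ice series
(lagged, saturating transform of inverse insolation plus trend ramp and
AR(1) noise) and CO₂ (affine anti-correlate of ice plus noise), plus a
long-term cooling trend (7 latent units over 3,500 kyr) and AR(1)
millennial noise (φ = 0.6). Taxon percentages follow Gaussian response
curves on this axis, renormalized, and counts are multinomial at 300–600
grains (the counting range of a standard pollen sum). The "true"
megabiome per sample is the biomization of the noise-free percentages;
trend-only transitions provide true change-point ages. Everything is
deterministic given (config, seed).

Calibration sites place the Gaussian *percentage* responses directly on a
uniform temperature gradient (the classical unimodal response model of
weighted-averaging theory) with multiplicative lognormal noise; rows are
deliberately not closed to 100 %, so exported optima are exact
response-curve truths. Closure bias — the flattening of percentage
responses where total pollen productivity varies — is therefore a real-
data feature the recovery tests do not probe, as is gradient-end
truncation beyond what the default ±8° gradient induces (noise-free
optima error vanishes as the gradient widens, a tested property).

More generally, the generator emulates compositional structure, orbital
cyclicity, trend and counting/millennial noise. It does not emulate
sediment taphonomy, differential pollen preservation or transport,
analyst effects, or age-model error. Passing recovery tests show the
estimators are correct under their stated models — not that those models
capture every property of a real core.

## Problem sizes and numerical choices

Default desk-scale runs use the full study conditions: 5,001 samples at
0.7-kyr spacing over 3,500 kyr, 1-kyr driver grids, 1,448 calibration
sites, 500 AR(1) replicates for the red-noise level check, n = 3,000 for
path-coefficient recovery, 600-sample step cores for change-point
recovery (where the brute-force oracle is exact). Rarefaction uses
log-gamma arithmetic throughout; CONISS maintains cluster sums for O(1)
merge-cost updates; the wavelet transform zero-pads to a power of two;
the spline posterior uses a jittered Cholesky factor for numerical
stability. Degenerate inputs (constant series, all-zero scores,
single-taxon samples, zero sedimentation rates) return defined values or
explicit errors as documented on each function, never silent zeros.
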