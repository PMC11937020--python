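# Methods

## Delayed-luminescence model

Photon emission after a 15-s light pulse is modelled as
`I(t) = A·csch²(t/B + C)` with `A > 0` (counts/s), `B > 0` (s) and `C > 0`
(dimensionless). `C ≤ 0` is rejected as a parameter-domain error because
the law diverges at the time origin. The time origin `t = 0` is the first
detection instant after illumination ends; counts are accumulated in
half-open 1-s bins `[k, k+1)`.

The macroscopic descriptors are exact consequences of the law:

* `I₀ = I(0) = A·csch²C`.
* `T` solves `I(T) = I₀/m`: `sinh²(T/B + C) = m·sinh²C`, hence
  `T = B·(arcsinh(√m·sinh C) − C)`. The decay factor `m` is restricted to
  [2, 4] and defaults to 3. The closed form is used everywhere; tests
  verify it against a root finder to 1e-9 relative.
* `I_W`, the mean of `I(t)` over `[0, W]`, uses the antiderivative of
  csch² (−coth): `I_W = (A·B/W)·[coth C − coth(W/B + C)]`, with
  `W = 300 s` by default (the decay recording length). Verified against
  numerical quadrature to 1e-6 relative.

## Fitting

Each bin's expected count is the exact integral of `I(t)` over the bin
plus `background_rate × bin_width` — bin-integrated means, not midpoint
evaluations, so no discretization bias enters either simulation or
fitting. Nonlinear least squares (`scipy.optimize.least_squares`, trf,
positive bounds) minimizes the discrepancy between observed and expected
counts with Poisson weights `1/√max(expected, 1)` by default (uniform
weighting available). Starting points sweep a coarse grid of `C₀`
(0.1–2.0); for each, `B₀` comes from the observed time for the smoothed
rate to fall to one-third of its initial value via the decay-time
identity, and `A₀` from matching the initial rate; the best of up to six
starts is kept. On exact (noise-free) bin means the truth is recovered to
machine precision; on Poisson traces at the default intensities the median
relative bias of A, B, C is under ~2%.

The dark-count rate estimated from the sample's own background run is part
of the fitted model's expected counts, so the decay parameters describe
the background-free signal (pass `background_rate=0` to fit raw counts).
Each of the three replicate decay runs per sample is fitted independently;
the sample-level parameter set is the mean of the converged replicate
fits, with replicate SDs retained. Non-converged fits withhold derived
parameters rather than propagating garbage.

## SPE, CPS and normalization

`CPS = N − n` with `N` and `n` the mean bin rates of the 600-point SPE run
and the 600-point background run. A negative CPS (noise-dominated sample)
is reported as-is and flagged, never clamped. The strength indicators
`I₀`, `I_W` and `CPS` are homogenized for sample geometry as
`value × thickness[mm] / mass[g]`; time-type quantities (`T`, `B`) and the
shape parameters are never normalized. Units for mass (g) and thickness
(mm) are fixed conventions of this package.

## Physiological indices

Pigments: `Ca = 9.99·A665 − 0.0872·A642`, `Cb = 17.7·A642 − 3.04·A665`,
`Cc = 4.92·A474 − 0.0255·Ca − 0.225·Cb` (mg/L), converted to mg/g by
`× V/m` with the protocol's 15 mL extract and 0.1 g leaf. Negative
computed concentrations are reported with a warning, not truncated.
Relative conductivity: `REC = (E2 − E1)/(E3 − E1)`, undefined when
`E3 ≤ E1`. ROS production rate: `v = 10·(k1 − k2)/g` with ordinary
least-squares slopes (with intercept) of fluorescence against time; the
fluorescence unit is instrument-defined and carried symbolically.

## MIC calling

The dilution ladder is exact two-fold descending (1024 → 8 µg/mL in eight
wells by default). The endpoint is 80% of the negative-control-corrected
growth-control OD600; the MIC is the lowest concentration whose corrected
OD falls below that endpoint — a monotone rule: raising any well's OD can
never lower the call. The literal "closest-OD-to-endpoint" reading is
available behind `rule="closest"` but is not monotone and is not the
default. Plates with growth control at or below the sterility control are
rejected. Replicates are summarized by the modal MIC, ties broken toward
the higher concentration; under OD noise a single spurious low-well dip
can produce an outlier replicate call, which the modal consensus absorbs.

## Screening and inference

LASSO screening standardizes features to zero mean and unit SD (n in the
denominator, so the univariate Gaussian solution reduces to the classical
soft-threshold form `sign(β̂)·max(|β̂| − λ, 0)`, which a test asserts).
The penalty grid is 60 log-spaced values from just above the smallest
all-zero-solution λ (the glmnet convention `max|Xᵀ(y − ȳ)|/n`) down by a
factor 10³. The response is binary control-vs-stressed membership fitted
by L1-penalized logistic regression (liblinear, fixed random state);
stratified k-fold CV (k = 10, capped at the minority class size with a
warning) scores each λ by held-out binomial deviance. `λ_min` minimizes
the mean CV deviance; `λ_1se` is the largest λ within one standard error
of that minimum. Constant features are dropped with a warning;
coefficients are reported on both the standardized and original scales.
A Gaussian (squared-error) variant is provided for the closed-form check.

PCA is centered and scaled. Group comparisons use the two-tailed unpaired
Student's t-test with pooled variance (Welch behind a flag); when both
groups are constant and equal the convention is t = 0, P = 1. Spearman ρ
uses average ranks for ties; for n ≤ 9 the two-sided P value is an exact
permutation test over all n! pairings (vectorized Pearson-on-ranks),
asymptotic otherwise. Network edges are retained at raw P ≤ 0.05, the
study's significance rule; Benjamini–Hochberg is deliberately not applied
by default. Edge attributes carry ρ, P, sign (solid/dotted convention) and
|ρ| (line width). Quality classification fails a group iff its mean
indirubin content is strictly below the 0.02 % standard (the boundary
passes).

## Synthetic studies

The generator emulates the measurement protocol: per sample, three
replicate 300-s DL decays, one 600-point SPE run and one 600-point
background run, all 1-s bins; six samples per group; groups control, two
or three salinity levels and drought. Counting noise is Poisson with bin
means from the exact decay-law integral plus dark counts. Each trace and
table draws from its own stream derived from (seed, sample id, run kind),
so generation is bit-reproducible and order-independent.

Default magnitudes are this package's choices (decay-curve count levels
are not published): control `A = 1500, B = 10 s, C = 0.5`
(`I₀ ≈ 5.5×10³ counts/s`), SPE 80 counts/s over a 30 counts/s dark rate —
DL well above SPE, as observed. Severe stress halves `I₀` by scaling `A`
only, leaving `B`, `C` and hence `T` unchanged (stress alters emission
"density", not decay "composition"); assay endpoints are scaled per group
so that contents and pigments fall with stress while leakage, ROS and MIC
rise — e.g. control indirubin 0.10 % with a 0.18 multiplier under high
salinity (≈ 0.018 %, below standard) and 0.46 under drought, REC roughly
2.4–3× control, MIC shifted one-to-three two-fold steps. Endpoint noise is
mean-one lognormal with 8% CV; mass 0.5 ± 0.05 g and thickness
0.4 ± 0.05 mm give the normalized intensities a ~15% relative spread, so
the halving of I₀ corresponds to a ≈ 4-SD group separation — the default
effect size of the planted-signal feature-table generator used in
screening-recovery studies.

What the generator does not emulate: detector dead time, PMT afterpulsing
or drift, spectral structure, temporal autocorrelation within assays,
between-day batch effects, or any real covariance between compound
chemistry and optical properties beyond shared group structure. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated stochastic model, not instrument-level validity.

## Problem sizes and numerics

Recovery studies use 200 Poisson traces per condition, 100 seeds for
LASSO selection (n = 6 per group), 500 seeds for t-test calibration, and
12–20 end-to-end salt-arm runs for correlation-sign recovery — sizes at
which Monte-Carlo error is small relative to the tolerances asserted.
Optimizer tolerances are 1e-15 (xtol/ftol/gtol); nonzero-coefficient
threshold 1e-8; exact-permutation comparisons use a 1e-12 guard on |ρ|
ties. CSV outputs use a fixed `%.10g` float format so manifest hashes are
byte-stable across runs.

## Known limitations

* The decay law is the only DL model offered; no multi-exponential or
  power-law alternatives.
* LASSO selection among strongly collinear parameters (A, I₀, I_W carry
  overlapping information in full-pipeline data) picks representatives of
  a correlated cluster; which representative wins varies by seed. The
  planted-signal recovery study plants effects in exactly two columns to
  make the target unambiguous.
* With six samples per group, 1-SE null calibration of CV-LASSO is noisy;
  the null empty-selection property is asserted at a CV-stable sample
  size (30 per group).
* Exact Spearman P values are limited to n ≤ 9 (9! pairings); beyond that
  the asymptotic approximation is used.
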