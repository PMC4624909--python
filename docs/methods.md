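# Methods

## Model

`ednasens` models the sensitivity of an eDNA monitoring event — the
probability that a survey of `N` water samples yields at least one
sequencing-confirmed PCR detection, given the ambient concentration
`C_M` (copies/L) of a species-specific marker.

Per water sample:

- capture: `N_S ~ Poisson(C_M · V_S)`.  Assumes a well-mixed water body,
  randomly distributed marker copies and independent samples.
- extraction: efficiency `φ ~ Triangular(lower, mode, upper)`, default
  `(0, 0.15, 0.3)` (symmetric, so mode = median = 0.15).  `φ` folds in
  filtration, extraction and storage/shipping losses.  The expected
  eluted copy number `N_E = φ·N_S` is kept continuous (it parameterizes a
  rate; rounding it would discard information).
- elution concentration: `C_E = N_E / V_E` copies/µl with `V_E = 100 µl`.
- aliquot: each of `k` replicates receives `V_A = 1 µl`, expected copy
  number `µ = C_E · V_A`; the realized copy count is `N_R ~ Poisson(µ)`.
- assays: gamma detection curves
  `P_F(x) = P(α_F, x/β_F)` and `P_S(x) = P(α_S, x/β_S)` (regularized
  lower incomplete gamma = gamma CDF with shape/scale parameterization).
  Fluorescence and sequencing are conditionally independent given the
  copy number, so a replicate is positive with probability `P_F · P_S`.

Event composition: replicates within a sample share `(N_S, φ)` and are
conditionally independent; samples are independent.
`p[A|C_M] = 1 − E_{N_S,φ}[(1 − p_rep)^k]` and
`p[E|C_M] = 1 − (1 − p[A|C_M])^N`.

Default assay calibrations (dimensionless shapes, scales in copies):

| marker  | α_F   | β_F   | α_S   | β_S    |
|---------|-------|-------|-------|--------|
| bighead | 1.885 | 1.486 | 0.877 | 41.631 |
| silver  | 2.092 | 2.238 | 0.289 | 6.968  |

## Composition modes

The package exposes three compositions of the subsampling and assay
stages, selected by `mode`:

- `expected` (default): the detection curves are evaluated at the
  *expected* aliquot copy number, `p_rep = P_F(µ)·P_S(µ)`.  This is the
  composition consistent with how the curves are calibrated — the
  dilution experiments record the *expected* copy number per aliquot, so
  the fitted curve already averages over aliquot-level randomness — and
  it is the composition that reproduces the published survey-design
  results for these assays (silver-carp MDC values to within ~3%,
  bighead to within ~9%).
- `realized`: the aliquot count is marginalized explicitly,
  `p_rep(µ) = Σ_n Poisson(n; µ) P_F(n) P_S(n)`.  If the curves are read
  as per-copy-number detection probabilities this is the exact
  composition; layering Poisson dispersion under curves that already
  embed it, however, double-counts aliquot variability.  Because
  `P_F·P_S` is convex at low copy numbers this mode is *more* sensitive
  (baseline bighead MDC 646 instead of 726 copies/L).
- `independent`: as `realized` but ignoring the within-sample sharing of
  `(N_S, φ)`: `p[A] = 1 − (1 − E[p_rep])^k`.  Replicates from one elution
  are positively correlated, so this textbook form overstates
  sensitivity; it is provided for comparison.

The Monte Carlo simulator implements the same three modes (for
`independent` it runs the hierarchy — the distinction only matters for
the closed-form composition).

## Semi-analytic evaluation

`sample_positive_prob` computes the double expectation by

- summation over `N_S` on a Poisson quantile window whose excluded tail
  mass is below `truncation_tol` (default 1e-12; the integrand is bounded
  by 1, so the truncation error is bounded by the tail mass);
- Gauss–Legendre quadrature of the triangular density, one panel per
  linear piece (default 32 nodes/panel).  A degenerate extraction model
  (`lower = mode = upper`) collapses to a single node of weight 1.

In `realized` mode the inner Poisson sum would otherwise run at ~1e5
`(N_S, φ)` pairs per evaluation, so `p_rep(µ)` is served from a cached
monotone PCHIP interpolant per assay: 6000 log-spaced nodes holding exact
truncated sums, with `p_rep ≡ 1` above a saturation mean where
`1 − p_rep < 1e-10` (spot-checked maximum absolute interpolation error
~2e-10 against direct summation).  The public scalar function
`replicate_positive_prob` always uses direct summation and serves as the
oracle in tests.

## Minimum detectable concentration

Sensitivity is strictly increasing in `C_M`, so the MDC at goal `g`
(default 0.95, valid in (0,1)) is found by Brent root finding on
`log10 C_M` over a default bracket of `[1e-2, 1e6]` copies/L, relative
tolerance 0.5%; a non-bracketing range raises an error carrying the
sensitivity reached at the bracket top.  After the root is located the
returned value is nudged upward (in quarter-tolerance steps) until the
goal is met, so `sensitivity(MDC) ≥ g` holds exactly.  An alternative
`method="mc"` estimates sensitivity on a 25-point log grid with a shared
seed, enforces monotonicity by isotonic pooling, and interpolates the
goal crossing; it exists to mimic purely simulation-based workflows and
carries that workflow's sampling error.

Protocol comparison: `unit_increase_strategies` builds the canonical
one-unit changes (+1 sample, +1 L volume, +1 replicate) and their
combinations; `delta_sensitivity` scores a change as a paired
(common-seed) sensitivity difference per concentration, and
`mdc_reduction` as the MDC decrease at the goal.  For these assays the
volume increase is the most effective single change and combined
reductions are subadditive.

## Monte Carlo simulator

One draw = one monitoring event.  Per chunk of 8192 draws the generator
is consumed in a fixed order (capture counts, efficiencies, then aliquot
counts / assay uniforms), making results bit-reproducible for a given
seed and independent of chunking.  `sensitivity_curve` spawns one child
seed per grid point from a root `SeedSequence`.  The binomial standard
error `sqrt(p̂(1−p̂)/n_draws)` is reported with every estimate.  Default
`n_draws = 50_000`, which resolves sensitivities near 0.95 to about
±0.001 and keeps every analysis in this package at desk scale (the full
test suite runs in well under a minute; the headline-reproduction script
in a few seconds).

## Calibration

`fit_gamma_moments` implements the method of moments over the expected
copy numbers of *positive* trials: `α = x̄²/s²`, `β = s²/x̄`, with the
sample (n−1) standard deviation (the convention is immaterial at
realistic experiment sizes).  Fewer than two positives, or positives with
zero spread, raise `CalibrationError`.  `fit_rmse` compares per-level
empirical positive fractions (grouped by unique expected count, levels
equally weighted) against the fitted CDF.

A property worth stating plainly: this estimator characterizes the
distribution of expected counts *among positive trials*.  It is
consistent for the curve parameters only when those counts sample the
gamma threshold distribution itself.  Under a one-shot dilution design —
every replicate tested once at its level, positives pooled — its
population limit is the design-weighted functional with weights
`w(x) ∝ P(positive | x)` over the level design, which generally differs
from the generating parameters (for truth `(α, β) = (2, 2)` on uniform
levels 1..15 the limit is ≈ `(6.30, 1.50)`).  The tests therefore check
exact moment round trips, consistency on threshold samples, and
convergence to the analytic functional — not "recovery of truth", which
this estimator does not deliver under that design.  Users calibrating
real assays should concentrate replicates at low expected counts, where
the curve rises, for the fitted curve to track the empirical fractions.

## Synthetic data generator

`generate_dilution_experiment` emulates the *structure* of a
serial-dilution calibration experiment: levels (default 1..15 copies),
fixed replication per level, realized copies Poisson around the level
mean (pipetting from a dilution captures a random copy number), and
Bernoulli outcomes from a known gamma curve at the realized count.  It
does not emulate PCR inhibition, pipetting volume error, plate effects,
or operator-dependent scoring of faint bands; passing tests show the
pipeline's statistical machinery is correct, not that any real assay
follows the gamma family.

## Degenerate inputs and tie-breaks

- `C_M = 0` returns sensitivity exactly 0 everywhere (simulator included).
- `φ` values of 0 are allowed and simply yield empty elutions; no
  truncation of the triangular support is applied.
- `aliquot_volume × n_replicates ≤ elution_volume` is enforced at
  protocol construction.
- Detection curves at copy number 0 are exactly 0; curve parameters must
  be strictly positive.
- `event_sensitivity` validates `p ∈ [0, 1]` and `N ≥ 1`.

## Limitations

- The Poisson capture model assumes a well-mixed water body; clumped
  (e.g. negative-binomial) marker distributions would lower event
  sensitivity at equal mean concentration and are not modelled.
- PCR inhibition is not modelled mechanistically; an
  `inhibition_factor ∈ (0, 1]` scaling the expected aliquot copy number
  is exposed for sensitivity analyses.
- The gamma detection curves are assay-specific empirical fits; nothing
  here validates them for other primers, platforms or scoring rules.
- Sequencing is composed per replicate (`P_F · P_S`); field protocols
  that sequence only one selected band per sample introduce a
  within-sample dependence this composition ignores.
- The residual few-percent gap on the bighead MDC reproduction (e.g. 726
  vs 789 copies/L at baseline) persists across every composition variant
  examined and most plausibly stems from unrecoverable numerical details
  of the original curve integration; the silver-carp values reproduce to
  within ~3%.
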