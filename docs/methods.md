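# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a user auditing results will want to know.

## Thermal performance curves

A TPC relates a performance trait (maximum jumping speed, cm/s) to body
temperature.  Candidate families are unimodal peak functions parameterised so
that all reach their maximum `a` at `T = b` with width `c > 0`:

| family | form | K |
|---|---|---|
| gaussian | `a·exp(−½u²)`, `u = (T−b)/c` | 3 |
| lorentzian | `a/(1+u²)` | 3 |
| logistic peak | `4a·e^(−u)/(1+e^(−u))²` | 3 |
| weibull peak | `a·g^(1−d)·z^(d−1)·e^(−z^d + (d−1)/d)`, `z = u + g`, `g = ((d−1)/d)^(1/d)` | 4 |

The Weibull peak is the one skewed family; its mode is kept at `b` and its
peak value at `a` by construction (shape `d > 1` controls asymmetry).  It is
excluded from the default candidate set so that routine selection runs over
the same three-way comparison used for the population curves; pass it
explicitly to include it.

**Fitting.** Nonlinear least squares (scipy trust-region reflective) with a
deterministic multi-start grid: data-driven starts (`a₀` = max speed, `b₀` =
argmax temperature, `c₀` = half the temperature range) each perturbed by
±50% on a 3×3×3 grid; lowest residual sum of squares wins, fixed grid order
breaks ties.  Population-level fits go through the per-temperature means of
individual trial averages (two trials per individual per temperature are
averaged first); individual-level fits use one individual's trial averages.
A family with `K` parameters requires at least `K+1` distinct test
temperatures.

**Model selection.** Least-squares AIC `n·ln(RSS/n) + 2K` (the small-sample
AICc correction is available by flag).  Only AIC *differences* are
interpretable across software, so the package reports `λ_i` and Akaike
weights alongside raw AICs; the lowest AIC wins, ties broken by fewer
parameters, then by a fixed family order.  A perfect fit (RSS = 0) reports
−∞ with a warning rather than failing.

**Critical limits.** Strictly positive peak functions never intercept the
x-axis, so "temperature at which performance is zero" is operationalised as
`curve(T) = ε·V_max` with ε = 0.05 by default and exposed everywhere.  This
is the single largest convention choice in the package: commercial
curve-fitting software that reports x-intercepts for skewed families will
give *much lower* `CT_min` values than a symmetric Gaussian at ε = 0.05
(whose lower limit sits `c·√(−2 ln ε) ≈ 2.45c` below the peak).  Upper limits
are far less sensitive because the descending limb is steep.  Between-package
comparisons of `CT_min` should therefore be made only at a stated ε.
Gaussian and Lorentzian limits use closed forms (`b ± c·√(−2 ln ε)`,
`b ± c·√(1/ε − 1)`); other families use outward-stepping bracketing plus
Brent root finding (agreement with the closed forms is tested to 1e-6).

## Repeated-measures acclimation contrasts

Each individual is measured under all acclimations (here in series:
measurement order equals acclimation order, as in the emulated design), so
trait values are modelled as

`y_ij = μ + acclimation_j + (log10 mass)β + u_i + v_order(j) + e_ij`

with random intercepts `u_i` (individual) and `v` (measurement order), fitted
by maximum likelihood (statsmodels MixedLM).  When order is aliased with
acclimation the order variance is weakly identified and routinely lands on
the zero boundary; boundary components are dropped with a warning and the
model refitted (the order term matters in counterbalanced designs, which the
module accepts via an `order` column).  The mass covariate defaults on for
`V_max` and `CRT_min` only.

**Scales.** Traits bounded away from 0 °C (`T_pref`, `T_opt`, `V_max`,
`CRT_max`, `CT_max`) are log10-transformed; contrasts for them are
differences of log10 means.  Cold limits (`CRT_min`, `CT_min`) cross 0 °C,
where a log transform is undefined, and are analysed on the identity scale
(an explicit `log_offset` enables `log10(x + offset)` if wanted).  Every
contrast records its scale, and the two scales are not directly comparable.

**Intervals.** The 95% CI inverts the likelihood-ratio test by profiling the
contrast coefficient: fixing the contrast at θ reduces to refitting with
`y − θ·x` (a linear model identity), and the bound solves
`2(ℓ̂ − ℓ(θ)) = χ²₀.₉₅(1)` by bracketing outward from the Wald bound and Brent
root finding.  If a bound cannot be bracketed (flat profile near a variance
boundary) the package falls back to a seeded parametric bootstrap (1000
refits, percentile interval) and says so.  An "effect" is declared exactly
when the interval excludes zero.  Null coverage of the profile interval is
checked by simulation in the test suite (500 seeded datasets of the study
size, 31 individuals × 3 occasions) and falls in the 92–98% band.

Degenerate inputs short-circuit: identical trait values give zero contrasts
with zero-width intervals; a perfectly deterministic mass trend returns the
exact slope.

## Operative temperatures and exceedance

Logger series (5-min cadence, 24 h per physical model) are parsed per model;
timestamps must be strictly increasing and longer-than-cadence steps are
flagged as gaps, never interpolated — fractions always use available time
units as the denominator.  Daytime analyses use a half-open clock window,
default **07:00–20:00**; the window is a parameter recorded in every output
because field conventions vary by an hour at either end, and all headline
numbers here are attached to this default.

The patch comparison is the balanced two-way ANOVA (exposure × moisture, two
replicate models per cell): main effects are tested in the additive model
(error df `n−3`, i.e. 1,5 with eight models) and the interaction in the full
factorial (df 1,4), reproducing the two-stage df structure conventional for
this design.  Water loss is `(mass_before − mass_after)/deployment_hours`; a
mass gain is reported as a negative rate with a warning rather than an error.

Warming scenarios shift every temperature by a constant offset (operative
temperature scales approximately linearly with air temperature).  Exceedance
classifies daytime time units into four bands, `(−∞, CT_min)`,
`[CT_min, T_opt]`, `(T_opt, CT_max]`, `(CT_max, ∞)`; the default time unit is
the 30-min interval mean pooled across a patch's replicate models (a raw
5-min mode is available — it weights brief spikes more heavily).  Each
scenario is judged against the TPC limits of a mapped acclimation (default:
current → 20 °C acclimation, +5 °C → 25 °C), on the premise that a population
under sustained warming carries the acclimation phenotype of its regime.
Scenario limits are the across-individual means of the extracted individual
parameters, not the population-curve limits: the population mean curve is
broadened by between-individual spread in `T_opt`, so its `CT_max` overstates
the typical individual's limit by 1–2 °C at the default settings.

## Calibration

Dorsal-vs-cloacal calibration averages readings within each chamber
temperature before regression, so df reflects the number of chamber settings
(7 → df 5), not the number of animals; `t = r·√((n−2)/(1−r²))`, with an
infinite sentinel for exactly collinear data.  Surrogate validation is the
two-group one-way ANOVA, whose F equals the squared pooled t (tested to
1e-8).

## Synthetic generator

The generator emulates the study design end to end: 31 individuals,
acclimations 10/20/25 °C measured in series, two trials per test temperature
at 5–7 temperatures per acclimation (warmer acclimations probed further up),
tolerance and preference traits drawn around per-acclimation means with
rejection enforcing `CRT_min < T_pref < CRT_max`, eight logger models (two
per patch, one per pond) at 5-min cadence for 24 h, and seven-point
calibration pairs.  One integer seed fully determines all four tables.

Defaults and rationale:

- **Curve truth**: Gaussian with `(a, b)` equal to the per-acclimation trait
  means for `V_max` and `T_opt` (8.46/22.68, 9.57/25.98, 11.41/26.37) and `c`
  chosen so the ε = 0.05 upper limit lands on the corresponding `CT_max` mean
  (c = 4.0, 3.5, 4.1 °C).
- **individual_sd = 0.10** (relative SD of per-individual parameters; one
  latent deviate per parameter per individual, shared across acclimations so
  repeated measures are correlated).  This puts the SD of individual `T_opt`
  near 2.6 °C, matching the 2.7–3.7 °C spread of the emulated traits.
  Within-individual repeatability of jump speed is not observable in the
  emulated design, so this is a free knob, exposed in the config.
- **noise_sd = 0.10**: multiplicative log-normal trial noise — speeds are
  positive and analysed on a log scale, so noise must not produce negative
  speeds; zero noise reproduces the generating curve exactly.
- **Diurnal T_e**: a clipped half-cosine from `night_min` to `day_peak`
  (peak 14:00, 7 h half-width) — the analysis needs realistic daytime
  structure, not heat-balance physics.  Patch defaults (night 8/9 °C, peaks
  21.6/22.0/32.0/33.2 °C for shade-wet/shade-dry/sun-wet/sun-dry) were solved
  from the window integral of that shape so the daytime sun−shade mean gap is
  ≈ 7.8 °C and the maximum gap ≈ 11 °C.  A per-model microsite offset
  (SD 0.7 °C) separates replicate models of the same patch; it is suppressed
  when a patch's noise SD is zero so noiseless configurations are exactly
  deterministic.
- **Water loss**: rate = 0.30 + 0.686·(dry) + 0.403·(sun) g/h, so the wet−dry
  and sun−shade main effects have realistic magnitudes by construction
  (50 g models, 13 h daytime deployment).
- **Calibration noise**: a shared 0.25 °C equilibration deviate plus 0.15 °C
  independent instrument noise per reading keeps the dorsal–cloacal
  correlation near 0.99.

What the generator does **not** emulate: ramping-protocol dynamics (only
endpoint values), skewed individual curves (truth is symmetric Gaussian
unless configured otherwise), weather (clouds, wind) in the diurnal cycle,
logger dropouts, and any biophysical coupling between patch moisture and
temperature.  Passing tests therefore demonstrate that the estimators recover
the structure they assume, at realistic noise — not that real field data meet
those assumptions.

## Problem sizes and determinism

The simulation-based checks in the test suite use: 200 synthetic datasets for
parameter recovery (one acclimation, 31 individuals each), 500 null datasets
for contrast-interval coverage, 100 random balanced designs for the ANOVA
oracle, and 100-point grids for the closed-form/bisection agreement.  All
random draws in the package flow through `numpy.random.default_rng` seeded
from the user-facing seed (one independent stream per generator, so each
output depends only on the seed, not on call order); fits use deterministic
multi-start grids.  Identical configuration therefore yields byte-identical
outputs, including `report.json`.

## Known limitations

- `CT_min` at ε = 0.05 on symmetric families is far above an x-intercept
  convention on skewed curves (see above); ε must be stated for any
  cross-study comparison.
- The profile interval uses the χ² calibration, which is asymptotic; with
  3-level order effects the order variance is on the boundary and the
  interval inherits mild conservatism from the refit-without-order path.
- The pipeline's per-individual fits reuse the acclimation-level best family
  rather than re-selecting per individual (the conventional choice; per
  individual selection is available via the library by calling
  `fit_candidates` per individual).
- The agar-vs-live comparison (`validate_surrogate`) has no synthetic input
  table of its own; the pipeline's calibration report covers the
  dorsal–cloacal regression, and the two-group check is exercised at the
  library level.
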