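# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Scoring

Six baseline behaviors are dichotomized: current nonsmoking (former
smokers count as healthy), drinking at most 23 g of ethanol — one *gou*
of sake — per occasion or not currently drinking (former drinkers
healthy), walking ≥ 1.0 h/day, sleeping 6.5–7.4 h/day, green leafy
vegetables almost daily, and BMI 18.5–24.9 kg/m². Sleep and BMI bounds
are closed intervals compared at one-decimal precision, matching how the
thresholds are stated; whether, say, 7.45 h "rounds into" the healthy
band is not derivable from the definitions, so the implementation
compares `round(x, 1)` against the printed endpoints and documents that
choice rather than guessing questionnaire granularity. The full score is
the count of healthy flags (0–6, grouped 0–2/3/4/5/6); smoking-stratified
analyses use the five non-smoking flags (0–5, grouped 0–1/2/3/4/5).
Behavior is scored at baseline only; time-varying behavior is out of
scope.

## Person-time

Follow-up intervals are real-valued ages; calendar dates are not
modeled. Each interval is intersected with half-open 5-year bands
[40, 45) … [80, 85), the tracked sub-band [85, 90), and the open
aggregate [85, ∞). Deaths are attributed to the band containing the
exact exit age, with boundary deaths going to the upper band — the
standard demographic convention, applied consistently and pinned by a
brute-force integration oracle in the tests. Exposure before age 40 is
truncated, not an error. Conservation (person-years and deaths summed
over closed bands plus the open aggregate equal the per-subject totals)
holds to float additive tolerance.

## Rates, the open interval, and standardization

Band rates are `m = D/PY`; zero deaths with positive exposure is a
defined zero, zero exposure is undefined. The open-interval correction
multiplies the observed 85–89 rate by the national 85+/85–89 rate ratio;
it is undefined when the 85–89 band has no deaths, and that undefined
state propagates to the stratum's life expectancy as a distinguished
sentinel (rendered "—"), never as NaN or zero.

Age adjustment is direct standardization with the *sex-specific
whole-cohort person-years* as the standard population. Two open choices
are resolved as follows:

* **Sexes are not pooled in the standard.** With a sex-specific standard,
  the whole cohort's adjusted rate equals its crude rate exactly — the
  identity visible in the published overall rows this package reproduces
  — which a pooled standard would break.
* **The adjusted-rate table standardizes the observed rates, not the
  corrected ones.** The same crude-rate identity forces this: including
  the corrected 85+ rate shifts the whole-cohort adjusted rate away from
  its crude rate (by about +1.4 per 1000 in the default synthetic
  cohort). Life tables, by contrast, always use the corrected open rate.
  An undefined band with positive standard weight makes the adjusted rate
  undefined rather than silently reweighted.

## Life tables and confidence intervals

Chiang's abridged construction (radix 100 000, pivots 40 and 60,
`z = 1.959964`) as given in the README. The fraction-of-last-interval
values `a_x` are an input from the reference life table, defaulting to
0.5 for bands where the reference is silent. The open interval takes
`q = 1` and `L = l/m`. The variance treats closed-band deaths as binomial
(`Var(q̂) = q²(1−q)/D`, zero when `D = 0`, which keeps CIs computable for
sparse-but-nonempty strata) and open-interval deaths as Poisson via the
delta method (`l² e² / D`); zero deaths in the open interval leave the
variance, and only the variance, undefined. The constant-hazard closed
form (`e = 1/m` when `a = 0.5` everywhere) and agreement with an
independent 1-year-band table (within 0.2 y for Gompertz profiles) pin
the algebra.

## Reference life tables

The reference CSV uses `age_start` values 40…80 for closed bands, `85`
for the 85–89 band and the literal `85+` for the open interval. National
life tables are sex-specific, so the pipeline accepts either one table
for both sexes or a per-sex mapping. For simulated data,
`reference_from_config` derives a self-consistent reference from the
generating hazards by building the stationary population of the profile
mixture (exact per-band closed forms), including `a_x` as the mean
fraction of the band lived by its decedents.

## Synthetic cohort

Defaults emulate the study conditions the pipeline was built for: 27 582
men and 34 524 women, entry ages uniform on [40, 79], mean administrative
follow-up horizon 14.5 years, plus a 10% move-out fraction with uniform
censoring times (the move-out share is not documented anywhere; 10% is a
plausible minority of all censoring). Behavior flags come from a
single-factor Gaussian copula; the correlation defaults to ρ = 0 —
behaviors are known to be mutually related, but no joint distribution is
documented, and independence keeps the analytic truth exact while the ρ
knob remains available and tested. Healthy-smoking prevalence matches the
documented 53.2%/4.9% current-smoker shares; the other prevalences and
the hazard ratios (smoking 1.7, the rest 1.15–1.25, applied
multiplicatively when unhealthy) are plausible all-cause penalties with
smoking deliberately the largest. Gompertz baselines
(λ(t) = b·e^{θt}, θ = 0.092/0.100 for men/women) were calibrated
analytically so the whole-cohort crude rates land at the target
magnitudes of 17 and 8.3 per 1000 person-years.

Death ages are drawn by exact inversion on the piecewise-exponential
survival function of the band-averaged hazard (no discrete-time
approximation). Because the hazard is constant within bands, the expected
deaths in a band equal the rate times expected person-years under any
entry/censoring design, so the band rates the person-year method
estimates — and hence the life expectancy the pipeline targets — are
computable exactly per stratum by integrating per-band closed forms over
the entry-age distribution. Truth and estimate share the same reference
table and `a_x`, so recovery tests measure estimation error only.

What the generator does *not* emulate: behavior change over follow-up,
competing risks, calendar-period effects, measurement error in
self-reported behaviors, and the health-based selection that makes real
volunteer cohorts lighter-mortality than their national population.
Passing recovery tests therefore demonstrate the estimator chain is
consistent for the declared design, not that real-data estimates are
unbiased.

## Problem sizes and numerical choices

The confidence-interval calibration study uses 1000 replicates of 20 000
men; coverage of the nominal 95% CI lands at 94–95%. Parameter recovery
uses 200 000 subjects per sex. The analytic truth integrates over entry
age on a 0.05-year midpoint grid; Gompertz band averages use 0.01-year
trapezoids; copula orthant probabilities use 101-node Gauss–Hermite
quadrature. At these sizes the sampling standard error of ê₄₀ is about
0.1–0.3 y for large strata but rises to ≈ 0.75 y for the smallest female
stratum (~8% prevalence), dominated by the handful of stratum-specific
85–89 deaths entering the open-interval correction — so point-recovery
checks tighter than ~1.5 standard errors on that stratum will fail for
typical seeds even though the estimator is unbiased (the coverage study
confirms calibration). The internal hazard grid extends to age 110, with
survival beyond handled on the last band's rate; with default entry ages
and horizon, no observable exit exceeds 93.5 years.

## Known limitations

* Real-valued ages are trusted as given; no date arithmetic or
  completed-years convention is imposed.
* The q-conversion clamps at 1 for extreme rates (`n·m` large), where the
  abridged approximation itself is poor.
* The copula truth for ρ > 0 is exact only under the single-factor
  structure the generator itself uses.
* Report rounding is fixed at one decimal at serialization; internal
  precision is full throughout.
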