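# lexpect

Life expectancy by healthy-lifestyle score in cohort follow-up data.

`lexpect` reimplements, as a reusable Python pipeline, the classical
cohort analysis that asks: *how many more years can a 40- or 60-year-old
expect to live if they keep six healthy behaviors* — not smoking, not
drinking heavily (≤ 23 g ethanol per occasion), walking ≥ 1 h/day,
sleeping 6.5–7.4 h, eating green leafy vegetables almost daily, and a BMI
of 18.5–24.9? It targets epidemiologists who have individual-level
follow-up records (entry age, exit age, vital status, baseline lifestyle)
and want stratified abridged life tables with honest confidence intervals,
and it ships a synthetic-cohort generator with exact analytic ground truth
so every stage can be validated without access to restricted data.

## Method

For each subject the six behaviors are dichotomized and summed into a 0–6
score; subjects keep their baseline stratum. Follow-up is split across
half-open 5-year age bands (Lexis expansion) starting at age 40, giving
deaths `D_x` and person-years `PY_x` per (sex, stratum, band), and rates
`m_x = D_x / PY_x`. Because finite follow-up under-represents the oldest
ages, the open 85+ rate is corrected against a national reference life
table:

    MR_85+ = MR_85–89 × JMR_85+ / JMR_85–89

where `JMR` are the national rates. Age-adjusted mortality is directly
standardized over the bands with the sex-specific whole-cohort
person-years as the standard (so the whole cohort's adjusted rate is its
crude rate exactly). Life tables follow Chiang's abridged construction
with fraction-of-last-interval values `a_x` from the reference table:

    q_x = n m_x / (1 + (1 − a_x) n m_x)          (closed bands, n = 5)
    L_x = n (l_x − d_x) + a_x n d_x,   L_85+ = l_85 / m_85+
    e_x = T_x / l_x,   T_x = Σ_{y ≥ x} L_y

with sampling variance

    Var(q̂_x) = q_x² (1 − q_x) / D_x
    Var(ê)  = [ Σ l_x² ((1 − a_x) n + e_{x+1})² Var(q̂_x)
                + l_85² e_85² / D_85+ ] / l_pivot²

and a normal 95% CI. Strata whose 85–89 band has no deaths cannot be
corrected; their life expectancy is reported as an explicit "—" sentinel,
never silently as a number.

The synthetic generator draws behavior profiles from a Gaussian copula,
death ages by inversion from a piecewise-constant (band-averaged Gompertz
× per-behavior hazard ratio) hazard, and applies administrative plus
move-out censoring; because the hazard is piecewise constant, the exact
band rates and life expectancies a given design estimates are computable
in closed form for any stratum (`true_life_expectancy`).

## Worked example

`examples/simulate_and_recover.py` simulates 30 000 men with known
hazards, runs the full estimation pipeline per behavior stratum, and
compares with the analytic truth:

```
 stratum      n  e40 est         95% CI   truth
     0-2   6267     39.7    (39.1-40.4)    39.7
       3   8983     42.1    (41.5-42.8)    42.7
       4   9042     45.6    (44.8-46.3)    45.6
       5   4679     48.0    (46.6-49.5)    49.2
       6   1029     52.9    (48.4-57.3)    53.8
```

Each row is the estimated further life expectancy at age 40 (years) for
men by number of healthy behaviors; estimates track the truth within
Monte-Carlo noise, and the gradient across strata reflects the hazard
ratios attached to each unhealthy behavior. The other examples cover
scoring (`score_behaviors.py`), life-table construction on explicit rates
(`build_life_table.py`), and the end-to-end config-driven pipeline
(`run_pipeline.py`). From a shell, the same pipeline runs as

```
lexpect simulate --config cfg.yaml --out sim/
lexpect analyze  --config cfg.yaml --out out/ --format csv
```

producing a mortality report, a life-expectancy report and a run manifest
that records every undefined estimate with its reason.

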