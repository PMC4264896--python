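# thermoperf

Thermal performance curves, acclimation plasticity and operative-temperature
exceedance for ectotherm climate-vulnerability analysis.

`thermoperf` is a Python library for the complete workflow of a
laboratory-plus-field thermal vulnerability study of an ectotherm population
(the motivating system is a small desert-pond frog measured under three
acclimation treatments): it fits thermal performance curves (TPCs) to
locomotor trials, selects among candidate curve families by AIC, compares
thermal traits across acclimations with repeated-measures mixed models,
validates surrogate temperature measurements, and projects how often field
operative temperatures would exceed the fitted thermal limits under warming
offsets.  A synthetic-data module generates all four study inputs with the
statistical structure the analysis assumes, so every stage is testable
without external data.

## The model

Performance (maximum jumping speed, cm/s) as a function of body temperature
*T* is fitted with unimodal peak functions, by default

- Gaussian: `a·exp(−½((T−b)/c)²)`
- Lorentzian: `a / (1 + ((T−b)/c)²)`
- logistic peak: `4a·e^(−(T−b)/c) / (1 + e^(−(T−b)/c))²`

(a four-parameter Weibull peak is available for skewed curves).  Families are
compared with the least-squares AIC, `n·ln(RSS/n) + 2K`, and Akaike weights
`w_i = exp(−λ_i/2)/Σ_j exp(−λ_j/2)` where `λ_i = AIC_i − min AIC`.  From the
winning curve the package extracts `T_opt` (argmax), `V_max = curve(T_opt)`,
and critical limits `CT_min`/`CT_max` defined as the two temperatures where
the curve falls to `ε·V_max` (default ε = 0.05; strictly positive peak
functions have no true zero intercept, so the threshold is explicit and
configurable).

Traits measured repeatedly on the same individuals under each acclimation are
compared with a linear mixed model (acclimation fixed; random intercepts for
individual and measurement order; log10 body mass as covariate for
size-dependent traits), reporting 95% profile-likelihood intervals for
between-acclimation mean differences.  Field operative temperatures (`T_e`,
from agar models in sun/shade × wet/dry patches) are summarised over a
daytime window, tested with the balanced two-way ANOVA (main effects on
df 1,5; interaction on df 1,4 for eight models), and — after shifting by a
warming offset — classified into TPC bands to give the fraction of daytime
intervals above `CT_max`: the hours when behavioral thermoregulation is
compulsory.

## Worked example

```python
from thermoperf import SynthConfig, generate_performance, fit_candidates, extract_parameters

perf = generate_performance(SynthConfig(seed=1))
fits = fit_candidates(perf, level="population", acclimation_c=20.0)
for f in fits:
    print(f"{f.family:>14s} K={f.k} AIC={f.aic:7.2f} lambda={f.lambda_i:6.2f} w={f.w_i:4.2f}")
p = extract_parameters(fits[0], epsilon=0.05)
print(f"T_opt={p.t_opt:.2f} V_max={p.v_max:.2f} CT={p.ct_min:.2f}..{p.ct_max:.2f}")
```

prints

```
      gaussian K=3 AIC= -40.58 lambda=  0.00 w=1.00
 logistic_peak K=3 AIC= -23.50 lambda= 17.08 w=0.00
    lorentzian K=3 AIC=  -6.53 lambda= 34.05 w=0.00
T_opt=25.91 V_max=7.49 CT=14.70..37.13
```

The Gaussian carries essentially all Akaike weight for the 20 °C acclimation;
its peak sits at 25.9 °C and performance falls to 5% of maximum at 14.7 and
37.1 °C.  Running the same fit across acclimations shows `T_opt` and `CT_max`
shifting upward with warmer acclimation — the plasticity signal — and the
`examples/` scripts continue the story: `04_operative_exceedance.py` finds no
daytime interval above `CT_max` under the current climate but ~23% of
sun–dry and ~8% of sun–wet intervals above it under a +5 °C offset (seed 1),
judged against the limits of the acclimation matched to each scenario.

One command runs everything and writes all tables plus `report.json`:

```sh
thermoperf run --synth --seed 1 --outdir run1
```

## Layout

- `src/thermoperf/synth.py` — synthetic study generator (all four inputs)
- `src/thermoperf/tpc.py` — curve families, AIC selection, parameter extraction
- `src/thermoperf/acclim.py` — repeated-measures trait models and contrasts
- `src/thermoperf/operative.py` — logger ingestion, daytime summaries, ANOVA, exceedance
- `src/thermoperf/calibration.py` — surrogate-temperature validation
- `src/thermoperf/pipeline.py`, `cli.py` — orchestration and the `thermoperf` command
- `docs/methods.md` — models, assumptions, numerical choices and limitations
- `examples/` — one short narrative script per capability
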