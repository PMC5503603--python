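# raitg

Semi-mechanistic modelling of serum thyroglobulin (Tg) kinetics and tumor
response in metastatic papillary thyroid cancer treated with repeated
radioiodine (RAI, ¹³¹I) courses.

Patients with RAI-avid lung metastases receive fixed activities
(3.7–5.5 GBq) every 6–8 months, with a stimulated Tg measurement before each
course. Whether a patient is responding is usually judged late, after many
cycles. This package implements a population model that turns the Tg series
into an estimate of the **tumor doubling time under treatment (Td)** — the
quantity that separates responders from non-responders — and supports that
call after as few as 3–4 courses.

## Model

Three coupled compartments, time in months:

```
dA/dt  = −a·ln2·A                A(t): effective RAI activity (GBq); each
                                 administration adds its activity A0; a is the
                                 decay rate of the delayed radiobiological
                                 effect, not the physical half-life
dN/dt  = (ln2/Td)·N − ρ·A·N      N(t): tumor cell count; exponential growth
                                 with doubling time Td against a log-linear
                                 kill term with efficiency ρ
dTg/dt = −ke·Tg + λ·N            Tg(t): serum thyroglobulin (µg/L), produced
                                 at λ per cell, eliminated at rate ke
```

`A` and `N` have closed forms (superposition of exponentials;
`N0·exp(ln2·t/Td − ρ∫A)`); `Tg` is evaluated by variation of constants with
controlled-accuracy quadrature.

The population layer is a nonlinear mixed-effects model: individual
parameters are log-normal around population medians, observations carry
proportional error `y = f·(1 + b·ε)`, and a latent two-category mixture acts
on `log Td` — category 1 (non-responders) is the reference, category 2
(responders) gains the covariate effect `βTd`, so the responder median is
`Td·exp(βTd)`. Estimation is a stochastic-approximation EM (SAEM) with a
Metropolis-within-Gibbs E-step and closed-form M-steps; per-patient calls
come from Laplace-approximated category posteriors.

Because no patient-level data are publicly deposited for this setting, the
package ships a first-class synthetic-cohort generator that reproduces the
study design (50–200 patients, 3–8 cycles, pre-dose sampling) from the
published population estimates, so every stage — forward model, fit,
classification, diagnostics — is testable end to end.

## Worked example

```python
from raitg import (CohortDesign, FitConfig, PopulationParameters,
                   fit_population, generate_cohort, group_summary, vpc)

truth = PopulationParameters.study_estimates()
cohort = generate_cohort(truth, CohortDesign(n_patients=200), seed=1)

config = FitConfig(n_burnin_iters=500, n_smoothing_iters=400, seed=2, initial=truth)
fit = fit_population(cohort, config)

pop = fit.pop_hat
print(f"doubling time, non-responders: {pop.td_non_responder:5.1f} months")
print(f"doubling time, responders:     {pop.td_responder:5.1f} months")
print(f"non-responder proportion:      {pop.pi1:5.1%}")
print(f"residual error coefficient b:  {pop.b:5.3f}")
print(group_summary(fit)[["n", "median", "geomean"]].round(1))
check = vpc(cohort, pop, n_sim=200, seed=0)
print(f"VPC: {check.within.sum()}/{check.within.size} percentile checks inside the 90% band")
```

prints

```
doubling time, non-responders:   9.9 months
doubling time, responders:      63.0 months
non-responder proportion:      28.9%
residual error coefficient b:  0.357
         n  median  geomean
group
1       52     9.3      9.3
2      148    62.8     63.0
VPC: 20/21 percentile checks inside the 90% band
```

The cohort was generated with medians 9.8 / 66.6 months, mixture 27.5% /
72.5% and b = 0.372; the fit recovers them from the noisy Tg series alone
(ρ, a, λ fixed, as in the original analysis). The group summary shows the
per-patient empirical-Bayes doubling times split by posterior category, and
the visual predictive check confirms the fitted model reproduces the
observed Tg percentiles.

A command-line interface mirrors the library:

```bash
raitg simulate --config sim.yaml --out cohort.csv
raitg fit      --data cohort.csv --config fit.yaml --out fitdir/
raitg classify --data cohort.csv --fit fitdir/population.json --k 4 --out calls.csv
raitg vpc      --data cohort.csv --fit fitdir/population.json --out vpc.csv
```

Datasets use the long-format NONMEM/Monolix-style CSV
(`ID,TIME,DV,AMT,EVID`).

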