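# Methods

## Forward model

The kinetic system couples effective radioiodine activity `A` (GBq), tumor
cell count `N`, and serum thyroglobulin `Tg` (µg/L), with time in months:

* `dA/dt = −a·ln2·A`, with `A` jumping by the administered activity at each
  treatment. `a` (1/month) describes the decay of the *delayed biological
  effect* of the isotope on tumor cells — a continuous low-dose irradiation
  — not the 8-day physical half-life of ¹³¹I. The printed population value
  `a = 0.0169/month` implies an effect half-life of ≈ 59 months; the
  equation is implemented as stated.
* `dN/dt = (ln2/Td)·N − ρ·A·N`. Growth is exponential — adequate over a 3–4
  year observation window — with doubling time `Td` assumed constant under
  treatment. The kill term is log-linear in the instantaneous activity with
  efficiency `ρ`; its unit is `1/(GBq·month)`, which is what makes the
  equation dimensionally consistent.
* `dTg/dt = −ke·Tg + λ·N`, production `λ` per cell per month, first-order
  elimination `ke`.

Because the first two equations are linear, `A(t)` is the superposition
`Σ A0_j·2^(−a·(t−t_j))` over administrations, `∫A` is piecewise analytic,
and `N(t) = N0·exp(ln2·t/Td − ρ·∫₀ᵗA)` is exact. `Tg` follows by variation
of constants; the public `tg_trajectory` marches over the knots formed by
dose and observation times with adaptive quadrature at relative tolerance
1e−8, so solver error never contaminates likelihoods. Tests verify both
paths against brute-force ODE integration (`solve_ivp`, rtol 1e−10) to
relative error < 1e−6 (A, N) and < 1e−5 (Tg) on randomized instances.

Inside the fitting loops, a vectorised engine evaluates the same
variation-of-constants integral with fixed composite Gauss–Legendre panels
(4 panels × 12 nodes per inter-knot segment, panel length ≤ 2 months for
the study design). For elimination rates up to several per month the panel
error is orders of magnitude below the residual noise; the engine is tested
to agree with the adaptive path to ~1e−9 in log-likelihood.

## Statistical model

Individual log-parameters are normal around population means (so parameters
are log-normal, guaranteeing positivity): `log θ_i = log θ_pop + η_i`,
`η_i ~ N(0, ω_θ²)`. A latent two-category mixture acts on `log Td`:
category 1 (non-responders, prior probability `π1`) is the reference and
category 2 (responders) adds the covariate effect `βTd ≥ 0`, making the
responder median `Td·exp(βTd)`. Residuals are proportional:
`y = f·(1 + b·ε)`, `ε ~ N(0,1)`. Observations recorded as 0 (possible in
simulation, where negative draws are truncated and flagged) enter the
likelihood as left-censored at a limit of quantification (default
0.1 µg/L) through the normal CDF, so the stated error model is preserved.

Default generating values (the published population estimates for this
disease setting): medians `ρ = 0.00407`, `a = 0.0169`, `λ = 3.86e−9`,
`ke = 0.319`, `Td = 9.8` months, `N0 = 1.12e9` cells; log-scale IIV
`ω_ke = 1.16`, `ω_λ = 2.47`, `ω_Td = 0.3`, none on `ρ`, `a`, `N0`; mixture
`π1 = 0.275`, `βTd = 1.92` (so the responder median is 66.6 months);
`b = 0.372`.

### Identifiability

Only the product `λ·N0` enters the Tg scale, so the default fit fixes `λ`
(which the original analysis also fixed) and estimates `N0`; the large `λ`
variability in the generating truth is then absorbed by the `N0` random
effect, leaving the identified quantities unchanged. With pre-dose-only
sampling every 6–8 months, `(ke, N0)` additionally trade off along the
quasi-steady ridge `Tg ≈ λN/ke`, and the responder-arm likelihood is nearly
flat in `Td` above ~60 months: the published relative standard errors (21%
on `ke`, 44% on the responder `Td`) reflect exactly this geometry, and the
parameter-recovery tolerances used in the tests (30%) are motivated by it.

### Baseline Tg

`tg_trajectory` takes an explicit initial condition. Two conventions are
supported in fitting and classification (`tg0_mode`):

* `steady_state` (default): `Tg(0) = λ_i·N0_i/ke_i`, the individual's
  production–elimination equilibrium, with the t=0 measurement treated as an
  ordinary noisy observation. This is the coherent choice for patients
  arriving with established disease, and is exactly how the synthetic
  cohorts are generated.
* `observed`: `Tg(0)` pinned at the first measured value, which then cannot
  also contribute a residual. This mirrors analyses that treat the baseline
  as a known regressor, but it takes the baseline's measurement error as
  exact: on synthetic steady-state cohorts the estimated `ke` is driven
  systematically low because small `ke` lets predictions ride the shared
  baseline error, so it is not the default here.

## SAEM estimation

`fit_population` implements stochastic-approximation EM:

* **E-step** — Metropolis-within-Gibbs, vectorised across patients. The
  latent category is Gibbs-sampled from its conditional (given `ψ_Td` it
  depends only on the Gaussian prior). Random effects are updated by (i) an
  independence proposal from the current prior, which dominates where the
  individual likelihood is flat, (ii) adaptive random-walk refinements
  (target acceptance 0.35), (iii) a joint category-switch move that flips
  the category while shifting `log Td` by `±βTd` (preserving the random
  effect), letting the chain cross between the well-separated mixture
  modes, and (iv) a correlated `(ke, N0)` move along the `λN0/ke` ridge.
* **SA-step** — exhaustive sufficient statistics smoothed with step size 1
  during burn-in and `k^(−α)` (default α = 1) afterwards. The mixture
  statistics are Rao-Blackwellised: the category is marginalised exactly
  given `ψ_Td`, removing label-sampling noise from the mixture updates.
* **M-step** — closed forms: Gaussian mean/variance updates for the log
  effects, a two-group regression for `(μ_Td, βTd)`, the expected category
  frequency for `π1`, and the root-mean-square relative residual for `b`.
  Category 1 is kept the smaller-`Td` group by relabelling whenever an
  update would make `βTd` negative, so estimates are comparable across
  runs.

Numerical safeguards (all active by default): the retained chain likelihood
is refreshed after each M-step because `b` enters it; during burn-in the
variance parameters anneal (shrink at most 5% per iteration) so the chain
keeps exploring; `b` is capped at 2.0 — a proportional CV beyond 200% only
arises transiently from unadapted states, and an inflated `b` flattens the
likelihood in a self-reinforcing way; estimated ω's have a floor of 0.01.
Records are canonically sorted by patient id, making estimates invariant to
dataset order, and all randomness flows from the config seed.

Initial values (`init_strategy="naive"`): per-patient log-Tg slopes are
corrected by the mean activity to growth rates, converted to doubling
times, and split by an exact 1-D two-means; `N0` starts from baseline
intercepts via `Tg·ke/λ`; `ke` starts at 0.5/month (a generic serum-protein
clearance scale) with a wide prior. Convergence is declared when every
tracked parameter's per-iteration relative change stays below the tolerance
(default 1e−3) over the final 50 smoothing iterations; failing that, the
result carries `converged=False` as a warning, not an error.

`choose_fixed_parameters` reproduces the practice of pinning parameters
whose exploratory-fit uncertainty is negligible; absent Fisher-information
machinery, its proxy is the stability (sd/mean) of the SAEM parameter trace
over the smoothing window. It is a screening heuristic, not a standard
error.

## Classification and early prediction

`posterior_category` computes `P(cat=1 | data) ∝ π1·m1(y)` with
per-category marginal likelihoods `m_c` by Laplace approximation around the
empirical-Bayes mode in standardized random-effect space (the shared
`(2π)^{d/2}` factors cancel; Hessians are finite-difference, eigenvalue-
floored). A record with no observations falls back to the prior `π1`
exactly. On a worst-case synthetic cohort, replacing Laplace by a
4000-draw Monte-Carlo marginal changed accuracy by under one percentage
point, so the approximation is not the accuracy bottleneck — the ~90%
ceiling is the Bayes limit of the generating conditions (five-ish noisy
observations per patient).

`classify_patient` calls non-responder iff the posterior reaches the
threshold (default 0.5; ties conservatively flag treatment failure), and
reports the doubling-time EBE under the more probable category.
`early_predict` applies the identical pipeline to the first `k`
observations (k ≥ 3, mirroring decision-making after 3–4 courses) against
the frozen population fit — only individual-level quantities are
re-estimated, never the population.

## Visual predictive check

`vpc` simulates replicate cohorts (default 200) under the fitted population
with the original regimens and observation schedules — new individuals,
steady-state baselines, proportional noise — and compares empirical
10/50/90 Tg percentiles per time bin with the central 90% interval of the
simulated percentiles. Bins are quantile-based (default 8) because
observation times cluster at cycle boundaries; bins holding fewer than 5
observations are merged into their smaller neighbour and flagged.

## What the synthetic cohorts emulate — and what they do not

The generator reproduces the study design: 3–8 cycles (eligibility floor 3;
8 the maximum course count reported), activities uniform on 3.7–5.5 GBq,
intervals uniform on 6–8 months, one pre-dose stimulated-Tg sample per
cycle (Tg is continuous, so the pre-dose value is the value at the dose
time), per-patient substreams keyed by (seed, id). Baselines are the
individual steady state. Not emulated: imaging endpoints, anti-Tg antibody
interference, TSH dynamics, time-varying doubling times (reported to
decrease over time in responders), dropout, or irregular visit schedules.
Passing tests therefore demonstrate correctness of the machinery under the
stated statistical model, not robustness to these real-data features.

## Problem sizes used in the test suite

Parameter recovery uses one 200-patient cohort with 500 burn-in and 400
smoothing iterations (~15 s); classification checks use a 200-patient
cohort against the generating population; VPC self-consistency pools five
replicate checks of 200 simulations each over a 50-patient cohort. These
sizes put Monte-Carlo noise well inside the stated tolerances while keeping
the whole suite under a minute of compute.

## Known limitations

* The responder-arm doubling time and the mixture proportion are weakly
  identified at n = 200 under the study design; across replicate cohorts
  their estimates scatter with SDs of roughly 30% and 16% respectively
  (essentially unbiased in the mean). Single-cohort results should be read
  with the published R.S.E.s in mind.
* Standard errors of population estimates are not computed (no
  Fisher-information or bootstrap machinery by default).
* The Laplace category posterior can be off by a few percent in probability
  for patients with very short series; calls near the threshold deserve the
  full-data refit.
* `b` estimation ignores censored observations in its closed-form update
  (they still contribute to the likelihood itself).
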