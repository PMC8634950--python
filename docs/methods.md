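# Methods

## Model structure

The package implements a three-state partitioned survival model (PSM) for a
two-arm comparison in second-line advanced/metastatic oesophageal squamous
cell carcinoma: camrelizumab monotherapy versus chemotherapy (docetaxel or
irinotecan, blended 50/50 within one arm). State occupancy at time *t* is
read directly off the arm's survival curves, with no transition
probabilities:

```
PFD(t)  = S_PFS(t)                    progression-free disease
PD(t)   = max(S_OS(t) - S_PFS(t), 0)  progressive disease
dead(t) = 1 - S_OS(t)
```

The whole cohort enters in PFD. If `S_PFS` exceeds `S_OS` by more than 0.02
anywhere on the cycle grid the curve pair is rejected as inconsistent;
smaller excesses (numerical noise) are clamped and counted.

Settings (defaults in parentheses): cycle length (1 month), horizon (120
months), annual discount rate (5%, compound, evaluated at the cycle
midpoint), willingness-to-pay thresholds at 1-3x China's 2020 per-capita GDP
($10,503.52/QALY), body surface area 1.72 m². Cost and utility accrual uses
trapezoidal (half-cycle corrected) occupancy — the mean of a cycle's start
and end occupancy — which converges to the continuous integral; a flag
switches to start-of-cycle accrual.

## Survival extrapolation

Six parametric families are supported, all with time in months and a
(shape γ, scale λ) pair:

| family      | S(t)                           |
|-------------|--------------------------------|
| exponential | exp(−λt)                       |
| weibull     | exp(−λ t^γ)                    |
| gompertz    | exp(−(λ/γ)(e^{γt}−1))          |
| log-logistic| 1/(1+λ t^γ)                    |
| gamma       | shape/scale (upper regularized gamma) |
| lognormal   | γ = sdlog, λ = exp(meanlog)    |

The log-logistic form is the one the source analysis states; the others
follow common health-technology-assessment conventions. Fitting maximizes
the right-censored log-likelihood (events contribute the density, censored
records the survivor function), with parameters optimized on the log scale
(unconstrained), three starting points, and Nelder-Mead; non-convergence is
reported through a flag, never an exception. Model choice takes the lowest
AIC among converged fits, ties broken by BIC, then by parameter count.

Base-case curve parameters (log-logistic, t in months):

| arm | endpoint | γ | λ |
|---|---|---|---|
| camrelizumab | PFS | 2.0011 | 0.1471 |
| camrelizumab | OS  | 1.2879 | 0.04461 |
| chemotherapy | PFS | 3.1368 | 0.08394 |
| chemotherapy | OS  | 2.1592 | 0.01946 |

The published Weibull camrelizumab-OS scale is printed as −0.04380, which is
impossible under exp(−λt^γ); the loader substitutes |λ| and records a warning
in the run manifest (the config key can be overridden with a corrected
value).

## Pseudo-IPD reconstruction

Digitized Kaplan-Meier coordinates plus a numbers-at-risk table are inverted
to patient-level records interval by interval: within each risk-table
interval, censorings are assumed uniformly spread; event counts at each
digitized step are solved from the relative survival drop
(d = round(n·(1 − s_k/S))); and the censoring total is iterated until the
reconstructed number at risk at the interval end matches the published
count. Patients remaining after the last interval are censored at the last
observed time. The procedure is deterministic, conserves the patient count
exactly, and is exact (event times and counts recovered perfectly) when the
risk table covers every event time and there is no censoring. The KM
estimator uses the standard product-limit form with right-continuous steps
and events processed before censorings at tied times. Digitization jitter up
to 0.005 absolute is clamped by a running minimum; larger monotonicity
violations are rejected as bad data rather than silently rewritten.

## Costs and utilities

Direct medical costs only: drug acquisition, follow-up, best supportive care
(BSC, the assumed post-progression treatment), and grade ≥3 severe adverse
event (SAE) management. Dosing: camrelizumab 200 mg flat every 14 days
(capped at 6 courses in the fixed-course scenario), docetaxel 75 mg/m² every
21 days (3 courses), irinotecan 180 mg/m² every 14 days (4 courses).
Administrations per monthly cycle are fractional (30.4375 days / interval);
a course cap converts to a treatment-duration cut-off of cap x interval.
Drug and SAE costs accrue on PFD occupancy while on treatment (flag:
alive occupancy); follow-up cost accrues on alive occupancy (the published
outcome table books it in both the PFD and PD rows); BSC on PD occupancy.
SAE management cost accrues per treatment cycle as expected incidence x unit
cost (the published SAE totals scale exactly with the drug totals across
scenarios, which identifies this timing). Utilities: PFD 0.741, PD 0.581;
SAE disutilities (anemia −0.074, neutropenia −0.090, vomiting −0.048) apply
during treatment, weighted by incidence. QALYs and life-years are
discounted like costs; QALYs can never exceed life-years.

## Sensitivity analyses

*One-way*: each parameter is moved to its published bounds (95% CI or ±25%;
camrelizumab price 50% downward only; discount rate 0-8%; the neutropenia
management-cost bounds are printed swapped in the source and are stored
sorted) with everything else at base; the tornado table is sorted by ICER
swing.

*Probabilistic*: 10,000 Monte-Carlo draws. Utilities, disutilities
(magnitude) and incidences are beta-distributed; costs gamma-distributed;
both moment-matched so the mean equals the base value. Dispersion: se =
(high − low)/(2·1.96) when a published range exists, otherwise 25% of the
mean. Survival-curve parameters are *not* varied by default — no ranges are
published for them and varying them at an invented dispersion changes the
acceptability curve qualitatively (negative incremental-QALY draws appear);
`vary_survival=true` samples them log-normally with a 10% log-scale sd. The
CEAC reports P(WTP·ΔQALY − ΔCost > 0); a draw with zero net monetary benefit
counts as not cost-effective. With frozen curves the engine's exposure sums
are computed once and per-draw totals are evaluated vectorized; a test
verifies draw-by-draw equality with full model re-evaluation.

## Synthetic data

The generator stands in for trial data that were never deposited. Per
patient a shared uniform drives inverse-CDF draws of OS and latent PFS
(comonotone coupling, PFS truncated at OS so progression never follows
death), followed by administrative censoring at the accrual horizon (24
months by default, matching the trial's follow-up scale) and optional
exponential loss to follow-up. Default cohort sizes mirror the trial: 228
and 220 per arm. `digitize` samples the KM curve on a grid (2-month default)
with bounded uniform noise ≤ 0.005 and the true at-risk counts. What passing
pipeline tests show: the reconstruction/fitting chain recovers generating
curves from digitizer-shaped evidence under clean step coordinates and
honest risk tables. What they do not show: robustness to systematic
digitization bias, mis-read risk tables, or informative censoring, none of
which the generator emulates.

## Reproducibility of the source analysis

Two findings from reconciling the published outcome table against the
published inputs, both preserved in the packaged replication configuration
and surfaced rather than hidden:

1. **Currency scale.** The published follow-up/BSC/SAE cost rows are
   consistent with the table's own QALY/LY rows only if those unit costs
   enter at ~6.9x their printed USD values — the stated 6.8974 CNY/USD
   conversion — while drug costs are consistent with USD prices as printed.
   The replication configuration therefore applies
   `costs.non_drug_unit_scale: 6.8974`; setting it to 1.0 gives a strict
   all-USD reanalysis (which roughly halves the incremental cost).

2. **Camrelizumab OS curve.** The printed camrelizumab OS parameters imply a
   discounted alive-time of ~20.3 months over the horizon, while every row
   of the published outcome table implies ~16.0 (life-years 1.33; PD QALYs
   0.56/0.581; the follow-up cost row); the printed curve's median (11.2
   months) also exceeds the trial's reported median OS, whereas the
   chemotherapy arm's parameters match their table rows and trial median
   closely. The printed input is almost certainly mistranscribed, but no
   published value permits a correction that is not itself fitted to the
   outcome table, so the printed value is used as-is. Consequently the
   camrelizumab QALY total computes to ~1.03 (published 0.83) and
   quantities downstream of that arm's PD tail (incremental cost, drug-cost
   share, the PSA cloud) deviate beyond the 10%/0.05-QALY reproduction
   bands, while ratio quantities in which the inflation largely cancels
   (the scenario-1 ICER, the camrelizumab total cost) land within a few
   percent. The acceptance suite asserts the stated bands regardless, so
   these checks fail visibly instead of being widened.

## Numerical choices and limitations

Occupancy conservation holds to 1e−12 and death occupancy is monotone by
construction. Discounting is per-cycle compound; halving the cycle length
changes totals by <1%. The engine is deterministic; all stochastic results
are reproducible from a single integer seed through `numpy`'s `default_rng`.
Not implemented (out of scope): spline/cure survival models, covariate
adjustment, interval censoring, Markov microsimulation, grade ≤2 adverse
events, EVPI, correlated PSA sampling, and image-based curve digitization
(coordinates are accepted as CSV).
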