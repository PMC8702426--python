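# Methods

This note records the model, the conventions chosen where the published
analysis left the design open, and what the synthetic-data calibration does
and does not establish.

## Model structure

A three-state Markov cohort model (progression-free, PFS; progressed, PD;
dead) with a 3-week cycle.  The whole cohort starts in PFS.  Per-cycle exit
probabilities come from fitted parametric survival curves:

* `p_death(k) = 1 − S_OS((k+1)Δ)/S_OS(kΔ)`, applied identically from PFS
  and PD — only one OS curve exists per arm, so no state-specific death
  hazard is identifiable;
* `p_progress(k) = max(0, p_exitPFS(k) − p_death(k))`, the residual PFS
  exit probability.  Where sampling noise puts the fitted PFS curve above
  the OS curve the progression probability is floored at zero and a warning
  is emitted.

The horizon is "lifetime", operationalized as: stop when the alive fraction
falls below 1e-4 or at 520 cycles (30 years), whichever comes first.  Costs
and health outcomes are discounted at an annual 5% (range 0–8%) with
`d(k) = (1+r)^(−kΔ/w)`, `w = 365.25/7` weeks per year.  No half-cycle
correction by default (the original analysis does not mention one); it is
available as a config switch.

## Accrual conventions

* **Drug cost** follows the *on-treatment* fraction: PFS occupancy scaled
  by the ratio of median time on treatment to median PFS, set to zero
  beyond the treatment cap.  The trial reports substantial early
  discontinuation but not the ratio itself; the default is 0.85 (invented,
  config-exposed).  Scaling the cost side rather than the survival side
  keeps the intention-to-treat curves intact.
* **Induction** is 4 cycles of triplet (or doublet) therapy (the trial
  allowed 4–6; 4 is the default, configurable), then maintenance;
  camrelizumab-arm treatment is capped at 35 cycles (2 years of 3-week
  cycles, rounded up).  The chemotherapy arm has no cap (pemetrexed until
  progression).
* **Adverse events** (grade 3–4 neutropenia, anemia, thrombocytopenia at
  the published arm-specific risks) are charged once at model entry, and
  their disutilities applied for one cycle's duration — severe toxicity of
  these regimens concentrates in the first cycles, and the source analysis
  does not state a timing.
* **Subsequent therapy** after progression reaches 58% (camrelizumab arm)
  and 70% (chemotherapy arm) of progressors, for at most 6 cycles per
  patient; eligibility is tracked by aging each cycle's incident
  progression cohort with the death hazard.  Everyone else in PD accrues
  best supportive care.  The per-cycle price of subsequent therapy is a
  weighted mix over the published second-line drug costs; the weights are
  **invented** (the trial's regimen breakdown is not public) and flagged in
  `synthetic_data.SUBSEQUENT_MIX`.  In the crossover-adjusted scenario the
  control-arm mix contains no PD-1 antibody, matching the question that
  scenario asks (camrelizumab vs chemotherapy *without* later PD-1 use).
* **Routine follow-up** is charged for everyone alive (the alternative —
  PFS only — is a config switch); **palliative care** once per incident
  death.

## Pseudo-IPD reconstruction

Events in risk-table interval *j* follow the relative drop of the digitized
curve, counted against the censoring-depleted risk set:
`e_j = round(n_{j+1}(S(start)/S(end) − 1))`, with censorings
`c_j = n_j − n_{j+1} − e_j` (floored at 0) spread uniformly over the
interval, which places them (in time) before the interval's digitized event
steps.  Solving the KM identity for `e_j` under exactly that placement
makes the re-estimated KM reproduce the digitized drops; the naive
allocation against the start-of-interval risk set drifts low by up to 0.17
sup-norm under heavy censoring.  The final interval applies the drop to the
remaining cohort and absorbs the rounding residue as censorings at the end
of follow-up, so reconstructed records always sum to the initial n.  A
round trip (simulate → digitize → reconstruct → KM) stays within 0.02
sup-norm wherever at least ~30 subjects remain at risk; below that, integer
allocation cannot represent the drops (published curves are normally
truncated before that point too).

## Survival fitting

Right-censored maximum likelihood for exponential (closed form λ = events /
follow-up), Weibull `S = exp(−(t/λ)^k)`, log-logistic `S = 1/(1+(t/λ)^k)`
and log-normal `S = Φ̄((ln t − μ)/σ)`.  Two-parameter families are
optimized by Nelder-Mead on log-transformed parameters from three starting
points (multi-start guards against local optima; positivity is enforced by
the transform).  AIC is the headline selection criterion (BIC is reported
alongside); ties break toward fewer parameters, then family listing order.
On the synthetic fixture the selected OS family is often log-logistic or
log-normal rather than Weibull — the crossover mixture and the OS ≥ PFS
conditioning genuinely thicken the tail — and which family wins can flip
between seeds at trial-size n.  This extrapolation sensitivity is a real
feature of the method, and is why reported pipeline quantities use large
simulated cohorts (below).

## RPSFT crossover adjustment

One-parameter model `U(ψ) = (T − T_on) + e^ψ T_on`, re-censored at
`D*(ψ) = min(C, C e^ψ)`; subjects without an administrative censor time get
the arm maximum.  ψ is g-estimated on a grid (default [−3, 1], step 0.01)
by zeroing the two-sample log-rank Z with linear interpolation at the sign
change; no sign change returns the minimizing ψ flagged non-converged.

Two exposure conventions are implemented because the one-parameter model
can place the experimental arm on either side of the comparison:

* **control-side** (default): only control-arm switch exposure is
  transformed.  Consistent when the acceleration acts through crossover
  exposure alone (no direct arm effect) — the configuration used for the
  ψ-recovery validation.
* **treatment-group** (`experimental_on_treatment=True`): the experimental
  arm counts as treated from randomization and is transformed too.  This is
  the common-treatment-effect assumption of the classical formulation and
  is what the pipeline uses on the fixture, where the arms genuinely differ:
  balancing a transformed control arm against an untransformed *effective*
  experimental arm would push ψ̂ positive and invert the adjustment.

The ψ-recovery check runs at n = 2,000/arm, where the estimator's
single-trial sd is ≈ 0.05; accuracy is therefore asserted on the mean of 20
replicates (each at the stated n) rather than on one draw.

Hazard ratios come from a single-covariate Cox partial likelihood (Breslow
ties) maximized by Newton iteration with step clipping; tests check it
against a brute-force grid maximization and an independent implementation.

## Synthetic trial generator

Per arm: PFS ~ Weibull; OS ~ Weibull conditioned on OS ≥ PFS, sampled
exactly by inverting the truncated survival function (identical in law to
rejection resampling, but with guaranteed termination for extreme PFS
draws).  Administrative censoring at 40 months.  Control progressors switch
with probability 0.46 at progression; their post-progression time is
multiplied by `e^{−ψ}` — the exact generative inverse of the RPSFT model,
making ψ recovery well-posed.  Arm size defaults to 205/arm (invented; the
publication does not print arm sizes).

Calibration targets the published summaries: PFS parameters are analytic
(shape 1.656 both arms, scales 61.30/45.03 weeks ⇒ medians 11.3/8.3 months
and HR 0.60 exactly under proportional hazards).  OS parameters were tuned
numerically at n = 40,000/arm because the OS ≥ PFS conditioning inflates
observed OS well above the nominal Weibull medians: scales 106/48 weeks,
shape 1.4, ψ_true = −1.45 yield observed medians 27.3/20.2 months and an
unadjusted OS HR of 0.726 (targets 27.9/20.5 and 0.73).  Under the
conditioning coupling the crossover acceleration had to exceed the
between-arm AFT gap to reproduce both the control median and the hazard
ratio, so the fixture world is deliberately *mis-specified* for the
common-effect RPSFT: the treatment-group ψ̂ on the fixture (≈ −0.32 at
large n) is an attenuated compromise, not ψ_true.  Its sign and the
direction of every downstream comparison are what the scenario analysis
relies on, and those are stable.

What the generator does **not** emulate: dependent censoring, accrual
ramps, PD-L1 subgroup biology (an alternate parameter set only),
time-varying hazard ratios, and adverse-event time series.  Passing tests
therefore demonstrate correctness of the machinery under a clean
Weibull-with-crossover world, not fidelity to the unavailable patient-level
data — which is also why the published absolute totals (e.g. $19,921 /
0.86 QALY) and CEAC percentages are not reproduction targets; directional
and structural properties are.

## Probabilistic and deterministic sensitivity analysis

One-way DSA re-evaluates the incremental result at each parameter's printed
bounds (±20% costs, ±10% utilities and AE risks, discount 0–8%), sorting
the tornado by ICER spread; evaluation failures are flagged on the entry
rather than dropped.  PSA draws costs from Gamma and
probabilities/utilities from Beta distributions, moment-matched with mean =
base value and sd = (high − low)/3.92 (the printed range read as a 95%
interval; the original parameterization is unstated).  The discount rate is
fixed in PSA.  Failed draws are excluded and counted.  CEAC(λ) is the
fraction of draws with positive net monetary benefit λ·ΔQALY − ΔCost on a
WTP grid of 0–100,000 by 1,000.  Because parameter uncertainty touches only
costs, risks and utilities, cohort traces are computed once and re-accrued
per draw.

## Problem sizes and determinism

Calibration checks run at n = 10,000/arm; ψ recovery at n = 2,000/arm × 20
replicates; the Markov engine is validated against a 100,000-subject
microsimulation; reported pipeline quantities use n = 10,000/arm with 1,000
PSA draws.  Every random stage takes an explicit seed; re-running any stage
with unchanged inputs reproduces byte-identical artifacts, and the run
manifest records the config hash and seed.

## Known limitations

* The subsequent-therapy mix and time-on-treatment ratio are invented
  placeholders for unavailable trial details; absolute cost totals shift
  with them (the tornado quantifies by how much).
* AE costs/disutilities as one-off entry effects understate toxicity that
  recurs across cycles.
* The single death hazard from both alive states ignores any
  post-progression excess mortality beyond what the OS curve carries.
* Family selection at trial-size n is unstable between seeds (extrapolation
  sensitivity); conclusions at the WTP threshold can flip with it.
* The control-side RPSFT default is only consistent absent a direct arm
  effect; analysts applying it to real data with an effective experimental
  arm should use the treatment-group convention, as the pipeline does.
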