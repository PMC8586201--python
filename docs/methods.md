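# Methods

## Model structure

Two-arm Markov cohort model for HFrEF: add-on empagliflozin (10 mg/day) vs
standard therapy alone. States are *alive with stable heart failure* and two
absorbing death states (cardiovascular, non-cardiovascular); hospitalization
for heart failure (HHF) is a transient within-cycle event — the acute stage
is assumed to last one month, hence the 1-month cycle, and survivors return
to stable HF. Within a cycle the three event processes are independent
expected-value streams applied to the alive fraction: HHF and death may
co-occur in the same cycle, and hospitalized patients face no elevated
death risk in that month. Transition probabilities are constant in time and
age. Deaths are removed from the alive fraction at the end of the cycle in
which they occur.

Monthly probabilities come from cumulative event proportions over a
16-month trial follow-up under a constant-hazard assumption,
`p_month = 1 − (1 − p_16)^(1/16)`. The bundled Taiwan inputs are already on
the monthly scale; back-converting them yields 16-month proportions of
roughly 18.3%/13.2% (HHF), 10.8%/10.0% (CV death) and 3.4%/3.3% (non-CV
death) for standard therapy/empagliflozin respectively. The "all-cause
death" input row is interpreted as *non-CV* death: treating it as a third
disjoint exit alongside CV death is the only reading that avoids
double-counting CV deaths and it reproduces the published 15-year mortality
(79.3%/81.4%) exactly.

## Accounting conventions

Where a convention was genuinely open, the default was chosen to reproduce
the published Taiwan analysis, and the textbook alternative is exposed as a
flag on `ModelSettings`:

- **Occupancy counting** (`occupancy_counting`, default `"boundary"`). The
  published totals credit state membership at both boundaries of each cycle
  — every alive cycle contributes *two* month-equivalents to life-years,
  utilities and the monthly (drug + chronic care) costs, while event
  rewards (HHF cost and disutility, the one-off pre-death costs) are
  credited once per event. This is characteristic of cohort software
  configured with both an initial and a final stage reward. The published
  life-years make this unambiguous: 12.89/12.42 discounted LY cannot arise
  from once-per-cycle accounting over a 15-year horizon (an immortal cohort
  would accrue at most 12.14), and the published half-drug-price scenario
  implies a discounted drug-occupancy of 155.3 months — exactly twice the
  once-per-cycle value. `"single"` gives standard accounting; it roughly
  halves costs, QALYs and LYs while moving the ICER per QALY by only a few
  percent (the ratio is scale-invariant in its occupancy-driven parts).
- **First cycle** (`first_cycle_event_free`, default `False`). The
  published cohort outcomes (mortality 79.3%/81.4%; 803 vs 1,099 HHF per
  1,000) match event accrual from cycle 1 exactly; the flag suppresses all
  cycle-1 events when set.
- **Discounting** (`discount_mode`, default `"monthly_compound"`): factor
  `(1+r)^(−(t−1)/12)`, cycle 1 undiscounted. `"annual_step"` discounts by
  whole elapsed years. The two differ by <0.1% on the ICER.
- **Age decrement** (`age_decrement_basis`, default `"credited"`). The
  −0.0016/yr utility decrement runs on credited time (2 months per cycle
  under boundary counting), consistent with the occupancy convention;
  `"calendar"` uses 1 month per cycle.
- **Half-cycle correction** (`half_cycle_correction`, default off): averages
  start- and end-of-cycle occupancy before the counting weight is applied.
- Dead states accrue nothing; pre-death costs are one-off, cause-specific,
  in the cycle of death; the HHF disutility (−0.321, annual scale) applies
  for exactly the event month, prorated by 1/12.
- If the age decrement would drive utility negative the utility is clamped
  at 0 with a logged warning (cannot happen with the bundled inputs inside
  the 15-year horizon).

Under these defaults the base case gives ICER US$20,088/QALY vs the
published 20,508 (−2.0%), with every component that the published scenario
rows pin down (drug occupancy, per-arm discounted HHF events, mortality,
HHF counts) matched to ≲1%; the residual traces to arithmetic
inconsistencies among the published rows themselves, whose own half-cost
scenarios decompose the incremental cost as ≈7,160 rather than the printed
7,402.

## Input parameters

| parameter | default | units | role |
|---|---|---|---|
| p_hhf, p_cvd, p_ncd (per arm) | Taiwan trial-derived (e.g. 0.0126 HHF, standard arm) | /month | transition probabilities |
| drug_cost | 35 (intervention), 0 (comparator) | US$/month | add-on acquisition cost |
| u_stable | 0.770 | – (annual) | stable-HF utility |
| u_age_decrement | −0.0016 | /year | utility lost per year of age |
| u_hhf_decrement | −0.321 | – (annual) | hospitalization month disutility |
| cost_stable | 450 | US$/month | chronic HF care |
| cost_hhf | 2,887 | US$/event | acute hospitalization |
| cost_pre_cvd / cost_pre_ncd | 3,430 / 3,390 | US$ one-off | terminal-month care |
| discount_rate_annual | 0.03 | /year | costs and outcomes |
| start_age / horizon | 67 / 180 cycles | years / months | cohort settings |
| wtp_1x / wtp_3x | 25,000 / 75,000 | US$/QALY | classification thresholds |

Country settings are YAML files (schema `empacea-setting/1`); numeric leaves
are either scalars or `{mean, se}` pairs, the SEs feeding the PSA.

## Sensitivity analyses

*One-way (tornado):* every input is perturbed ±10% one at a time
(arm-specific inputs per arm, shared inputs jointly), the model rerun, and
bars sorted by ICER range. Entries store the *signed* ΔCost/ΔQALY ratio so
that perturbations which flip the intervention to dominated (e.g. raising
its CV-death probability above the comparator's) remain well defined.
Perturbations that would leave a parameter's admissible range are clamped
to the boundary and logged. With the bundled inputs the ranking is CV-death
probability ≫ non-CV-death probability > stable-HF utility and chronic
cost, matching the published tornado.

*Scenarios:* named override sets (`scenario_suite`) reproduce the
published suite — intervention risk set equal to the comparator's (CV
death, non-CV death, HHF), half drug / half HHF cost, 16-month and 30-year
horizons, 0%/10% discount rates. Overrides are pure (the base setting is
never mutated). One published row (equal HHF risk) is arithmetically
inconsistent with the same publication's half-HHF-cost rows and is
reproduced per its definition, not its printed value.

*Adverse events:* generic expected-value streams (per-arm monthly
probability, cost per event, utility decrement for the event month) added
to the accumulation, supporting extended-model analyses without changing
the state structure.

*Threshold price:* the ICER is affine and strictly increasing in the
intervention drug price (slope = discounted drug-occupancy months; ΔQALY
unaffected), so the price at which ICER = WTP is found by bracketed
root-finding on NMB over [0, 10× base price], tolerance US$0.01, verified
by a round-trip property test. Note the published threshold-price row is
consistent with a base-case ICER near 21,500 US$/QALY rather than the
published base case itself (four of its five prices fall on that line); a
model that reproduces the published base case therefore solves ≈US$34.8 at
WTP 20,000, not 31.5.

## Probabilistic sensitivity analysis

Each of n = 1,000 iterations draws every uncertain input: beta
(method-of-moments from mean and SE) for probabilities and utilities —
negative decrements sampled on the magnitude and negated — and gamma for
costs. Utilities and costs are shared across arms within a draw.

Two structural choices, both exposed as arguments:

- **Arm coupling** (`couple_arms=True`): the two arms' probabilities for
  the same event type share one quantile, mapped through each arm's own
  beta. This preserves the relative treatment effect across draws, as when
  baseline risk and relative effect are sampled. Fully independent per-arm
  sampling makes the *sign* of the incremental QALYs essentially a coin
  flip (the arms' CV-death distributions overlap heavily), which collapses
  the CEAC to ≈0.6 at every WTP and cannot produce the published curve.
- **Subject-level sampling** (`n_subjects=1865`, half the 3,730-patient
  two-arm trial the probabilities derive from): each iteration simulates
  that many patients per arm at the drawn parameters — death month
  geometric at the arm's monthly all-cause probability, cause assigned
  proportionally, HHF count binomial over the months alive — and averages
  their discounted outcomes under the same accounting conventions as the
  cohort model. The draws therefore carry the first-order sampling noise
  of a trial-sized cohort on top of second-order parameter uncertainty
  ("subjects randomly sampled"). `n_subjects=None` gives a pure
  second-order PSA whose draw means converge to the deterministic base
  increments (verified within 3 SE at n = 10,000).

Numerical choice: within a patient's lifetime, each hospitalization is
valued at the mean discount factor of the patient's alive months; the event
*count* is exact, only its within-life timing is averaged, contributing
negligible variance relative to death-timing noise.

The CEAC reports, on a WTP grid of US$0–100,000 in steps of 1,000, the
fraction of draws with ΔQALY × WTP − ΔCost > 0. At the default seed the
Taiwan run gives 62.6% at 25,000 and 91.1% at 75,000 (published: 63.4% and
93.7%; seed-to-seed spread ≈ ±2–3 points at n = 1,000). All results are
bit-reproducible under a fixed seed.

## Synthetic trial generator

`simulate_trial` emulates the statistical structure the probability
derivation assumes: per patient, three independent constant-hazard monthly
Bernoulli processes (HHF, CV death, non-CV death) over a 16-month
follow-up, summarized as first-event proportions per arm. Event processes
are deliberately **not** censored by death, so the expected proportion is
exactly `1 − (1 − p)^16` and `derive_arm_parameters` (the proportion →
monthly-probability conversion) is exactly self-consistent; parameter
recovery at n = 50,000/arm lands within 3 binomial-propagated SEs of truth.
What this does not emulate: censoring of follow-up at death (a real trial's
HHF proportion would be a few percent lower at these hazards), competing
risks between the two death causes, randomization covariates, or
non-constant hazards. Passing recovery tests therefore validates the
derivation pipeline, not robustness to those real-data features.
`fabricate_country` produces schema-valid country settings (cost scaling,
bounded utility jitter) for multi-country runner tests.

## Problem sizes and determinism

All deterministic analyses run 180–360 cycles and complete in milliseconds;
the PSA (1,000 iterations × 2 × 1,865 subjects) takes ~1 s; synthetic
recovery tests use 50,000–100,000 patients/arm. Every stochastic component
takes an explicit integer seed (NumPy `default_rng`); there is no hidden
global state.

## Known limitations

- Boundary occupancy counting doubles absolute costs/QALYs/LYs relative to
  textbook cohort accounting; comparisons with other models should use
  `occupancy_counting="single"` or compare ICERs only.
- No half-cycle-corrected published targets exist, so the correction
  interacts with boundary counting only in the documented, untargeted way.
- Adverse events are expected-value add-ons, not states; recurrent-event
  correlation and time-varying hazards are out of scope.
- The PSA's subject-level noise model treats the cohort size as fixed and
  ignores within-patient event-timing variance for hospitalizations.
- Only direct medical costs are modeled; no societal costs, equity
  weighting, or value-of-information measures.
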