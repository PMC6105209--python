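# Methods note

`cardiovert` is a decision-analytic model of anticoagulation strategy around
elective electrical cardioversion (ECV) of atrial fibrillation (AF): a fixed
daily dose of rivaroxaban versus dose-adjusted vitamin K antagonists (VKA)
with INR monitoring, evaluated over a 1-year horizon from the societal and
the health-care payer perspective for a Dutch-style care setting.

## Model structure

The model is a **two-phase Markov cohort model**.

**Phase 1 — waiting for the procedure (daily cycles).** The cohort starts in
symptomatic AF on anticoagulation and waits for its scheduled ECV: 22 days on
rivaroxaban, 30 days on VKA (time to stable therapeutic anticoagulation).
Each day the waiting mass is exposed to ischemic stroke (IS), myocardial
infarction (MI), intracranial hemorrhage (ICH), major hemorrhage (MaH),
gastrointestinal hemorrhage (GIH), minor hemorrhage (MiH), spontaneous
conversion to sinus rhythm (SSR), and background death. Any clinical event or
SSR cancels the scheduled procedure (a cancellation within 48 h of the
procedure forfeits half the ECV tariff; an earlier one costs 30 minutes of
nursing time; SSR additionally incurs an outpatient consult). MiH is
transient: it costs its acute amount but does not exclude the patient from
the procedure.

On the scheduled day the waiting mass splits three ways: inadequately
anticoagulated patients (0.24% on rivaroxaban for either attempt; 44.19%
first / 20.00% second attempt on VKA) are cancelled last-minute and
rescheduled with a fresh full waiting period; the rest undergo the procedure,
converting to sinus rhythm with probability 86.4% or failing. A failed or
cancelled second attempt ends in permanent AF (at most two attempts).

**Phase 2 — after disposition (weekly cycles to 52 weeks).** States:
sinus rhythm, recurrent AF, permanent AF, post-IS, post-MI, post-ICH,
post-MaH, post-GIH — each split by on/off anticoagulation (ICH is a single
state because it terminates anticoagulation) — plus death; 16 state columns.
Sinus rhythm can relapse to recurrent AF. IS, MI and ICH are absorbing
(weekly follow-up costs and reduced utility); MaH and GIH are transient after
the procedure (acute cost, return to the originating state); MiH costs only.
Background mortality is age-specific (a step-function life table) and
advances with calendar time.

**Anticoagulation duration.** Everyone reaching sinus rhythm through a
performed ECV (or SSR) stays anticoagulated 6 weeks; afterwards only the
stroke-risk-eligible fraction continues — men with CHA₂DS₂-VASc ≥ 1 and women
≥ 2, i.e. `1 − [male·P(<1) + (1−male)·P(<2)] = 1 − (0.74·0.026 + 0.26·0.127)
= 0.94774`. Patients who enter the post phase without a performed
procedure (pre-ECV events, inadequately anticoagulated second attempts) are
split by that fraction immediately at entry.

## Numerical choices

* **Entry-cohort tunnels.** Post-phase cohorts are keyed by (entry day,
  6-week-window flag) and stepped weekly in lockstep, vectorized across
  cohorts. One full two-arm deterministic run takes ~13 ms, which makes a
  10,000-iteration PSA (~4.5 min) practical in pure NumPy.
* **Competing risks.** Within a cycle, survival is the joint-survivor product
  S = Π(1−pᵢ) and the event mass 1−S is allocated proportionally to the pᵢ.
  The micro-simulation samples from exactly this law, so the two routes agree
  in expectation by construction of the *law*, but not of the *arithmetic*.
* **Cycle accounting.** Occupancy accrues at the start of each cycle; event
  exits enter their post-phase state the following day. The final week
  truncated by the horizon accrues time pro rata but applies no transitions
  (an inert partial cycle); the engine and the micro-simulation implement the
  identical rule.
* **Rate/probability conversions.** Annual rates convert by `1−exp(−r·t)`,
  annual probabilities by `1−(1−p)^(t/365)`, with t in years; a year is
  365 days and the horizon is 52 weeks = 364 days.
* **Problem sizes** (this package's own choices): 52 weekly cycles, daily
  pre-ECV cycles, 10,000 PSA iterations in the acceptance run, 100,000
  simulated patients in the oracle comparison.

## Outcomes

QALYs are undiscounted occupancy × utility × time (no discounting at a 1-year
horizon); waiting counts as symptomatic AF, sinus rhythm as asymptomatic AF,
MiH has zero disutility. Costs per category: drug (per anticoagulated day),
INR monitoring (VKA only: 5.5 measurements per waiting period plus 21.1
thrombosis-service / 23.5 home measurements per on-treatment year, blended
56.9%/43.1%), the ECV tariff per performed procedure, cancellations, event
care (acute per incident event plus weekly follow-up per occupied
event-state), productivity loss, and informal care. Productivity and
informal-care costs accrue on the symptomatic share of AF time (70% while
waiting, 32% after disposition) and on all post-event occupancy (26 h/week
informal care for IS/MI/ICH, 8 h/week otherwise). The payer perspective
zeroes the last two categories. Comparisons report ΔC, ΔQ, the unrounded
ICER, net monetary benefit at €20,000/QALY, and a dominance label.

## Uncertainty analyses

* **PSA.** Beta distributions for probabilities and utilities, gamma for
  costs, both by method of moments from (mean, SE); drug prices and indirect
  unit costs stay fixed. Parameters shared between arms are stored once and
  hence drawn once per iteration. Each iteration uses its own
  `SeedSequence`-spawned substream. Outputs: CE plane, CEAC, probability of
  cost saving, both perspectives from one model pass.
* **Univariate scenarios.** Age ±20% (with the productivity unit cost
  re-derived from the demographics table at the shifted age), male share
  ±20%, VKA inadequacy ±20%, ECV success ±20% (clipped at 1), rivaroxaban
  waiting time 12/30 days, rivaroxaban nonadherence (inadequacy raised to the
  VKA level, one-sided), ECV-related costs ×0.5/×2, non-health-care costs
  ×0.5/×2. The tornado sorts by the incremental-cost span.

## Synthetic inputs and their limits

Headline quantities (waiting times, inadequacy and success probabilities,
cohort demographics, the CHA₂DS₂-VASc distribution, WTP, the INR monitoring
schedule, cancellation rules, symptomatic shares, informal-care hours) are
pinned at their published values. The remaining inputs — annual event
probabilities, state utilities (derived from a modified-EHRA class mix),
Dutch unit costs, the life table and labour-market table — are drawn from
documented plausibility ranges by `generate_parameter_set(seed)` and recorded
field-by-field in the provenance map. Consequences to keep in mind:

* Absolute cost and QALY levels depend on the synthetic unit costs and
  utilities; directional results (rivaroxaban cost-saving societally, mildly
  cost-increasing for the payer, small positive QALY gain) are robust across
  generator seeds, but magnitudes are not calibrated to any published table.
* Under the bundled inputs the payer-perspective mean ICER lands near the
  €20,000/QALY threshold, so the payer CEAC crosses ~0.5–0.6 at the
  threshold. That knife-edge behaviour is an artifact of where the synthetic
  draws place the increments, not a structural property.
* The generator enforces internal consistency (monotone symptom-class
  utilities, symptomatic ≤ permanent ≤ asymptomatic state utilities, a
  validating parameter set for every seed), verified by a 300-seed fuzz test.

## Validation

* Unit-cohort mass conserved to <1e-10 at every day; no resurrection.
* An equal-arm configuration yields exactly zero increments.
* A degenerate "forced pathway" (no events, certain first-attempt success)
  matches closed-form occupancy, QALYs and all cost categories to ~1e-12.
* The cohort engine agrees with an independently implemented 100,000-patient
  micro-simulation within 3 Monte-Carlo SEs on every reported quantity, in
  both arms.
* Method-of-moments distributions recover their declared moments at 1e6
  draws; a fully-fixed parameter set makes the PSA reproduce the
  deterministic result bit for bit.

## Limitations

One-year horizon with no discounting; no long-term sequelae beyond the
horizon. Transition probabilities are time-homogeneous apart from background
mortality. The cohort model tracks expectations only (no variance across
patients except via the micro-simulation). Half-cycle correction is not
applied; with daily/weekly cycles the discretization error is small relative
to parameter uncertainty. Costs are single-currency, single-year price
levels; no price indexation is modelled.
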