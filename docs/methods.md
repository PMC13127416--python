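# Methods

## Model structure

`adtcea` evaluates policies for giving a short (4–6 month) course of
androgen deprivation therapy (ADT) alongside radiotherapy in
intermediate-risk prostate cancer, using a deterministic Markov cohort
model with four health states:

1. **stable on ADT** — no evidence of disease, currently affected by ADT;
2. **stable off ADT** — no evidence of disease;
3. **metastatic** — distant metastatic disease;
4. **dead** (absorbing).

Cycles are one year; the default horizon is 15 cycles with cohort entry at
age 71. The on-ADT state is enterable only at model start and is occupied
for at most one cycle: survivors move to the off-ADT state, implementing
the assumption that ADT's utility effect lasts one year after initiation
(consistent with typical testosterone-recovery kinetics). The model has no
biochemical- or local-failure states; metastasis is the only disease event
short of death.

Each *strategy* is a probability mixture of homogeneous *arms* (e.g.
"biomarker-positive, receives ADT") with weights summing to one. Arms carry
a per-cycle metastasis-probability schedule and a one-time upfront cost
(test price if tested, ADT drug/administration cost if treated). ADT-bearing
arms enter in the on-ADT state, others in the off-ADT state.

### Transitions

Within a cycle, competing risks compose multiplicatively with other-cause
death applied first. From a stable state at cycle *t*:

- to metastatic: `p_met[t] · (1 − p_other[t])`
- to dead: `p_other[t]`
- stay (on-ADT survivors move off ADT): the remainder.

From the metastatic state, death occurs with
`1 − (1 − p_other[t]) · (1 − p_excess[t])`, where `p_excess` is the
cancer-specific excess death probability. The composition order is a
modeling convention and is stated here because conventions differ between
tools; at the probability magnitudes involved the alternative orderings
differ at the fourth decimal.

Other-cause mortality is shared by all strategies (the equal-overall-
survival assumption: the strategies' value difference is driven by
quality of life and cost, not survival). The default `p_death_other`
schedule is a bundled 15-value slice for ages 71–85 approximating a recent
US male period life table; it is synthetic (not transcribed from a
published table) and overridable in any spec file.

Deaths exiting the metastatic state count as cancer deaths; deaths exiting
stable states as other-cause. This decomposition drives end-of-life cost
allocation: each strategy pays the cancer end-of-life cost in proportion to
its own 15-year cancer-specific mortality, and the (lower) non-cancer
end-of-life cost for the remainder of its deaths, at the cycle of death.

### Accrual, discounting, half-cycle correction

Per-cycle rewards — utility weights (on-ADT, off-ADT, metastatic; dead = 0)
and the annual metastatic care cost — accrue on the trapezoidal average of
adjacent state occupancies when the half-cycle correction is on (the
default), or on end-of-cycle occupancy when off. Cycle-*t* accruals are
discounted by `(1 + r)^−t` with `r = 0.03`/year by default. One-time
transition costs are not half-cycle corrected: upfront costs apply
undiscounted at cycle 0; end-of-life costs apply at the cycle of death with
that cycle's discount factor. Note that with the trapezoid, a one-cycle
on-ADT occupancy contributes half a person-year at the on-ADT utility — the
standard consequence of treating transitions as mid-cycle events.

## Incremental analysis

Strategies are compared on the cost-effectiveness plane. Strict dominance
removes any strategy weakly beaten in both dimensions (exact duplicates
keep the first by input order, annotated "equivalent"). Extended dominance
removes interior strategies that break the non-decreasing ICER sequence
along the cost-sorted frontier — equivalently, strategies beaten by a
convex blend of their neighbours; the test suite checks this equivalence
against brute-force blend enumeration. Frontier rows report incremental
cost, incremental QALYs and the ICER versus the previous frontier strategy.
A cheaper-and-more-effective comparison is labelled **dominant** rather
than shown as a negative ICER; the raw signed ratio is retained separately
because published tables sometimes print it. Net monetary benefit is
`NMB = QALY · λ − cost`; money is rounded to whole dollars and QALYs to two
decimals only in the console rendering — CSV outputs are full precision.

## Sensitivity analyses

**One-way (tornado).** Each declared range re-runs the full model at its
low and high bound, all else at base, recording the incremental NMB of a
comparison strategy versus a reference (default: biomarker vs NCCN).
Entries are sorted by spread. Parameters are addressed by dotted path;
quantities that must co-vary are *derived parameters* re-computed after
every assignment:

- `complement` — a mixture weight set to one minus its siblings (varying a
  biomarker-positive fraction can never break the sum-to-one invariant);
- `sum` — an arm's upfront cost composed from shared scalar parameters
  (the ADT course cost enters five arms across three strategies; the test
  price adds on top in the biomarker strategy);
- `difference` — the on-ADT utility is the off-ADT utility minus a
  decrement, so the decrement is the sensitivity handle and the ordering
  `utility_on ≤ utility_off` holds by construction;
- `fill` — a per-cycle schedule filled from one scalar (constant-hazard
  metastasis schedules stay addressable as single parameters).

**Probabilistic.** Each parameter draws from its declared family: beta for
quantities on [0, 1], gamma for non-negative costs, both moment-matched
with mean = base value and sd = (high − low)/(2·1.96), i.e. the declared
bounds are read as a 95% range; uniform on its support; `fixed` passes the
base through. An infeasible moment match (sd too large for the mean) falls
back to uniform on the bounds with a logged warning. One seeded generator
drives a run; draws are consumed in declaration order, so results are
bit-reproducible given (spec, n, seed). The acceptability curve reports,
per willingness-to-pay, the fraction of draws with strictly positive
incremental NMB (ties count against). Because distribution families and
the derived-parameter structure are modeling choices, PSA outputs are
tolerance-level quantities, not exact reproductions of any external
analysis.

## Synthetic scenario generator

`gen_model_spec` emits the full three-strategy decision problem from a
small `ScenarioConfig`. Structural choices:

- **Nesting.** Biomarker-positive patients are nested within the NCCN
  unfavorable-risk group, and the positive fraction (default 0.33) is below
  the unfavorable fraction (default 0.60). Every strategy therefore treats
  all positives; strategies differ only in how many biomarker-negative
  patients receive unnecessary ADT. This mirrors the clinical argument that
  a predictive test is valuable exactly when it recommends treatment to
  fewer patients than the guideline rule does.
- **Effect pattern.** Under the default `benefit_in_positives_only`, ADT
  brings treated positives down to the biomarker-negative metastasis hazard
  and does nothing for negatives; metastasis and survival are then equal
  across strategies at base case, and the comparison is decided by ADT
  cost, test cost and the one-year utility decrement. `uniform_benefit`
  extends the hazard reduction to treated negatives (a stress scenario in
  which treat-more strategies gain effectiveness); `null` removes every ADT
  effect, making the strategies' QALY trajectories identical so the
  frontier is decided purely by cost.
- **Magnitudes.** Plausibility-window values, mildly jittered by seed:
  ADT course costs by regimen (flutamide-based trial regimen ≈ $9 500,
  leuprolide ≈ $2 400, relugolix ≈ $4 800 — the three regimens also form
  the one-way ADT-cost range), test price ≈ $760, metastatic care ≈
  $90 000/yr, end-of-life ≈ $80 000 cancer / $30 000 non-cancer, utilities
  ≈ 0.83 off ADT with a 0.05–0.07 on-ADT decrement and ≈ 0.60 metastatic,
  untreated-positive metastasis ≈ 1.9%/yr versus ≈ 0.41%/yr in negatives,
  metastatic excess mortality ≈ 25%/yr. These are synthetic stand-ins
  chosen once for realism, not transcriptions of published inputs; with
  them the generated scenarios reproduce the expected qualitative result
  (biomarker strategy cheapest and most effective; ADT-for-all costliest
  and least effective) for every seed, and no shipped one-way range flips
  the biomarker-vs-NCCN decision.
- Shipped DSA ranges span ±25% of base values (clipped to valid supports);
  PSA distributions reuse those bounds with beta/gamma families; the
  discount rate is varied one-way but held fixed in the PSA.

`gen_microsim_trajectories` steps individual patients through the same
transition matrices and returns empirical occupancy/new-death series. It
exists to validate the cohort engine: the analytic trace must sit within
binomial sampling error of the microsimulation. The validation applies the
three-standard-error-per-cell standard simultaneously across all
state-cycle cells (Bonferroni-corrected threshold) together with a bound on
the mean standardized deviation, which is the statistically consistent
version of a per-cell band when ~10³ correlated cells are checked at once.

### What passing synthetic tests does and does not show

The generator emulates the *structure* of the decision problem (arm
mixtures, nested subgroups, shared mortality, one-cycle utility decrement,
regimen cost alternatives) with constant per-cycle hazards and
plausibility-window magnitudes. It does not emulate time-varying hazards,
correlations between inputs, individual-level heterogeneity within arms, or
the actual trial-derived transition probabilities — so green tests certify
the engine's arithmetic, invariants and qualitative behaviour, not the
numeric conclusions for any real cohort. Reproducing a published base case
requires transcribing that study's inputs into a spec file
(`data/base_case.yaml`), at which point the golden tests in
`tests/test_acceptance.py` run against it.

## Numerical conventions and degenerate inputs

- Weights must sum to 1 within 1e-9; transition rows are constructed
  row-stochastic and verified within 1e-12.
- Frontier ties: equal cost and QALYs keep the first strategy by input
  order; extended dominance pops a strategy only on a strictly decreasing
  ICER step, so collinear points stay on the frontier.
- A zero-QALY-difference comparison has no ICER (`None`), only a dominance
  label.
- `p_death_other = 1` absorbs the cohort in one cycle; all-zero schedules
  leave occupancy constant (after the structural on→off move); both are
  exercised as unit tests.
- Problem sizes in the validation suite — 200 000 microsimulated
  individuals per schedule, 200 random frontier point sets, 200 fuzzed
  generator seeds, 20 000-draw acceptance PSA — were chosen to make
  sampling error small relative to the tolerances while keeping the full
  suite fast on a single CPU.

## Known limitations

- The cohort engine is memoryless by state: time-in-state effects (e.g.
  metastatic mortality rising with duration) require state splitting, which
  the four-state structure does not do.
- End-of-life cost timing uses the cycle-of-death discount factor; models
  that accrue terminal costs over the final year will differ slightly.
- The bundled life-table slice is an approximation; analyses intended for
  publication should supply their own `mortality.p_death_other`.
- The PSA samples parameters independently (no correlation structure), and
  mixture weights re-derived through complements absorb sampling of one
  weight only per strategy.
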