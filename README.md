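# adtcea

Markov cohort cost-effectiveness analysis of strategies for guiding
short-term androgen deprivation therapy (ADT) in intermediate-risk prostate
cancer.

## The problem

Adding a 4–6 month course of ADT to radiotherapy reduces distant metastasis
in intermediate-risk prostate cancer, but ADT carries real quality-of-life
costs and not every patient benefits. Three treatment policies compete:

1. **ADT-for-all** — every patient receives short-term ADT;
2. **NCCN** — only the unfavorable intermediate-risk subgroup receives ADT;
3. **biomarker** — only patients positive on a predictive biomarker test
   receive ADT (with the test purchased for everyone).

`adtcea` is a toolkit for health-economics researchers who want to compare
such policies with a transparent, fully scriptable model instead of
proprietary decision-tree software. It implements:

- a four-state Markov cohort engine (stable on ADT / stable off ADT /
  metastatic / dead) with annual cycles, half-cycle correction, 3% annual
  discounting and a 15-year horizon (cohort entry at age 71);
- cause-split mortality accounting, so end-of-life costs divide between
  cancer and non-cancer deaths in proportion to each strategy's 15-year
  cancer-specific mortality;
- stepwise incremental cost-effectiveness ratios (ICERs) with strict and
  extended dominance, and net monetary benefit, `NMB = QALY · λ − cost` at a
  willingness-to-pay threshold λ (default $100 000/QALY);
- one-way deterministic sensitivity analysis (tornado diagrams of
  incremental NMB) and probabilistic sensitivity analysis (moment-matched
  beta/gamma input distributions, Monte Carlo, cost-effectiveness
  acceptability curves);
- a synthetic scenario generator and an individual-level microsimulation
  used to validate the cohort engine against sampling theory.

Models are described in a documented YAML/JSON spec format (JSON Schema in
`src/adtcea/data/model_spec.schema.json`); sensitivity analyses address
parameters by dotted paths (`econ.utility_off_adt`,
`strategies[2].components[0].weight`), with co-varying quantities
(mixture-weight complements, composed upfront costs) re-derived
automatically so no analysis can break the model's invariants.

## Worked example

Generate a synthetic base-like scenario and run the base-case comparison:

```bash
adtcea gen --out demo.yaml --seed 0
adtcea run --spec demo.yaml --out demo_out
```

```
Strategy         Cost ($)   QALY  Inc. cost Inc. QALY         ICER    NMB ($)  Status
biomarker          31,280   7.37          —         —     dominant    706,053  on_frontier
nccn               33,229   7.37      1,949     -0.01    dominated    703,307  strictly_dominated
adt_for_all        37,133   7.35      5,853     -0.02    dominated    698,221  strictly_dominated
(NMB at WTP $100,000/QALY)
```

The biomarker-guided strategy is cheapest (it avoids the ADT course in
biomarker-negative patients, which more than pays for the test) and most
effective (fewer patients suffer the one-year on-ADT utility decrement), so
it *dominates* both comparators: the NCCN and ADT-for-all rows are strictly
dominated and the frontier contains a single strategy. Full-precision
values, per-strategy cohort traces and a run manifest are written to
`demo_out/`.

Probabilistic sensitivity analysis with the spec's shipped distributions:

```bash
adtcea psa --spec demo.yaml --out demo_psa --n 5000 --seed 1
```

```
P(biomarker cost-effective vs nccn at $50,000/QALY) = 0.994
P(biomarker cost-effective vs nccn at $100,000/QALY) = 0.993
P(biomarker cost-effective vs nccn at $150,000/QALY) = 0.992
```

Each probability is the fraction of Monte Carlo draws in which the
incremental NMB of the biomarker strategy versus the NCCN strategy is
positive at that willingness-to-pay. `adtcea dsa` produces the
corresponding tornado table (and `--plot` renders tornado/CEAC figures).

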