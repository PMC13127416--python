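"""Synthetic scenario generator: complete, structurally faithful model specs.

The generator emits the full three-strategy decision problem so every stage
of the pipeline is testable without external inputs.  Its structure mirrors
the clinical setting: a cohort of 71-year-old men with intermediate-risk
prostate cancer in whom a predictive biomarker identifies the subgroup that
benefits from adding a short ADT course to radiotherapy.  Assumptions baked
into generated specs:

* the biomarker-positive fraction is smaller than the NCCN unfavorable-risk
  fraction, and positives are nested within the unfavorable group (so every
  strategy treats all positives and the strategies differ only in how many
  biomarker-negative patients receive unnecessary ADT);
* ADT reduces the metastasis hazard only in biomarker-positive patients
  (under the default effect pattern), bringing treated positives down to the
  hazard of biomarker-negative patients; because every strategy treats all
  positives, metastasis and survival outcomes are equal across strategies at
  base case — the trade-off is driven by ADT cost, test cost, and a one-year
  on-ADT utility decrement;
* three alternative ADT cost regimens (the trial's flutamide-based regimen,
  leuprolide alone, relugolix) span the one-way cost range;
* all magnitudes are plausibility-window values (four-digit ADT course
  costs, five-digit annual metastatic care costs, utilities within a few
  points of each other), jittered mildly by seed — they are synthetic, not
  transcriptions of any published inputs.

Constant per-cycle metastasis hazards are used (the generator's scalar
``params`` are filled into per-cycle schedules by derived rules, which also
keeps them addressable by the sensitivity analyses as single parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from adtcea.life_tables import qx_schedule
from adtcea.model_spec import (
    Arm,
    DerivedParam,
    DSARange,
    EconomicInputs,
    HealthState,
    ModelSpec,
    MortalityInputs,
    N_STATES,
    ParamDistribution,
    Strategy,
    StrategyComponent,
    SpecValidationError,
    apply_derived_params,
    validate_spec,
)
from adtcea.markov_engine import Trace

__all__ = [
    "ScenarioConfig",
    "gen_model_spec",
    "gen_microsim_trajectories",
    "ADT_FOR_ALL",
    "NCCN",
    "BIOMARKER",
]

ADT_FOR_ALL = "adt_for_all"
NCCN = "nccn"
BIOMARKER = "biomarker"

REGIMEN_COSTS = {"rtog9408": 9_500.0, "leuprolide": 2_400.0, "relugolix": 4_800.0}
EFFECT_PATTERNS = ("benefit_in_positives_only", "uniform_benefit", "null")

# plausibility-window base magnitudes (synthetic; see module docstring)
TEST_COST = 760.0
COST_METASTATIC = 90_000.0
COST_EOL_CANCER = 80_000.0
COST_EOL_NONCANCER = 30_000.0
UTILITY_OFF_ADT = 0.83
ADT_UTILITY_DECREMENT = 0.05
UTILITY_METASTATIC = 0.60
P_MET_POSITIVE_NO_ADT = 0.019   # per-cycle; ~25% 15-year risk untreated positives
P_MET_NEGATIVE = 0.0041         # per-cycle; ~6% 15-year risk in negatives
P_DEATH_MET_EXCESS = 0.25


@dataclass
class ScenarioConfig:
    """Knobs for one synthetic scenario.

    ``effect_pattern``: "benefit_in_positives_only" (default) gives the ADT
    metastasis benefit only to biomarker-positive patients;
    "uniform_benefit" extends it to everyone treated; "null" removes every
    ADT effect (no metastasis benefit and no utility decrement), so the
    strategies share identical QALY trajectories and differ only in cost.
    """

    seed: int = 0
    frac_biomarker_positive: float = 0.33
    frac_unfavorable: float = 0.60
    adt_regimen: str = "rtog9408"
    effect_pattern: str = "benefit_in_positives_only"


def _jitter(rng: np.random.Generator, base: float, rel: float = 0.10) -> float:
    return float(base * rng.uniform(1.0 - rel, 1.0 + rel))


def gen_model_spec(config: ScenarioConfig) -> ModelSpec:
    """Emit a complete, validated spec for the configured scenario.

    Fully deterministic given ``config.seed``.  Raises ValueError for
    fractions outside [0, 1] or a positive fraction exceeding the
    unfavorable fraction (positives are nested within the unfavorable
    group), and for unknown regimens or effect patterns.
    """
    f_p = config.frac_biomarker_positive
    f_u = config.frac_unfavorable
    if not (0.0 <= f_p <= 1.0 and 0.0 <= f_u <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if f_p > f_u:
        raise ValueError(
            "frac_biomarker_positive must not exceed frac_unfavorable "
            "(positives are nested within the unfavorable group)"
        )
    if config.adt_regimen not in REGIMEN_COSTS:
        raise ValueError(f"unknown ADT regimen {config.adt_regimen!r}")
    if config.effect_pattern not in EFFECT_PATTERNS:
        raise ValueError(f"unknown effect pattern {config.effect_pattern!r}")

    rng = np.random.default_rng(config.seed)
    regimen_costs = {name: _jitter(rng, c) for name, c in REGIMEN_COSTS.items()}
    cost_adt = regimen_costs[config.adt_regimen]
    cost_test = _jitter(rng, TEST_COST)
    cost_met = _jitter(rng, COST_METASTATIC)
    cost_eol_ca = _jitter(rng, COST_EOL_CANCER)
    cost_eol_other = _jitter(rng, COST_EOL_NONCANCER)
    u_off = UTILITY_OFF_ADT + rng.uniform(-0.02, 0.02)
    decrement = ADT_UTILITY_DECREMENT + rng.uniform(0.0, 0.02)
    u_met = UTILITY_METASTATIC + rng.uniform(-0.05, 0.05)

    p_met_pos_noadt = _jitter(rng, P_MET_POSITIVE_NO_ADT)
    hr = float(rng.uniform(0.35, 0.45))  # treated-negative benefit (uniform pattern)
    p_met_neg = _jitter(rng, P_MET_NEGATIVE)
    p_excess = _jitter(rng, P_DEATH_MET_EXCESS)

    pattern = config.effect_pattern
    # ADT brings treated positives down to the biomarker-negative hazard
    p_met_pos_adt = p_met_neg if pattern != "null" else p_met_pos_noadt
    p_met_neg_adt = p_met_neg * hr if pattern == "uniform_benefit" else p_met_neg
    if pattern == "null":
        decrement = 0.0
    u_on = u_off - decrement

    horizon = 15
    params = {
        "cost_adt": cost_adt,
        "cost_test": cost_test,
        "adt_utility_decrement": decrement,
        "p_met_positive_adt": p_met_pos_adt,
        "p_met_positive_noadt": p_met_pos_noadt,
        "p_met_negative_adt": p_met_neg_adt,
        "p_met_negative_noadt": p_met_neg,
        "p_death_met_excess": p_excess,
    }

    def arm(arm_id: str, adt: bool) -> Arm:
        # schedules/upfronts are placeholders; derived rules fill them below
        return Arm(id=arm_id, receives_adt=adt, p_metastasis=[0.0] * horizon)

    strategies = [
        Strategy(
            ADT_FOR_ALL,
            [
                StrategyComponent(f_p, arm("positive_adt", True)),
                StrategyComponent(1.0 - f_p, arm("negative_adt", True)),
            ],
        ),
        Strategy(
            NCCN,
            [
                StrategyComponent(f_p, arm("positive_adt", True)),
                StrategyComponent(f_u - f_p, arm("negative_adt", True)),
                StrategyComponent(1.0 - f_u, arm("negative_no_adt", False)),
            ],
        ),
        Strategy(
            BIOMARKER,
            [
                StrategyComponent(f_p, arm("positive_tested_adt", True)),
                StrategyComponent(1.0 - f_p, arm("negative_tested_no_adt", False)),
            ],
        ),
    ]

    fills = {
        "strategies[0].components[0].arm.p_metastasis": "params.p_met_positive_adt",
        "strategies[0].components[1].arm.p_metastasis": "params.p_met_negative_adt",
        "strategies[1].components[0].arm.p_metastasis": "params.p_met_positive_adt",
        "strategies[1].components[1].arm.p_metastasis": "params.p_met_negative_adt",
        "strategies[1].components[2].arm.p_metastasis": "params.p_met_negative_noadt",
        "strategies[2].components[0].arm.p_metastasis": "params.p_met_positive_adt",
        "strategies[2].components[1].arm.p_metastasis": "params.p_met_negative_noadt",
        "mortality.p_death_metastatic_excess": "params.p_death_met_excess",
    }
    sums = {
        "strategies[0].components[0].arm.upfront_cost": ["params.cost_adt"],
        "strategies[0].components[1].arm.upfront_cost": ["params.cost_adt"],
        "strategies[1].components[0].arm.upfront_cost": ["params.cost_adt"],
        "strategies[1].components[1].arm.upfront_cost": ["params.cost_adt"],
        "strategies[2].components[0].arm.upfront_cost": ["params.cost_adt", "params.cost_test"],
        "strategies[2].components[1].arm.upfront_cost": ["params.cost_test"],
    }
    derived = (
        [
            DerivedParam(target="strategies[0].components[1].weight", kind="complement"),
            DerivedParam(target="strategies[1].components[1].weight", kind="complement"),
            DerivedParam(target="strategies[2].components[1].weight", kind="complement"),
            # the on-ADT utility co-varies with the off-ADT utility so the
            # decrement, not the level, is the sensitivity-analysis handle
            DerivedParam(
                target="econ.utility_on_adt",
                kind="difference",
                sources=["econ.utility_off_adt", "params.adt_utility_decrement"],
            ),
        ]
        + [DerivedParam(target=t, kind="fill", sources=[s]) for t, s in fills.items()]
        + [DerivedParam(target=t, kind="sum", sources=s) for t, s in sums.items()]
    )

    econ = EconomicInputs(
        cost_metastatic=cost_met,
        cost_eol_cancer=cost_eol_ca,
        cost_eol_noncancer=cost_eol_other,
        utility_on_adt=u_on,
        utility_off_adt=u_off,
        utility_metastatic=u_met,
    )
    mortality = MortalityInputs(
        p_death_other=qx_schedule(horizon),
        p_death_metastatic_excess=[p_excess] * horizon,
    )

    def pct(value: float, lo_clip: float = 0.0, hi_clip: float = np.inf) -> tuple[float, float]:
        return max(lo_clip, 0.75 * value), min(hi_clip, 1.25 * value)

    favorable = 1.0 - f_u
    dsa: list[DSARange] = [
        DSARange("params.cost_adt", min(regimen_costs.values()), max(regimen_costs.values())),
        DSARange("params.cost_test", *pct(cost_test)),
        DSARange("strategies[2].components[0].weight", *pct(f_p, hi_clip=1.0)),
        DSARange(
            "strategies[1].components[2].weight",
            max(0.0, 0.75 * favorable),
            min(1.25 * favorable, 1.0 - f_p),
        ),
        DSARange("params.adt_utility_decrement", *pct(decrement, hi_clip=1.0)),
        DSARange("econ.utility_off_adt", 0.75 * u_off, min(1.0, 1.25 * u_off)),
        DSARange("econ.utility_metastatic", *pct(u_met, hi_clip=1.0)),
        DSARange("econ.cost_metastatic", *pct(cost_met)),
        DSARange("econ.cost_eol_cancer", *pct(cost_eol_ca)),
        DSARange("econ.cost_eol_noncancer", *pct(cost_eol_other)),
        DSARange("econ.discount_rate", *pct(0.03)),
        DSARange("params.p_met_positive_adt", *pct(p_met_pos_adt, hi_clip=1.0)),
        DSARange("params.p_met_negative_noadt", *pct(p_met_neg, hi_clip=1.0)),
        DSARange("params.p_death_met_excess", *pct(p_excess, hi_clip=1.0)),
    ]

    beta_paths = {
        "strategies[2].components[0].weight",
        "strategies[1].components[2].weight",
        "params.adt_utility_decrement",
        "econ.utility_off_adt",
        "econ.utility_metastatic",
        "params.p_met_positive_adt",
        "params.p_met_negative_noadt",
        "params.p_death_met_excess",
    }
    gamma_paths = {
        "params.cost_adt",
        "params.cost_test",
        "econ.cost_metastatic",
        "econ.cost_eol_cancer",
        "econ.cost_eol_noncancer",
    }
    psa: list[ParamDistribution] = []
    for rng_spec in dsa:
        path = rng_spec.param_path
        if path in beta_paths:
            family = "beta"
        elif path in gamma_paths:
            family = "gamma"
        else:
            family = "fixed"  # discount rate held at base in the PSA
        base = {
            "params.cost_adt": cost_adt,
            "params.cost_test": cost_test,
            "strategies[2].components[0].weight": f_p,
            "strategies[1].components[2].weight": favorable,
            "params.adt_utility_decrement": decrement,
            "econ.utility_off_adt": u_off,
            "econ.utility_metastatic": u_met,
            "econ.cost_metastatic": cost_met,
            "econ.cost_eol_cancer": cost_eol_ca,
            "econ.cost_eol_noncancer": cost_eol_other,
            "econ.discount_rate": 0.03,
            "params.p_met_positive_adt": p_met_pos_adt,
            "params.p_met_negative_noadt": p_met_neg,
            "params.p_death_met_excess": p_excess,
        }[path]
        psa.append(
            ParamDistribution(
                param_path=path,
                family=family,
                base=base,
                bound_low=rng_spec.low,
                bound_high=rng_spec.high,
            )
        )

    spec = ModelSpec(
        strategies=strategies,
        econ=econ,
        mortality=mortality,
        horizon=horizon,
        params=params,
        derived_params=derived,
        dsa_ranges=dsa,
        psa_distributions=psa,
    )
    apply_derived_params(spec)
    violations = validate_spec(spec)
    if violations:  # pragma: no cover - generator guarantees validity
        raise SpecValidationError(violations)
    return spec


def gen_microsim_trajectories(
    schedule: np.ndarray,
    n: int,
    seed: int,
    init: np.ndarray | None = None,
) -> Trace:
    """Empirical trace from ``n`` simulated individuals (cohort-trace oracle).

    Each individual starts in a state drawn from ``init`` (default: everyone
    in the stable-on-ADT state) and steps through the categorical transitions
    of ``schedule``.  Returns empirical occupancy fractions and new-death
    series with the same shape as the analytic :class:`Trace`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    schedule = np.asarray(schedule, dtype=float)
    T = schedule.shape[0]
    rng = np.random.default_rng(seed)
    if init is None:
        states = np.zeros(n, dtype=np.int64)
    else:
        init = np.asarray(init, dtype=float)
        states = rng.choice(N_STATES, size=n, p=init / init.sum())
    occ = np.zeros((T + 1, N_STATES))
    ndc = np.zeros(T + 1)
    ndo = np.zeros(T + 1)
    occ[0] = np.bincount(states, minlength=N_STATES) / n
    dead = int(HealthState.DEAD)
    met = int(HealthState.METASTATIC)
    for t in range(T):
        cum = np.cumsum(schedule[t], axis=1)
        u = rng.random(n)
        nxt = (u[:, None] > cum[states]).sum(axis=1)
        died = (nxt == dead) & (states != dead)
        ndc[t + 1] = np.count_nonzero(died & (states == met)) / n
        ndo[t + 1] = np.count_nonzero(died & (states != met)) / n
        states = nxt
        occ[t + 1] = np.bincount(states, minlength=N_STATES) / n
    return Trace(occupancy=occ, new_deaths_cancer=ndc, new_deaths_other=ndo)
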