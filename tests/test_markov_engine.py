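import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adtcea.markov_engine import (
    DEAD,
    MET,
    OFF,
    ON,
    Trace,
    accrue_costs_qalys,
    build_transition_schedule,
    evaluate_strategy,
    run_cohort_trace,
    strategy_trace,
)
from adtcea.model_spec import Arm, EconomicInputs, MortalityInputs, set_path, apply_derived_params
from adtcea.synthetic_data import ScenarioConfig, gen_model_spec

HORIZON = 15


def make_arm(p_met=0.0, adt=False, upfront=0.0, horizon=HORIZON):
    return Arm(id="arm", receives_adt=adt, p_metastasis=[p_met] * horizon, upfront_cost=upfront)


def make_mortality(p_other=0.0, p_excess=0.0, horizon=HORIZON):
    return MortalityInputs([p_other] * horizon, [p_excess] * horizon)


def econ(u_on=0.8, u_off=0.9, u_met=0.5, c_met=0.0, c_eol_ca=0.0, c_eol_other=0.0, r=0.0):
    return EconomicInputs(c_met, c_eol_ca, c_eol_other, u_on, u_off, u_met, discount_rate=r)


@st.composite
def random_schedules(draw):
    horizon = draw(st.integers(min_value=1, max_value=12))
    p = st.floats(min_value=0.0, max_value=0.6, allow_nan=False)
    arm = Arm(
        "r",
        True,
        [draw(p) for _ in range(horizon)],
    )
    mort = MortalityInputs(
        [draw(p) for _ in range(horizon)],
        [draw(p) for _ in range(horizon)],
    )
    return build_transition_schedule(arm, mort, horizon)


class TestBuildTransitionSchedule:
    def test_competing_risk_composition_hand_computed(self):
        """Other-cause death applied first, then metastasis among survivors."""
        sched = build_transition_schedule(
            make_arm(p_met=0.1), make_mortality(p_other=0.02, p_excess=0.3), HORIZON
        )
        M = sched[0]
        # stable rows: to MET 0.1*0.98 = 0.098, to DEAD 0.02, stay 0.882
        assert M[OFF, MET] == pytest.approx(0.098, abs=1e-15)
        assert M[OFF, DEAD] == pytest.approx(0.02, abs=1e-15)
        assert M[OFF, OFF] == pytest.approx(0.882, abs=1e-15)
        # on-ADT survivors move off ADT
        assert M[ON, OFF] == pytest.approx(0.882, abs=1e-15)
        assert M[ON, ON] == 0.0
        # metastatic: to DEAD 1 - 0.98*0.7 = 0.314
        assert M[MET, DEAD] == pytest.approx(0.314, abs=1e-15)
        assert M[MET, MET] == pytest.approx(0.686, abs=1e-15)
        assert M[DEAD].tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_zero_schedules_give_stay_matrices(self):
        sched = build_transition_schedule(make_arm(), make_mortality(), HORIZON)
        for M in sched:
            assert M[OFF, OFF] == 1.0
            assert M[ON, OFF] == 1.0  # up to the on->off move
            assert M[MET, MET] == 1.0
            assert M[DEAD, DEAD] == 1.0

    def test_certain_death_absorbs_in_one_cycle(self):
        sched = build_transition_schedule(make_arm(), make_mortality(p_other=1.0), HORIZON)
        trace = run_cohort_trace(sched, np.eye(4)[OFF])
        assert trace.occupancy[1:, DEAD].tolist() == [1.0] * HORIZON

    def test_short_schedule_rejected(self):
        with pytest.raises(ValueError, match="shorter than horizon"):
            build_transition_schedule(make_arm(horizon=5), make_mortality(), HORIZON)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(random_schedules())
    def test_rows_stochastic(self, sched):
        assert np.allclose(sched.sum(axis=2), 1.0, atol=1e-12)
        assert sched.min() >= 0.0


class TestRunCohortTrace:
    def test_stay_schedule_keeps_occupancy_constant(self):
        sched = build_transition_schedule(make_arm(), make_mortality(), HORIZON)
        init = np.array([0.0, 0.6, 0.4, 0.0])
        trace = run_cohort_trace(sched, init)
        assert np.allclose(trace.occupancy, init)

    def test_nonstochastic_init_rejected(self):
        sched = build_transition_schedule(make_arm(), make_mortality(), HORIZON)
        with pytest.raises(ValueError, match="distribution"):
            run_cohort_trace(sched, np.array([0.5, 0.2, 0.0, 0.0]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(random_schedules())
    def test_probability_conservation_and_death_decomposition(self, sched):
        """Rows sum to 1, DEAD is monotone, and the cause-specific new-death
        series sums to the absorbing-state occupancy."""
        trace = run_cohort_trace(sched, np.eye(4)[ON])
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, DEAD]
        assert np.all(np.diff(dead) >= -1e-15)
        cum = np.cumsum(trace.new_deaths_cancer + trace.new_deaths_other)
        assert np.allclose(cum, dead, atol=1e-9)

    def test_matches_microsimulation_within_sampling_error(self):
        from adtcea.synthetic_data import gen_microsim_trajectories

        spec = gen_model_spec(ScenarioConfig(seed=3))
        arm = spec.strategies[0].components[0].arm
        sched = build_transition_schedule(arm, spec.mortality, spec.horizon)
        n = 100_000
        emp = gen_microsim_trajectories(sched, n=n, seed=11)
        ana = run_cohort_trace(sched, np.eye(4)[ON])
        se = np.sqrt(ana.occupancy * (1 - ana.occupancy) / n)
        assert np.all(np.abs(emp.occupancy - ana.occupancy) <= 3 * se + 1e-12)


class TestAccrual:
    def test_all_zero_rewards_accrue_nothing(self):
        sched = build_transition_schedule(make_arm(), make_mortality(), HORIZON)
        trace = run_cohort_trace(sched, np.eye(4)[OFF])
        cost, qaly = accrue_costs_qalys(trace, make_arm(), econ(u_on=0, u_off=0, u_met=0))
        assert (cost, qaly) == (0.0, 0.0)

    def test_undiscounted_undying_cohort_accrues_horizon_qalys(self):
        sched = build_transition_schedule(make_arm(), make_mortality(), HORIZON)
        trace = run_cohort_trace(sched, np.eye(4)[OFF])
        _, qaly = accrue_costs_qalys(trace, make_arm(), econ(u_off=1.0, r=0.0))
        assert qaly == pytest.approx(15.0, abs=1e-12)

    def test_discounting_matches_geometric_series(self):
        """Undying cohort at utility 1: QALY equals the 15-term annuity sum."""
        sched = build_transition_schedule(make_arm(), make_mortality(), HORIZON)
        trace = run_cohort_trace(sched, np.eye(4)[OFF])
        _, qaly = accrue_costs_qalys(trace, make_arm(), econ(u_off=1.0, r=0.03))
        expected = sum(1.03 ** -t for t in range(1, 16))
        assert qaly == pytest.approx(expected, abs=1e-12)

    def test_upfront_cost_undiscounted_and_eol_costs_discounted(self):
        sched = build_transition_schedule(make_arm(), make_mortality(p_other=1.0), HORIZON)
        trace = run_cohort_trace(sched, np.eye(4)[OFF])
        e = econ(u_on=0, u_off=0, u_met=0, c_eol_other=1000.0, r=0.03)
        cost, _ = accrue_costs_qalys(trace, make_arm(upfront=500.0), e)
        assert cost == pytest.approx(500.0 + 1000.0 / 1.03, abs=1e-9)

    def test_half_cycle_correction_brackets(self):
        """Trapezoid accrual lies between end-of-cycle and start-of-cycle
        conventions for a monotone-declining cohort."""
        sched = build_transition_schedule(make_arm(), make_mortality(p_other=0.05), HORIZON)
        trace = run_cohort_trace(sched, np.eye(4)[OFF])
        e = econ(u_off=1.0, r=0.03)
        _, q_end = accrue_costs_qalys(trace, make_arm(), e, half_cycle_correction=False)
        _, q_mid = accrue_costs_qalys(trace, make_arm(), e, half_cycle_correction=True)
        disc = 1.03 ** -np.arange(1, HORIZON + 1)
        q_start = float(disc @ trace.occupancy[:-1, OFF])
        assert q_end < q_mid < q_start

    def test_negative_rewards_rejected(self):
        sched = build_transition_schedule(make_arm(), make_mortality(), HORIZON)
        trace = run_cohort_trace(sched, np.eye(4)[OFF])
        bad = econ()
        bad.cost_metastatic = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            accrue_costs_qalys(trace, make_arm(), bad)


class TestEvaluateStrategy:
    def test_mixture_of_identical_arms_equals_single_arm(self, base_spec):
        spec = base_spec.copy()
        strat = spec.strategies[0]
        arm = strat.components[0].arm
        import copy as _copy

        from adtcea.model_spec import Strategy, StrategyComponent

        single = Strategy("single", [StrategyComponent(1.0, _copy.deepcopy(arm))])
        split = Strategy(
            "split",
            [
                StrategyComponent(0.5, _copy.deepcopy(arm)),
                StrategyComponent(0.5, _copy.deepcopy(arm)),
            ],
        )
        r1 = evaluate_strategy(single, spec)
        r2 = evaluate_strategy(split, spec)
        assert r1.cost == pytest.approx(r2.cost, abs=1e-9)
        assert r1.qaly == pytest.approx(r2.qaly, abs=1e-9)
        assert r1.p_death_15y == pytest.approx(r2.p_death_15y, abs=1e-12)

    def test_equal_overall_survival_without_excess_mortality(self, base_spec):
        """With no cancer-specific excess death, all strategies share the
        same 15-year death risk (the shared-background-mortality property)."""
        spec = base_spec.copy()
        set_path(spec, "params.p_death_met_excess", 0.0)
        apply_derived_params(spec)
        deaths = [evaluate_strategy(s, spec).p_death_15y for s in spec.strategies]
        assert max(deaths) - min(deaths) <= 1e-12

    def test_discounting_monotonicity(self, base_spec):
        """Cost and QALYs never increase as the discount rate rises."""
        spec = base_spec.copy()
        prev = None
        for r in (0.0, 0.015, 0.03, 0.06):
            spec.econ.discount_rate = r
            res = evaluate_strategy(spec.strategies[2], spec)
            if prev is not None:
                assert res.cost <= prev.cost + 1e-9
                assert res.qaly <= prev.qaly + 1e-9
            prev = res

    def test_mortality_bounds(self, base_results):
        for res in base_results:
            assert 0.0 <= res.p_cancer_death_15y <= res.p_death_15y <= 1.0
            assert res.cost >= 0.0
            assert 0.0 <= res.qaly <= 15.0

    def test_strategy_trace_tidy_export(self, base_spec):
        tr = strategy_trace(base_spec.strategies[1], base_spec)
        df = tr.to_frame()
        assert set(df.columns) == {
            "cycle", "state", "occupancy", "new_deaths_cancer", "new_deaths_other",
        }
        assert len(df) == (base_spec.horizon + 1) * 4
        totals = df.groupby("cycle")["occupancy"].sum()
        assert np.allclose(totals, 1.0, atol=1e-9)
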