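"""Unit and property tests for the Markov cohort engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from markov_cea import (
    CostSchedule,
    HealthState,
    LifeTable,
    ModelSettings,
    NoChangeFirstCycleMode,
    Perspective,
    StrategyDefinition,
    annual_to_cycle_prob,
    build_transition_matrix,
    cycle_cost,
    discount_weight,
    run_cohort,
)
from markov_cea.synthetic import make_random_model

from conftest import random_strategy

I, N, D, X = (
    HealthState.IMPROVED_ON_TX,
    HealthState.NOCHANGE_ON_TX,
    HealthState.DISCONTINUED,
    HealthState.DEAD,
)


class TestRateConversions:
    @pytest.mark.parametrize(
        "p, length, expected",
        [(0.0, 0.5, 0.0), (1.0, 0.5, 1.0), (0.01, 0.5, 0.0050126)],
    )
    def test_annual_to_cycle_examples(self, p, length, expected):
        assert annual_to_cycle_prob(p, length) == pytest.approx(expected, abs=1e-6)

    def test_annual_to_cycle_monotone_and_bounded(self):
        grid = np.linspace(0, 1, 101)
        vals = [annual_to_cycle_prob(p, 0.5) for p in grid]
        assert all(0 <= v <= 1 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_annual_to_cycle_domain_error_names_parameter(self):
        with pytest.raises(ValueError, match="p_annual"):
            annual_to_cycle_prob(1.5, 0.5)

    @pytest.mark.parametrize(
        "rate, k, length, expected",
        [(0.0, 7, 0.5, 1.0), (0.03, 3, 0.5, 0.970874), (0.03, 21, 0.5, 0.744094)],
    )
    def test_discount_weight_examples(self, rate, k, length, expected):
        assert discount_weight(rate, k, length) == pytest.approx(expected, abs=1e-6)

    def test_discount_weight_first_cycle_is_one(self):
        assert discount_weight(0.07, 1, 0.5) == 1.0

    def test_discount_weight_rejects_bad_cycle(self):
        with pytest.raises(ValueError):
            discount_weight(0.03, 0, 0.5)


class TestTransitionMatrix:
    def test_improved_row_second_cycle(self, aga_model, zero_mortality):
        strat = aga_model.strategy("minoxidil")
        m = build_transition_matrix(strat, aga_model.settings, 2, zero_mortality)
        assert m[I] == pytest.approx([0.91, 0.0, 0.09, 0.0])

    def test_all_continue_gives_identity_alive_rows(self, simple_strategy, zero_mortality):
        m = build_transition_matrix(simple_strategy, ModelSettings(), 3, zero_mortality)
        assert np.allclose(m[[I, N, D]], np.eye(4)[[I, N, D]])

    def test_dead_is_absorbing(self, aga_model):
        for k in (1, 2, 5):
            m = build_transition_matrix(
                aga_model.strategy("prp"), aga_model.settings, k, aga_model.life_table
            )
            assert m[X] == pytest.approx([0, 0, 0, 1])

    def test_discontinued_only_stays_or_dies(self, aga_model):
        m = build_transition_matrix(
            aga_model.strategy("prp"), aga_model.settings, 4, aga_model.life_table
        )
        assert m[D, I] == 0 and m[D, N] == 0
        assert m[D, D] + m[D, X] == pytest.approx(1)

    def test_offtx_table_mode_applies_only_at_second_cycle(self, aga_model, zero_mortality):
        settings = ModelSettings(nochange_first_cycle_mode=NoChangeFirstCycleMode.OFFTX_TABLE)
        strat = aga_model.strategy("prp")  # alt off-treatment probability 0.20
        m2 = build_transition_matrix(strat, settings, 2, zero_mortality)
        assert m2[N, N] == pytest.approx(0.80)
        m3 = build_transition_matrix(strat, settings, 3, zero_mortality)
        assert m3[N, N] == pytest.approx(0.50)

    @hsettings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), cycle=st.integers(1, 12))
    def test_rows_sum_to_one_for_random_strategies(self, seed, cycle):
        rng = np.random.default_rng(seed)
        strat = random_strategy(rng)
        lt = LifeTable((20, 50, 80), tuple(rng.uniform(0, 1, 3)))
        m = build_transition_matrix(strat, ModelSettings(start_age_years=30), cycle, lt)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all()

    def test_malformed_strategy_reports_fields(self):
        with pytest.raises(ValueError, match="p_improve_first"):
            StrategyDefinition(
                name="bad",
                p_improve_first=1.2,
                p_continue_improved_first=0.5,
                p_continue_improved_subsequent=0.5,
                p_continue_nochange=0.5,
                utility_improved=0.9,
                utility_baseline=0.85,
                cost_schedule=CostSchedule(),
            )


class TestCycleCost:
    def test_prp_first_cycle_healthcare(self, aga_model):
        c = cycle_cost(aga_model.strategy("prp"), N, 1, Perspective.HEALTHCARE)
        assert c == pytest.approx(150 + 3 * 717.67)  # 2303.01

    def test_discontinued_accrues_nothing(self, aga_model):
        assert cycle_cost(aga_model.strategy("minoxidil"), D, 7, Perspective.HEALTHCARE) == 0.0
        assert cycle_cost(aga_model.strategy("prp"), X, 2, Perspective.SOCIETAL) == 0.0

    def test_prp_subsequent_societal(self, aga_model):
        c = cycle_cost(aga_model.strategy("prp"), I, 2, Perspective.SOCIETAL)
        assert c == pytest.approx(717.67 + 166.55)  # 884.22

    def test_unknown_state_rejected(self, aga_model):
        with pytest.raises(ValueError):
            cycle_cost(aga_model.strategy("prp"), 7, 1, Perspective.HEALTHCARE)


class TestRunCohort:
    def test_perfect_health_one_year(self, zero_mortality):
        strat = StrategyDefinition(
            name="perfect",
            p_improve_first=0.5,
            p_continue_improved_first=1.0,
            p_continue_improved_subsequent=1.0,
            p_continue_nochange=1.0,
            utility_improved=1.0,
            utility_baseline=1.0,
            cost_schedule=CostSchedule(),
        )
        trace = run_cohort(strat, ModelSettings(horizon_years=1.0, discount_rate_annual=0.0), zero_mortality)
        assert trace.total_qaly == pytest.approx(1.0)
        assert trace.total_cost == 0.0

    def test_two_cycle_hand_trace(self, simple_strategy, undiscounted_settings, zero_mortality):
        # 2 half-year cycles, 60/40 split between utilities 0.9 and 0.85:
        # QALY = 2 * 0.5 * (0.6*0.9 + 0.4*0.85) = 0.88
        trace = run_cohort(simple_strategy, undiscounted_settings, zero_mortality)
        assert trace.total_qaly == pytest.approx(0.88, abs=1e-12)

    def test_non_integer_cycle_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            ModelSettings(horizon_years=1.25)

    def test_trace_invariants_on_reference_model(self, aga_model):
        for name in aga_model.strategy_names:
            trace = aga_model.run(name)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert ((trace.occupancy >= 0) & (trace.occupancy <= 1)).all()
            dead = trace.occupancy[:, X]
            assert (np.diff(dead) >= -1e-15).all()
            assert trace.total_cost == pytest.approx(trace.cost_per_cycle.sum(), abs=1e-9)
            assert trace.total_qaly == pytest.approx(trace.qaly_per_cycle.sum(), abs=1e-9)

    def test_path_enumeration_oracle(self, aga_model):
        """Totals from the cohort recursion match an exhaustive sum over all
        state paths weighted by path probability (4-cycle horizon)."""
        settings = ModelSettings(horizon_years=2.0, perspective=Perspective.SOCIETAL)
        for name in aga_model.strategy_names:
            strat = aga_model.strategy(name)
            lt = aga_model.life_table
            n = settings.n_cycles
            mats = [build_transition_matrix(strat, settings, k, lt) for k in range(1, n + 1)]
            utilities = {
                I: strat.utility_improved,
                N: strat.utility_baseline,
                D: strat.utility_baseline,
                X: 0.0,
            }
            exp_cost = exp_qaly = 0.0
            stack = [(0, HealthState.NOCHANGE_ON_TX, 1.0, 0.0, 0.0)]
            while stack:
                k, state, prob, cost_acc, qaly_acc = stack.pop()
                if k == n:
                    exp_cost += prob * cost_acc
                    exp_qaly += prob * qaly_acc
                    continue
                for nxt in HealthState:
                    p = mats[k][state, nxt]
                    if p == 0.0:
                        continue
                    w = discount_weight(settings.discount_rate_annual, k + 1, 0.5)
                    stack.append(
                        (
                            k + 1,
                            nxt,
                            prob * p,
                            cost_acc + w * cycle_cost(strat, nxt, k + 1, settings.perspective),
                            qaly_acc + w * 0.5 * utilities[nxt],
                        )
                    )
            trace = run_cohort(strat, settings, lt)
            assert trace.total_cost == pytest.approx(exp_cost, abs=1e-9)
            assert trace.total_qaly == pytest.approx(exp_qaly, abs=1e-9)

    def test_mortality_scaling_never_increases_qalys(self, aga_model):
        strat = aga_model.strategy("minoxidil")
        base_q = np.array(aga_model.life_table.q_annual)
        prev = math.inf
        for scale in (0.0, 1.0, 3.0, 10.0):
            lt = LifeTable(aga_model.life_table.ages, tuple(np.clip(base_q * scale, 0, 1)))
            total = run_cohort(strat, aga_model.settings, lt).total_qaly
            assert total <= prev + 1e-12
            prev = total

    def test_discount_limits(self, aga_model, zero_mortality):
        strat = aga_model.strategy("prp")
        s0 = ModelSettings(discount_rate_annual=0.0)
        trace0 = run_cohort(strat, s0, zero_mortality)
        undiscounted_qaly = sum(
            0.5 * (trace0.occupancy[k] @ np.array([0.89, 0.85, 0.85, 0.0]))
            for k in range(1, s0.n_cycles + 1)
        )
        assert trace0.total_qaly == pytest.approx(undiscounted_qaly, abs=1e-9)
        # discounting factorizes: per-cycle accruals at any rate equal the
        # discount weights times the undiscounted accruals, so raising the
        # rate shrinks totals toward the (undiscounted) first cycle
        s_high = ModelSettings(discount_rate_annual=0.9)
        trace_high = run_cohort(strat, s_high, zero_mortality)
        weights = np.array(
            [discount_weight(0.9, k, 0.5) for k in range(1, s_high.n_cycles + 1)]
        )
        assert np.allclose(trace_high.cost_per_cycle, weights * trace0.cost_per_cycle)
        assert np.allclose(trace_high.qaly_per_cycle, weights * trace0.qaly_per_cycle)
        assert trace_high.cost_per_cycle[0] == trace0.cost_per_cycle[0]

    def test_societal_minus_healthcare_equals_wage_losses(self, aga_model):
        """Perspective identity: the perspectives differ exactly by the
        discounted expected half-day wage payments."""
        for name in aga_model.strategy_names:
            strat = aga_model.strategy(name)
            hc = aga_model.run(name, Perspective.HEALTHCARE)
            so = aga_model.run(name, Perspective.SOCIETAL)
            cs = strat.cost_schedule
            expected = 0.0
            for k in range(1, aga_model.settings.n_cycles + 1):
                visits = cs.visits_first_cycle_societal if k == 1 else cs.visits_subsequent_cycle_societal
                on_tx = hc.occupancy[k, I] + hc.occupancy[k, N]
                expected += (
                    discount_weight(0.03, k, 0.5) * on_tx * visits * cs.halfday_wage_loss
                )
            assert so.total_cost - hc.total_cost == pytest.approx(expected, abs=1e-9)

    def test_half_cycle_correction_trapezoid(self, simple_strategy, zero_mortality):
        s = ModelSettings(horizon_years=1.0, discount_rate_annual=0.0, half_cycle_correction=True)
        trace = run_cohort(simple_strategy, s, zero_mortality)
        # occupancy is stationary after the split, so the trapezoid equals
        # 0.5 + 1 + 0.5 = 2 half-cycles of the post-split mix
        assert trace.total_qaly == pytest.approx(0.88, abs=1e-12)

    def test_random_models_conserve_occupancy(self):
        for seed in range(40):
            model = make_random_model(seed)
            for name in model.strategy_names:
                trace = model.run(name)
                assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)


class TestLifeTable:
    def test_lookup_clamps_beyond_ends(self):
        lt = LifeTable((30, 40, 50), (0.001, 0.002, 0.004))
        assert lt.q_at(20) == 0.001
        assert lt.q_at(95) == 0.004
        assert lt.q_at(41.7) == 0.002

    def test_rejects_non_increasing_ages(self):
        with pytest.raises(ValueError, match="increasing"):
            LifeTable((30, 30), (0.1, 0.1))

    def test_csv_round_trip(self, tmp_path):
        lt = LifeTable((25, 26, 27), (0.0008, 0.0009, 0.001))
        p = tmp_path / "lt.csv"
        lt.to_csv(p)
        assert LifeTable.from_csv(p) == lt
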