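import numpy as np
import pytest

from markov_cea import (
    CostSchedule,
    DecisionModel,
    LifeTable,
    ModelSettings,
    StrategyDefinition,
    load_aga_reference,
)


@pytest.fixture(scope="session")
def aga_model() -> DecisionModel:
    return load_aga_reference()


@pytest.fixture
def zero_mortality() -> LifeTable:
    return LifeTable(ages=(25, 90), q_annual=(0.0, 0.0))


@pytest.fixture
def simple_strategy() -> StrategyDefinition:
    """A hand-traceable strategy: 60% responders, everyone continues."""
    return StrategyDefinition(
        name="simple",
        p_improve_first=0.6,
        p_continue_improved_first=1.0,
        p_continue_improved_subsequent=1.0,
        p_continue_nochange=1.0,
        utility_improved=0.9,
        utility_baseline=0.85,
        cost_schedule=CostSchedule(),
    )


@pytest.fixture
def undiscounted_settings() -> ModelSettings:
    return ModelSettings(horizon_years=1.0, discount_rate_annual=0.0)


def random_strategy(rng: np.random.Generator, name: str = "s") -> StrategyDefinition:
    return StrategyDefinition(
        name=name,
        p_improve_first=float(rng.uniform()),
        p_continue_improved_first=float(rng.uniform()),
        p_continue_improved_subsequent=float(rng.uniform()),
        p_continue_nochange=float(rng.uniform()),
        p_offtx_nochange_alt=float(rng.uniform()),
        utility_improved=float(rng.uniform()),
        utility_baseline=float(rng.uniform()),
        cost_schedule=CostSchedule(
            initial_visit_cost=float(rng.uniform(0, 300)),
            drug_cost_per_cycle=float(rng.uniform(0, 200)),
            injection_unit_cost=float(rng.uniform(0, 900)),
            injections_first_cycle=int(rng.integers(0, 4)),
            injections_subsequent_cycle=int(rng.integers(0, 3)),
            halfday_wage_loss=float(rng.uniform(0, 300)),
            visits_first_cycle_societal=int(rng.integers(0, 4)),
            visits_subsequent_cycle_societal=int(rng.integers(0, 3)),
        ),
    )
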