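"""Synthetic inputs: a Gompertz-Makeham adult-male life table and random
valid model configurations for property-based testing.

The life table stands in for a national all-cause mortality table: the
hazard ``mu(x) = a + b*exp(c*x)`` combines an age-independent background
term with an exponentially rising senescent term, and the annual death
probability is ``q(x) = 1 - exp(-mu(x))``.  The default parameters give
probabilities rising from about 8e-4 at age 25 to about 2e-2 at age 74,
order-of-magnitude consistent with recent US adult-male mortality; no finer
demographic accuracy is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CostSchedule,
    DecisionModel,
    LifeTable,
    ModelSettings,
    Perspective,
    StrategyDefinition,
)

__all__ = ["LifeTableModel", "make_life_table", "default_life_table", "make_random_model"]


@dataclass(frozen=True)
class LifeTableModel:
    """Gompertz-Makeham hazard parameters and the age range to tabulate."""

    makeham_a: float = 5e-4
    gompertz_b: float = 3e-5
    gompertz_c: float = 0.085
    age_start: int = 25
    age_end: int = 74

    def __post_init__(self) -> None:
        if self.makeham_a < 0 or self.gompertz_b < 0:
            raise ValueError("hazard parameters makeham_a and gompertz_b must be >= 0")
        if not 0 <= self.age_start <= self.age_end <= 110:
            raise ValueError("age range must satisfy 0 <= start <= end <= 110")


def make_life_table(model: LifeTableModel = LifeTableModel()) -> LifeTable:
    """Tabulate annual death probabilities ``q(x) = 1 - exp(-(a + b e^{cx}))``
    over the model's age range."""
    ages = np.arange(model.age_start, model.age_end + 1)
    hazard = model.makeham_a + model.gompertz_b * np.exp(model.gompertz_c * ages)
    q = 1.0 - np.exp(-hazard)
    return LifeTable(tuple(int(a) for a in ages), tuple(float(v) for v in q))


def default_life_table() -> LifeTable:
    """The package's default synthetic adult-male life table (ages 25-74)."""
    return make_life_table(LifeTableModel())


def make_random_model(seed: int, n_strategies: int | None = None) -> DecisionModel:
    """Draw a random but valid :class:`DecisionModel` for property tests.

    All probabilities and utilities are uniform on [0, 1], costs are
    non-negative, and the horizon is a random whole number of cycles, so
    every draw passes the core validators.  Reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    if n_strategies is None:
        n_strategies = int(rng.integers(1, 5))

    strategies = []
    for i in range(n_strategies):
        cs = CostSchedule(
            initial_visit_cost=float(rng.uniform(0, 500)),
            drug_cost_per_cycle=float(rng.uniform(0, 300)),
            injection_unit_cost=float(rng.uniform(0, 1000)),
            injections_first_cycle=int(rng.integers(0, 4)),
            injections_subsequent_cycle=int(rng.integers(0, 3)),
            halfday_wage_loss=float(rng.uniform(0, 400)),
            visits_first_cycle_societal=int(rng.integers(0, 4)),
            visits_subsequent_cycle_societal=int(rng.integers(0, 3)),
        )
        strategies.append(
            StrategyDefinition(
                name=f"strategy_{i}",
                p_improve_first=float(rng.uniform()),
                p_continue_improved_first=float(rng.uniform()),
                p_continue_improved_subsequent=float(rng.uniform()),
                p_continue_nochange=float(rng.uniform()),
                p_offtx_nochange_alt=float(rng.uniform()),
                utility_improved=float(rng.uniform()),
                utility_baseline=float(rng.uniform()),
                cost_schedule=cs,
            )
        )

    n_cycles = int(rng.integers(1, 81))
    settings = ModelSettings(
        cycle_length_years=0.5,
        horizon_years=n_cycles * 0.5,
        discount_rate_annual=float(rng.uniform(0, 0.1)),
        start_age_years=float(rng.integers(20, 60)),
        perspective=Perspective.HEALTHCARE if rng.uniform() < 0.5 else Perspective.SOCIETAL,
    )
    lt_model = LifeTableModel(
        makeham_a=float(rng.uniform(0, 2e-3)),
        gompertz_b=float(rng.uniform(0, 1e-4)),
        gompertz_c=float(rng.uniform(0.05, 0.11)),
        age_start=18,
        age_end=100,
    )
    return DecisionModel(tuple(strategies), settings, make_life_table(lt_model))
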