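"""Discrete-time Markov cohort state-transition model.

The engine simulates a closed cohort moving through four health states --
improved on treatment, no change/worse on treatment, discontinued, and dead
-- in fixed-length cycles, accruing discounted costs and quality-adjusted
life-years (QALYs).  Transition probabilities may differ between the first
cycle (treatment response), the second cycle (early continuation) and all
later cycles, and an age-indexed life table supplies background mortality
that applies uniformly to every alive state.

Conventions
-----------
* Transitions occur at cycle boundaries; rewards accrue on the state
  occupied *during* a cycle.
* Cycle 1's occupancy is the post-entry-split distribution: the cohort
  enters the model, survives the first cycle's mortality draw, and splits
  into responders and non-responders.
* The discount weight of cycle ``k`` is ``(1+r)^(-(k-1)*L)`` with ``L`` the
  cycle length in years, so the first cycle is undiscounted.
* Annual mortality probabilities are converted to per-cycle probabilities
  via ``1 - (1-q)**L`` and the age used for cycle ``k`` is
  ``floor(start_age + (k-1)*L)``, clamped to the life-table range.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "Perspective",
    "NoChangeFirstCycleMode",
    "CostSchedule",
    "StrategyDefinition",
    "LifeTable",
    "ModelSettings",
    "CohortTrace",
    "DecisionModel",
    "annual_to_cycle_prob",
    "discount_weight",
    "cycle_cost",
    "build_transition_matrix",
    "run_cohort",
]


class HealthState(enum.IntEnum):
    """The four model states. ``DEAD`` is absorbing; ``DISCONTINUED`` can
    only stay put or die."""

    IMPROVED_ON_TX = 0
    NOCHANGE_ON_TX = 1
    DISCONTINUED = 2
    DEAD = 3


#: States in which the cohort is receiving active treatment.
ON_TREATMENT_STATES = (HealthState.IMPROVED_ON_TX, HealthState.NOCHANGE_ON_TX)


class Perspective(str, enum.Enum):
    """Costing perspective: direct medical costs only, or with productivity
    losses (half-day wages per clinic visit) added."""

    HEALTHCARE = "healthcare"
    SOCIETAL = "societal"


class NoChangeFirstCycleMode(str, enum.Enum):
    """How non-responders behave at their first continuation decision.

    ``CONTINUE_50`` applies the generic 50% per-cycle continuation from the
    start.  ``OFFTX_TABLE`` instead applies a strategy-specific first-cycle
    discontinuation probability at the first opportunity (the cycle-1 to
    cycle-2 boundary), falling back to the generic continuation afterwards.
    Both are defensible readings of the published inputs; neither is
    asserted as the original model's intent.
    """

    CONTINUE_50 = "continue_50"
    OFFTX_TABLE = "offtx_table"


def _check(cond: bool, errors: list[str], msg: str) -> None:
    if not cond:
        errors.append(msg)


@dataclass(frozen=True)
class CostSchedule:
    """Per-cycle cost components for one strategy, in constant currency.

    Healthcare costs are the initial visit (model entry only), a per-cycle
    drug cost and per-injection procedure costs; the societal perspective
    adds lost half-day wages for each clinic visit.
    """

    initial_visit_cost: float = 0.0
    drug_cost_per_cycle: float = 0.0
    injection_unit_cost: float = 0.0
    injections_first_cycle: int = 0
    injections_subsequent_cycle: int = 0
    halfday_wage_loss: float = 0.0
    visits_first_cycle_societal: int = 0
    visits_subsequent_cycle_societal: int = 0

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        for name in (
            "initial_visit_cost",
            "drug_cost_per_cycle",
            "injection_unit_cost",
            "halfday_wage_loss",
        ):
            _check(getattr(self, name) >= 0, errs, f"{name} must be >= 0")
        for name in (
            "injections_first_cycle",
            "injections_subsequent_cycle",
            "visits_first_cycle_societal",
            "visits_subsequent_cycle_societal",
        ):
            v = getattr(self, name)
            _check(v >= 0 and int(v) == v, errs, f"{name} must be a non-negative integer")
        return errs

    def __post_init__(self) -> None:
        errs = self.validation_errors()
        if errs:
            raise ValueError("invalid CostSchedule: " + "; ".join(errs))


@dataclass(frozen=True)
class StrategyDefinition:
    """One treatment arm: response/continuation probabilities, state
    utilities and its cost schedule."""

    name: str
    p_improve_first: float
    p_continue_improved_first: float
    p_continue_improved_subsequent: float
    p_continue_nochange: float
    utility_improved: float
    utility_baseline: float
    cost_schedule: CostSchedule
    #: Alternative first-cycle discontinuation probability for
    #: non-responders; only consulted under ``OFFTX_TABLE`` mode.
    p_offtx_nochange_alt: float = 0.0

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        _check(bool(self.name), errs, "name must be non-empty")
        for nm in (
            "p_improve_first",
            "p_continue_improved_first",
            "p_continue_improved_subsequent",
            "p_continue_nochange",
            "p_offtx_nochange_alt",
            "utility_improved",
            "utility_baseline",
        ):
            v = getattr(self, nm)
            _check(0.0 <= v <= 1.0, errs, f"{nm}={v!r} outside [0, 1]")
        errs.extend(self.cost_schedule.validation_errors())
        return errs

    def validate(self) -> None:
        errs = self.validation_errors()
        if errs:
            raise ValueError(f"invalid strategy {self.name!r}: " + "; ".join(errs))

    def __post_init__(self) -> None:
        self.validate()


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual probabilities of death.

    Lookups outside the tabulated age range clamp to the nearest endpoint.
    """

    ages: tuple[int, ...]
    q_annual: tuple[float, ...]

    def __post_init__(self) -> None:
        ages = tuple(int(a) for a in self.ages)
        q = tuple(float(v) for v in self.q_annual)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)
        if len(ages) == 0 or len(ages) != len(q):
            raise ValueError("life table needs equal, non-zero numbers of ages and probabilities")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("life-table ages must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in q):
            raise ValueError("annual mortality probabilities must lie in [0, 1]")

    def q_at(self, age: float) -> float:
        """Annual death probability at integer ``floor(age)``, clamped to
        the table's range."""
        a = int(math.floor(age))
        if a <= self.ages[0]:
            return self.q_annual[0]
        if a >= self.ages[-1]:
            return self.q_annual[-1]
        idx = int(np.searchsorted(np.asarray(self.ages), a, side="right")) - 1
        return self.q_annual[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_mortality_probability": self.q_annual})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"age", "annual_mortality_probability"}
        if not required.issubset(df.columns):
            raise ValueError(f"life-table CSV must have columns {sorted(required)}")
        return cls(tuple(df["age"]), tuple(df["annual_mortality_probability"]))


@dataclass(frozen=True)
class ModelSettings:
    """Run-level knobs: horizon, cycle length, discounting, perspective."""

    cycle_length_years: float = 0.5
    horizon_years: float = 35.0
    discount_rate_annual: float = 0.03
    start_age_years: float = 25.0
    perspective: Perspective = Perspective.HEALTHCARE
    half_cycle_correction: bool = False
    nochange_first_cycle_mode: NoChangeFirstCycleMode = NoChangeFirstCycleMode.CONTINUE_50

    def __post_init__(self) -> None:
        object.__setattr__(self, "perspective", Perspective(self.perspective))
        object.__setattr__(
            self, "nochange_first_cycle_mode", NoChangeFirstCycleMode(self.nochange_first_cycle_mode)
        )
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if not 0.0 <= self.discount_rate_annual < 1.0:
            raise ValueError("discount_rate_annual must lie in [0, 1)")
        if self.cycle_length_years <= 0:
            raise ValueError("cycle_length_years must be positive")
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"horizon_years={self.horizon_years} is not an integer number of "
                f"{self.cycle_length_years}-year cycles"
            )

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))


@dataclass(frozen=True)
class CohortTrace:
    """Result of a cohort run: per-cycle occupancy and discounted accruals.

    ``occupancy`` has ``n_cycles + 1`` rows; row 0 is the entry distribution
    (the whole cohort in ``NOCHANGE_ON_TX``, awaiting its response draw) and
    row ``k`` is the distribution occupied during cycle ``k``.  The accrual
    vectors are already discounted (and, if half-cycle correction is on,
    already carry the trapezoid weights), so the totals are plain sums.
    """

    occupancy: np.ndarray
    cost_per_cycle: np.ndarray
    qaly_per_cycle: np.ndarray
    ages: np.ndarray
    perspective: Perspective

    @property
    def total_cost(self) -> float:
        return float(self.cost_per_cycle.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_per_cycle.sum())

    @property
    def totals(self) -> tuple[float, float]:
        return (self.total_cost, self.total_qaly)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.cost_per_cycle)
        occ = self.occupancy[1 : n + 1]
        return pd.DataFrame(
            {
                "cycle": np.arange(1, n + 1),
                "age": self.ages[:n],
                "improved_on_tx": occ[:, HealthState.IMPROVED_ON_TX],
                "nochange_on_tx": occ[:, HealthState.NOCHANGE_ON_TX],
                "discontinued": occ[:, HealthState.DISCONTINUED],
                "dead": occ[:, HealthState.DEAD],
                "discounted_cost": self.cost_per_cycle,
                "discounted_qaly": self.qaly_per_cycle,
            }
        )


def annual_to_cycle_prob(p_annual: float, cycle_length_years: float) -> float:
    """Convert an annual event probability to a per-cycle probability under
    a constant hazard: ``1 - (1 - p)**L``."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual={p_annual!r} outside [0, 1]")
    if cycle_length_years <= 0:
        raise ValueError("cycle_length_years must be positive")
    return 1.0 - (1.0 - p_annual) ** cycle_length_years


def discount_weight(rate_annual: float, cycle_index: int, cycle_length_years: float) -> float:
    """Discount weight of cycle ``cycle_index`` (1-based); cycle 1 is
    undiscounted because rewards accrue at cycle start."""
    if rate_annual < 0:
        raise ValueError("rate_annual must be >= 0")
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    return (1.0 + rate_annual) ** (-(cycle_index - 1) * cycle_length_years)


def cycle_cost(
    strategy: StrategyDefinition,
    state: HealthState,
    cycle_index: int,
    perspective: Perspective,
) -> float:
    """Undiscounted per-person cost of spending ``cycle_index`` in ``state``.

    Only on-treatment states accrue costs: cycle 1 adds the initial visit
    and the first-cycle injection series; later cycles accrue drug and
    maintenance-injection costs.  The societal perspective adds lost
    half-day wages per clinic visit.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    state = HealthState(state)
    perspective = Perspective(perspective)
    if state not in ON_TREATMENT_STATES:
        return 0.0
    cs = strategy.cost_schedule
    if cycle_index == 1:
        cost = (
            cs.initial_visit_cost
            + cs.drug_cost_per_cycle
            + cs.injections_first_cycle * cs.injection_unit_cost
        )
        visits = cs.visits_first_cycle_societal
    else:
        cost = cs.drug_cost_per_cycle + cs.injections_subsequent_cycle * cs.injection_unit_cost
        visits = cs.visits_subsequent_cycle_societal
    if perspective is Perspective.SOCIETAL:
        cost += visits * cs.halfday_wage_loss
    return cost


def _state_utilities(strategy: StrategyDefinition) -> np.ndarray:
    u = np.empty(4)
    u[HealthState.IMPROVED_ON_TX] = strategy.utility_improved
    u[HealthState.NOCHANGE_ON_TX] = strategy.utility_baseline
    u[HealthState.DISCONTINUED] = strategy.utility_baseline
    u[HealthState.DEAD] = 0.0
    return u


def build_transition_matrix(
    strategy: StrategyDefinition,
    settings: ModelSettings,
    cycle_index: int,
    life_table: LifeTable,
) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix applied entering cycle
    ``cycle_index``.

    Death applies uniformly to all alive states; conditional on survival,
    cycle 1 splits the entering cohort into responders and non-responders,
    cycle 2 applies the early continuation probabilities, and later cycles
    the steady-state ones.  There is no transition between the two
    on-treatment states after the entry split.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    strategy.validate()
    age = math.floor(settings.start_age_years + (cycle_index - 1) * settings.cycle_length_years)
    d = annual_to_cycle_prob(life_table.q_at(age), settings.cycle_length_years)
    s = 1.0 - d

    I, N, D, X = (
        HealthState.IMPROVED_ON_TX,
        HealthState.NOCHANGE_ON_TX,
        HealthState.DISCONTINUED,
        HealthState.DEAD,
    )
    m = np.zeros((4, 4))
    m[X, X] = 1.0
    m[D, D] = s
    m[D, X] = d

    if cycle_index == 1:
        # entry split: the cohort (parked in NOCHANGE_ON_TX) draws its
        # treatment response; the IMPROVED row mirrors it for stochasticity
        # of the (unoccupied) row.
        for row in (I, N):
            m[row, I] = s * strategy.p_improve_first
            m[row, N] = s * (1.0 - strategy.p_improve_first)
            m[row, X] = d
        return m

    c_improved = (
        strategy.p_continue_improved_first
        if cycle_index == 2
        else strategy.p_continue_improved_subsequent
    )
    m[I, I] = s * c_improved
    m[I, D] = s * (1.0 - c_improved)
    m[I, X] = d

    if (
        cycle_index == 2
        and settings.nochange_first_cycle_mode is NoChangeFirstCycleMode.OFFTX_TABLE
    ):
        c_nochange = 1.0 - strategy.p_offtx_nochange_alt
    else:
        c_nochange = strategy.p_continue_nochange
    m[N, N] = s * c_nochange
    m[N, D] = s * (1.0 - c_nochange)
    m[N, X] = d
    return m


def run_cohort(
    strategy: StrategyDefinition,
    settings: ModelSettings,
    life_table: LifeTable,
) -> CohortTrace:
    """Run the cohort simulation for one strategy and return its trace.

    Per-cycle QALYs are occupancy x utility x cycle length x discount
    weight; per-cycle costs are occupancy x state cost x discount weight,
    for the perspective configured in ``settings``.  With half-cycle
    correction on, the per-cycle vectors carry trapezoid weights (half
    weight on cycle 1 plus a half-weighted extra cycle beyond the horizon).
    """
    n = settings.n_cycles
    L = settings.cycle_length_years
    utilities = _state_utilities(strategy)

    n_reward = n + 1 if settings.half_cycle_correction else n
    occupancy = np.zeros((n + 1, 4))
    occupancy[0, HealthState.NOCHANGE_ON_TX] = 1.0
    cost = np.zeros(n_reward)
    qaly = np.zeros(n_reward)
    ages = np.zeros(n_reward)

    state_costs_first = np.array(
        [cycle_cost(strategy, HealthState(j), 1, settings.perspective) for j in range(4)]
    )
    state_costs_later = np.array(
        [cycle_cost(strategy, HealthState(j), 2, settings.perspective) for j in range(4)]
    )

    occ = occupancy[0]
    for k in range(1, n_reward + 1):
        m = build_transition_matrix(strategy, settings, k, life_table)
        occ = occ @ m
        if k <= n:
            occupancy[k] = occ
        w = discount_weight(settings.discount_rate_annual, k, L)
        state_costs = state_costs_first if k == 1 else state_costs_later
        cost[k - 1] = w * float(occ @ state_costs)
        qaly[k - 1] = w * L * float(occ @ utilities)
        ages[k - 1] = math.floor(settings.start_age_years + (k - 1) * L)

    if settings.half_cycle_correction:
        cost[0] *= 0.5
        qaly[0] *= 0.5
        cost[-1] *= 0.5
        qaly[-1] *= 0.5

    return CohortTrace(
        occupancy=occupancy,
        cost_per_cycle=cost,
        qaly_per_cycle=qaly,
        ages=ages,
        perspective=settings.perspective,
    )


@dataclass(frozen=True)
class DecisionModel:
    """A complete decision problem: competing strategies, shared settings
    and a shared life table."""

    strategies: tuple[StrategyDefinition, ...]
    settings: ModelSettings
    life_table: LifeTable

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate strategy names: {names}")
        if not self.strategies:
            raise ValueError("a DecisionModel needs at least one strategy")

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.strategies)

    def strategy(self, name: str) -> StrategyDefinition:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}; have {self.strategy_names}")

    def with_settings(self, **changes) -> "DecisionModel":
        return replace(self, settings=replace(self.settings, **changes))

    def run(self, name: str, perspective: Perspective | None = None) -> CohortTrace:
        settings = self.settings
        if perspective is not None:
            settings = replace(settings, perspective=Perspective(perspective))
        return run_cohort(self.strategy(name), settings, self.life_table)

    def run_all(self, perspective: Perspective | None = None) -> dict[str, CohortTrace]:
        return {s.name: self.run(s.name, perspective) for s in self.strategies}

    def totals(self, perspective: Perspective | None = None) -> pd.DataFrame:
        """Total discounted cost and QALYs per strategy, as a DataFrame
        indexed by strategy name."""
        rows = {
            name: {"cost": t.total_cost, "qaly": t.total_qaly}
            for name, t in self.run_all(perspective).items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")
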