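"""Probabilistic sensitivity analysis (second-order Monte Carlo).

Parameter uncertainty is expressed through beta distributions for
probabilities and utilities and gamma distributions for costs, both
parameterized by their mean and standard deviation via the method of
moments.  Each iteration draws one value per uncertain parameter (a single
draw shared across strategies for shared parameters), re-runs the
deterministic cohort model, and records total cost and QALYs per strategy.
Cost-effectiveness acceptability curves report, per willingness-to-pay
threshold, the fraction of iterations in which each strategy attains the
highest net monetary benefit.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DecisionModel, Perspective
from .paths import get_param, set_param

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "DistributionSpec",
    "PSAResult",
    "beta_from_mean_sd",
    "gamma_from_mean_sd",
    "default_distribution_specs",
    "run_psa",
    "ceac",
]


class Family(str, enum.Enum):
    BETA = "beta"
    GAMMA = "gamma"


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta parameters ``(alpha, beta)``.

    Requires ``0 < mean < 1`` and ``sd**2 < mean * (1 - mean)``; the
    returned distribution has exactly the requested mean and SD.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean!r}")
    if sd <= 0:
        raise ValueError(f"beta sd must be positive, got {sd!r}")
    v = sd * sd
    bound = mean * (1.0 - mean)
    if v >= bound:
        raise ValueError(
            f"infeasible beta moments: sd^2={v:g} must be < mean*(1-mean)={bound:g}"
        )
    nu = bound / v - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma parameters ``(shape, scale)``."""
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma mean and sd must be positive, got {mean!r}, {sd!r}")
    return (mean / sd) ** 2, sd * sd / mean


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty on one parameter path.

    ``sd == 0`` is allowed and degenerates to the (deterministic) mean,
    which is convenient for switch-off experiments.
    """

    path: str
    family: Family
    mean: float
    sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.sd > 0:
            # raises on infeasible moments
            if self.family is Family.BETA:
                beta_from_mean_sd(self.mean, self.sd)
            else:
                gamma_from_mean_sd(self.mean, self.sd)
        elif self.family is Family.BETA and not 0.0 <= self.mean <= 1.0:
            raise ValueError("degenerate beta mean must lie in [0, 1]")
        elif self.family is Family.GAMMA and self.mean < 0:
            raise ValueError("degenerate gamma mean must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        if self.family is Family.BETA:
            a, b = beta_from_mean_sd(self.mean, self.sd)
            return rng.beta(a, b, size=n)
        shape, scale = gamma_from_mean_sd(self.mean, self.sd)
        return rng.gamma(shape, scale, size=n)


def default_distribution_specs(
    model: DecisionModel,
    rel_sd_prob: float = 0.10,
    rel_sd_cost: float = 0.20,
) -> list[DistributionSpec]:
    """Default uncertain-parameter set for a model.

    Per strategy: the first-cycle improvement probability and the improved
    utility (beta, relative SD ``rel_sd_prob``); shared across carrying
    strategies: the per-cycle drug cost and the per-injection cost (gamma,
    relative SD ``rel_sd_cost``).  SDs of beta parameters are truncated to
    stay inside the feasible moment region.
    """
    specs: list[DistributionSpec] = []
    for s in model.strategies:
        for fld in ("p_improve_first", "utility_improved"):
            mean = get_param(model, f"{s.name}/{fld}")
            if not 0.0 < mean < 1.0:
                continue
            sd = rel_sd_prob * mean
            sd_max = 0.999 * np.sqrt(mean * (1.0 - mean))
            specs.append(
                DistributionSpec(f"{s.name}/{fld}", Family.BETA, mean, min(sd, sd_max))
            )
    for fld in ("cost_schedule.drug_cost_per_cycle", "cost_schedule.injection_unit_cost"):
        try:
            mean = get_param(model, f"*/{fld}")
        except (KeyError, ValueError):
            continue
        specs.append(DistributionSpec(f"*/{fld}", Family.GAMMA, mean, rel_sd_cost * mean))
    return specs


@dataclass
class PSAResult:
    """Monte Carlo iterations of the cohort model under parameter
    uncertainty."""

    n_iterations: int
    seed: int
    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iterations, n_strategies)
    qalys: np.ndarray
    wtp_grid: tuple[float, ...]
    perspective: Perspective
    draws: pd.DataFrame = field(repr=False, default=None)
    clip_count: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_cost": self.costs.mean(axis=0),
                "sd_cost": self.costs.std(axis=0, ddof=1) if self.n_iterations > 1 else 0.0,
                "mean_qaly": self.qalys.mean(axis=0),
                "sd_qaly": self.qalys.std(axis=0, ddof=1) if self.n_iterations > 1 else 0.0,
            },
            index=list(self.strategies),
        )

    def acceptability(self, wtp_grid: tuple[float, ...] | None = None) -> pd.DataFrame:
        return ceac(self, wtp_grid)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for j, name in enumerate(self.strategies):
            recs.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iterations),
                        "strategy": name,
                        "cost": self.costs[:, j],
                        "qaly": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)


def run_psa(
    model: DecisionModel,
    specs: list[DistributionSpec] | None = None,
    n_iterations: int = 10_000,
    seed: int = 0,
    wtp_grid: tuple[float, ...] = (50_000.0, 100_000.0, 200_000.0),
    perspective: Perspective | None = None,
) -> PSAResult:
    """Run the probabilistic sensitivity analysis.

    All randomness flows through one seeded generator; parameters are
    sampled in sorted-path order, so identical seeds and specs give
    bit-identical results.  Sampled beta values are clipped into [0, 1]
    (clip events are counted and logged).
    """
    if specs is None:
        specs = default_distribution_specs(model)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    specs = sorted(specs, key=lambda s: s.path)
    paths = [s.path for s in specs]
    if len(set(paths)) != len(paths):
        raise ValueError(f"duplicate distribution paths: {paths}")

    persp = Perspective(perspective) if perspective is not None else model.settings.perspective
    rng = np.random.default_rng(seed)

    draws = np.empty((n_iterations, len(specs)))
    clip_count = 0
    for j, spec in enumerate(specs):
        x = spec.sample(rng, n_iterations)
        if spec.family is Family.BETA:
            clipped = np.clip(x, 0.0, 1.0)
            clip_count += int((clipped != x).sum())
            x = clipped
        draws[:, j] = x
    if clip_count:
        logger.info("PSA clipped %d sampled values into [0, 1]", clip_count)

    names = model.strategy_names
    costs = np.empty((n_iterations, len(names)))
    qalys = np.empty((n_iterations, len(names)))
    for i in range(n_iterations):
        m = model
        for j, spec in enumerate(specs):
            m = set_param(m, spec.path, float(draws[i, j]))
        totals = m.totals(persp)
        costs[i] = totals["cost"].to_numpy()
        qalys[i] = totals["qaly"].to_numpy()

    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        strategies=tuple(names),
        costs=costs,
        qalys=qalys,
        wtp_grid=tuple(wtp_grid),
        perspective=persp,
        draws=pd.DataFrame(draws, columns=paths),
        clip_count=clip_count,
    )


def ceac(result: PSAResult, wtp_grid: tuple[float, ...] | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each WTP, the fraction of iterations in which each strategy has
    the maximum net monetary benefit; ties go to the strategy with the
    lower cost in that iteration, so the fractions sum to exactly 1.
    """
    if result.n_iterations < 1 or result.costs.size == 0:
        raise ValueError("empty PSA result")
    grid = tuple(wtp_grid) if wtp_grid is not None else result.wtp_grid
    rows = []
    order_by_cost = np.argsort(result.costs, axis=1, kind="stable")
    for w in grid:
        nmb = w * result.qalys - result.costs
        # scan strategies from cheapest to dearest per iteration; the first
        # one attaining the row max wins ties
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best
        winner = np.empty(result.n_iterations, dtype=int)
        for i in range(result.n_iterations):
            for j in order_by_cost[i]:
                if is_best[i, j]:
                    winner[i] = j
                    break
        frac = np.bincount(winner, minlength=len(result.strategies)) / result.n_iterations
        rows.append({"wtp": w, **{s: frac[j] for j, s in enumerate(result.strategies)}})
    return pd.DataFrame(rows).set_index("wtp")
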