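"""Cost-effectiveness metrics: CE ratios, ICERs, net monetary benefit, and
incremental analysis with strict and extended dominance.

The efficiency frontier is the set of strategies on the upper-left convex
hull of the (QALY, cost) cloud: strictly dominated strategies (another
strategy is at least as cheap and at least as effective, one strictly) are
removed first, then extendedly dominated ones (their incremental
cost-effectiveness ratio exceeds that of the next more-effective
candidate), leaving strategies with strictly increasing cost, effect and
ICER.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .model import DecisionModel, Perspective

__all__ = [
    "Dominance",
    "StrategyOutcome",
    "StrategyRow",
    "CEAResult",
    "ce_ratio",
    "icer",
    "nmb",
    "incremental_analysis",
    "evaluate_model",
]


class Dominance(str, enum.Enum):
    NONE = "none"
    STRICT = "strict"
    EXTENDED = "extended"


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-strategy totals feeding the incremental analysis."""

    name: str
    total_cost: float
    total_qaly: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.total_cost):
            raise ValueError(f"{self.name}: total_cost must be finite")
        if self.total_qaly < 0:
            raise ValueError(f"{self.name}: total_qaly must be >= 0")


def ce_ratio(cost: float, qaly: float) -> float:
    """Average cost-effectiveness ratio, cost per QALY."""
    if qaly <= 0:
        raise ValueError(f"qaly must be positive, got {qaly!r}")
    return cost / qaly


def icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio; sign-preserving."""
    if delta_qaly == 0:
        raise ZeroDivisionError(
            "ICER undefined for delta_qaly == 0; report dominance/equivalence instead"
        )
    return delta_cost / delta_qaly


def nmb(wtp: float, qaly: float, cost: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold:
    ``wtp * qaly - cost``."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * qaly - cost


@dataclass
class StrategyRow:
    """One line of the incremental-analysis table."""

    name: str
    cost: float
    qaly: float
    ce_ratio: float
    dominance: Dominance = Dominance.NONE
    comparator: str | None = None
    incremental_cost: float | None = None
    incremental_qaly: float | None = None
    icer: float | None = None
    on_frontier: bool = True
    nmb: dict[float, float] = field(default_factory=dict)


@dataclass
class CEAResult:
    """Incremental analysis over a strategy set.

    ``rows`` are ordered by ascending cost (ties broken by higher QALY);
    ``preferred`` maps each WTP threshold to the NMB-maximizing strategy.
    """

    rows: list[StrategyRow]
    wtp_list: tuple[float, ...]
    perspective: Perspective | None = None

    @property
    def frontier(self) -> list[str]:
        return [r.name for r in self.rows if r.on_frontier]

    @property
    def preferred(self) -> dict[float, str]:
        out: dict[float, str] = {}
        for w in self.wtp_list:
            # ties (measure-zero) break toward lower cost = earlier row
            out[w] = max(self.rows, key=lambda r: (r.nmb[w], -r.cost)).name
        return out

    def row(self, name: str) -> StrategyRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "strategy": r.name,
                "cost": r.cost,
                "incremental_cost": r.incremental_cost,
                "qaly": r.qaly,
                "incremental_qaly": r.incremental_qaly,
                "ce_ratio": r.ce_ratio,
                "icer": r.icer,
                "comparator": r.comparator,
                "dominance": r.dominance.value,
                "on_frontier": r.on_frontier,
            }
            for w in self.wtp_list:
                rec[f"nmb_at_{w:g}"] = r.nmb[w]
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


def _strictly_dominated(row: StrategyRow, others: list[StrategyRow]) -> bool:
    for o in others:
        if o is row:
            continue
        if o.cost <= row.cost and o.qaly >= row.qaly and (o.cost < row.cost or o.qaly > row.qaly):
            return True
    return False


def incremental_analysis(
    outcomes: list[StrategyOutcome],
    wtp_list: tuple[float, ...] = (50_000.0, 100_000.0),
    perspective: Perspective | None = None,
) -> CEAResult:
    """Full incremental cost-effectiveness analysis.

    Sorts by cost, flags strict and extended dominance, computes ICERs
    along the efficiency frontier (each frontier member vs the previous
    one), and NMBs for every strategy at every WTP.  Dominated strategies
    still get a labelled ICER against the cheapest strategy, mirroring how
    published tables often report them.
    """
    names = [o.name for o in outcomes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy names: {names}")
    if not outcomes:
        raise ValueError("need at least one strategy outcome")

    ordered = sorted(outcomes, key=lambda o: (o.total_cost, -o.total_qaly))
    rows = [
        StrategyRow(
            name=o.name,
            cost=o.total_cost,
            qaly=o.total_qaly,
            ce_ratio=ce_ratio(o.total_cost, o.total_qaly) if o.total_qaly > 0 else math.nan,
            nmb={w: nmb(w, o.total_qaly, o.total_cost) for w in wtp_list},
        )
        for o in ordered
    ]

    for r in rows:
        if _strictly_dominated(r, rows):
            r.dominance = Dominance.STRICT
            r.on_frontier = False

    # extended dominance: repeatedly drop candidates whose ICER vs the
    # previous survivor exceeds the next candidate's
    candidates = [r for r in rows if r.on_frontier]
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            prev, cur, nxt = candidates[i - 1], candidates[i], candidates[i + 1]
            if cur.qaly == prev.qaly:
                continue
            icer_cur = icer(cur.cost - prev.cost, cur.qaly - prev.qaly)
            icer_nxt = icer(nxt.cost - cur.cost, nxt.qaly - cur.qaly) if nxt.qaly != cur.qaly else math.inf
            if icer_cur > icer_nxt:
                cur.dominance = Dominance.EXTENDED
                cur.on_frontier = False
                candidates.pop(i)
                changed = True
                break

    # equal-outcome duplicates of a frontier member add nothing
    frontier = [r for r in rows if r.on_frontier]
    seen: list[StrategyRow] = []
    for r in frontier:
        if seen and r.cost == seen[-1].cost and r.qaly == seen[-1].qaly:
            r.on_frontier = False
        else:
            seen.append(r)
    frontier = [r for r in rows if r.on_frontier]

    # ICERs along the frontier
    for prev, cur in zip(frontier, frontier[1:]):
        cur.comparator = prev.name
        cur.incremental_cost = cur.cost - prev.cost
        cur.incremental_qaly = cur.qaly - prev.qaly
        cur.icer = icer(cur.incremental_cost, cur.incremental_qaly)

    # labelled ICERs for dominated strategies, vs the cheapest strategy
    cheapest = rows[0]
    for r in rows:
        if r.on_frontier or r is cheapest:
            continue
        r.comparator = cheapest.name
        r.incremental_cost = r.cost - cheapest.cost
        r.incremental_qaly = r.qaly - cheapest.qaly
        r.icer = icer(r.incremental_cost, r.incremental_qaly) if r.incremental_qaly != 0 else None

    return CEAResult(rows=rows, wtp_list=tuple(wtp_list), perspective=perspective)


def evaluate_model(
    model: DecisionModel,
    wtp_list: tuple[float, ...] = (50_000.0, 100_000.0),
    perspective: Perspective | None = None,
) -> CEAResult:
    """Run every strategy of a :class:`DecisionModel` and perform the
    incremental analysis on the resulting totals."""
    persp = Perspective(perspective) if perspective is not None else model.settings.perspective
    totals = model.totals(persp)
    outcomes = [
        StrategyOutcome(name, float(row["cost"]), float(row["qaly"]))
        for name, row in totals.iterrows()
    ]
    return incremental_analysis(outcomes, wtp_list=tuple(wtp_list), perspective=persp)
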