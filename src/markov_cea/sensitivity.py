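"""Deterministic sensitivity analysis: one-way sweeps, two-way grids, and
threshold (break-even price) analysis.

Each grid point re-runs the full cohort model with exactly one (or two)
parameters changed from the base case, computes every strategy's net
monetary benefit at the chosen willingness-to-pay, and labels the
NMB-maximizing strategy (ties go to the cheaper strategy).  Outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import nmb
from .model import DecisionModel, Perspective
from .paths import get_param, set_param

__all__ = ["ParameterRange", "TwoWayGrid", "one_way", "two_way", "threshold_price"]


@dataclass(frozen=True)
class ParameterRange:
    """An evenly spaced sweep over one parameter path.

    A degenerate range (``lower == upper``, ``n_points == 1``) evaluates a
    single point; otherwise ``lower < upper`` and ``n_points >= 2``.
    """

    path: str
    lower: float
    upper: float
    n_points: int = 101

    def __post_init__(self) -> None:
        if self.lower == self.upper:
            if self.n_points != 1:
                raise ValueError("a degenerate range (lower == upper) needs n_points == 1")
        elif not (self.lower < self.upper and self.n_points >= 2):
            raise ValueError("need lower < upper and n_points >= 2")

    def values(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_points)


@dataclass(frozen=True)
class TwoWayGrid:
    """Result of a two-way sweep: preferred strategy per (x, y) cell."""

    x_path: str
    y_path: str
    x_values: np.ndarray
    y_values: np.ndarray
    preferred: np.ndarray  # shape (len(y_values), len(x_values)), strategy names
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                self.x_path: self.x_values[j],
                self.y_path: self.y_values[i],
                "preferred": self.preferred[i, j],
            }
            for i in range(len(self.y_values))
            for j in range(len(self.x_values))
        ]
        return pd.DataFrame.from_records(recs)


def _nmbs(model: DecisionModel, wtp: float, perspective: Perspective | None) -> dict[str, float]:
    totals = model.totals(perspective)
    return {
        name: nmb(wtp, float(row["qaly"]), float(row["cost"])) for name, row in totals.iterrows()
    }


def _preferred(model: DecisionModel, nmbs: dict[str, float], perspective, _costs=None) -> str:
    # tie-break: lower total cost wins
    totals = model.totals(perspective) if _costs is None else _costs
    return max(nmbs, key=lambda n: (nmbs[n], -float(totals.loc[n, "cost"])))


def one_way(
    model: DecisionModel,
    parameter_range: ParameterRange,
    wtp: float,
    perspective: Perspective | None = None,
) -> pd.DataFrame:
    """Sweep one parameter, holding everything else at base case.

    Returns a table with the parameter value, each strategy's NMB, and the
    preferred (NMB-maximizing) strategy per grid point.
    """
    records = []
    for v in parameter_range.values():
        m = set_param(model, parameter_range.path, float(v))
        totals = m.totals(perspective)
        nmbs = {
            name: nmb(wtp, float(r["qaly"]), float(r["cost"])) for name, r in totals.iterrows()
        }
        rec = {parameter_range.path: float(v)}
        rec.update({f"nmb_{n}": x for n, x in nmbs.items()})
        rec["preferred"] = _preferred(m, nmbs, perspective, _costs=totals)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def two_way(
    model: DecisionModel,
    range_x: ParameterRange,
    range_y: ParameterRange,
    wtp: float,
    perspective: Perspective | None = None,
) -> TwoWayGrid:
    """Full-factorial two-parameter sweep labelling the preferred strategy
    in each cell."""
    xs = range_x.values()
    ys = range_y.values()
    preferred = np.empty((len(ys), len(xs)), dtype=object)
    for i, y in enumerate(ys):
        my = set_param(model, range_y.path, float(y))
        for j, x in enumerate(xs):
            m = set_param(my, range_x.path, float(x))
            totals = m.totals(perspective)
            nmbs = {
                name: nmb(wtp, float(r["qaly"]), float(r["cost"]))
                for name, r in totals.iterrows()
            }
            preferred[i, j] = _preferred(m, nmbs, perspective, _costs=totals)
    return TwoWayGrid(
        x_path=range_x.path,
        y_path=range_y.path,
        x_values=xs,
        y_values=ys,
        preferred=preferred,
        wtp=wtp,
    )


def threshold_price(
    model: DecisionModel,
    parameter_path: str,
    strategy: str,
    comparator: str,
    wtp: float,
    bracket: tuple[float, float] = (0.0, 1000.0),
    perspective: Perspective | None = None,
    tol: float = 0.01,
) -> float | None:
    """Break-even value of a cost parameter between two strategies.

    Finds the parameter value at which ``NMB(strategy) == NMB(comparator)``
    at the given WTP.  The NMB difference is affine in any unit-cost
    parameter (the discounted expected number of billed units does not
    depend on the price), so the bisection root is cross-checked against
    the exact two-point linear solution; the two must agree to ``tol``.
    Returns ``None`` when the difference does not change sign inside the
    bracket.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lower < upper")

    def diff(price: float) -> float:
        m = set_param(model, parameter_path, price)
        nmbs = _nmbs(m, wtp, perspective)
        return nmbs[strategy] - nmbs[comparator]

    f_lo, f_hi = diff(lo), diff(hi)
    # closed-form root of the affine difference through the bracket ends
    slope = (f_hi - f_lo) / (hi - lo)
    linear_root = lo - f_lo / slope if slope != 0 else None

    if f_lo == 0.0 and f_hi == 0.0:
        return None  # identically equal: nothing to cross
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return None

    a, b, fa = lo, hi, f_lo
    while b - a > tol:
        mid = 0.5 * (a + b)
        fm = diff(mid)
        if fm == 0.0:
            a = b = mid
            break
        if fa * fm < 0:
            b = mid
        else:
            a, fa = mid, fm
    root = 0.5 * (a + b)

    if linear_root is not None and abs(root - linear_root) > max(tol, 1e-6 * max(1.0, abs(root))):
        raise ArithmeticError(
            f"bisection root {root:.4f} disagrees with the affine closed form "
            f"{linear_root:.4f}; NMB difference is not linear in {parameter_path!r}"
        )
    return float(linear_root if linear_root is not None else root)
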