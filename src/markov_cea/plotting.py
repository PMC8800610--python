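"""Matplotlib figures: two-way sensitivity heatmaps, PSA scatterplots and
cost-effectiveness acceptability curves.

Figures are built without pyplot so plotting works headless; every
function returns the Figure and optionally saves it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .psa import PSAResult
from .sensitivity import TwoWayGrid

__all__ = ["plot_two_way", "plot_ceac", "plot_psa_scatter"]

_COLORS = ["#1f77b4", "#9467bd", "#d62728", "#2ca02c", "#ff7f0e", "#8c564b"]


def _save(fig: Figure, path) -> Figure:
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def plot_two_way(grid: TwoWayGrid, path=None) -> Figure:
    """Heatmap of the preferred strategy over a two-parameter grid."""
    names = sorted({str(v) for v in grid.preferred.ravel()})
    index = {n: i for i, n in enumerate(names)}
    z = np.vectorize(index.get)(grid.preferred).astype(float)

    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap([_COLORS[i % len(_COLORS)] for i in range(len(names))])
    ax.pcolormesh(grid.x_values, grid.y_values, z, cmap=cmap, vmin=-0.5, vmax=len(names) - 0.5)
    ax.set_xlabel(grid.x_path)
    ax.set_ylabel(grid.y_path)
    ax.set_title(f"Preferred strategy at WTP ${grid.wtp:,.0f}/QALY")
    handles = [
        ax.plot([], [], "s", color=_COLORS[i % len(_COLORS)], label=n)[0]
        for i, n in enumerate(names)
    ]
    ax.legend(handles=handles, loc="best", fontsize=8)
    return _save(fig, path)


def plot_ceac(acceptability: pd.DataFrame, path=None) -> Figure:
    """Acceptability fractions (rows: WTP; columns: strategies) as curves."""
    fig = Figure(figsize=(6, 4))
    ax = fig.add_subplot(111)
    for i, col in enumerate(acceptability.columns):
        ax.plot(
            acceptability.index,
            acceptability[col],
            marker="o",
            color=_COLORS[i % len(_COLORS)],
            label=col,
        )
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Fraction of iterations cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curves")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_psa_scatter(result: PSAResult, path=None) -> Figure:
    """Scatter of (QALY, cost) iterations, one cloud per strategy."""
    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    for j, name in enumerate(result.strategies):
        ax.scatter(
            result.qalys[:, j],
            result.costs[:, j],
            s=4,
            alpha=0.3,
            color=_COLORS[j % len(_COLORS)],
            label=name,
        )
    ax.set_xlabel("Effectiveness (QALY)")
    ax.set_ylabel(f"Cost ({result.perspective.value} perspective, $)")
    ax.set_title(f"PSA scatter, {result.n_iterations} iterations")
    ax.legend(fontsize=8)
    return _save(fig, path)
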