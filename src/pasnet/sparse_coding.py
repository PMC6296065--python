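"""Percentile-threshold sparse coding and per-layer sparsity search.

A layer's sparsity level ``S`` in [0, 100] is the percentage of its
weights to drop: the mask keeps entries with ``|w| >= Q`` where ``Q`` is
the S-th percentile of ``|W|``.  The per-layer optimum ``S*`` is found by
scoring a small grid of levels with the training cost, fitting a cubic
spline through the (S, cost) points, and taking the spline's argmin over
the grid range.  The gene→pathway layer is never sparsified this way —
its mask is the pathway biadjacency matrix for the whole of training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .network import NetworkState

__all__ = [
    "DEFAULT_GRID",
    "SparsitySearchResult",
    "percentile_threshold",
    "build_mask",
    "optimize_layer_sparsity",
    "apply",
]

DEFAULT_GRID: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)

# relative slack used to call interpolated costs tied (tie → sparser model)
_TIE_RTOL = 1e-12


@dataclass
class SparsitySearchResult:
    """Audit record of one per-layer sparsity search."""

    grid: np.ndarray
    grid_costs: np.ndarray
    optimum: float          # S*
    dense_levels: np.ndarray
    dense_costs: np.ndarray  # interpolant evaluations retained for audit

    @property
    def interpolated_minimum(self) -> float:
        return float(self.dense_costs.min())


def percentile_threshold(W: np.ndarray, S: float) -> float:
    """S-th percentile of |W| under the linear-interpolation convention."""
    W = np.asarray(W)
    if W.size == 0:
        raise ValueError("empty weight matrix")
    if not 0.0 <= S <= 100.0:
        raise ValueError("S must lie in [0, 100]")
    return float(np.percentile(np.abs(W), S, method="linear"))


def build_mask(W: np.ndarray, S: float) -> np.ndarray:
    """Binary keep-mask at sparsity level ``S``: 1 iff ``|w| >= Q``.

    ``S = 0`` yields a fully connected layer and ``S = 100`` drops every
    connection; the latter overrides the literal ``>=`` rule (which would
    always keep the largest weight).
    """
    W = np.asarray(W)
    if S >= 100.0:
        return np.zeros_like(W, dtype=float)
    if S <= 0.0:
        return np.ones_like(W, dtype=float)
    Q = percentile_threshold(W, S)
    return (np.abs(W) >= Q).astype(float)


def _fit_interpolant(grid: np.ndarray, costs: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    if len(grid) >= 4:
        return CubicSpline(grid, costs)
    kind = "quadratic" if len(grid) == 3 else "linear"
    return interp1d(grid, costs, kind=kind)


def optimize_layer_sparsity(
    evaluate_cost: Callable[[float], float],
    grid: Sequence[float] = DEFAULT_GRID,
    fine_step: float = 0.5,
) -> SparsitySearchResult:
    """Find the sparsity level minimizing the interpolated cost curve.

    ``evaluate_cost(S)`` scores one grid level.  A cubic spline is fitted
    through the grid scores (quadratic/linear fallback below four
    points), evaluated densely at ``fine_step`` resolution over the grid
    range, and the minimizing level returned.  Ties break toward the
    largest (sparsest) level.
    """
    grid = np.unique(np.asarray(grid, dtype=float))
    if grid.size < 2:
        raise ValueError("sparsity grid needs >= 2 distinct levels")
    if np.any((grid < 0) | (grid > 100)):
        raise ValueError("grid levels must lie in [0, 100]")
    costs = np.array([float(evaluate_cost(S)) for S in grid])
    if not np.all(np.isfinite(costs)):
        raise ValueError("non-finite cost on sparsity grid")

    f = _fit_interpolant(grid, costs)
    lo, hi = grid[0], grid[-1]
    n_steps = int(np.floor((hi - lo) / fine_step))
    dense = np.unique(np.concatenate([lo + fine_step * np.arange(n_steps + 1), [hi], grid]))
    vals = np.asarray(f(dense), dtype=float)
    vmin = vals.min()
    tol = _TIE_RTOL * max(1.0, abs(vmin))
    optimum = float(dense[np.flatnonzero(vals <= vmin + tol)[-1]])
    return SparsitySearchResult(grid, costs, optimum, dense, vals)


def apply(
    state: NetworkState,
    layer: int,
    cost_closure: Callable[[float], float],
    grid: Sequence[float] = DEFAULT_GRID,
    fine_step: float = 0.5,
) -> SparsitySearchResult:
    """Re-derive a layer's mask at its own optimal sparsity, in place.

    Only layers 1 (pathway→hidden) and 2 (hidden→output) may be
    sparsified; the gene→pathway mask is invariant.  ``cost_closure(S)``
    must score the network with that layer's candidate mask in place and
    all other masks fixed; weights themselves are not modified.
    """
    if layer not in (1, 2):
        raise ValueError(
            "only layers 1 and 2 can be sparsified; the gene→pathway mask "
            "is fixed by the pathway biadjacency matrix"
        )
    levels = np.unique(np.asarray(grid, dtype=float))
    if levels.size == 1:  # nothing to search — pin the layer at that level
        cost = np.array([float(cost_closure(levels[0]))])
        result = SparsitySearchResult(levels, cost, float(levels[0]), levels, cost)
    else:
        result = optimize_layer_sparsity(cost_closure, grid, fine_step)
    state.masks[layer] = build_mask(state.weights[layer], result.optimum)
    return result
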