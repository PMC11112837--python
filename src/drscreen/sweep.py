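"""Deterministic sensitivity analyses over the cost model.

A one-way sweep recomputes both strategies' per-patient totals and their
difference while one parameter of one strategy moves over a grid; a
two-way sweep evaluates the full cartesian product of two parameter grids.
Because the cost model is affine in every parameter, the break-even value
(where the two strategies cost the same) has a closed form obtained from
two evaluations; a bisection fallback covers non-affine extensions.

Default grids mirror the published ranges: automated screening fee $33 to
$164 (the conventional DRG weight), conventional-screening patient time
0.5 h to 2 h, automated-screening patient time 5 minutes (1/12 h) to 2 h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .econ import ScreeningStrategy, per_patient_cost
from .errors import ConfigError

__all__ = [
    "ParameterGrid",
    "SweepResult",
    "one_way_sweep",
    "two_way_sweep",
    "break_even",
    "default_ai_cost_grid",
    "default_manual_time_grid",
    "default_ai_time_grid",
]


@dataclass(frozen=True)
class ParameterGrid:
    """An ordered set of values for one (strategy, parameter) target."""

    strategy: str
    parameter: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ConfigError("parameter grid must be non-empty")
        if not all(np.isfinite(vals)):
            raise ConfigError("parameter grid values must be finite")
        object.__setattr__(self, "values", vals)

    @classmethod
    def linspace(
        cls, strategy: str, parameter: str, low: float, high: float, steps: int
    ) -> "ParameterGrid":
        """Inclusive-endpoint evenly spaced grid."""
        return cls(strategy, parameter, tuple(np.linspace(low, high, steps)))


def default_ai_cost_grid(steps: int = 12) -> ParameterGrid:
    return ParameterGrid.linspace("ai", "screening_cost", 33.0, 164.0, steps)


def default_manual_time_grid(steps: int = 7) -> ParameterGrid:
    return ParameterGrid.linspace("manual", "patient_time_hours", 0.5, 2.0, steps)


def default_ai_time_grid(steps: int = 12) -> ParameterGrid:
    return ParameterGrid.linspace("ai", "patient_time_hours", 1.0 / 12.0, 2.0, steps)


@dataclass(frozen=True)
class SweepResult:
    """Per-patient totals and cost differences over one or two grids.

    For a one-way sweep the arrays are vectors over the grid; for a
    two-way sweep they are matrices with entry (i, j) evaluated at
    ``axes[0].values[i]`` and ``axes[1].values[j]``.  The difference is
    total(a) - total(b): positive means strategy b is cost-saving.
    """

    axes: tuple[ParameterGrid, ...]
    strategy_a: str
    strategy_b: str
    total_a: np.ndarray
    total_b: np.ndarray
    difference: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: axis value(s), both totals, difference."""
        if len(self.axes) == 1:
            g = self.axes[0]
            return pd.DataFrame(
                {
                    f"{g.strategy}.{g.parameter}": list(g.values),
                    f"total_{self.strategy_a}": self.total_a,
                    f"total_{self.strategy_b}": self.total_b,
                    "difference": self.difference,
                }
            )
        g1, g2 = self.axes
        v1, v2 = np.meshgrid(g1.values, g2.values, indexing="ij")
        return pd.DataFrame(
            {
                f"{g1.strategy}.{g1.parameter}": v1.ravel(),
                f"{g2.strategy}.{g2.parameter}": v2.ravel(),
                f"total_{self.strategy_a}": self.total_a.ravel(),
                f"total_{self.strategy_b}": self.total_b.ravel(),
                "difference": self.difference.ravel(),
            }
        )

    def to_dict(self) -> dict:
        return {
            "axes": [
                {"strategy": g.strategy, "parameter": g.parameter, "values": list(g.values)}
                for g in self.axes
            ],
            "strategy_a": self.strategy_a,
            "strategy_b": self.strategy_b,
            "total_a": self.total_a.tolist(),
            "total_b": self.total_b.tolist(),
            "difference": self.difference.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _substitute(
    base_a: ScreeningStrategy,
    base_b: ScreeningStrategy,
    grid: ParameterGrid,
    value: float,
) -> tuple[ScreeningStrategy, ScreeningStrategy]:
    if grid.strategy == base_a.name:
        return base_a.with_value(grid.parameter, value), base_b
    if grid.strategy == base_b.name:
        return base_a, base_b.with_value(grid.parameter, value)
    raise ConfigError(
        f"grid targets strategy {grid.strategy!r}; bases are "
        f"{base_a.name!r} and {base_b.name!r}"
    )


def one_way_sweep(
    base_a: ScreeningStrategy, base_b: ScreeningStrategy, grid: ParameterGrid
) -> SweepResult:
    """Evaluate both totals and their difference along one parameter grid."""
    ta, tb = [], []
    for v in grid.values:
        a, b = _substitute(base_a, base_b, grid, v)
        ta.append(per_patient_cost(a).per_patient_total)
        tb.append(per_patient_cost(b).per_patient_total)
    ta = np.asarray(ta)
    tb = np.asarray(tb)
    return SweepResult((grid,), base_a.name, base_b.name, ta, tb, ta - tb)


def two_way_sweep(
    base_a: ScreeningStrategy,
    base_b: ScreeningStrategy,
    grid1: ParameterGrid,
    grid2: ParameterGrid,
) -> SweepResult:
    """Evaluate the cartesian product of two distinct parameter grids."""
    if (grid1.strategy, grid1.parameter) == (grid2.strategy, grid2.parameter):
        raise ConfigError(
            f"two-way sweep requires distinct parameters; got "
            f"{grid1.strategy}.{grid1.parameter} twice"
        )
    shape = (len(grid1.values), len(grid2.values))
    ta = np.empty(shape)
    tb = np.empty(shape)
    for i, v1 in enumerate(grid1.values):
        a1, b1 = _substitute(base_a, base_b, grid1, v1)
        for j, v2 in enumerate(grid2.values):
            a2, b2 = _substitute(a1, b1, grid2, v2)
            ta[i, j] = per_patient_cost(a2).per_patient_total
            tb[i, j] = per_patient_cost(b2).per_patient_total
    return SweepResult((grid1, grid2), base_a.name, base_b.name, ta, tb, ta - tb)


def break_even(
    base_a: ScreeningStrategy,
    base_b: ScreeningStrategy,
    target: tuple[str, str],
    bracket: tuple[float, float],
    tol: float = 1e-9,
) -> float | None:
    """Parameter value at which the two strategies cost the same.

    The cost model is affine in every parameter, so the root follows from
    evaluating the difference at the bracket ends; if the difference turns
    out non-affine (a custom strategy subclass), bisection is used.
    Returns ``None`` when no root lies within the bracket.
    """
    low, high = bracket
    if not low < high:
        raise ConfigError(f"bracket must satisfy low < high, got {bracket}")
    grid = ParameterGrid(target[0], target[1], (low, high))

    def diff(v: float) -> float:
        a, b = _substitute(base_a, base_b, grid, v)
        return per_patient_cost(a).per_patient_total - per_patient_cost(b).per_patient_total

    d_low, d_high = diff(low), diff(high)
    slope = (d_high - d_low) / (high - low)
    if abs(slope) < tol:
        # constant difference over the bracket
        return low if abs(d_low) < tol else None
    root = low - d_low / slope
    if not (low <= root <= high):
        return None
    if abs(diff(root)) <= max(tol, 1e-9 * max(abs(d_low), abs(d_high))):
        return root
    # non-affine extension: fall back to bisection on a sign change
    if d_low * d_high > 0:
        return None
    a, b = low, high
    fa = d_low
    for _ in range(200):
        m = 0.5 * (a + b)
        fm = diff(m)
        if abs(fm) <= tol or (b - a) < tol:
            return m
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
    return 0.5 * (a + b)
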