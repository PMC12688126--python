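"""Steady-state parameter surfaces and regulatory-variant comparisons.

Reproduces the model-level readouts of the study: GA4 at steady state over a
repression-strength x degradation-rate grid, side-by-side dynamics of the
three regulatory variants, and diagnostics for the claim that the
GA-degradable repressor responds nonlinearly to its expression level while
the non-degradable one responds near-linearly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ga_network import (
    ModelDefinition,
    ParameterSet,
    SPECIES_INDEX,
    VariantSpec,
)
from .simulate import (
    DEFAULT_SS_TOL,
    DEFAULT_T_MAX,
    SteadyStateResult,
    Trajectory,
    find_steady_state,
    integrate,
)

__all__ = [
    "ParameterAxis",
    "SweepResult",
    "VariantComparison",
    "sweep_2d",
    "compare_variants",
    "relative_reduction",
    "nonlinearity_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterAxis:
    """One swept parameter: its name, ordered values, and axis scale tag."""

    name: str
    values: tuple[float, ...]
    scale: str = "log"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.name not in ParameterSet.field_names():
            raise ValueError(f"axis parameter {self.name!r} not in ParameterSet")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"axis scale must be linear|log, got {self.scale!r}")
        if len(self.values) < 1 or not np.all(np.diff(self.values) > 0):
            raise ValueError("axis values must be strictly increasing")

    @classmethod
    def log_around(
        cls, name: str, center: float, decades: float = 2.0, n: int = 8
    ) -> "ParameterAxis":
        """``n`` log-spaced values spanning ``10**(-decades)..10**decades`` x center."""
        if center <= 0:
            raise ValueError("log axis needs a positive center value")
        vals = center * np.logspace(-decades, decades, n)
        return cls(name, tuple(vals), "log")

    def to_dict(self) -> dict:
        return {"name": self.name, "values": list(self.values), "scale": self.scale}

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterAxis":
        unknown = sorted(set(data) - {"name", "values", "scale"})
        if unknown:
            raise ValueError(f"unknown axis keys: {', '.join(unknown)}")
        return cls(data["name"], tuple(data["values"]), data.get("scale", "log"))


@dataclass
class SweepResult:
    """Steady-state readout over a 2-D parameter grid.

    ``readout_matrix[i, j]`` is the steady-state readout at
    ``y_axis.values[i]``, ``x_axis.values[j]``; unconverged cells hold NaN
    and are flagged False in ``converged``.
    """

    x_axis: ParameterAxis
    y_axis: ParameterAxis
    readout: str
    readout_matrix: np.ndarray
    converged: np.ndarray
    variant: VariantSpec

    def __post_init__(self) -> None:
        shape = (len(self.y_axis.values), len(self.x_axis.values))
        if self.readout_matrix.shape != shape or self.converged.shape != shape:
            raise ValueError(f"sweep matrices must have shape {shape}")

    def to_long_records(self) -> list[dict]:
        """Long-format rows: x_name, x_value, y_name, y_value, readout, converged."""
        rows = []
        for i, yv in enumerate(self.y_axis.values):
            for j, xv in enumerate(self.x_axis.values):
                rows.append(
                    {
                        "x_name": self.x_axis.name,
                        "x_value": xv,
                        "y_name": self.y_axis.name,
                        "y_value": yv,
                        "readout": self.readout_matrix[i, j],
                        "converged": bool(self.converged[i, j]),
                    }
                )
        return rows


@dataclass
class VariantComparison:
    """The three regulatory variants run from one shared configuration."""

    trajectories: dict[str, Trajectory]
    steady_states: dict[str, SteadyStateResult]
    readout: str = "ga4"

    def readout_trajectory(self, variant: str) -> np.ndarray:
        return self.trajectories[variant][self.readout]

    def steady_readout(self, variant: str) -> float:
        return self.steady_states[variant][self.readout]


def sweep_2d(
    params: ParameterSet,
    variant: VariantSpec,
    axis_x: ParameterAxis,
    axis_y: ParameterAxis,
    readout: str = "ga4",
    tol: float = DEFAULT_SS_TOL,
    t_max: float = DEFAULT_T_MAX,
) -> SweepResult:
    """Steady-state readout at every grid cell of two parameter axes.

    Each cell overrides the two axis parameters on ``params``, applies the
    variant, and locates the steady state.  Along each row the search is
    warm-started from the previous cell's solution (the surface is
    continuous); on non-convergence the cell falls back to the default
    initial state before being flagged.
    """
    if axis_x.name == axis_y.name:
        raise ValueError("sweep axes must reference distinct parameters")
    if readout not in SPECIES_INDEX:
        raise ValueError(f"unknown readout species {readout!r}")
    ny, nx = len(axis_y.values), len(axis_x.values)
    matrix = np.full((ny, nx), np.nan)
    conv = np.zeros((ny, nx), dtype=bool)
    for i, yv in enumerate(axis_y.values):
        warm = None
        for j, xv in enumerate(axis_x.values):
            cell = params.replace(**{axis_x.name: xv, axis_y.name: yv})
            model = ModelDefinition(cell, variant)
            ss = find_steady_state(model, warm, tol=tol, t_max=t_max)
            if not ss.converged and warm is not None:
                ss = find_steady_state(model, None, tol=tol, t_max=t_max)
            if ss.converged:
                matrix[i, j] = ss[readout]
                conv[i, j] = True
                warm = ss.state
            else:
                logger.warning(
                    "sweep cell (%s=%g, %s=%g) did not converge",
                    axis_y.name,
                    yv,
                    axis_x.name,
                    xv,
                )
                warm = None
    return SweepResult(axis_x, axis_y, readout, matrix, conv, variant)


def compare_variants(
    params: ParameterSet,
    init: np.ndarray | None,
    t_grid: np.ndarray,
    target: str = "GA20ox",
    tol: float = DEFAULT_SS_TOL,
    t_max: float = DEFAULT_T_MAX,
) -> VariantComparison:
    """Run wildtype, no-degron repressor, and GAHACR from identical inputs.

    All three share the pre-variant parameter set, initial state and time
    grid; each reports its trajectory and certified steady state.
    """
    trajectories: dict[str, Trajectory] = {}
    steady: dict[str, SteadyStateResult] = {}
    for name in ("wildtype", "no_degron_cr", "gahacr"):
        spec = VariantSpec(name, "none" if name == "wildtype" else target)
        model = ModelDefinition(params, spec)
        trajectories[name] = integrate(model, init, t_grid)
        steady[name] = find_steady_state(model, init, tol=tol, t_max=t_max)
        if not steady[name].converged:
            logger.warning("variant %s steady state did not converge", name)
    return VariantComparison(trajectories, steady)


def relative_reduction(
    sweep: SweepResult, baseline: SteadyStateResult
) -> np.ndarray:
    """Fractional drop of each sweep cell below a no-repressor baseline.

    ``(baseline - cell) / baseline`` per cell; NaN where the cell did not
    converge.  The baseline must be converged with a positive readout.
    """
    if not baseline.converged:
        raise ValueError("baseline steady state is not converged")
    base = baseline[sweep.readout]
    if base <= 0:
        raise ValueError(f"baseline readout must be > 0, got {base}")
    out = (base - sweep.readout_matrix) / base
    out[~sweep.converged] = np.nan
    return out


def nonlinearity_score(
    x: np.ndarray, y: np.ndarray | None = None
) -> float:
    """Departure of a response curve from a straight line: ``1 - R**2``.

    Accepts either an ``(n, 2)`` array of ordered (parameter, readout)
    pairs or two separate vectors.  Exactly linear data scores 0 (a
    constant counts as linear); pure curvature pushes the score toward 1.
    Requires at least 4 points with strictly increasing parameter values.
    """
    if y is None:
        pairs = np.asarray(x, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (parameter, readout) pairs")
        x, y = pairs[:, 0], pairs[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("nonlinearity score needs at least 4 points")
    if x.shape != y.shape:
        raise ValueError("parameter and readout vectors differ in length")
    if not np.all(np.diff(x) > 0):
        raise ValueError("parameter values must be strictly increasing")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    return max(ss_res / ss_tot, 0.0)
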