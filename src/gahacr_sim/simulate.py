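"""Deterministic time-course integration and steady-state location.

Steady states are found by integrate-then-polish: the trajectory is advanced
over successively longer horizons until the RHS residual is small, then a
damped Newton/hybrid root solve is seeded at the integration endpoint.  The
integration phase selects the biologically reached branch; the polish
certifies the equilibrium to tight tolerance.  A result is only marked
converged when its residual actually satisfies the requested bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .ga_network import (
    N_SPECIES,
    SPECIES,
    SPECIES_INDEX,
    ModelDefinition,
)

__all__ = [
    "Trajectory",
    "SteadyStateResult",
    "IntegrationError",
    "integrate",
    "find_steady_state",
    "residual_norm",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "DEFAULT_SS_TOL",
    "DEFAULT_T_MAX",
]

logger = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_SS_TOL = 1e-8
DEFAULT_T_MAX = 5000.0

#: State norms beyond this are treated as divergence, not an equilibrium hunt.
DIVERGENCE_BOUND = 1e12


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time point."""

    def __init__(self, message: str, t_last: float, state_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass
class Trajectory:
    """Solution of one initial-value problem on an explicit time grid."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), n_species)
    species: tuple[str, ...] = SPECIES
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    n_steps: int = 0
    clipped: bool = False  # negative excursions below -atol were zeroed

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.t.size, len(self.species)):
            raise ValueError(
                f"state matrix shape {self.states.shape} inconsistent with "
                f"{self.t.size} time points x {len(self.species)} species"
            )

    def __getitem__(self, species: str) -> np.ndarray:
        """Concentration time series for one species."""
        return self.states[:, SPECIES_INDEX[species]]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class SteadyStateResult:
    """An equilibrium candidate with its certification."""

    state: np.ndarray
    converged: bool
    residual: float
    method: str  # "integration" or "root"
    t_reached: float = np.nan

    def __getitem__(self, species: str) -> float:
        return float(self.state[SPECIES_INDEX[species]])


def integrate(
    model: ModelDefinition,
    init: np.ndarray | None,
    t_grid: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Solve the initial-value problem, reporting the state on ``t_grid``.

    Uses a stiff-capable solver.  Negative excursions beyond ``-atol`` are
    clipped to zero with a logged warning (standard practice for stiff
    biochemical systems); smaller ones are clipped silently.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    y0 = model.prepare_initial_state(init)
    sol = solve_ivp(
        model.rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t_grid[0]
        y_last = sol.y[:, -1] if sol.t.size else y0
        raise IntegrationError(
            f"integration failed at t={t_last:g}: {sol.message}", t_last, y_last
        )
    states = sol.y.T.copy()
    clipped = bool((states < -atol).any())
    if clipped:
        worst = states.min()
        logger.warning(
            "clipping negative concentrations (most negative %.3e) to zero", worst
        )
    np.clip(states, 0.0, None, out=states)
    species = tuple(getattr(model, "species", None) or (f"x{k}" for k in range(y0.size)))
    return Trajectory(
        t=t_grid,
        states=states,
        species=species,
        rtol=rtol,
        atol=atol,
        n_steps=int(sol.t.size if sol.t_events is None else sol.t.size),
        clipped=clipped,
    )


def residual_norm(model: ModelDefinition, state: np.ndarray) -> float:
    """Max-abs norm of the RHS; zero exactly at an equilibrium."""
    return float(np.max(np.abs(model.rhs(0.0, np.asarray(state, dtype=float)))))


def _polish(model: ModelDefinition, guess: np.ndarray, tol: float):
    """Root-solve the RHS from ``guess``; returns (state, residual) or None."""
    try:
        sol = root(lambda y: model.rhs(0.0, y), guess, method="hybr")
    except Exception:  # pragma: no cover - solver-internal failure
        return None
    y = sol.x
    if (y < -1e-9).any() or not np.isfinite(y).all():
        return None
    y = np.clip(y, 0.0, None)
    res = residual_norm(model, y)
    return (y, res) if res < tol else None


def find_steady_state(
    model: ModelDefinition,
    init: np.ndarray | None = None,
    tol: float = DEFAULT_SS_TOL,
    t_max: float = DEFAULT_T_MAX,
    method: str = "root",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SteadyStateResult:
    """Locate the equilibrium reached from ``init``.

    ``method="root"`` (default) integrates over growing horizons and polishes
    with a hybrid root solver as soon as the trajectory is near equilibrium;
    ``method="integration"`` relies on integration alone until the residual
    drops below ``tol``.  On failure the result carries ``converged=False``
    and the best state seen — a sweep never aborts on one bad cell.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if method not in ("root", "integration"):
        raise ValueError(f"unknown steady-state method {method!r}")
    y = model.prepare_initial_state(init)
    t_now = 0.0
    horizon = 50.0
    best = (y.copy(), residual_norm(model, y))
    while t_now < t_max:
        horizon = min(horizon, t_max - t_now)
        try:
            traj = integrate(
                model, y, np.array([0.0, horizon]), rtol=rtol, atol=atol
            )
        except IntegrationError as err:
            logger.warning("steady-state integration aborted: %s", err)
            break
        y = traj.final_state
        t_now += horizon
        horizon *= 2.0
        res = residual_norm(model, y)
        if res < best[1]:
            best = (y.copy(), res)
        if np.max(np.abs(y)) > DIVERGENCE_BOUND:
            logger.warning("state norm exceeded divergence bound; not converged")
            return SteadyStateResult(y, False, res, method, t_now)
        if method == "integration":
            if res < tol:
                return SteadyStateResult(y, True, res, "integration", t_now)
        else:
            # polish once the transient has visibly relaxed
            if res < max(tol, 1e-3):
                polished = _polish(model, y, tol)
                if polished is not None:
                    return SteadyStateResult(
                        polished[0], True, polished[1], "root", t_now
                    )
                if res < tol:
                    return SteadyStateResult(y, True, res, "root", t_now)
    # last attempt at a polish from the best state seen
    if method == "root":
        polished = _polish(model, best[0], tol)
        if polished is not None:
            return SteadyStateResult(polished[0], True, polished[1], "root", t_now)
    state, res = best
    return SteadyStateResult(state, res < tol, res, method, t_now)
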