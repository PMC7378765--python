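"""Replicator dynamics of the regulator–manufacturer game on the unit square.

The state (x, y) evolves under two coupled replicator equations: each
side's strategy share grows in proportion to its payoff advantage over its
own population average,

    dx/dt = x (1 - x) * A(y),   A(y) = E11(y) - E12(y),
    dy/dt = y (1 - y) * B(x),   B(x) = E21(x) - E22(x),

where A and B are the payoff advantages of self-discipline and of active
supervision.  In closed form, with D = RV2 + FV1 + FV2 and effective costs
CG1/pi, CG2/psi:

    A(y) = y D (alpha - beta*lam) + RV1 - RV2 + beta*lam*D
    B(x) = (alpha - beta*lam) RG (1 - x) + lam*CG2/psi - CG1/pi

The unit square is forward invariant and its four corners are fixed points
for every parameter set.  Depending on the ordering of epsilon, alpha and
beta*lam the interior may contain a neutrally stable center surrounded by
closed orbits; trajectory classification below distinguishes convergence
to a vertex, an interior rest point, persistent cycling, and everything
else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    GameParameters,
    StateLike,
    StateVector,
    as_state,
    effective_costs,
    require_unit_square,
)

__all__ = [
    "IntegrationError",
    "Trajectory",
    "LongRunOutcome",
    "manufacturer_advantage",
    "regulator_advantage",
    "vector_field",
    "integrate_trajectory",
    "detect_long_run_behavior",
    "simulate_until_settled",
    "CORNERS",
]

#: The four pure-strategy corner states.
CORNERS = (
    StateVector(0.0, 0.0),
    StateVector(0.0, 1.0),
    StateVector(1.0, 0.0),
    StateVector(1.0, 1.0),
)


class IntegrationError(RuntimeError):
    """Numerical integration of the dynamic system failed."""


def manufacturer_advantage(params: GameParameters, y: float) -> float:
    """A(y) = E11 - E12: payoff advantage of self-discipline.

    Linear and decreasing in y when alpha < beta*lam, increasing when
    alpha > beta*lam.
    """
    p = params
    bl = p.beta * p.lam
    return y * p.total_loss * (p.alpha - bl) + p.RV1 - p.RV2 + bl * p.total_loss


def regulator_advantage(params: GameParameters, x: float) -> float:
    """B(x) = E21 - E22: payoff advantage of active supervision."""
    p = params
    active_cost, passive_cost = effective_costs(p)
    return (p.alpha - p.beta * p.lam) * p.RG * (1 - x) + p.lam * passive_cost - active_cost


def vector_field(params: GameParameters, state: StateLike) -> tuple[float, float]:
    """Replicator vector field (dx/dt, dy/dt) at a state in [0,1]^2."""
    s = require_unit_square(state)
    return (
        s.x * (1 - s.x) * manufacturer_advantage(params, s.y),
        s.y * (1 - s.y) * regulator_advantage(params, s.x),
    )


def _rhs(params: GameParameters) -> Callable[[float, np.ndarray], list[float]]:
    # Polynomial extension without range checks, for the ODE solver's
    # trial evaluations slightly outside [0,1]^2.
    def fun(_t: float, z: np.ndarray) -> list[float]:
        x, y = z
        return [
            x * (1 - x) * manufacturer_advantage(params, y),
            y * (1 - y) * regulator_advantage(params, x),
        ]

    return fun


@dataclass
class Trajectory:
    """A solution of the dynamic system: strictly increasing times and the
    matching (x, y) states, all within [0,1]^2 (up to clamping tolerance)."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    params: GameParameters

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != 2:
            raise ValueError("states must have shape (n, 2)")
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def initial_state(self) -> StateVector:
        return StateVector(*self.states[0])

    @property
    def terminal_state(self) -> StateVector:
        return StateVector(*self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "x": self.states[:, 0], "y": self.states[:, 1]})

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV with header ``t,x,y``."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def integrate_trajectory(
    params: GameParameters,
    init: StateLike,
    horizon: float = 500.0,
    *,
    t0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    clamp_tol: float = 1e-9,
) -> Trajectory:
    """Integrate the system from ``init`` over ``[t0, t0 + horizon]``.

    Uses an adaptive Runge–Kutta method (RK45) at rtol 1e-8, tight enough
    to keep closed orbits around a zero-trace center from artificially
    spiralling over the horizons used here.  States are recorded at the
    solver's accepted steps and clamped onto [0,1]; excursions beyond
    ``clamp_tol`` raise :class:`IntegrationError`.
    """
    s = require_unit_square(init)
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    sol = solve_ivp(
        _rhs(params),
        (t0, t0 + horizon),
        [s.x, s.y],
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    states = sol.y.T
    worst = max(float(-states.min(initial=0.0)), float(states.max(initial=1.0) - 1.0))
    if worst > clamp_tol:
        raise IntegrationError(
            f"state left the unit square by {worst:.3e} (> clamp "
            f"tolerance {clamp_tol:.1e})"
        )
    return Trajectory(sol.t, np.clip(states, 0.0, 1.0), params)


@dataclass
class LongRunOutcome:
    """Classification of a trajectory's long-run behavior.

    ``label`` is one of ``vertex(0,0)``, ``vertex(0,1)``, ``vertex(1,0)``,
    ``vertex(1,1)``, ``interior-fixed``, ``cycling``, ``undetermined``.
    """

    label: str
    terminal_state: StateVector
    diagnostics: dict = field(default_factory=dict)

    @property
    def vertex(self) -> Optional[StateVector]:
        if self.label.startswith("vertex"):
            a, b = self.label[len("vertex("):-1].split(",")
            return StateVector(float(a), float(b))
        return None


def _window(traj: Trajectory, frac: float, min_points: int) -> np.ndarray:
    t_end = traj.times[-1]
    span = t_end - traj.times[0]
    mask = traj.times >= t_end - frac * span
    if mask.sum() < min_points:
        return traj.states[-min_points:]
    return traj.states[mask]


def detect_long_run_behavior(
    traj: Trajectory,
    *,
    vertex_tol: float = 1e-3,
    settle_frac: float = 0.1,
    field_tol: float = 1e-6,
    min_points: int = 5,
) -> LongRunOutcome:
    """Label a trajectory's long-run behavior.

    A vertex label requires the state to stay within ``vertex_tol``
    (Chebyshev distance) of that corner over the final ``settle_frac`` of
    the time span — a settle *window*, not a single endpoint, so a
    transient pass near a saddle corner is not mistaken for convergence.
    ``interior-fixed`` requires a quiescent window away from the corners
    with a vanishing vector field.  ``cycling`` requires a persistent
    oscillation: comparable amplitude in the two halves of the trajectory's
    second half and a state that recurs near the final point.
    """
    if len(traj) < 2 * min_points:
        raise ValueError("trajectory too short to classify")
    window = _window(traj, settle_frac, min_points)
    terminal = traj.terminal_state
    diags: dict = {}

    corner_dists = {}
    for corner in CORNERS:
        d = np.abs(window - [corner.x, corner.y]).max()
        corner_dists[f"({corner.x:g},{corner.y:g})"] = float(d)
        if d < vertex_tol:
            return LongRunOutcome(
                f"vertex({corner.x:g},{corner.y:g})", terminal,
                {"window_corner_distance": float(d)},
            )
    diags["corner_distances"] = corner_dists

    amp = window.max(axis=0) - window.min(axis=0)
    fx, fy = vector_field(traj.params, terminal)
    field_norm = math.hypot(fx, fy)
    diags["window_amplitude"] = [float(amp[0]), float(amp[1])]
    diags["terminal_field_norm"] = field_norm
    if amp.max() < vertex_tol and field_norm < field_tol:
        return LongRunOutcome("interior-fixed", terminal, diags)

    # Persistent-oscillation check over the trajectory's second half.
    half_mask = traj.times >= (traj.times[0] + traj.times[-1]) / 2
    half = traj.states[half_mask]
    if len(half) >= 2 * min_points:
        first, second = np.array_split(half, 2)
        amp1 = (first.max(axis=0) - first.min(axis=0)).max()
        amp2 = (second.max(axis=0) - second.min(axis=0)).max()
        recur = np.hypot(*(first - traj.states[-1]).T).min()
        diags.update(
            half_amplitudes=[float(amp1), float(amp2)], recurrence=float(recur)
        )
        if (
            amp1 > 10 * vertex_tol
            and amp2 > 10 * vertex_tol
            and amp2 >= 0.5 * amp1
            and recur < 0.25 * max(amp1, amp2)
        ):
            return LongRunOutcome("cycling", terminal, diags)
    return LongRunOutcome("undetermined", terminal, diags)


def simulate_until_settled(
    params: GameParameters,
    init: StateLike,
    *,
    chunk: float = 150.0,
    max_horizon: float = 1500.0,
    vertex_tol: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[Trajectory, LongRunOutcome]:
    """Integrate in chunks, stopping early once a vertex has been reached.

    Convergence to an asymptotically stable corner is exponential, so most
    trajectories settle within the first chunk; cycling or slowly moving
    trajectories run to ``max_horizon`` and are then classified on the
    full history.
    """
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    current = as_state(init)
    t0 = 0.0
    outcome: Optional[LongRunOutcome] = None
    while t0 < max_horizon:
        horizon = min(chunk, max_horizon - t0)
        piece = integrate_trajectory(
            params, current, horizon, t0=t0, rtol=rtol, atol=atol
        )
        drop = 1 if times else 0  # chunk start duplicates previous end
        times.append(piece.times[drop:])
        states.append(piece.states[drop:])
        full = Trajectory(np.concatenate(times), np.concatenate(states), params)
        outcome = detect_long_run_behavior(full, vertex_tol=vertex_tol)
        if outcome.label.startswith("vertex"):
            return full, outcome
        current = piece.terminal_state
        t0 += horizon
    assert outcome is not None
    return full, outcome
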