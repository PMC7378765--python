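"""Simulation experiments: phase portraits, parameter sweeps, the critical
fine, and a constrained parameter sampler.

The experiment of central policy interest is the fine sweep: raising the
penalty FV1 lowers the profit–loss ratio epsilon = (RV2-RV1)/(RV2+FV1+FV2)
monotonically, and the dynamic regime changes exactly where epsilon
crosses the detection probabilities.  The crossing with the passive
channel, epsilon = beta*lam, has the closed form

    FV1* = (RV2 - RV1) / (beta*lam) - RV2 - FV2,

which equals 4.5 at the baseline calibration: fines above the threshold
push manufacturers toward self-discipline, fines below it let
non-self-discipline persist.  :func:`find_critical_fine` locates the
threshold by bisection on the sign of epsilon(FV1) - beta*lam and
cross-checks it against the closed form.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .model import (
    GameParameters,
    PARAM_FIELDS,
    ParameterError,
    StateLike,
    StateVector,
    as_state,
    derived_quantities,
    validate_parameters,
)
from .dynamics import (
    LongRunOutcome,
    Trajectory,
    simulate_until_settled,
)
from .stability import RegimeClassification, classify_regime, interior_equilibrium

__all__ = [
    "PortraitRun",
    "PortraitResult",
    "SweepEntry",
    "SweepResult",
    "ThresholdResult",
    "interior_grid",
    "run_baseline",
    "sweep_parameter",
    "epsilon_of_fine",
    "critical_fine_closed_form",
    "find_critical_fine",
    "sample_parameters",
]


# ---------------------------------------------------------------------------
# phase portrait

@dataclass
class PortraitRun:
    start: StateVector
    trajectory: Trajectory
    outcome: LongRunOutcome


@dataclass
class PortraitResult:
    params: GameParameters
    runs: list[PortraitRun]
    tally: Counter = field(default_factory=Counter)


def interior_grid(n: int = 5) -> list[StateVector]:
    """A uniform n x n grid strictly inside the unit square."""
    pts = [(i + 1) / (n + 1) for i in range(n)]
    return [StateVector(x, y) for x in pts for y in pts]


def run_baseline(
    params: GameParameters,
    starts: Optional[Iterable[StateLike]] = None,
    *,
    chunk: float = 150.0,
    max_horizon: float = 1500.0,
    vertex_tol: float = 1e-3,
) -> PortraitResult:
    """Integrate a grid of initial states and tally the long-run outcomes.

    The default start set is a 5x5 uniform interior grid; corner starts
    are allowed and simply yield constant trajectories.
    """
    if starts is None:
        starts = interior_grid(5)
    runs = []
    tally: Counter = Counter()
    for start in starts:
        traj, outcome = simulate_until_settled(
            params, start, chunk=chunk, max_horizon=max_horizon,
            vertex_tol=vertex_tol,
        )
        runs.append(PortraitRun(as_state(start), traj, outcome))
        tally[outcome.label] += 1
    return PortraitResult(params, runs, tally)


# ---------------------------------------------------------------------------
# parameter sweeps

#: Names accepted by :func:`sweep_parameter` (config spelling included).
_SWEEP_ALIASES = {"lambda": "lam"}


@dataclass
class SweepEntry:
    value: float
    valid: bool
    regime: Optional[RegimeClassification] = None
    outcome: Optional[LongRunOutcome] = None
    terminal: Optional[StateVector] = None
    error: Optional[str] = None


@dataclass
class SweepResult:
    parameter: str
    init: StateVector
    entries: list[SweepEntry]

    @property
    def values(self) -> list[float]:
        return [e.value for e in self.entries]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append({
                "value": e.value,
                "valid": e.valid,
                "case_id": e.regime.case_id if e.regime else "",
                "outcome": e.outcome.label if e.outcome else "",
                "terminal_x": e.terminal.x if e.terminal else math.nan,
                "terminal_y": e.terminal.y if e.terminal else math.nan,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def sweep_parameter(
    params: GameParameters,
    name: str,
    values: Sequence[float],
    init: StateLike = (0.5, 0.5),
    *,
    chunk: float = 150.0,
    max_horizon: float = 1500.0,
    vertex_tol: float = 1e-3,
) -> SweepResult:
    """Re-run regime classification + simulation along one parameter axis.

    ``values`` must be strictly monotone.  A value that violates a hard
    parameter invariant is recorded as invalid and the sweep continues.
    """
    field_name = _SWEEP_ALIASES.get(name, name)
    if field_name not in PARAM_FIELDS:
        raise ParameterError(f"unknown parameter {name!r}")
    diffs = np.diff(np.asarray(values, dtype=float))
    if len(values) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("sweep values must be strictly monotone")
    init_state = as_state(init)

    entries = []
    for value in values:
        candidate = params.replace(**{field_name: float(value)})
        report = validate_parameters(candidate)
        if not report.ok:
            entries.append(SweepEntry(float(value), False, error="; ".join(report.errors)))
            continue
        regime = classify_regime(candidate)
        traj, outcome = simulate_until_settled(
            candidate, init_state, chunk=chunk, max_horizon=max_horizon,
            vertex_tol=vertex_tol,
        )
        entries.append(SweepEntry(
            float(value), True, regime=regime, outcome=outcome,
            terminal=traj.terminal_state,
        ))
    return SweepResult(name, init_state, entries)


# ---------------------------------------------------------------------------
# critical fine

@dataclass
class ThresholdResult:
    parameter: str
    critical_value: float
    bracket: tuple[float, float]
    tol: float
    criterion: str
    closed_form: float


def epsilon_of_fine(params: GameParameters, fine: float) -> float:
    """The profit–loss ratio as a function of the fine FV1 alone."""
    return derived_quantities(params.replace(FV1=float(fine))).epsilon


def critical_fine_closed_form(params: GameParameters) -> float:
    """FV1* solving epsilon(FV1) = beta*lam:
    (RV2 - RV1)/(beta*lam) - RV2 - FV2."""
    bl = params.passive_detection
    if bl == 0:
        raise ParameterError("beta*lambda must be nonzero")
    return (params.RV2 - params.RV1) / bl - params.RV2 - params.FV2


def find_critical_fine(
    params: GameParameters,
    bracket: tuple[float, float] = (0.0, 20.0),
    tol: float = 1e-6,
) -> ThresholdResult:
    """Locate the fine threshold by bisection on sign(epsilon - beta*lam).

    Raises ``ValueError`` when the criterion does not change sign over the
    bracket (e.g. the degenerate RV1 = RV2 case, where epsilon vanishes
    identically).
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    bl = params.passive_detection

    def criterion(fine: float) -> float:
        return epsilon_of_fine(params, fine) - bl

    f_lo, f_hi = criterion(lo), criterion(hi)
    if f_lo == 0.0:
        root = lo
    elif f_hi == 0.0:
        root = hi
    elif f_lo * f_hi > 0:
        raise ValueError(
            f"no crossing: epsilon - beta*lambda has the same sign at both "
            f"bracket endpoints ({f_lo:.6g}, {f_hi:.6g})"
        )
    else:
        root = float(bisect(criterion, lo, hi, xtol=tol))
    return ThresholdResult(
        parameter="FV1",
        critical_value=root,
        bracket=(lo, hi),
        tol=tol,
        criterion="sign of epsilon(FV1) - beta*lambda",
        closed_form=critical_fine_closed_form(params),
    )


# ---------------------------------------------------------------------------
# parameter sampler

#: Uniform sampling ranges for each parameter, spanning the baseline
#: calibration with room on both sides.  Invalid draws are rejected.
_SAMPLER_RANGES: dict[str, tuple[float, float]] = {
    "CG1": (0.5, 3.0),
    "CG2": (1.0, 9.0),
    "RG": (0.5, 10.0),
    "alpha": (0.05, 0.95),
    "beta": (0.1, 1.0),
    "lam": (0.05, 0.95),
    "RV1": (0.5, 4.0),
    "RV2": (1.0, 10.0),
    "FV1": (0.0, 15.0),
    "FV2": (0.0, 5.0),
    "CV": (0.0, 2.0),
    "pi": (0.5, 2.0),
    "psi": (0.5, 2.0),
}


def _regime_margin(params: GameParameters) -> float:
    """Smallest decisive gap among the regime-defining comparisons."""
    dq = derived_quantities(params)
    eps, alpha, bl = dq.epsilon, params.alpha, params.passive_detection
    cost_gap = params.lam * dq.passive_cost - dq.active_cost
    return min(abs(eps - alpha), abs(eps - bl), abs(bl - alpha), abs(cost_gap))


def sample_parameters(
    seed: int,
    n: int,
    *,
    require_mu_gt_1: bool = False,
    target_case: Optional[str] = None,
    margin: float = 0.0,
    require_interior: bool = False,
    max_tries: Optional[int] = None,
) -> list[GameParameters]:
    """Draw ``n`` valid parameter sets by rejection sampling.

    Deterministic for a fixed ``seed``.  Options: ``require_mu_gt_1``
    keeps only sets with FV1 > RV2; ``target_case`` keeps only sets whose
    regime classification matches; ``margin`` additionally requires every
    decisive regime gap to exceed the given value, so targeted sets sit
    well inside an open regime rather than on its boundary;
    ``require_interior`` keeps only sets admitting the interior rest point
    (necessary for the closed-orbit behavior of the cycling regime).

    Raises ``RuntimeError`` when the rejection budget (default
    ``20000 * n`` draws) is exhausted — the requested constraint
    combination is infeasible or far too rare under the sampling ranges.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    budget = max_tries if max_tries is not None else 20000 * n
    out: list[GameParameters] = []
    for _ in range(budget):
        draw = {
            name: float(rng.uniform(lo, hi))
            for name, (lo, hi) in _SAMPLER_RANGES.items()
        }
        params = GameParameters(**draw)
        if not validate_parameters(params).ok:
            continue
        if require_mu_gt_1 and not params.FV1 > params.RV2:
            continue
        if margin > 0 and _regime_margin(params) <= margin:
            continue
        if target_case is not None:
            if classify_regime(params).case_id != target_case:
                continue
        if require_interior and interior_equilibrium(params)[0] is None:
            continue
        out.append(params)
        if len(out) == n:
            return out
    raise RuntimeError(
        f"rejection budget exhausted: drew {budget} candidates, "
        f"accepted {len(out)} < {n}"
    )
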