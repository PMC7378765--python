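"""Payoff structure of the regulator–manufacturer vaccine-quality game.

Two boundedly rational populations interact repeatedly: vaccine
manufacturers choose between *self-discipline* (producing qualified
vaccines, revenue ``RV1``) and *non-self-discipline* (producing defective
vaccines, revenue ``RV2 > RV1`` but penalty ``FV1`` plus rectification cost
``FV2`` if caught), while the government regulator chooses between *active
supervision* (proactive inspection, cost ``CG1/pi``, detection probability
``alpha``) and *passive supervision* (inspection only after a third-party
report, which arrives with probability ``lam``; cost ``CG2/psi``, detection
probability ``beta > alpha``).

The state of the game is the pair ``(x, y)`` of population shares: ``x`` is
the fraction of self-disciplined manufacturers and ``y`` the fraction of
actively supervising regulators.  This module defines the parameter set,
the 2x2 bimatrix of stage payoffs, the expected (mixed-strategy) payoffs of
each side and the derived scalars used throughout the stability analysis —
most importantly the profit–loss ratio

    epsilon = (RV2 - RV1) / (RV2 + FV1 + FV2),

the temptation of cheating relative to its total downside, whose position
relative to the detection probabilities ``alpha`` and ``beta*lam``
determines the dynamic regime.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Union

__all__ = [
    "PARAM_FIELDS",
    "GameParameters",
    "StateVector",
    "PayoffCell",
    "PayoffMatrix",
    "ExpectedPayoffs",
    "DerivedQuantities",
    "ValidationReport",
    "ParameterError",
    "as_state",
    "validate_parameters",
    "effective_costs",
    "build_payoff_matrix",
    "expected_payoffs",
    "derived_quantities",
]

#: Field names of :class:`GameParameters`, in canonical order.  The
#: third-party reporting probability is stored as ``lam`` (``lambda`` is a
#: Python keyword); config files may spell it ``lambda``.
PARAM_FIELDS = (
    "CG1", "CG2", "RG", "alpha", "beta", "lam",
    "RV1", "RV2", "FV1", "FV2", "CV", "pi", "psi",
)


class ParameterError(ValueError):
    """A parameter set violates a hard model constraint."""


@dataclass(frozen=True)
class GameParameters:
    """The 13 scalar parameters of the inspection game.

    Attributes
    ----------
    CG1, CG2:
        Base costs of active and passive supervision (payoff units, > 0).
        Effective costs are ``CG1/pi`` and ``CG2/psi``.
    RG:
        Government benefit from discovering a non-self-disciplined firm
        (payoff units, >= 0).
    alpha, beta:
        Detection success probabilities of active and passive supervision;
        ``0 < alpha < beta <= 1``.
    lam:
        Probability that a non-self-disciplined firm is reported by a third
        party, triggering passive supervision; in [0, 1].
    RV1, RV2:
        Manufacturer revenue under self-discipline and non-self-discipline;
        ``RV2 > RV1``.
    FV1:
        Penalty plus reputation loss when non-self-discipline is detected
        (>= 0).
    FV2:
        Rectification/disposal cost after detection (>= 0).
    CV:
        Manufacturer's cost of cooperating with an inspection (>= 0).
    pi:
        Strictness coefficient of government power and regulations (> 0);
        stricter regulation lowers the active-supervision cost.
    psi:
        Coefficient of corruption-of-government / public awareness (> 0);
        stronger public awareness lowers the passive-supervision cost.
    """

    CG1: float
    CG2: float
    RG: float
    alpha: float
    beta: float
    lam: float
    RV1: float
    RV2: float
    FV1: float
    FV2: float
    CV: float
    pi: float = 1.0
    psi: float = 1.0

    @classmethod
    def baseline(cls) -> "GameParameters":
        """The standard baseline calibration of the model."""
        return cls(
            CG1=1.0, CG2=5.0, RG=3.0, alpha=0.3, beta=0.8, lam=0.4,
            RV1=2.0, RV2=6.0, FV1=4.0, FV2=2.0, CV=1.0, pi=1.0, psi=1.0,
        )

    def replace(self, **changes: float) -> "GameParameters":
        """Return a copy with the given fields substituted."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_FIELDS}

    # -- convenience scalars used all over the analysis -------------------

    @property
    def passive_detection(self) -> float:
        """beta*lam: probability the passive channel catches a violator."""
        return self.beta * self.lam

    @property
    def total_loss(self) -> float:
        """RV2 + FV1 + FV2: what a caught violator stands to lose."""
        return self.RV2 + self.FV1 + self.FV2


@dataclass(frozen=True)
class StateVector:
    """Population state: share ``x`` of self-disciplined manufacturers and
    share ``y`` of actively supervising regulators, both in [0, 1]."""

    x: float
    y: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)

    def distance_to(self, other: "StateVector") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


StateLike = Union[StateVector, tuple, list]


def as_state(state: StateLike) -> StateVector:
    """Coerce a pair or StateVector to a StateVector (no range check)."""
    if isinstance(state, StateVector):
        return state
    x, y = state
    return StateVector(float(x), float(y))


def require_unit_square(state: StateLike, tol: float = 0.0) -> StateVector:
    s = as_state(state)
    if not (math.isfinite(s.x) and math.isfinite(s.y)):
        raise ParameterError(f"state {s} is not finite")
    if s.x < -tol or s.x > 1 + tol or s.y < -tol or s.y > 1 + tol:
        raise ParameterError(f"state {s} lies outside the unit square")
    return s


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_parameters`.

    ``errors`` are hard constraint violations (the model is undefined or
    its analysis invalid); ``warnings`` flag soft assumptions, currently
    only the penalty coefficient mu = FV1/RV2 <= 1 (a fine that does not
    exceed the illicit revenue weakens the deterrence story but leaves the
    dynamics well defined).
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_for_errors(self) -> None:
        if self.errors:
            raise ParameterError("; ".join(self.errors))


def validate_parameters(params: GameParameters) -> ValidationReport:
    """Check the hard invariants of the parameter set.

    Hard errors: non-finite values, non-positive costs or coefficients,
    negative benefits/penalties, ``alpha``/``beta`` outside (0, 1] or
    ``alpha >= beta``, ``lam`` outside [0, 1], ``RV2 <= RV1``, or effective
    passive cost not exceeding effective active cost
    (``CG2/psi <= CG1/pi``).  Soft warning: penalty coefficient
    ``mu = FV1/RV2 <= 1``.
    """
    rep = ValidationReport()
    err = rep.errors.append

    for name in PARAM_FIELDS:
        value = getattr(params, name)
        if not isinstance(value, (int, float)) or not math.isfinite(float(value)):
            err(f"{name} must be a finite number, got {value!r}")
    if rep.errors:
        return rep

    for name in ("CG1", "CG2", "pi", "psi"):
        if getattr(params, name) <= 0:
            err(f"{name} must be > 0")
    for name in ("RG", "FV1", "FV2", "CV"):
        if getattr(params, name) < 0:
            err(f"{name} must be >= 0")

    if not (0 < params.alpha <= 1):
        err("alpha must lie in (0, 1]")
    if not (0 < params.beta <= 1):
        err("beta must lie in (0, 1]")
    if params.alpha >= params.beta:
        err("alpha must be < beta")
    if not (0 <= params.lam <= 1):
        err("lambda must lie in [0, 1]")
    if params.RV2 <= params.RV1:
        err("RV2 must exceed RV1")

    if params.pi > 0 and params.psi > 0:
        active = params.CG1 / params.pi
        passive = params.CG2 / params.psi
        if not (passive > active > 0):
            err("effective passive cost CG2/psi must exceed effective "
                "active cost CG1/pi (> 0)")

    if params.RV2 > 0 and params.FV1 / params.RV2 <= 1:
        rep.warnings.append(
            "penalty coefficient mu = FV1/RV2 = "
            f"{params.FV1 / params.RV2:.6g} <= 1: the fine does not exceed "
            "the non-self-discipline revenue, weakening deterrence"
        )
    return rep


def effective_costs(params: GameParameters) -> tuple[float, float]:
    """Effective supervision costs ``(CG1/pi, CG2/psi)``.

    Stricter regulation (larger ``pi``) cheapens active supervision;
    stronger public awareness (larger ``psi``) cheapens passive
    supervision.
    """
    if params.pi == 0 or params.psi == 0:
        raise ParameterError("pi and psi must be nonzero")
    return params.CG1 / params.pi, params.CG2 / params.psi


@dataclass(frozen=True)
class PayoffCell:
    """One cell of the bimatrix: (manufacturer payoff, government payoff)."""

    manufacturer: float
    government: float


@dataclass(frozen=True)
class PayoffMatrix:
    """The 2x2 bimatrix of stage payoffs.

    Rows index the manufacturer strategy (self-discipline vs.
    non-self-discipline), columns the regulator strategy (active vs.
    passive supervision).  Under passive supervision an inspection happens
    only upon a third-party report (probability ``lam``), so the passive
    column is already a ``lam``-mixture over report / no report.
    """

    self_active: PayoffCell
    self_passive: PayoffCell
    nonself_active: PayoffCell
    nonself_passive: PayoffCell

    def cell(self, discipline: str, regulation: str) -> PayoffCell:
        key = {
            ("self", "active"): self.self_active,
            ("self", "passive"): self.self_passive,
            ("nonself", "active"): self.nonself_active,
            ("nonself", "passive"): self.nonself_passive,
        }
        try:
            return key[(discipline, regulation)]
        except KeyError:
            raise KeyError(
                f"no cell ({discipline!r}, {regulation!r}); use "
                "discipline in {'self','nonself'} and regulation in "
                "{'active','passive'}"
            ) from None


def build_payoff_matrix(params: GameParameters) -> PayoffMatrix:
    """Evaluate the four bimatrix cells for a parameter set."""
    p = params
    active_cost, passive_cost = effective_costs(p)
    caught_loss = p.FV1 + p.FV2

    self_active = PayoffCell(p.RV1 - p.CV, -active_cost)
    # Self-disciplined firms still incur the cooperation cost CV when a
    # report triggers an inspection.
    self_passive = PayoffCell(
        p.lam * (p.RV1 - p.CV) + (1 - p.lam) * p.RV1,
        p.lam * (-passive_cost),
    )
    nonself_active = PayoffCell(
        (1 - p.alpha) * p.RV2 - p.alpha * caught_loss - p.CV,
        p.alpha * p.RG - active_cost,
    )
    nonself_passive = PayoffCell(
        p.lam * ((1 - p.beta) * p.RV2 - p.beta * caught_loss - p.CV)
        + (1 - p.lam) * p.RV2,
        p.lam * (p.beta * (p.RG - passive_cost) + (1 - p.beta) * (-passive_cost)),
    )
    return PayoffMatrix(self_active, self_passive, nonself_active, nonself_passive)


@dataclass(frozen=True)
class ExpectedPayoffs:
    """Expected payoffs of each pure strategy and the population averages.

    ``E11``/``E12``: manufacturer payoff to self-discipline /
    non-self-discipline (functions of the regulator share ``y`` only);
    ``E21``/``E22``: regulator payoff to active / passive supervision
    (functions of the manufacturer share ``x`` only); ``E1bar``/``E2bar``:
    the population-average payoffs that drive the replicator dynamics.
    """

    E11: float
    E12: float
    E1bar: float
    E21: float
    E22: float
    E2bar: float


def expected_payoffs(params: GameParameters, state: StateLike) -> ExpectedPayoffs:
    """Mixed-strategy expected payoffs at population state ``(x, y)``."""
    s = require_unit_square(state)
    p = params
    m = build_payoff_matrix(p)
    x, y = s.x, s.y

    E11 = y * m.self_active.manufacturer + (1 - y) * m.self_passive.manufacturer
    E12 = y * m.nonself_active.manufacturer + (1 - y) * m.nonself_passive.manufacturer
    E1bar = x * E11 + (1 - x) * E12

    E21 = x * m.self_active.government + (1 - x) * m.nonself_active.government
    E22 = x * m.self_passive.government + (1 - x) * m.nonself_passive.government
    E2bar = y * E21 + (1 - y) * E22
    return ExpectedPayoffs(E11, E12, E1bar, E21, E22, E2bar)


@dataclass(frozen=True)
class DerivedQuantities:
    """Dimensionless scalars that organise the stability analysis."""

    epsilon: float       #: (RV2-RV1)/(RV2+FV1+FV2), temptation of cheating
    mu: float            #: FV1/RV2, penalty coefficient
    active_cost: float   #: CG1/pi
    passive_cost: float  #: CG2/psi


def derived_quantities(params: GameParameters) -> DerivedQuantities:
    """Compute epsilon, mu and the effective supervision costs.

    Deliberately does not re-validate the parameter set, so the scalars
    can also be evaluated on degenerate sets (e.g. RV1 = RV2 gives
    epsilon = 0) for diagnostic and oracle purposes.
    """
    p = params
    if p.total_loss == 0:
        raise ParameterError("RV2 + FV1 + FV2 must be nonzero")
    active_cost, passive_cost = effective_costs(p)
    mu = p.FV1 / p.RV2 if p.RV2 != 0 else math.inf
    epsilon = (p.RV2 - p.RV1) / p.total_loss
    return DerivedQuantities(epsilon, mu, active_cost, passive_cost)
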