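"""Equilibria, Jacobian analysis and regime classification.

The replicator system always has the four pure-strategy corners of the
unit square as rest points; when the profit–loss ratio epsilon lies
strictly between the two detection probabilities alpha and beta*lam (and
the cost gap is compatible), an interior mixed-strategy rest point

    x* = 1 - (lam*CG2/psi - CG1/pi) / ((beta*lam - alpha) * RG)
    y* = (RV1 - RV2 + beta*lam*D) / (D * (beta*lam - alpha)),   D = RV2+FV1+FV2

appears as well.  Local stability is read off the Jacobian: an equilibrium
is an evolutionarily stable strategy (ESS) of the dynamics iff
tr J < 0 and det J > 0; at the corners the Jacobian is diagonal, so this
reduces to both diagonal entries being negative, and at the interior point
the trace vanishes identically, making it at best a neutrally stable
center (det J > 0) surrounded by closed orbits — never an ESS.

Regime classification orders epsilon against alpha and beta*lam and
compares the regulator's effective cost gap lam*CG2/psi vs CG1/pi,
assigning one of the enumerated regimes (cycling transition period, or an
ESS at a specific corner).  Parameter sets whose ordering/cost combination
falls outside the enumerated regimes are labelled ``outside_enumerated``
and handled by direct corner sign analysis, which is always reported
alongside the regime call so the two can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    GameParameters,
    ParameterError,
    StateLike,
    StateVector,
    derived_quantities,
    effective_costs,
    require_unit_square,
)
from .dynamics import CORNERS, manufacturer_advantage, regulator_advantage

__all__ = [
    "JacobianEntries",
    "EquilibriumReport",
    "RegimeClassification",
    "interior_equilibrium",
    "find_equilibria",
    "jacobian_entries",
    "classify_equilibrium",
    "analyze_equilibria",
    "sign_analysis_ess",
    "classify_regime",
    "verify_claimed_ess",
]

REGIME_CASES = (
    "cycle_case", "case2_00", "case2_10", "case3_01", "case3_11",
    "outside_enumerated",
)


@dataclass(frozen=True)
class JacobianEntries:
    """The four entries of the system Jacobian at a point."""

    a11: float
    a12: float
    a21: float
    a22: float

    @property
    def trace(self) -> float:
        return self.a11 + self.a22

    @property
    def det(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21


def jacobian_entries(params: GameParameters, point: StateLike) -> JacobianEntries:
    """Evaluate the Jacobian of the replicator system at a state.

    With A(y), B(x) the payoff-advantage brackets of the two replicator
    equations:

        a11 = (1 - 2x) A(y)          a12 = x(1-x) A'(y)
        a21 = y(1-y) B'(x)           a22 = (1 - 2y) B(x)

    At each corner x(1-x) = y(1-y) = 0, so the off-diagonals vanish and
    the matrix is diagonal; at the interior rest point A = B = 0, so the
    diagonal vanishes and the trace is exactly zero.
    """
    s = require_unit_square(point)
    p = params
    x, y = s.x, s.y
    bl = p.beta * p.lam
    a11 = (1 - 2 * x) * manufacturer_advantage(p, y)
    a12 = x * (1 - x) * p.total_loss * (p.alpha - bl)
    a21 = y * (1 - y) * (bl - p.alpha) * p.RG
    a22 = (1 - 2 * y) * regulator_advantage(p, x)
    return JacobianEntries(a11, a12, a21, a22)


@dataclass
class EquilibriumReport:
    """An equilibrium point with (optionally) its Jacobian and stability
    label: ESS | saddle | unstable | center | non-hyperbolic."""

    point: StateVector
    kind: str  # "pure" | "interior"
    jacobian: Optional[JacobianEntries] = None
    label: Optional[str] = None
    flags: list[str] = field(default_factory=list)


def interior_equilibrium(
    params: GameParameters, tol: float = 1e-12
) -> tuple[Optional[StateVector], Optional[str]]:
    """The interior mixed-strategy rest point, if it exists.

    Returns ``(point, None)`` when both closed-form coordinates lie
    strictly inside (0, 1); ``(None, "degenerate")`` when the formulas are
    singular (beta*lam = alpha, or RG = 0); ``(None, "outside")`` when the
    candidate falls outside the open square.
    """
    p = params
    bl = p.beta * p.lam
    denom = bl - p.alpha
    if abs(denom) < tol or p.RG == 0:
        return None, "degenerate"
    active_cost, passive_cost = effective_costs(p)
    x_star = 1 - (p.lam * passive_cost - active_cost) / (denom * p.RG)
    y_star = (p.RV1 - p.RV2 + bl * p.total_loss) / (p.total_loss * denom)
    if 0 < x_star < 1 and 0 < y_star < 1:
        return StateVector(x_star, y_star), None
    return None, "outside"


def find_equilibria(params: GameParameters) -> list[EquilibriumReport]:
    """Enumerate the rest points of the system (labels left unset).

    Always the four pure-strategy corners; plus the interior mixed point
    when its closed-form coordinates lie strictly inside the square.  A
    degenerate denominator (beta*lam = alpha or RG = 0) is flagged on the
    corner reports rather than silently ignored.
    """
    reports = [EquilibriumReport(c, "pure") for c in CORNERS]
    point, reason = interior_equilibrium(params)
    if point is not None:
        reports.append(EquilibriumReport(point, "interior"))
    elif reason == "degenerate":
        for rep in reports:
            rep.flags.append("interior-degenerate")
    return reports


def classify_equilibrium(
    params: GameParameters, report: EquilibriumReport, tol: float = 1e-9
) -> EquilibriumReport:
    """Fill in the Jacobian and the stability label of an equilibrium.

    ESS: tr J < 0 and det J > 0 (local asymptotic stability); saddle:
    det J < 0; unstable: tr J > 0 and det J > 0; center: interior point
    with det J > 0 and |tr J| < tol.  Any decisive quantity within ``tol``
    of zero at a corner yields ``non-hyperbolic`` instead of a guess.
    """
    jac = jacobian_entries(params, report.point)
    report.jacobian = jac
    if report.kind == "pure":
        # Diagonal matrix: the eigenvalues are a11 and a22.
        if min(abs(jac.a11), abs(jac.a22)) < tol:
            report.label = "non-hyperbolic"
        elif jac.a11 < 0 and jac.a22 < 0:
            report.label = "ESS"
        elif jac.a11 > 0 and jac.a22 > 0:
            report.label = "unstable"
        else:
            report.label = "saddle"
    else:
        tr, det = jac.trace, jac.det
        if det < -tol:
            report.label = "saddle"
        elif abs(tr) < tol and det > tol:
            report.label = "center"
        elif tr < -tol and det > tol:
            report.label = "ESS"
        elif tr > tol and det > tol:
            report.label = "unstable"
        else:
            report.label = "non-hyperbolic"
    return report


def analyze_equilibria(params: GameParameters, tol: float = 1e-9) -> list[EquilibriumReport]:
    """Enumerate and classify all equilibria of a parameter set."""
    return [classify_equilibrium(params, rep, tol) for rep in find_equilibria(params)]


def sign_analysis_ess(params: GameParameters, tol: float = 1e-9) -> list[StateVector]:
    """Corners that are ESS by direct sign analysis of the diagonal
    Jacobian entries (both strictly negative beyond ``tol``)."""
    stable = []
    for corner in CORNERS:
        jac = jacobian_entries(params, corner)
        if jac.a11 < -tol and jac.a22 < -tol:
            stable.append(corner)
    return stable


@dataclass
class RegimeClassification:
    """Which enumerated dynamic regime a parameter set falls in.

    ``ordering`` spells out the realized ordering among epsilon, alpha and
    beta*lambda; ``cost_comparison`` is the sign of
    lam*CG2/psi - CG1/pi; ``predicted_ess`` is the regime's ESS corner
    (None for the cycling regime and for unresolved cases);
    ``sign_analysis_ess`` is the always-computed list of corners stable by
    direct sign analysis, the authoritative fallback; ``critical`` lists
    decisive quantities lying exactly on a regime boundary.
    """

    case_id: str
    ordering: str
    cost_comparison: int
    predicted_ess: Optional[StateVector]
    sign_analysis_ess: list[StateVector]
    critical: list[str] = field(default_factory=list)
    interior_exists: bool = False
    epsilon: float = float("nan")
    alpha: float = float("nan")
    beta_lambda: float = float("nan")


def _ordering_string(eps: float, alpha: float, bl: float) -> str:
    items = sorted(
        [("epsilon", eps), ("alpha", alpha), ("beta*lambda", bl)],
        key=lambda kv: -kv[1],
    )
    parts = [items[0][0]]
    for (prev_name, prev), (name, val) in zip(items, items[1:]):
        parts.append("=" if prev == val else ">")
        parts.append(name)
    return " ".join(parts)


def classify_regime(params: GameParameters, tol: float = 1e-9) -> RegimeClassification:
    """Assign a parameter set to one of the enumerated dynamic regimes.

    The strict inequality chains are evaluated on the given floats with no
    epsilon-padding; quantities within ``tol`` of a boundary are recorded
    in ``critical`` and the set falls through to ``outside_enumerated``.
    The enumerated regimes are:

    - ``cycle_case``: epsilon strictly between alpha and beta*lam — the
      transition period with no ESS (closed orbits around the interior
      center, when that center exists);
    - ``case2_00`` / ``case2_10``: lam*CG2/psi < CG1/pi with epsilon above
      (resp. below) both detection probabilities → ESS (0,0) (resp. (1,0));
    - ``case3_01`` / ``case3_11``: lam*CG2/psi > CG1/pi with epsilon above
      (resp. below) both detection probabilities → ESS (0,1) (resp. (1,1)).
    """
    p = params
    dq = derived_quantities(p)
    eps, alpha, bl = dq.epsilon, p.alpha, p.passive_detection
    cost_gap = p.lam * dq.passive_cost - dq.active_cost

    critical = []
    if abs(eps - bl) < tol:
        critical.append("epsilon = beta*lambda")
    if abs(eps - alpha) < tol:
        critical.append("epsilon = alpha")
    if abs(bl - alpha) < tol:
        critical.append("beta*lambda = alpha")
    if abs(cost_gap) < tol:
        critical.append("lambda*CG2/psi = CG1/pi")

    point, _ = interior_equilibrium(p)
    result = RegimeClassification(
        case_id="outside_enumerated",
        ordering=_ordering_string(eps, alpha, bl),
        cost_comparison=0 if abs(cost_gap) < tol else (1 if cost_gap > 0 else -1),
        predicted_ess=None,
        sign_analysis_ess=sign_analysis_ess(p, tol),
        critical=critical,
        interior_exists=point is not None,
        epsilon=eps,
        alpha=alpha,
        beta_lambda=bl,
    )
    if critical:
        return result

    if (alpha > eps > bl > 0) or (0 < alpha < eps < bl):
        result.case_id = "cycle_case"
    elif eps > bl > alpha > 0 and cost_gap < 0:
        result.case_id = "case2_00"
        result.predicted_ess = StateVector(0.0, 0.0)
    elif 0 < eps < bl < alpha and cost_gap < 0:
        result.case_id = "case2_10"
        result.predicted_ess = StateVector(1.0, 0.0)
    elif eps > alpha > bl > 0 and cost_gap > 0:
        result.case_id = "case3_01"
        result.predicted_ess = StateVector(0.0, 1.0)
    elif 0 < eps < alpha < bl and cost_gap > 0:
        result.case_id = "case3_11"
        result.predicted_ess = StateVector(1.0, 1.0)
    else:
        if len(result.sign_analysis_ess) == 1:
            result.predicted_ess = result.sign_analysis_ess[0]
    return result


def verify_claimed_ess(
    params: GameParameters,
    claimed: StateLike = (0.0, 0.0),
    tol: float = 1e-9,
) -> dict:
    """Audit a claimed evolutionarily stable corner against sign analysis.

    The full-defection outcome (0,0) — manufacturers cheat, the regulator
    supervises passively — is often quoted as the baseline attractor of
    this model, but at the default calibration the Jacobian at (0,0) has
    diagonal entries of opposite sign (a saddle) and the actual unique
    stable corner is (0,1): manufacturers cheat while the regulator
    supervises actively.  This diagnostic makes such conflicts explicit
    instead of silently overriding either answer.
    """
    claimed_state = require_unit_square(claimed)
    if claimed_state not in CORNERS:
        raise ParameterError("claimed ESS must be one of the four corners")
    report = classify_equilibrium(
        params, EquilibriumReport(claimed_state, "pure"), tol
    )
    actual = sign_analysis_ess(params, tol)
    return {
        "claimed": claimed_state,
        "claimed_label": report.label,
        "claimed_is_ess": report.label == "ESS",
        "sign_analysis_ess": actual,
        "conflict": claimed_state not in actual,
    }
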