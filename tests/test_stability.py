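"""Equilibrium enumeration, Jacobian analysis and regime classification."""

import pytest

from vaxgame import (
    StateVector,
    analyze_equilibria,
    classify_regime,
    derived_quantities,
    find_equilibria,
    interior_equilibrium,
    jacobian_entries,
    sign_analysis_ess,
    verify_claimed_ess,
)
from vaxgame.dynamics import CORNERS
from vaxgame.experiments import sample_parameters

CORNER_SET = {(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)}


class TestEquilibria:
    def test_baseline_has_only_the_four_corners(self, baseline):
        reports = find_equilibria(baseline)
        assert {r.point.as_tuple() for r in reports} == CORNER_SET
        # the interior candidate x* = 1 - (2-1)/(0.02*3) is far below 0
        assert interior_equilibrium(baseline) == (None, "outside")

    def test_center_calibration_adds_the_mixed_point(self, center_params):
        reports = find_equilibria(center_params)
        assert len(reports) == 5
        inner = [r for r in reports if r.kind == "interior"][0]
        assert inner.point.x == pytest.approx(0.5, abs=1e-12)
        assert inner.point.y == pytest.approx(8 / 13, abs=1e-12)

    def test_every_valid_set_has_exactly_the_four_corners(self):
        for params in sample_parameters(31, 25):
            pure = [r for r in find_equilibria(params) if r.kind == "pure"]
            assert {r.point.as_tuple() for r in pure} == CORNER_SET

    def test_degenerate_detection_probabilities_flagged(self, baseline):
        # beta*lam == alpha makes the closed forms singular
        degenerate = baseline.replace(lam=0.375)  # 0.8 * 0.375 = 0.3 = alpha
        point, reason = interior_equilibrium(degenerate)
        assert point is None and reason == "degenerate"
        reports = find_equilibria(degenerate)
        assert all("interior-degenerate" in r.flags for r in reports)


class TestJacobian:
    def test_baseline_corner_entries(self, baseline):
        j00 = jacobian_entries(baseline, (0.0, 0.0))
        assert j00.a11 == pytest.approx(-0.16)
        assert j00.a22 == pytest.approx(0.94)
        assert (j00.a12, j00.a21) == (0.0, 0.0)
        j01 = jacobian_entries(baseline, (0.0, 1.0))
        assert j01.a11 == pytest.approx(-0.4)
        assert j01.a22 == pytest.approx(-0.94)

    def test_corner_off_diagonals_vanish_everywhere(self):
        for params in sample_parameters(32, 25):
            for corner in CORNERS:
                jac = jacobian_entries(params, corner)
                assert jac.a12 == 0.0 and jac.a21 == 0.0

    def test_interior_diagonal_vanishes(self, center_params):
        point, _ = interior_equilibrium(center_params)
        jac = jacobian_entries(center_params, point)
        assert abs(jac.a11) < 1e-10 and abs(jac.a22) < 1e-10
        assert abs(jac.trace) < 1e-10

    def test_trace_zero_at_every_sampled_interior_equilibrium(self):
        sets = sample_parameters(
            33, 15, target_case="cycle_case", require_interior=True
        )
        for params in sets:
            point, _ = interior_equilibrium(params)
            assert abs(jacobian_entries(params, point).trace) < 1e-10

    def test_mixed_y_coordinate_identity(self):
        # y* = (beta*lam - epsilon) / (beta*lam - alpha) wherever defined
        for params in sample_parameters(34, 40):
            bl, alpha = params.passive_detection, params.alpha
            if abs(bl - alpha) < 1e-6:
                continue
            eps = derived_quantities(params).epsilon
            p = params.total_loss
            y_star = (params.RV1 - params.RV2 + bl * p) / (p * (bl - alpha))
            assert y_star == pytest.approx((bl - eps) / (bl - alpha), abs=1e-10)


class TestClassification:
    def test_baseline_labels(self, baseline):
        labels = {r.point.as_tuple(): r.label for r in analyze_equilibria(baseline)}
        assert labels[(0.0, 1.0)] == "ESS"
        assert labels[(0.0, 0.0)] == "saddle"
        assert labels[(1.0, 1.0)] == "saddle"
        assert labels[(1.0, 0.0)] == "unstable"

    def test_center_calibration_interior_is_a_center(self, center_params):
        inner = [r for r in analyze_equilibria(center_params) if r.kind == "interior"][0]
        assert inner.label == "center"
        assert inner.jacobian.det > 0

    def test_center_calibration_corners_are_all_saddles(self, center_params):
        pure = [r for r in analyze_equilibria(center_params) if r.kind == "pure"]
        assert all(r.label == "saddle" for r in pure)


class TestRegime:
    def test_baseline_falls_outside_the_enumerated_cases(self, baseline):
        regime = classify_regime(baseline)
        assert regime.case_id == "outside_enumerated"
        assert regime.ordering == "epsilon > beta*lambda > alpha"
        assert regime.cost_comparison == 1
        assert regime.predicted_ess == StateVector(0.0, 1.0)
        assert regime.sign_analysis_ess == [StateVector(0.0, 1.0)]

    def test_strong_fine_reaches_full_cooperation_case(self, baseline):
        regime = classify_regime(baseline.replace(FV1=10.0))
        assert regime.case_id == "case3_11"
        assert regime.predicted_ess == StateVector(1.0, 1.0)
        assert regime.epsilon == pytest.approx(4 / 18)

    def test_intermediate_fine_is_the_cycling_transition(self, baseline):
        regime = classify_regime(baseline.replace(FV1=5.0))
        assert regime.case_id == "cycle_case"
        assert regime.predicted_ess is None

    def test_exact_tie_reported_as_critical(self, baseline):
        regime = classify_regime(baseline.replace(FV1=4.5))
        assert regime.case_id == "outside_enumerated"
        assert "epsilon = beta*lambda" in regime.critical

    def test_targeted_samples_satisfy_their_case_conditions(self):
        for params in sample_parameters(35, 10, target_case="cycle_case"):
            eps = derived_quantities(params).epsilon
            lo, hi = sorted((params.alpha, params.passive_detection))
            assert lo < eps < hi


class TestClaimedEssAudit:
    def test_baseline_full_defection_claim_is_flagged(self, baseline):
        audit = verify_claimed_ess(baseline, (0.0, 0.0))
        assert audit["claimed_label"] == "saddle"
        assert not audit["claimed_is_ess"]
        assert audit["conflict"]
        assert audit["sign_analysis_ess"] == [StateVector(0.0, 1.0)]

    def test_consistent_claim_passes(self, baseline):
        audit = verify_claimed_ess(baseline, (0.0, 1.0))
        assert audit["claimed_is_ess"] and not audit["conflict"]
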