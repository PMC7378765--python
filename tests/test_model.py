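"""Payoff structure: validation, bimatrix cells, expected payoffs and the
derived scalars."""

import pytest
from hypothesis import given, settings, strategies as st

from vaxgame import (
    GameParameters,
    ParameterError,
    build_payoff_matrix,
    derived_quantities,
    effective_costs,
    expected_payoffs,
    validate_parameters,
)
from vaxgame.experiments import sample_parameters


class TestValidation:
    def test_baseline_is_valid_with_weak_penalty_warning(self, baseline):
        report = validate_parameters(baseline)
        assert report.ok
        assert len(report.warnings) == 1
        assert "mu" in report.warnings[0]  # FV1/RV2 = 4/6 < 1

    @pytest.mark.parametrize(
        "changes, fragment",
        [
            ({"alpha": 0.9}, "alpha must be < beta"),
            ({"RV1": 6.0}, "RV2 must exceed RV1"),
            ({"RV1": 7.0}, "RV2 must exceed RV1"),
            ({"psi": 5.0}, "passive cost"),     # CG2/psi = 1 = CG1/pi
            ({"pi": -1.0}, "pi must be > 0"),
            ({"CG1": 0.0}, "CG1 must be > 0"),
            ({"lam": 1.5}, "lambda must lie in [0, 1]"),
            ({"alpha": 0.0}, "alpha must lie in (0, 1]"),
            ({"FV1": -1.0}, "FV1 must be >= 0"),
            ({"RG": float("nan")}, "finite"),
        ],
    )
    def test_hard_invariant_violations(self, baseline, changes, fragment):
        report = validate_parameters(baseline.replace(**changes))
        assert not report.ok
        assert any(fragment in e for e in report.errors)
        with pytest.raises(ParameterError):
            report.raise_for_errors()

    def test_strong_penalty_silences_warning(self, baseline):
        report = validate_parameters(baseline.replace(FV1=7.0))
        assert report.ok and not report.warnings


class TestEffectiveCosts:
    def test_baseline(self, baseline):
        assert effective_costs(baseline) == (1.0, 5.0)

    def test_stricter_regulation_halves_active_cost(self, baseline):
        active, passive = effective_costs(baseline.replace(pi=2.0))
        assert active == pytest.approx(0.5)
        assert passive == pytest.approx(5.0)


class TestPayoffMatrix:
    def test_baseline_cells(self, baseline):
        m = build_payoff_matrix(baseline)
        assert m.self_active.manufacturer == pytest.approx(1.0)
        assert m.self_active.government == pytest.approx(-1.0)
        assert m.nonself_active.manufacturer == pytest.approx(1.4)
        assert m.nonself_active.government == pytest.approx(-0.1)
        assert m.self_passive.manufacturer == pytest.approx(1.6)
        assert m.self_passive.government == pytest.approx(-2.0)
        assert m.nonself_passive.manufacturer == pytest.approx(1.76)
        assert m.nonself_passive.government == pytest.approx(-1.04)

    def test_cell_lookup(self, baseline):
        m = build_payoff_matrix(baseline)
        assert m.cell("nonself", "passive") is m.nonself_passive
        with pytest.raises(KeyError):
            m.cell("self", "lenient")


class TestExpectedPayoffs:
    def test_nonself_payoff_under_full_active_supervision(self, baseline):
        assert expected_payoffs(baseline, (0.5, 1.0)).E12 == pytest.approx(1.4)

    def test_nonself_payoff_under_full_passive_supervision(self, baseline):
        assert expected_payoffs(baseline, (0.5, 0.0)).E12 == pytest.approx(1.76)

    def test_state_outside_unit_square_rejected(self, baseline):
        with pytest.raises(ParameterError):
            expected_payoffs(baseline, (1.2, 0.5))

    @given(x=st.floats(0, 1), y=st.floats(0, 1))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_averages_mix_the_pure_payoffs(self, x, y):
        ep = expected_payoffs(GameParameters.baseline(), (x, y))
        assert ep.E1bar == pytest.approx(x * ep.E11 + (1 - x) * ep.E12, abs=1e-12)
        assert ep.E2bar == pytest.approx(y * ep.E21 + (1 - y) * ep.E22, abs=1e-12)

    def test_pure_states_reduce_to_matrix_cells(self):
        # At y in {0,1} the manufacturer payoffs are single bimatrix cells
        # (the passive column already carries the lambda mixture); at
        # x in {0,1} likewise for the regulator.
        for params in sample_parameters(11, 20):
            m = build_payoff_matrix(params)
            at = lambda x, y: expected_payoffs(params, (x, y))
            assert at(0.5, 1.0).E11 == pytest.approx(m.self_active.manufacturer)
            assert at(0.5, 0.0).E11 == pytest.approx(m.self_passive.manufacturer)
            assert at(0.5, 1.0).E12 == pytest.approx(m.nonself_active.manufacturer)
            assert at(0.5, 0.0).E12 == pytest.approx(m.nonself_passive.manufacturer)
            assert at(1.0, 0.5).E21 == pytest.approx(m.self_active.government)
            assert at(0.0, 0.5).E21 == pytest.approx(m.nonself_active.government)
            assert at(1.0, 0.5).E22 == pytest.approx(m.self_passive.government)
            assert at(0.0, 0.5).E22 == pytest.approx(m.nonself_passive.government)


class TestDerivedQuantities:
    def test_baseline_profit_loss_ratio(self, baseline):
        dq = derived_quantities(baseline)
        assert dq.epsilon == pytest.approx(1 / 3)
        assert dq.mu == pytest.approx(4 / 6)
        assert (dq.active_cost, dq.passive_cost) == (1.0, 5.0)

    def test_threshold_fine_puts_epsilon_on_passive_detection(self, baseline):
        dq = derived_quantities(baseline.replace(FV1=4.5))
        assert dq.epsilon == pytest.approx(0.32)
        assert dq.epsilon == pytest.approx(baseline.passive_detection)

    def test_degenerate_equal_revenues_give_zero_epsilon(self, baseline):
        # Invalid as a model calibration, but the scalar is still defined.
        assert derived_quantities(baseline.replace(RV1=6.0)).epsilon == 0.0

    @given(
        fv=st.tuples(st.floats(0, 30), st.floats(0, 30)).filter(
            lambda ab: abs(ab[0] - ab[1]) > 1e-9
        )
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_epsilon_strictly_decreasing_in_fine(self, fv):
        lo, hi = sorted(fv)
        p = GameParameters.baseline()
        assert (
            derived_quantities(p.replace(FV1=hi)).epsilon
            < derived_quantities(p.replace(FV1=lo)).epsilon
        )

    def test_epsilon_strictly_decreasing_in_rectification_cost(self, baseline):
        eps = [
            derived_quantities(baseline.replace(FV2=v)).epsilon
            for v in (0.0, 1.0, 2.0, 5.0, 10.0)
        ]
        assert all(a > b for a, b in zip(eps, eps[1:]))
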