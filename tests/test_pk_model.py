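"""Structural PK model: covariate machinery, hybrid constants, closed-form
prediction against an ODE oracle, and steady-state exposure identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pkpdkit.pk_model import (
    ConfigurationError,
    CovariateEffect,
    PKParams,
    PopulationPKModel,
    Regimen,
    apply_covariates_pk,
    auc_ss,
    cavg_ss,
    conc_matrix,
    cv_to_omega2,
    hybrid_constants,
    omega2_to_cv,
    predict_concentration,
    qd_regimen,
)

REF = PKParams(0.755, 19.1, 1.41, 0.184, 0.156, 1.0)


def ode_concentration(params: PKParams, regimen: Regimen, times, food_mult=1.0):
    """Adaptive-ODE oracle for the transit -> central <-> peripheral system."""
    k10, k23, k32 = params.k10, params.k23, params.k32
    out = np.zeros_like(np.asarray(times, dtype=float))
    for td, amt, fed in zip(regimen.times, regimen.amounts, regimen.food):
        if amt == 0:
            continue
        ka = params.ka * (food_mult if fed else 1.0)

        def rhs(t, y):
            return [-ka * y[0], ka * y[0] - (k10 + k23) * y[1] + k32 * y[2],
                    k23 * y[1] - k32 * y[2]]

        sol = solve_ivp(rhs, (0.0, max(np.max(times) - td, 1.0)),
                        [amt * params.f1_rel, 0.0, 0.0],
                        dense_output=True, rtol=1e-11, atol=1e-13)
        dt = np.asarray(times) - td
        out += np.where(dt >= 0, sol.sol(np.clip(dt, 0, None))[1] / params.vc_f, 0.0)
    return out


class TestCovariates:
    def test_identity_at_reference(self):
        model = PopulationPKModel(REF, [
            CovariateEffect("cl_f", "weight", "power", 0.61, reference=83.7),
            CovariateEffect("cl_f", "female", "proportional", -0.127),
        ], {}, 0.3, 0.5)
        p = apply_covariates_pk(model, {"weight": 83.7, "female": 0})
        assert p.cl_f == pytest.approx(0.755)

    def test_female_proportional_shift_on_clearance(self):
        model = PopulationPKModel(REF, [
            CovariateEffect("cl_f", "female", "proportional", -0.127)], {}, 0.3, 0.5)
        p = apply_covariates_pk(model, {"female": 1})
        assert p.cl_f == pytest.approx(0.755 * (1 - 0.127))
        assert p.cl_f == pytest.approx(0.659115, abs=5e-6)

    def test_food_effect_reduces_ka_by_78pct(self):
        model = PopulationPKModel(REF, [
            CovariateEffect("ka", "food", "proportional", -0.777)], {}, 0.3, 0.5)
        p = apply_covariates_pk(model, {"food": 1})
        assert p.ka == pytest.approx(1.41 * 0.223)
        assert p.ka == pytest.approx(0.31443, abs=5e-6)
        assert model.food_ka_multiplier() == pytest.approx(0.223)

    def test_missing_covariate_raises_named_error(self):
        model = PopulationPKModel(REF, [
            CovariateEffect("cl_f", "egfr", "power", 0.574, reference=89.3)], {}, 0.3, 0.5)
        with pytest.raises(ConfigurationError, match="egfr"):
            apply_covariates_pk(model, {"weight": 80.0})

    def test_effect_order_is_immaterial(self):
        effects = [
            CovariateEffect("cl_f", "weight", "power", 0.61, reference=83.7),
            CovariateEffect("cl_f", "egfr", "power", 0.574, reference=89.3),
            CovariateEffect("cl_f", "female", "proportional", -0.127),
        ]
        cov = {"weight": 95.0, "egfr": 70.0, "female": 1}
        m1 = PopulationPKModel(REF, effects, {}, 0.3, 0.5)
        m2 = PopulationPKModel(REF, effects[::-1], {}, 0.3, 0.5)
        assert apply_covariates_pk(m1, cov).cl_f == pytest.approx(
            apply_covariates_pk(m2, cov).cl_f)


class TestHybridConstants:
    def test_final_model_half_lives(self):
        _, _, tha, thb = hybrid_constants(REF)
        assert tha == pytest.approx(1.91, abs=0.005)
        assert thb == pytest.approx(40.7, abs=0.05)

    def test_decoupled_compartments(self):
        p = PKParams(0.755, 19.1, 1.41, 1e-12, 0.156, 1.0)
        alpha, beta, _, _ = hybrid_constants(p)
        assert sorted([alpha, beta]) == pytest.approx(sorted([p.k10, p.k32]), rel=1e-6)

    @given(
        cl=st.floats(0.05, 20), vc=st.floats(1, 300),
        k23=st.floats(1e-4, 2), k32=st.floats(1e-4, 2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_vieta_identities(self, cl, vc, k23, k32):
        p = PKParams(cl, vc, 1.0, k23, k32, 1.0)
        alpha, beta, _, _ = hybrid_constants(p)
        assert alpha + beta == pytest.approx(p.k10 + k23 + k32, rel=1e-12)
        assert alpha * beta == pytest.approx(p.k10 * k32, rel=1e-10)
        assert alpha >= beta > 0


class TestPredictConcentration:
    def test_zero_before_absorption(self):
        reg = qd_regimen(180.0, 1)
        assert predict_concentration(REF, reg, [0.0])[0] == 0.0

    def test_matches_ode_oracle(self):
        reg = Regimen(np.array([0.0, 24.0, 48.0]), np.array([180.0, 120.0, 180.0]),
                      np.array([False, True, False]))
        t = np.linspace(0.25, 120, 60)
        closed = predict_concentration(REF, reg, t, food_ka_multiplier=0.223)
        oracle = ode_concentration(REF, reg, t, food_mult=0.223)
        assert np.max(np.abs(closed - oracle) / np.abs(oracle)) < 1e-8

    def test_superposition_of_two_doses(self):
        t = np.linspace(0, 96, 50)
        both = predict_concentration(
            REF, Regimen([0.0, 24.0], [180.0, 180.0], [False, False]), t)
        d1 = predict_concentration(REF, Regimen([0.0], [180.0], [False]), t)
        d2 = predict_concentration(REF, Regimen([24.0], [180.0], [False]), t)
        np.testing.assert_allclose(both, d1 + d2, rtol=1e-12, atol=1e-15)

    def test_dose_proportionality(self):
        t = np.linspace(0.5, 72, 30)
        c1 = predict_concentration(REF, qd_regimen(60.0, 2), t)
        c3 = predict_concentration(REF, qd_regimen(180.0, 2), t)
        np.testing.assert_allclose(c3, 3.0 * c1, rtol=1e-12)

    def test_near_coincident_exponents_finite(self):
        p = PKParams(0.755, 19.1, REF.k10 * (1 + 1e-9), 0.184, 0.156, 1.0)
        c = predict_concentration(p, qd_regimen(180.0, 1), np.linspace(0.5, 48, 20))
        assert np.all(np.isfinite(c)) and np.all(c > 0)

    def test_conc_matrix_agrees_with_scalar_path(self):
        reg = qd_regimen(180.0, 4)
        t = np.linspace(0.5, 100, 25)
        scalar = predict_concentration(REF, reg, t)
        matrix = conc_matrix(
            *(np.array([v]) for v in (REF.cl_f, REF.vc_f, REF.ka, REF.k23, REF.k32, 1.0)),
            reg, t[None, :],
        )
        np.testing.assert_allclose(matrix[0], scalar, rtol=1e-12)

    def test_mass_balance_of_linear_system(self):
        # oracle integration conserves dose; closed form agrees with oracle
        reg = Regimen([0.0], [180.0], [False])
        k10, k23, k32, ka = REF.k10, REF.k23, REF.k32, REF.ka

        def rhs(t, y):
            return [-ka * y[0], ka * y[0] - (k10 + k23) * y[1] + k32 * y[2],
                    k23 * y[1] - k32 * y[2], k10 * y[1]]

        sol = solve_ivp(rhs, (0, 96), [180.0, 0, 0, 0], dense_output=True,
                        rtol=1e-11, atol=1e-13)
        t = np.linspace(0, 96, 40)
        total = sol.sol(t).sum(axis=0)
        np.testing.assert_allclose(total, 180.0, rtol=1e-8)

    def test_food_shifts_peak_but_not_auc(self):
        t = np.linspace(0.0, 24 * 30, 20000)
        fasted = predict_concentration(REF, Regimen([0.0], [180.0], [False]), t)
        fed = predict_concentration(REF, Regimen([0.0], [180.0], [True]), t,
                                    food_ka_multiplier=0.223)
        assert t[np.argmax(fed)] > t[np.argmax(fasted)]
        assert np.trapezoid(fed, t) == pytest.approx(np.trapezoid(fasted, t), rel=1e-3)


class TestAUC:
    def test_zero_dose(self):
        assert auc_ss(REF, 0.0) == 0.0

    def test_dose_over_clearance_identity(self):
        assert auc_ss(REF, 180.0) == pytest.approx(238.41, abs=0.005)
        assert cavg_ss(REF, 180.0) == pytest.approx(9.93, abs=0.005)

    def test_matches_trapezoidal_steady_state_integral(self):
        reg = qd_regimen(180.0, 120)
        t = np.linspace(119 * 24.0, 120 * 24.0, 4001)
        c = predict_concentration(REF, reg, t)
        assert np.trapezoid(c, t) == pytest.approx(auc_ss(REF, 180.0), rel=1e-3)


def test_cv_omega_round_trip():
    assert omega2_to_cv(cv_to_omega2(29.7)) == pytest.approx(29.7)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        PKParams(-1.0, 19.1, 1.41, 0.184, 0.156, 1.0)
    with pytest.raises(ValueError):
        CovariateEffect("cl_f", "female", "proportional", -1.5)
    with pytest.raises(ValueError):
        CovariateEffect("cl_f", "weight", "power", 0.5)  # no reference
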