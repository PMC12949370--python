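"""Survival-model functions, least-squares fitting, iso-dose solving, SER."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from radioser.models import (
    LQParams,
    MTSHParams,
    TCParams,
    UnattainableSurvivalError,
    UnderdeterminedError,
    alpha_beta_ratio,
    compute_ser,
    dose_at_sf,
    fit_model,
    fit_report,
    lq_dose_at_sf,
    lq_sf,
    mtsh_sf,
    tc_sf,
)

DOSE_GRID = np.linspace(0.0, 10.0, 41)


class TestModelFunctions:
    def test_lq_hand_value(self):
        # exp(-(0.45*2 + 0.05*4)) = exp(-1.1)
        assert lq_sf(2.0, LQParams(0.45, 0.05)) == pytest.approx(math.exp(-1.1), rel=1e-12)

    def test_lq_null_parameters_give_unit_survival(self):
        assert lq_sf(4.0, LQParams(0.0, 0.0)) == 1.0

    def test_mtsh_single_target_reduces_to_exponential(self):
        assert mtsh_sf(1.0, MTSHParams(1.0, 1.0)) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_mtsh_hand_value(self):
        expected = 1.0 - (1.0 - math.exp(-2.0)) ** 2
        assert mtsh_sf(2.0, MTSHParams(1.0, 2.0)) == pytest.approx(expected, rel=1e-12)

    def test_tc_hand_value(self):
        expected = math.exp(-1.0) * (1.0 - (1.0 - math.exp(-1.0)) ** 2)
        assert tc_sf(1.0, TCParams(1.0, 1.0, 2.0)) == pytest.approx(expected, rel=1e-12)

    def test_tc_reduces_to_mtsh_when_single_hit_component_vanishes(self):
        d = np.linspace(0, 8, 17)
        tc = tc_sf(d, TCParams(1e9, 1.3, 2.5))
        mtsh = mtsh_sf(d, MTSHParams(1.3, 2.5))
        np.testing.assert_allclose(tc, mtsh, rtol=1e-8)

    @pytest.mark.parametrize(
        "fn, params",
        [
            (lq_sf, LQParams(0.45, 0.05)),
            (mtsh_sf, MTSHParams(1.2, 3.0)),
            (tc_sf, TCParams(4.0, 1.2, 3.0)),
        ],
    )
    def test_unit_survival_at_zero_and_monotone_decreasing(self, fn, params):
        vals = fn(DOSE_GRID, params)
        assert vals[0] == 1.0
        assert np.all(np.diff(vals) <= 1e-15)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lq_sf(-0.1, LQParams(0.3, 0.03))

    @pytest.mark.parametrize(
        "cls, kwargs",
        [
            (LQParams, dict(alpha=-0.1, beta=0.05)),
            (MTSHParams, dict(d0=0.0, n_targets=2.0)),
            (MTSHParams, dict(d0=1.0, n_targets=0.5)),
            (TCParams, dict(d1=0.0, dn=1.0, n_targets=2.0)),
        ],
    )
    def test_invalid_parameters_rejected(self, cls, kwargs):
        with pytest.raises(ValueError):
            cls(**kwargs)


class TestFitting:
    def test_noiseless_lq_recovery_to_1e6(self):
        truth = LQParams(0.45, 0.05)
        pts = [(d, lq_sf(d, truth)) for d in (0, 1, 2, 3, 4, 5, 6)]
        fit = fit_model(pts, model="lq")
        assert fit.params.alpha == pytest.approx(0.45, abs=1e-6)
        assert fit.params.beta == pytest.approx(0.05, abs=1e-6)
        assert fit.r_squared > 1 - 1e-10

    def test_pure_linear_truth_pins_beta_at_bound(self):
        pts = [(d, lq_sf(d, LQParams(0.3, 0.0))) for d in (0, 1, 2, 3, 4, 5, 6)]
        fit = fit_model(pts, model="lq")
        assert fit.params.alpha == pytest.approx(0.3, abs=1e-6)
        assert fit.params.beta == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize(
        "model, truth, maker",
        [
            ("mtsh", (1.4, 3.2), lambda th, d: mtsh_sf(d, MTSHParams(*th))),
            ("tc", (5.0, 1.4, 3.2), lambda th, d: tc_sf(d, TCParams(*th))),
        ],
    )
    def test_noiseless_recovery_other_models(self, model, truth, maker):
        pts = [(d, maker(truth, d)) for d in (0, 1, 2, 3, 4, 5, 6, 8)]
        fit = fit_model(pts, model=model, init=np.asarray(truth) * 1.3)
        assert np.allclose(fit.theta, truth, atol=1e-4)

    def test_fit_idempotence(self):
        rng = np.random.default_rng(3)
        truth = LQParams(0.45, 0.05)
        pts = [(d, max(0.0, lq_sf(d, truth) + rng.normal(0, 0.02))) for d in range(7)]
        fit1 = fit_model(pts, model="lq")
        fit2 = fit_model(pts, model="lq", init=fit1.theta)
        assert fit2.params.alpha == pytest.approx(fit1.params.alpha, abs=1e-7)
        assert fit2.params.beta == pytest.approx(fit1.params.beta, abs=1e-7)

    def test_max_dose_excludes_high_points(self):
        truth = LQParams(0.45, 0.05)
        pts = [(d, lq_sf(d, truth)) for d in (0, 1, 2, 3, 4, 5, 6, 8)]
        fit = fit_model(pts, model="lq", max_dose=6.0)
        assert fit.doses.max() == 6.0

    def test_underdetermined_rejected(self):
        with pytest.raises(UnderdeterminedError):
            fit_model([(0, 1.0), (2, 0.4)], model="lq")

    def test_residual_bookkeeping(self):
        truth = LQParams(0.45, 0.05)
        rng = np.random.default_rng(11)
        pts = [
            (d, max(0.0, lq_sf(d, truth) + rng.normal(0, 0.02)))
            for d in (0, 0, 0, 2, 2, 2, 4, 4, 4)
        ]
        fit = fit_model(pts, model="lq")
        assert len(fit.residuals) == 9
        assert set(fit.dose_sds) == {0.0, 2.0, 4.0}
        assert fit.r_squared <= 1.0
        assert "input_digest" in fit_report(fit)


class TestIsoSurvivalDose:
    def test_d10_hand_value(self):
        assert lq_dose_at_sf(LQParams(0.45, 0.05), 0.1) == pytest.approx(3.6426, abs=2e-4)

    def test_pure_linear_closed_form(self):
        assert lq_dose_at_sf(LQParams(0.45, 0.0), 0.1) == pytest.approx(
            math.log(10) / 0.45, rel=1e-12
        )

    def test_tiny_beta_is_numerically_stable(self):
        # near-zero beta from a bounded optimizer must not collapse to 0
        d = lq_dose_at_sf(LQParams(0.45, 1e-18), 0.1)
        assert d == pytest.approx(math.log(10) / 0.45, rel=1e-9)

    def test_closed_form_matches_bisection_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = LQParams(rng.uniform(0.05, 1.0), rng.uniform(0.0, 0.2))
            s = rng.uniform(0.01, 0.9)
            closed = lq_dose_at_sf(p, s)
            brute = optimize.bisect(lambda d: lq_sf(d, p) - s, 0.0, 200.0, xtol=1e-9)
            assert closed == pytest.approx(brute, abs=1e-6)

    @settings(deadline=None, max_examples=60)
    @given(
        alpha=st.floats(0.05, 1.5),
        beta=st.floats(0.0, 0.3),
        target=st.floats(0.01, 0.95),
    )
    def test_inverse_property(self, alpha, beta, target):
        p = LQParams(alpha, beta)
        assert lq_sf(lq_dose_at_sf(p, target), p) == pytest.approx(target, abs=1e-9)

    def test_mtsh_root_finding_against_function(self):
        fit = fit_model(
            [(d, mtsh_sf(d, MTSHParams(1.4, 3.0))) for d in (0, 1, 2, 3, 4, 5, 6, 8)],
            model="mtsh",
        )
        d10 = dose_at_sf(fit, 0.1)
        assert mtsh_sf(d10, fit.params) == pytest.approx(0.1, abs=1e-5)

    def test_unattainable_survival(self):
        with pytest.raises(UnattainableSurvivalError):
            lq_dose_at_sf(LQParams(0.0, 0.0), 0.1)


class TestSER:
    def test_identical_fits_give_unit_ser(self):
        pts = [(d, lq_sf(d, LQParams(0.45, 0.05))) for d in range(7)]
        fit = fit_model(pts)
        assert compute_ser(fit, fit) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "ctrl, treat, expected",
        [
            ((0.45, 0.05), (0.5686, 0.06), 1.190),
            ((0.31, 0.07), (0.4755, 0.06), 1.160),
        ],
    )
    def test_ser_from_analytic_truths(self, ctrl, treat, expected):
        fc = fit_model([(d, lq_sf(d, LQParams(*ctrl))) for d in range(7)])
        ft = fit_model([(d, lq_sf(d, LQParams(*treat))) for d in range(7)])
        assert compute_ser(fc, ft) == pytest.approx(expected, abs=5e-4)


class TestAlphaBetaRatio:
    def test_direct_ratio(self):
        assert alpha_beta_ratio(LQParams(0.45, 0.05)) == pytest.approx(9.0)
        assert alpha_beta_ratio(LQParams(0.40, 0.06)) == pytest.approx(6.667, abs=1e-3)

    def test_zero_beta_is_unavailable_not_error(self):
        assert math.isnan(alpha_beta_ratio(LQParams(0.4, 0.0)))
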