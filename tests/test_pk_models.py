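"""Clearance estimators: exact cases, analytic oracles, and invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from plasmaclear import (
    NonDecliningCurveError,
    NonInformativeCurveError,
    PlasmaSample,
    SubjectSession,
    TwoSampleInput,
    clearance_trapezoidal,
    clearance_two_sample,
    fit_one_compartment,
    fit_two_compartment,
    log_linear_tail,
    subtract_background,
    trapezoid_auc,
)
from conftest import SCHEDULE, biexp_session, make_session, monoexp_session


class TestSessionValidation:
    def test_rejects_nonpositive_dose(self):
        with pytest.raises(ValueError, match="dose"):
            make_session([10, 20], [5, 4], dose_ug=0.0)

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SubjectSession(
                "s", 0, "m", 100.0,
                (PlasmaSample(20, 5.0), PlasmaSample(10, 6.0)),
            )

    def test_rejects_duplicate_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_session([10, 10, 20], [5, 5, 4])

    def test_requires_two_post_dose_samples(self):
        with pytest.raises(ValueError, match="post-dose"):
            make_session([0, 10], [0, 5])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            PlasmaSample(10.0, -1.0)


class TestSubtractBackground:
    def test_zero_background_is_identity_on_post_dose(self):
        sess = make_session([2, 30, 60], [80, 50, 20])
        out = subtract_background(sess)
        assert out.samples == sess.samples

    def test_subtracts_background_from_each_sample(self):
        sess = make_session([30, 60], [50.0, 20.0], background=2.0)
        out = subtract_background(sess)
        assert out.samples[0].concentration == pytest.approx(48.0)
        assert out.samples[1].concentration == pytest.approx(18.0)
        assert not out.samples[0].clamped

    def test_clamps_at_zero_and_flags(self):
        sess = make_session([30, 300], [50.0, 4.0], background=5.0)
        out = subtract_background(sess)
        assert out.samples[-1].concentration == 0.0
        assert out.samples[-1].clamped

    def test_t0_sample_becomes_background_and_is_removed(self):
        sess = make_session([0, 30, 60], [3.0, 50.0, 20.0])
        out = subtract_background(sess)
        assert out.background_conc == 3.0
        assert [s.time_min for s in out.samples] == [30, 60]
        assert out.samples[0].concentration == pytest.approx(47.0)

    def test_all_samples_below_background_raises(self):
        sess = make_session([30, 60], [1.0, 0.5], background=2.0)
        with pytest.raises(NonInformativeCurveError):
            subtract_background(sess)


class TestTrapezoidAuc:
    def test_single_trapezoid(self):
        samples = (PlasmaSample(0, 100.0), PlasmaSample(10, 50.0))
        assert trapezoid_auc(samples) == pytest.approx(750.0)

    def test_constant_function(self):
        samples = (PlasmaSample(0, 100.0), PlasmaSample(10, 100.0))
        assert trapezoid_auc(samples) == pytest.approx(1000.0)

    def test_exceeds_analytic_integral_on_convex_curve(self):
        # 12-point sampling of 100 e^{-0.01 t}: the chords of a convex
        # decreasing curve lie above it, so the trapezoid sum must exceed
        # the integral computed by an independent quadrature oracle.
        times = np.array(SCHEDULE)
        samples = tuple(
            PlasmaSample(t, 100.0 * math.exp(-0.01 * t)) for t in times
        )
        oracle, _ = quad(lambda t: 100.0 * math.exp(-0.01 * t), 0.0, 300.0)
        auc = trapezoid_auc(samples)
        assert auc > oracle
        assert auc == pytest.approx(oracle, rel=0.05)

    @settings(derandomize=True, max_examples=50)
    @given(rate=st.floats(1e-3, 0.1), c0=st.floats(1.0, 500.0))
    def test_refinement_converges_monotonically(self, rate, c0):
        prev = None
        for n in (6, 12, 24, 48):
            t = np.linspace(0.0, 300.0, n + 1)
            auc = trapezoid_auc(
                tuple(PlasmaSample(ti, c0 * math.exp(-rate * ti)) for ti in t)
            )
            analytic = c0 / rate * (1.0 - math.exp(-rate * 300.0))
            assert auc >= analytic * (1 - 1e-12)
            if prev is not None:
                assert auc <= prev * (1 + 1e-12)
            prev = auc

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            trapezoid_auc((PlasmaSample(0, 1.0),))


class TestLogLinearTail:
    def test_below_threshold_no_tail(self):
        samples = (PlasmaSample(240, 0.6), PlasmaSample(300, 0.4))
        tail, rate = log_linear_tail(samples, threshold=0.5)
        assert tail == 0.0

    def test_clamped_when_terminal_below_threshold(self):
        # exact points on 50 e^{-0.02 t}: C(300) = 50 e^{-6} < 0.5
        samples = tuple(
            PlasmaSample(t, 50.0 * math.exp(-0.02 * t)) for t in (240, 300)
        )
        tail, _ = log_linear_tail(samples, threshold=0.5)
        assert tail == 0.0

    def test_matches_analytic_exponential_integral(self):
        # exact points on 100 e^{-0.01 t}; the analytic integral of the
        # fitted exponential from t_last down to 0.5 µg/mL is
        # (100 e^{-3} - 0.5)/0.01 = 447.871.
        samples = tuple(
            PlasmaSample(t, 100.0 * math.exp(-0.01 * t)) for t in (180, 240, 300)
        )
        tail, rate = log_linear_tail(samples, threshold=0.5)
        expected = (100.0 * math.exp(-3.0) - 0.5) / 0.01
        assert rate == pytest.approx(0.01, rel=1e-9)
        assert tail == pytest.approx(expected, rel=1e-9)
        assert tail == pytest.approx(447.871, abs=5e-3)

    def test_non_declining_terminal_phase_raises(self):
        samples = (PlasmaSample(240, 1.0), PlasmaSample(300, 2.0))
        with pytest.raises(NonDecliningCurveError):
            log_linear_tail(samples, threshold=0.5)


class TestClearanceTrapezoidal:
    def test_dense_grid_recovers_monoexponential_clearance(self):
        t = np.arange(0.0, 601.0)
        sess = make_session(t, 100.0 * np.exp(-0.01 * t), dose_ug=10_000.0)
        est = clearance_trapezoidal(sess, threshold=0.0)
        assert est.clearance_ml_min == pytest.approx(1.0, rel=5e-3)
        assert est.auc == pytest.approx(est.auc_observed + est.auc_extrapolated)

    def test_schedule_agrees_with_dense_grid_oracle(self):
        def build(times):
            times = np.asarray(times, dtype=float)
            return make_session(times, 100.0 * np.exp(-0.01 * times))

        coarse = clearance_trapezoidal(build(SCHEDULE), threshold=0.5)
        dense = clearance_trapezoidal(build(np.arange(0.0, 301.0)), threshold=0.5)
        assert coarse.clearance_ml_min == pytest.approx(
            dense.clearance_ml_min, rel=0.05
        )

    def test_clearance_is_linear_in_dose(self):
        t = np.array(SCHEDULE)
        single = make_session(t, 100.0 * np.exp(-0.01 * t), dose_ug=10_000.0)
        double = make_session(t, 100.0 * np.exp(-0.01 * t), dose_ug=20_000.0)
        assert clearance_trapezoidal(double).clearance_ml_min == pytest.approx(
            2.0 * clearance_trapezoidal(single).clearance_ml_min
        )


class TestOneCompartment:
    def test_exact_recovery_on_monoexponential(self):
        sess = monoexp_session(
            50.0, 0.02, (30, 60, 90, 120, 180, 240, 300), dose_ug=5000.0
        )
        est = fit_one_compartment(sess)
        assert est.terms[0].coefficient == pytest.approx(50.0, rel=1e-9)
        assert est.terms[0].rate == pytest.approx(0.02, rel=1e-9)
        assert est.clearance_ml_min == pytest.approx(2.0, rel=1e-9)

    def test_t_min_excludes_distribution_phase_points(self):
        sess = monoexp_session(50.0, 0.02, SCHEDULE[1:], dose_ug=5000.0)
        est = fit_one_compartment(sess, t_min=30.0)
        assert est.diagnostics["n_samples"] == 7  # 30..300 of the 11 post-dose

    def test_median_recovery_under_noise(self, rng):
        times = np.array([30, 60, 90, 120, 180, 240, 300.0])
        errs = []
        for _ in range(200):
            noise = rng.lognormal(sigma=0.05, size=times.size)
            sess = make_session(
                times, 50.0 * np.exp(-0.02 * times) * noise, dose_ug=5000.0
            )
            errs.append(fit_one_compartment(sess).clearance_ml_min)
        assert np.median(errs) == pytest.approx(2.0, rel=0.02)

    def test_rising_curve_raises(self):
        sess = make_session([30, 60, 90], [1.0, 2.0, 4.0])
        with pytest.raises(NonDecliningCurveError):
            fit_one_compartment(sess)

    def test_too_few_points_raises(self):
        sess = make_session([2, 5, 30], [100.0, 90.0, 50.0])
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_one_compartment(sess)


class TestTwoCompartment:
    def test_analytic_auc_of_exact_biexponential(self):
        sess = biexp_session(80.0, 0.15, 40.0, 0.01, SCHEDULE[1:])
        est = fit_two_compartment(sess)
        assert est.auc == pytest.approx(80 / 0.15 + 40 / 0.01, rel=1e-6)
        assert est.clearance_ml_min == pytest.approx(10_000 / (80 / 0.15 + 40 / 0.01), rel=1e-6)
        fast, slow = est.terms
        assert fast.rate > slow.rate
        assert fast.rate == pytest.approx(0.15, rel=1e-6)
        assert slow.rate == pytest.approx(0.01, rel=1e-6)

    def test_monoexponential_input_takes_fallback_path(self):
        sess = monoexp_session(50.0, 0.02, SCHEDULE[1:], dose_ug=5000.0)
        est = fit_two_compartment(sess)
        assert est.method == "two_compartment"
        assert "fallback" in est.diagnostics
        assert est.clearance_ml_min == pytest.approx(2.0, rel=1e-6)

    def test_too_few_samples_raises(self):
        sess = make_session([2, 30, 60, 300], [100, 50, 25, 1.0])
        with pytest.raises(ValueError, match=">= 5"):
            fit_two_compartment(sess)


class TestTwoSample:
    def test_exact_monoexponential_points(self):
        inp = TwoSampleInput(10_000.0, 30.0, 90.0, 74.0818, 40.6570)
        est = clearance_two_sample(inp)
        assert est.terms[0].rate == pytest.approx(0.01, rel=1e-4)
        assert est.terms[0].coefficient == pytest.approx(100.0, rel=1e-4)
        assert est.clearance_ml_min == pytest.approx(1.0, rel=1e-4)

    @settings(derandomize=True, max_examples=100)
    @given(
        t1=st.floats(1.0, 150.0),
        dt=st.floats(1.0, 200.0),
        b=st.floats(1.0, 500.0),
        beta=st.floats(1e-3, 0.1),
        dose=st.floats(100.0, 1e5),
    )
    def test_time_choice_irrelevant_on_model_consistent_data(
        self, t1, dt, b, beta, dose
    ):
        t2 = t1 + dt
        inp = TwoSampleInput(
            dose, t1, t2, b * math.exp(-beta * t1), b * math.exp(-beta * t2)
        )
        est = clearance_two_sample(inp)
        assert est.clearance_ml_min == pytest.approx(dose * beta / b, rel=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        t1=st.floats(1.0, 150.0),
        dt=st.floats(1.0, 200.0),
        c1=st.floats(0.5, 500.0),
        ratio=st.floats(1.01, 50.0),
        dose=st.floats(100.0, 1e5),
    )
    def test_equivalence_with_two_point_one_compartment_fit(
        self, t1, dt, c1, ratio, dose
    ):
        """The defining contract: identical to the log-linear fit on {t1, t2}."""
        t2, c2 = t1 + dt, c1 / ratio
        two = clearance_two_sample(TwoSampleInput(dose, t1, t2, c1, c2))
        sess = make_session([t1, t2], [c1, c2], dose_ug=dose)
        one = fit_one_compartment(sess, t_min=0.0)
        assert two.clearance_ml_min == pytest.approx(
            one.clearance_ml_min, rel=1e-9
        )

    def test_non_declining_pair_rejected(self):
        with pytest.raises(NonDecliningCurveError):
            TwoSampleInput(1000.0, 30.0, 90.0, 5.0, 5.0)

    def test_equal_times_rejected(self):
        with pytest.raises(ValueError):
            TwoSampleInput(1000.0, 30.0, 30.0, 5.0, 4.0)


class TestDoseAucConsistency:
    """clearance · auc = dose to 1e-9 relative, for every estimator."""

    @pytest.fixture
    def session(self):
        return biexp_session(80.0, 0.15, 40.0, 0.01, SCHEDULE[1:])

    @pytest.mark.parametrize("estimator", [
        clearance_trapezoidal, fit_one_compartment, fit_two_compartment,
    ])
    def test_product_recovers_dose(self, session, estimator):
        est = estimator(session)
        assert est.clearance_ml_min * est.auc == pytest.approx(
            session.dose_ug, rel=1e-9
        )

    def test_two_sample_product(self):
        est = clearance_two_sample(TwoSampleInput(5000.0, 30.0, 90.0, 40.0, 10.0))
        assert est.clearance_ml_min * est.auc == pytest.approx(5000.0, rel=1e-9)
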