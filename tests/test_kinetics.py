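import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, solve_ivp

from petgfr import (
    FitWindow,
    KidneyTruth,
    NoiseModel,
    apply_window,
    fit_1tc,
    goodness_of_fit,
    simulate_kidney_tac,
    solve_model,
)
from petgfr.frames import SampledCurve, ValidationError, make_frame_schedule
from petgfr.kinetics import plasma_nodes, window_mask


def ode_oracle(k1, k2, c_p, schedule):
    """Independent stiff ODE integration of dC/dt = K1 C_P - k2 C (rates 1/min)."""
    t_nodes, p_nodes = plasma_nodes(c_p)

    def rhs(t, y):
        cp = np.interp(t, t_nodes, p_nodes)
        return [(k1 / 60.0) * cp - (k2 / 60.0) * y[0]]

    sol = solve_ivp(
        rhs, (0.0, t_nodes[-1]), [0.0], method="LSODA",
        t_eval=schedule.mid_times, rtol=1e-10, atol=1e-12, max_step=1.0,
    )
    return sol.y[0]


class TestSolveModel:
    def test_no_uptake_limit(self, plasma_curve, aorta_curve):
        curves = solve_model(0.0, 0.1, 0.3, plasma_curve, aorta_curve)
        assert np.all(curves.c_ec.values == 0.0)
        np.testing.assert_allclose(curves.c_model.values, 0.3 * aorta_curve.values)

    def test_k2_zero_running_integral(self, plasma_curve, aorta_curve, clinical_schedule):
        curves = solve_model(0.2, 0.0, 0.0, plasma_curve, aorta_curve)
        t = np.concatenate(([0.0], clinical_schedule.mid_times))
        p = np.concatenate(([0.0], plasma_curve.values))
        expected = (0.2 / 60.0) * cumulative_trapezoid(p, t)
        np.testing.assert_allclose(curves.c_ec.values, expected, rtol=1e-12)

    @pytest.mark.parametrize(
        "k1,k2",
        [(0.2, 0.05), (0.01, 0.0), (0.5, 0.3), (0.1, 0.001), (0.35, 0.15)],
    )
    def test_against_ode_integration(self, k1, k2, plasma_curve, aorta_curve, clinical_schedule):
        """Exact piecewise-linear convolution matches a stiff ODE solver to <0.1%."""
        ours = solve_model(k1, k2, 0.0, plasma_curve, aorta_curve).c_ec.values
        ref = ode_oracle(k1, k2, plasma_curve, clinical_schedule)
        scale = ref.max()
        np.testing.assert_allclose(ours / scale, ref / scale, atol=1e-3)

    def test_operational_curve_assembly(self, plasma_curve, aorta_curve):
        vb = 0.25
        curves = solve_model(0.3, 0.08, vb, plasma_curve, aorta_curve)
        manual = (1 - vb) * curves.c_ec.values + vb * aorta_curve.values
        np.testing.assert_allclose(curves.c_model.values, manual, rtol=1e-12)

    def test_invalid_params_rejected(self, plasma_curve, aorta_curve):
        with pytest.raises(ValidationError):
            solve_model(-0.1, 0.1, 0.2, plasma_curve, aorta_curve)
        with pytest.raises(ValidationError):
            solve_model(0.1, 0.1, 1.5, plasma_curve, aorta_curve)


class TestApplyWindow:
    def test_full_schedule_with_exclusion(self, clinical_schedule):
        """Closed [120, 600] s exclusion removes the 18x10 s and 10x30 s frames.

        Enumerating the 72 mid-times: 28 fall inside [120, 600] (125...585 s),
        so 44 frames remain.
        """
        mids = clinical_schedule.mid_times
        expected = int(np.sum((mids <= 1800) & ~((mids >= 120) & (mids <= 600))))
        assert expected == 44
        mask = window_mask(clinical_schedule, FitWindow(1800.0, (120.0, 600.0)))
        assert int(mask.sum()) == 44

    def test_truncation_only(self, clinical_schedule, plasma_curve):
        t, v = apply_window(plasma_curve, FitWindow(900.0, None))
        assert t.size == int(np.sum(clinical_schedule.mid_times <= 900.0)) == 57
        assert np.all(t <= 900.0)

    def test_exclusion_outside_range_is_identity(self, clinical_schedule, plasma_curve):
        t, v = apply_window(plasma_curve, FitWindow(1800.0, (2000.0, 3000.0)))
        assert t.size == 72

    def test_empty_window_rejected(self, plasma_curve):
        with pytest.raises(ValidationError):
            apply_window(plasma_curve, FitWindow(1800.0, (0.0, 1800.0)))


class TestGoodnessOfFit:
    def test_perfect_fit_sentinel(self):
        chi2, aic = goodness_of_fit(np.zeros(10), np.ones(10))
        assert chi2 == 0.0 and aic == float("-inf")

    def test_forced_arithmetic(self):
        """r = (1,1,1,1), w = 1: chi2 = 4, AIC = 4 ln(1) + 6 = 6."""
        chi2, aic = goodness_of_fit(np.ones(4), np.ones(4))
        assert chi2 == pytest.approx(4.0)
        assert aic == pytest.approx(6.0)

    def test_matches_direct_formula(self):
        """Brute-force reimplementation on random residuals agrees to 1e-12."""
        rng = np.random.default_rng(3)
        r = rng.normal(size=30)
        w = rng.uniform(0.5, 2.0, size=30)
        chi2, aic = goodness_of_fit(r, w, n_params=3)
        chi2_ref = float(sum(wi * ri**2 for wi, ri in zip(w, r)))
        aic_ref = 30 * np.log(chi2_ref / 30) + 2 * 3
        assert chi2 == pytest.approx(chi2_ref, abs=1e-12)
        assert aic == pytest.approx(aic_ref, abs=1e-12)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValidationError):
            goodness_of_fit(np.ones(3), np.ones(3), n_params=3)


class TestFit:
    def test_noise_free_parameter_recovery(self, plasma_curve, aorta_curve):
        """A curve generated by the forward model returns (K1, k2, vB) to <0.1%."""
        truth = (0.15, 0.04, 0.2)
        target = solve_model(*truth, plasma_curve, aorta_curve).c_model
        fit = fit_1tc(target, plasma_curve, aorta_curve)
        assert fit.k1 == pytest.approx(truth[0], rel=1e-3)
        assert fit.k2 == pytest.approx(truth[1], rel=1e-3)
        assert fit.vb == pytest.approx(truth[2], rel=1e-3)
        assert fit.converged

    def test_zero_tac_pins_k1_at_bound(self, plasma_curve, aorta_curve, clinical_schedule):
        zero = SampledCurve(clinical_schedule, np.zeros(72))
        fit = fit_1tc(zero, plasma_curve, aorta_curve)
        assert fit.k1 == pytest.approx(0.0, abs=1e-5)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_exclusion_improves_contaminated_fit(
        self, plasma_curve, aorta_curve, clinical_schedule
    ):
        """With urine spill-over, excluding 2-10 min lowers chi2 and AIC."""
        truth = KidneyTruth(0.3, 0.08, 0.2, 140.0, spill_fraction=1.5e-3, spill_delay_s=60.0)
        cort, _ = simulate_kidney_tac(plasma_curve, aorta_curve, truth, clinical_schedule)
        full = fit_1tc(cort, plasma_curve, aorta_curve, FitWindow(1800.0, None))
        excl = fit_1tc(cort, plasma_curve, aorta_curve, FitWindow(1800.0, (120.0, 600.0)))
        assert excl.chi2 < full.chi2
        assert excl.aic < full.aic
        assert excl.n_points == 44 and full.n_points == 72

    def test_k1_bias_shrinks_with_noise(self, plasma_curve, aorta_curve, clinical_schedule, default_truth):
        """Median |K1 bias| decreases monotonically as sigma0 -> 0."""
        biases = []
        for sigma0 in (2.0, 0.5, 0.0):
            errs = []
            for rep in range(12):
                rng = np.random.default_rng(100 + rep)
                cort, _ = simulate_kidney_tac(
                    plasma_curve, aorta_curve, default_truth, clinical_schedule,
                    noise=NoiseModel(sigma0=sigma0), rng=rng,
                )
                fit = fit_1tc(cort, plasma_curve, aorta_curve)
                errs.append(abs(fit.k1 - default_truth.k1_per_min) / default_truth.k1_per_min)
            biases.append(float(np.median(errs)))
        assert biases[0] >= biases[1] >= biases[2]
        assert biases[1] < 0.05  # moderate noise: median K1 error < 5%

    def test_too_few_frames_rejected(self, aorta_curve):
        sched = make_frame_schedule([(5, 10)])
        short = SampledCurve(sched, np.ones(5))
        with pytest.raises(ValidationError):
            fit_1tc(short, short, short)

    def test_duration_weighting_scheme(self, plasma_curve, aorta_curve):
        target = solve_model(0.2, 0.05, 0.15, plasma_curve, aorta_curve).c_model
        fit = fit_1tc(target, plasma_curve, aorta_curve, weights="duration")
        assert fit.k1 == pytest.approx(0.2, rel=1e-3)
        with pytest.raises(ValidationError):
            fit_1tc(target, plasma_curve, aorta_curve, weights="bogus")
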