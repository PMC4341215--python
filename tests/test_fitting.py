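"""BP estimators: linear solver, ratio, and the two-step model fits."""

import numpy as np
import pytest

from dualprobe.fitting import (
    SolverOptions,
    bp_ratio,
    estimate_bp,
    fit_targeted_dpm,
    fit_targeted_dpmns,
    fit_untargeted_dpm,
    fit_untargeted_dpmns,
    kaczmarz_tikhonov_solve,
    predict_totals,
)
from dualprobe.kinetics import (
    ConcentrationCurve,
    RateConstants,
    simulate_dual_probe,
)


class TestKaczmarzTikhonov:
    def test_identity_system(self):
        b = np.array([3.0, -1.0, 2.0, 0.5])
        sol = kaczmarz_tikhonov_solve(
            np.eye(4), b, SolverOptions(tikhonov_lambda=0.0)
        )
        np.testing.assert_allclose(sol.coefficients, b, atol=1e-10)
        assert sol.converged

    def test_regularization_dominance(self, rng):
        B = rng.normal(size=(11, 3))
        b = rng.normal(size=11)
        sol = kaczmarz_tikhonov_solve(B, b, SolverOptions(tikhonov_lambda=1e9))
        assert np.linalg.norm(sol.coefficients) <= 1e-6 * np.linalg.norm(b)

    def test_matches_closed_form_ridge(self, rng):
        B = rng.normal(size=(11, 3))
        b = rng.normal(size=11)
        lam = 1e-3
        sol = kaczmarz_tikhonov_solve(B, b, SolverOptions(tikhonov_lambda=lam))
        direct = np.linalg.solve(B.T @ B + lam * np.eye(3), B.T @ b)
        np.testing.assert_allclose(sol.coefficients, direct, atol=1e-6)

    def test_deterministic_under_seed(self, rng):
        B = rng.normal(size=(8, 4))
        b = rng.normal(size=8)
        opts = SolverOptions(tikhonov_lambda=1e-4, max_sweeps=7, seed=5)
        a = kaczmarz_tikhonov_solve(B, b, opts)
        c = kaczmarz_tikhonov_solve(B, b, opts)
        assert np.array_equal(a.coefficients, c.coefficients)

    def test_objective_monotone_in_sweeps(self, rng):
        """The regularized objective never increases sweep over sweep."""
        B = rng.normal(size=(11, 3))
        b = rng.normal(size=11)
        lam = 1e-3

        def objective(max_sweeps):
            sol = kaczmarz_tikhonov_solve(
                B,
                b,
                SolverOptions(
                    tikhonov_lambda=lam, max_sweeps=max_sweeps, tolerance=1e-300, seed=0
                ),
            )
            c = sol.coefficients
            return sol.residual_norm**2 + lam * float(c @ c)

        values = [objective(k) for k in range(1, 15)]
        assert all(b2 <= a2 + 1e-12 for a2, b2 in zip(values, values[1:]))

    def test_nonconformable_rejected(self):
        with pytest.raises(ValueError):
            kaczmarz_tikhonov_solve(np.eye(3), np.ones(4))


class TestBpRatio:
    def test_identical_curves_give_zero(self, study_rates, schedule):
        rates = RateConstants(F=1.0, k5=0.16, k6=0.06)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0)
        for idx in range(len(m.targeted)):
            assert bp_ratio(m, rinse_index=idx) == pytest.approx(0.0, abs=1e-10)

    def test_final_rinse_arithmetic(self, schedule):
        t = schedule.measurement_times()
        tgt = np.linspace(100, 30, len(t))
        un = np.linspace(90, 10, len(t))
        from dualprobe.kinetics import DualProbeMeasurement

        m = DualProbeMeasurement(
            "s",
            "x",
            ConcentrationCurve("targeted", t, tgt),
            ConcentrationCurve("untargeted", t, un),
        )
        assert bp_ratio(m) == pytest.approx((30 - 10) / 10)

    def test_tiny_reference_rejected(self, schedule):
        t = schedule.measurement_times()
        from dualprobe.kinetics import DualProbeMeasurement

        m = DualProbeMeasurement(
            "s",
            "x",
            ConcentrationCurve("targeted", t, np.ones_like(t)),
            ConcentrationCurve("untargeted", t, np.zeros_like(t)),
        )
        with pytest.raises(ZeroDivisionError):
            bp_ratio(m)

    def test_out_of_range_index(self, study_rates, schedule):
        m = simulate_dual_probe(study_rates, schedule, 0.0, seed=0)
        with pytest.raises(IndexError):
            bp_ratio(m, rinse_index=99)

    @pytest.mark.parametrize("F", [0.2, 0.32958])
    def test_quasi_equilibrium_closed_form(self, schedule, F):
        """With fast binding and no NS pool the noiseless ratio follows
        exp(F·t·BP/(1+BP)) − 1; it equals BP only at one rinse depth
        (F·t = (1+BP)·ln(1+BP)/BP — here F≈0.3296 puts it at rinse 10)."""
        bp = 2.0
        rates = RateConstants(F=F, k3=20.0 * bp, k4=20.0)  # fast exchange
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0, variant="DPM")
        t_final = m.times[-1]
        expected = np.exp(F * t_final * bp / (1 + bp)) - 1
        assert bp_ratio(m) == pytest.approx(expected, rel=0.02)
        if F == 0.32958:
            assert bp_ratio(m) == pytest.approx(bp, rel=0.03)


class TestUntargetedDpm:
    def test_exact_monoexponential_recovery(self, schedule):
        t = schedule.measurement_times()
        c = ConcentrationCurve("untargeted", t, 150 * np.exp(-0.2 * t))
        fit = fit_untargeted_dpm(c)
        assert fit.rates.F == pytest.approx(0.2, abs=1e-6)
        assert fit.amplitudes[0] == pytest.approx(150.0, abs=1e-4)
        assert fit.converged

    def test_constant_curve_gives_zero_washout(self, schedule):
        t = schedule.measurement_times()
        fit = fit_untargeted_dpm(ConcentrationCurve("untargeted", t, np.full_like(t, 80.0)))
        assert fit.rates.F == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_curve_rejected(self, schedule):
        t = schedule.measurement_times()
        with pytest.raises(ValueError, match="degenerate"):
            fit_untargeted_dpm(ConcentrationCurve("untargeted", t, np.zeros_like(t)))

    def test_wrong_probe_label_rejected(self, schedule):
        t = schedule.measurement_times()
        with pytest.raises(ValueError):
            fit_untargeted_dpm(ConcentrationCurve("targeted", t, np.exp(-t)))

    def test_noisy_replicates_unbiased(self, schedule, rng):
        t = schedule.measurement_times()
        clean = 150 * np.exp(-0.2 * t)
        sigma = 0.0048 * np.sqrt(np.mean(clean**2))
        Fs = [
            fit_untargeted_dpm(
                ConcentrationCurve("untargeted", t, clean + rng.normal(0, sigma, t.shape))
            ).rates.F
            for _ in range(100)
        ]
        assert np.mean(Fs) == pytest.approx(0.2, rel=0.02)


class TestTargetedDpm:
    def test_self_model_round_trip(self, schedule):
        rates = RateConstants(F=0.2, k3=0.3, k4=0.1)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0, variant="DPM")
        un = fit_untargeted_dpm(m.untargeted)
        fit = fit_targeted_dpm(m.targeted, F_fixed=un.rates.F)
        assert fit.bp == pytest.approx(3.0, abs=1e-3)
        assert fit.converged

    def test_null_data_gives_zero_bp(self, schedule):
        rates = RateConstants(F=0.3, k3=0.0, k4=0.1)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0, variant="DPM")
        fit = fit_targeted_dpm(m.targeted, F_fixed=0.3)
        assert fit.bp <= 0.01

    def test_biased_under_unmodeled_nonspecific_binding(self, schedule):
        """Ignoring the NS pool distorts BP (why the NS-aware model exists)."""
        rates = RateConstants(F=1.0, k3=0.217, k4=0.1, k5=0.16, k6=0.06)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0)
        un = fit_untargeted_dpm(m.untargeted)
        fit = fit_targeted_dpm(m.targeted, F_fixed=un.rates.F)
        assert abs(fit.bp - 2.17) > 0.2

    def test_negative_f_rejected(self, schedule):
        t = schedule.measurement_times()
        with pytest.raises(ValueError):
            fit_targeted_dpm(ConcentrationCurve("targeted", t, np.exp(-t)), F_fixed=-1.0)


class TestUntargetedDpmns:
    def test_noiseless_rate_recovery(self, schedule):
        rates = RateConstants(F=0.2, k5=0.16, k6=0.06)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0)
        fit = fit_untargeted_dpmns(m.untargeted)
        assert fit.rates.F == pytest.approx(0.2, rel=0.01)
        assert fit.rates.k5 == pytest.approx(0.16, rel=0.01)
        assert fit.rates.k6 == pytest.approx(0.06, rel=0.01)
        assert fit.converged

    def test_collapses_to_monoexponential_without_ns(self, schedule):
        rates = RateConstants(F=0.2, k5=0.0, k6=0.0)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0)
        fit = fit_untargeted_dpmns(m.untargeted)
        assert fit.rates.F == pytest.approx(0.2, rel=0.01)
        assert fit.rates.k5 <= 0.01

    def test_noisy_replicates_recover_ns_ratio(self, schedule):
        rates = RateConstants(F=1.0, k5=0.16, k6=0.06)
        ratios = []
        for i in range(100):
            m = simulate_dual_probe(
                rates, schedule, 0.48, seed=np.random.SeedSequence(21, spawn_key=(0, i))
            )
            fit = fit_untargeted_dpmns(m.untargeted)
            ratios.append(fit.rates.k5 / fit.rates.k6)
        assert np.median(ratios) == pytest.approx(0.16 / 0.06, rel=0.25)


class TestTargetedDpmns:
    def test_self_model_round_trip_at_study_bp(self, schedule):
        rates = RateConstants(F=1.0, k3=0.217, k4=0.1, k5=0.16, k6=0.06)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0)
        fit = estimate_bp(m, "DPM-NS")
        assert fit.bp == pytest.approx(2.17, rel=0.02)

    def test_null_recovery(self, schedule):
        rates = RateConstants(F=1.0, k3=0.0, k4=0.1, k5=0.16, k6=0.06)
        m = simulate_dual_probe(rates, schedule, 0.0, seed=0)
        un = fit_untargeted_dpmns(m.untargeted)
        fit = fit_targeted_dpmns(m.targeted, un.rates.F, un.rates.k5, un.rates.k6)
        assert fit.bp <= 0.01

    def test_noisy_replicates_unbiased_at_moderate_bp(self, schedule, study_rates):
        bps = []
        for i in range(100):
            m = simulate_dual_probe(
                study_rates,
                schedule,
                0.48,
                seed=np.random.SeedSequence(12345, spawn_key=(0, i)),
            )
            bps.append(estimate_bp(m, "DPM-NS").bp)
        assert abs(np.mean(bps) - 1.0) <= 0.1

    def test_negative_rate_rejected(self, schedule):
        t = schedule.measurement_times()
        curve = ConcentrationCurve("targeted", t, np.exp(-t))
        with pytest.raises(ValueError):
            fit_targeted_dpmns(curve, F=0.5, k5=-0.1, k6=0.06)


class TestEstimateBp:
    def test_unknown_estimator_rejected(self, study_rates, schedule):
        m = simulate_dual_probe(study_rates, schedule, 0.0, seed=0)
        with pytest.raises(ValueError):
            estimate_bp(m, "nope")

    def test_fit_report_serializes(self, study_rates, schedule):
        m = simulate_dual_probe(study_rates, schedule, 0.0, seed=0)
        d = estimate_bp(m, "DPM-NS").to_dict()
        assert d["estimator"] == "DPM-NS"
        assert set(d["rates"]) == {"F", "k3", "k4", "k5", "k6"}
        assert d["bp"] == pytest.approx(1.0, rel=0.01)
        assert isinstance(d["converged"], bool)

    def test_predicted_curve_matches_noiseless_data(self, study_rates, schedule):
        m = simulate_dual_probe(study_rates, schedule, 0.0, seed=0)
        fit = estimate_bp(m, "DPM-NS")
        pred = predict_totals(fit, m.times)
        np.testing.assert_allclose(pred, m.targeted.values, rtol=5e-3)
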