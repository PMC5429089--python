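"""Model-fitting tests: kinetic recovery, line-tension law, energy ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macquant.models import (EnergyRatioInputs, BOLTZMANN_J_PER_K,
                             energy_ratio, fit_line_tension,
                             fit_monoexponential, line_tension_model,
                             monoexponential)
from macquant.synthdata import generate_kinetic_series

# final contour-length changes reported at the three bath temperatures
PRINTED_KINETIC_PARAMS = [(188.0, 9.5), (314.0, 5.6), (706.3, 4.4)]


class TestMonoexponentialFit:
    @pytest.mark.parametrize("L_final,tau", PRINTED_KINETIC_PARAMS)
    def test_noiseless_recovery_to_machine_precision(self, L_final, tau):
        t = np.linspace(1.0, 30.0, 30)
        data = generate_kinetic_series((L_final, tau, 1.0), t)
        fit = fit_monoexponential(data[:, 0], data[:, 1], t0=1.0)
        assert fit.L_final == pytest.approx(L_final, rel=1e-6)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.residual_rms < 1e-6 * L_final

    def test_noisy_fit_agrees_with_grid_search_oracle(self):
        """The optimizer's minimum matches an exhaustive 2-D grid search
        within the grid resolution (independent minimizer oracle)."""
        t = np.linspace(1.0, 30.0, 60)
        data = generate_kinetic_series((314.0, 5.6, 1.0), t,
                                       noise_sigma_um=5.0, seed=42)
        fit = fit_monoexponential(data[:, 0], data[:, 1], t0=1.0)

        Lg = np.linspace(250, 400, 301)
        tg = np.linspace(2, 12, 301)
        LL, TT = np.meshgrid(Lg, tg, indexing="ij")
        pred = LL[..., None] * -np.expm1(-(t - 1.0)[None, None] / TT[..., None])
        ssr = ((pred - data[:, 1]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
        assert fit.L_final == pytest.approx(Lg[i], abs=2 * (Lg[1] - Lg[0]))
        assert fit.tau == pytest.approx(tg[j], abs=2 * (tg[1] - tg[0]))

    def test_noisy_estimates_within_3_sigma(self):
        t = np.linspace(1.0, 30.0, 60)
        data = generate_kinetic_series((314.0, 5.6, 1.0), t,
                                       noise_sigma_um=5.0, seed=7)
        fit = fit_monoexponential(data[:, 0], data[:, 1], t0=1.0)
        assert abs(fit.L_final - 314.0) < 3 * fit.L_final_stderr
        assert abs(fit.tau - 5.6) < 3 * fit.tau_stderr

    def test_replicate_recovery_median_error_below_5pct(self):
        """Over 200 seeded replicates (n=60, noise 5% of the plateau) the
        median relative error of both parameters is < 5% and the estimator
        bias < 2%."""
        L_true, tau_true = 314.0, 5.6
        t = np.linspace(1.0, 30.0, 60)
        ests = []
        for seed in range(200):
            data = generate_kinetic_series((L_true, tau_true, 1.0), t,
                                           noise_sigma_um=0.05 * L_true,
                                           seed=seed)
            fit = fit_monoexponential(data[:, 0], data[:, 1], t0=1.0)
            ests.append((fit.L_final, fit.tau))
        ests = np.array(ests)
        rel_err = np.abs(ests / [L_true, tau_true] - 1)
        assert np.median(rel_err, axis=0).max() < 0.05
        bias = np.abs(ests.mean(axis=0) / [L_true, tau_true] - 1)
        assert bias.max() < 0.02

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 data points"):
            fit_monoexponential([1, 2], [0, 1])
        with pytest.raises(ValueError, match="t0"):
            fit_monoexponential([0.0, 2, 3, 4], [0, 1, 2, 3], t0=1.0)


class TestLineTensionFit:
    def test_published_points_give_86_um(self):
        """The three measured final contour-length changes yield an
        amplitude of 86 +- 9 um at T = 0 degC with TC = 37 degC."""
        fit = fit_line_tension([24, 29, 32], [188.0, 314.0, 706.3], TC=37.0)
        assert abs(fit.A - 86.0) <= 9.0
        assert fit.A == pytest.approx(85.6, abs=0.1)  # closed form

    def test_single_point_exact(self):
        fit = fit_line_tension([24.0], [100.0], TC=37.0)
        assert fit.A == pytest.approx(100.0 * 13.0 / 37.0, rel=1e-12)
        assert fit.residuals[0] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_inversion(self):
        T = np.array([17.0, 27.0, 32.0])
        L = line_tension_model(T, A=50.0, TC=37.0)
        assert L == pytest.approx([92.5, 185.0, 370.0])
        fit = fit_line_tension(T, L, TC=37.0)
        assert fit.A == pytest.approx(50.0, rel=1e-12)

    def test_closed_form_equals_iterative_least_squares(self):
        """Closed-form amplitude agrees with an iterative nonlinear
        least-squares solver to 1e-10 relative."""
        from scipy.optimize import curve_fit
        rng = np.random.default_rng(0)
        T = np.array([5.0, 14.0, 22.0, 28.0, 33.0])
        L = line_tension_model(T, A=120.0, TC=37.0) + rng.normal(0, 10, T.size)
        fit = fit_line_tension(T, L, TC=37.0)
        popt, _ = curve_fit(lambda TT, A: line_tension_model(TT, A, 37.0),
                            T, L, p0=[50.0])
        assert fit.A == pytest.approx(popt[0], rel=1e-10)

    def test_weighted_mode(self):
        T = [24.0, 29.0, 32.0]
        L = [188.0, 314.0, 706.3]
        unweighted = fit_line_tension(T, L)
        weighted = fit_line_tension(T, L, weights=[1 / 16.0, 1 / 2.25, 1 / 6.25])
        assert weighted.weighted and not unweighted.weighted
        assert weighted.A != pytest.approx(unweighted.A, rel=1e-3)

    def test_temperature_at_or_above_tc_rejected(self):
        with pytest.raises(ValueError, match="TC"):
            fit_line_tension([24.0, 38.0], [100.0, 200.0], TC=37.0)

    def test_fitted_curve_strictly_increasing_below_tc(self):
        fit = fit_line_tension([24, 29, 32], [188.0, 314.0, 706.3], TC=37.0)
        T = np.linspace(0, 36.5, 200)
        pred = fit.predict(T)
        assert np.all(np.diff(pred) > 0)


class TestEnergyRatio:
    def test_published_worked_example_rounds_to_six(self):
        ratio = energy_ratio(EnergyRatioInputs())
        assert round(ratio) == 6
        assert ratio == pytest.approx(6.15, abs=0.01)

    def test_self_ratio_is_exactly_one(self):
        T = 300.0
        x = 1e-21 / (BOLTZMANN_J_PER_K * T)
        inputs = EnergyRatioInputs(line_tension_pN=1.0, elongation_nm=1.0,
                                   transfer_energy_kBT=x, temperature_K=T)
        assert energy_ratio(inputs) == pytest.approx(1.0, rel=1e-12)

    def test_doubled_line_tension_halves_ratio(self):
        base = energy_ratio(EnergyRatioInputs())
        doubled = energy_ratio(EnergyRatioInputs(line_tension_pN=2.0))
        assert doubled == pytest.approx(base / 2, rel=1e-12)
        assert doubled == pytest.approx(3.08, abs=0.01)

    def test_linear_in_transfer_energy_inverse_in_elongation(self):
        base = energy_ratio(EnergyRatioInputs())
        assert energy_ratio(EnergyRatioInputs(transfer_energy_kBT=3.0)) == \
            pytest.approx(2 * base, rel=1e-12)
        assert energy_ratio(EnergyRatioInputs(elongation_nm=2.0)) == \
            pytest.approx(base / 2, rel=1e-12)

    @pytest.mark.parametrize("kw", [
        {"line_tension_pN": 0.0}, {"elongation_nm": -1.0},
        {"transfer_energy_kBT": 0.0}, {"temperature_K": -5.0},
    ])
    def test_nonpositive_inputs_rejected(self, kw):
        with pytest.raises(ValueError):
            EnergyRatioInputs(**kw)


class TestPropertyBased:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(A=st.floats(1.0, 1e3), TC=st.floats(35.0, 60.0),
           temps=st.lists(st.floats(0.0, 33.0), min_size=1, max_size=6,
                          unique=True))
    def test_line_tension_fit_inverts_its_own_model(self, A, TC, temps):
        """Fitting noiseless model output recovers the amplitude exactly
        for any admissible amplitude, TC and temperature set."""
        L = line_tension_model(np.array(temps), A, TC)
        fit = fit_line_tension(temps, L, TC=TC)
        assert fit.A == pytest.approx(A, rel=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(gamma=st.floats(0.1, 10.0), ell=st.floats(0.1, 10.0),
           e=st.floats(0.1, 10.0), T=st.floats(250.0, 330.0))
    def test_energy_ratio_scaling_laws(self, gamma, ell, e, T):
        """The ratio is linear in transfer energy and inversely
        proportional to line tension x elongation."""
        base = energy_ratio(EnergyRatioInputs(gamma, ell, e, T))
        assert energy_ratio(EnergyRatioInputs(2 * gamma, ell, e, T)) == \
            pytest.approx(base / 2, rel=1e-12)
        assert energy_ratio(EnergyRatioInputs(gamma, ell, 2 * e, T)) == \
            pytest.approx(2 * base, rel=1e-12)
        assert energy_ratio(EnergyRatioInputs(gamma, 2 * ell, e, T)) == \
            pytest.approx(base / 2, rel=1e-12)


class TestModelFunctions:
    def test_monoexponential_is_zero_before_t0(self):
        assert monoexponential(np.array([0.0, 0.5, 1.0]), 100, 5, 1.0) == \
            pytest.approx([0.0, 0.0, 0.0])

    def test_line_tension_model_diverges_toward_tc(self):
        vals = line_tension_model(np.array([0.0, 30.0, 36.0]), A=86.0, TC=37.0)
        assert vals[0] == pytest.approx(86.0)
        assert np.all(np.diff(vals) > 0)
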