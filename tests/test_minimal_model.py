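import numpy as np
import pytest

from ivgttkit.cohort import insulin_curve
from ivgttkit.minimal_model import (
    FitConfig,
    MinimalModelParams,
    PiecewiseLinearForcing,
    fit_minimal_model,
    insulin_forcing,
    simulate_minimal_model,
    simulate_piecewise_linear,
)
from ivgttkit.types import Genotype, IVGTTCurve, Treatment, ValidationError

from conftest import SCHEDULE, make_synthetic_curve


class TestInsulinForcing:
    def test_linear_midpoint(self):
        f = insulin_forcing([0.0, 1.0], [180.0, 900.0])
        assert f(0.5) == pytest.approx(540.0)

    def test_hold_extrapolation_beyond_last_sample(self):
        f = insulin_forcing(SCHEDULE, [180, 900, 400, 250, 200, 190])
        assert f(60.0) == f(50.0) == 190.0

    def test_exact_at_nodes(self):
        vals = [180.0, 900.0, 400.0, 250.0, 200.0, 190.0]
        f = insulin_forcing(SCHEDULE, vals)
        np.testing.assert_array_equal(f(SCHEDULE), vals)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValidationError):
            insulin_forcing([0.0], [180.0])


class TestSimulator:
    def test_initial_condition_exact(self):
        p = MinimalModelParams(p1=0.05, p2=0.05, p3=1e-5, G0=21.0, G_b=8.0, I_b=150.0)
        f = insulin_forcing([0, 50], [150.0, 150.0])
        g = simulate_minimal_model(p, f, [0.0, 10.0])
        assert g[0] == 21.0

    def test_closed_form_single_point(self):
        # p3 = 0 reduces to G(t) = G_b + (G0-G_b) e^{-p1 t}; 8 + 12 e^{-0.6}
        p = MinimalModelParams(p1=0.06, p2=0.05, p3=0.0, G0=20.0, G_b=8.0, I_b=180.0)
        f = insulin_forcing([0, 50], [180.0, 180.0])
        g = simulate_minimal_model(p, f, [10.0])
        assert g[0] == pytest.approx(8 + 12 * np.exp(-0.6), rel=1e-7)

    @pytest.mark.parametrize("p1", [0.003, 0.012, 0.037, 0.060, 0.065, 0.2])
    def test_closed_form_agreement_across_grid(self, p1):
        """With p3 = 0 the simulator matches the mono-exponential solution."""
        p = MinimalModelParams(p1=p1, p2=0.05, p3=0.0, G0=20.0, G_b=8.0, I_b=180.0)
        f = insulin_forcing(SCHEDULE, [180.0] * 6)
        t = SCHEDULE
        exact = 8.0 + 12.0 * np.exp(-p1 * t)
        got = simulate_minimal_model(p, f, t)
        np.testing.assert_allclose(got, exact, rtol=1e-7)

    def test_fine_grid_euler_oracle(self):
        """Full model agrees with an independent fixed-step Euler integration."""
        p = MinimalModelParams(p1=0.06, p2=0.05, p3=2e-5, G0=20.0, G_b=8.0, I_b=180.0)
        pulse = insulin_curve(180.0, Treatment.VEHICLE, pulse_A=400.0, pulse_tp=1.0)
        eval_t = np.array([5.0, 10.0, 20.0, 50.0])

        dt = 1e-4
        n = int(round(50.0 / dt))
        ts = np.arange(n) * dt
        ins = np.asarray(pulse(ts)) - 180.0
        G, X = 20.0, 0.0
        targets = {round(t / dt): t for t in eval_t}
        euler = {}
        for j in range(n):
            dG = -(p.p1 + X) * G + p.p1 * p.G_b
            dX = -p.p2 * X + p.p3 * ins[j]
            G += dt * dG
            X += dt * dX
            if (j + 1) in targets:
                euler[targets[j + 1]] = G

        got = simulate_minimal_model(p, pulse, eval_t)
        oracle = np.array([euler[t] for t in eval_t])
        np.testing.assert_allclose(got, oracle, rtol=1e-4)

    def test_fast_kernel_matches_adaptive_reference(self):
        p = MinimalModelParams(p1=0.06, p2=0.05, p3=7.25e-6, G0=19.9, G_b=7.9, I_b=183.0)
        f = PiecewiseLinearForcing(SCHEDULE, [183, 592, 230, 190, 184, 183])
        ref = simulate_minimal_model(p, f, SCHEDULE)
        fast = simulate_piecewise_linear(p, f, SCHEDULE)
        np.testing.assert_allclose(fast, ref, rtol=1e-6)

    def test_increasing_p1_never_increases_suprabasal_glucose(self):
        """Monotone effect of glucose effectiveness on a parameter grid.

        Higher p1 pulls glucose toward basal faster, so suprabasal glucose
        can only fall; once insulin action drives glucose below baseline,
        higher p1 instead restores it toward basal, so the comparison is
        restricted to the suprabasal regime.
        """
        f = PiecewiseLinearForcing(SCHEDULE, [183, 592, 230, 190, 184, 183])
        t = np.array([1.0, 5.0, 10.0, 20.0, 50.0])
        for p3 in (0.0, 1e-5, 1e-4):
            prev = None
            for p1 in (0.005, 0.02, 0.06, 0.1, 0.2):
                p = MinimalModelParams(p1=p1, p2=0.05, p3=p3, G0=20.0, G_b=8.0, I_b=183.0)
                g = np.asarray(simulate_piecewise_linear(p, f, t))
                if prev is not None:
                    above = (g >= 8.0) & (prev >= 8.0)
                    assert np.all(g[above] <= prev[above] + 1e-10)
                prev = g

    def test_params_invariants_enforced(self):
        with pytest.raises(ValidationError):
            MinimalModelParams(p1=-0.01, p2=0.05, p3=0.0, G0=20, G_b=8, I_b=180)
        with pytest.raises(ValidationError):
            MinimalModelParams(p1=0.06, p2=0.05, p3=0.0, G0=5, G_b=8, I_b=180)


class TestFit:
    def test_round_trip_wildtype_means(self):
        """Noise-free data at wildtype group means: S_G and S_I to < 1 %."""
        curve = make_synthetic_curve(s_g=0.060, s_i=1.45e-4)
        fit = fit_minimal_model(curve)
        assert fit.converged
        assert fit.s_g == pytest.approx(0.060, rel=0.01)
        assert fit.s_i * 1e4 == pytest.approx(1.45, rel=0.01)

    def test_round_trip_glp1r_ko_mean_sg(self):
        curve = make_synthetic_curve(s_g=0.037, s_i=0.94e-4)
        fit = fit_minimal_model(curve)
        assert fit.s_g == pytest.approx(0.037, rel=0.01)

    @pytest.mark.parametrize("s_g", [0.003, 0.012, 0.037, 0.060, 0.065])
    @pytest.mark.parametrize("fix_p2", [0.05, None])
    def test_round_trip_identifiability_across_sg_span(self, s_g, fix_p2):
        """(S_G, S_I, G0) recovered to < 1 % on noise-free 6-point data,
        with p2 fixed or freely estimated."""
        curve = make_synthetic_curve(s_g=s_g, s_i=1.0e-4, g0=19.9)
        fit = fit_minimal_model(curve, FitConfig(fix_p2=fix_p2))
        assert fit.s_g == pytest.approx(s_g, rel=0.01)
        assert fit.s_i == pytest.approx(1.0e-4, rel=0.01)
        assert fit.params.G0 == pytest.approx(19.9, rel=0.01)

    def test_monoexponential_constant_insulin_recovers_rate(self):
        """Pure exponential decay with flat insulin: p1 = k, S_I flagged."""
        k = 0.045
        t = SCHEDULE
        glucose = 8.0 + 12.0 * np.exp(-k * t)
        glucose[0] = 8.0
        curve = IVGTTCurve("flat", Genotype.WT, Treatment.VEHICLE, t, glucose, [183.0] * 6)
        fit = fit_minimal_model(curve)
        assert fit.s_g == pytest.approx(k, rel=0.01)
        assert not fit.si_identifiable

    def test_fit_is_deterministic(self, wildtype_curve):
        a = fit_minimal_model(wildtype_curve)
        b = fit_minimal_model(wildtype_curve)
        assert a.params == b.params
        assert a.weighted_ssr == b.weighted_ssr

    def test_too_few_post_samples_rejected(self):
        curve = IVGTTCurve("short", Genotype.WT, Treatment.VEHICLE,
                           [0, 1, 5, 10], [8, 20, 16, 13], [180, 600, 300, 220])
        with pytest.raises(ValidationError, match="'short'"):
            fit_minimal_model(curve)

    def test_noise_robustness_median_sg(self):
        """200 noisy replicates of one animal: median recovered S_G within
        15 % of the generating value (2 % glucose, 4 % insulin CV)."""
        rng = np.random.default_rng(11)
        base = make_synthetic_curve(s_g=0.060, s_i=1.45e-4)
        recovered = []
        for k in range(200):
            g = base.glucose * rng.lognormal(0.0, 0.02, size=6)
            i = base.insulin * rng.lognormal(0.0, 0.04, size=6)
            curve = IVGTTCurve(f"rep{k}", Genotype.WT, Treatment.VEHICLE,
                               base.times, g, i)
            recovered.append(fit_minimal_model(curve).s_g)
        assert np.median(recovered) == pytest.approx(0.060, rel=0.15)
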