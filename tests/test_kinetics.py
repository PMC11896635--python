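import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinhop import (
    einstein_rate,
    extrapolate_to_unit_alpha,
    fit_decay,
    fit_growth,
    rate_from_lifetime,
    triplet_quantum_yield,
)
from spinhop.kinetics import FitError


class TestGrowthFit:
    def test_noise_free_recovery(self):
        t = np.linspace(0.0, 200.0, 400)
        y = 0.8 * (1.0 - np.exp(-(t - 5.0) / 30.0))
        y = np.clip(y, 0.0, 1.0)
        fit = fit_growth((t[t >= 5.0], y[t >= 5.0]), None)
        assert fit.tau_fs == pytest.approx(30.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.8, rel=1e-6)
        assert fit.shift_fs == pytest.approx(5.0, abs=1e-4)

    def test_noisy_recovery_within_ten_percent(self):
        """Median recovered tau over 100 noisy repeats is within 10%."""
        rng = np.random.default_rng(4)
        t = np.linspace(0.0, 200.0, 400)
        clean = 0.8 * (1.0 - np.exp(-t / 30.0))
        taus = []
        for _ in range(100):
            y = np.clip(clean + rng.normal(0, 0.02, t.shape), 0, 1)
            taus.append(fit_growth((t, y), None).tau_fs)
        assert np.median(taus) == pytest.approx(30.0, rel=0.10)

    def test_constant_series_raises(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(FitError):
            fit_growth((t, np.zeros_like(t)), None)


class TestDecayFit:
    def test_noise_free_recovery(self):
        t = np.linspace(0.0, 200.0, 400)
        y = 1.0 * np.exp(-t / 26.3)
        fit = fit_decay((t, y), None)
        assert fit.tau_fs == pytest.approx(26.3, rel=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-8)

    def test_offset_does_not_bias_tau(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0.0, 300.0, 400)
        clean = 0.2 + 0.7 * np.exp(-t / 40.0)
        taus = []
        for _ in range(100):
            y = np.clip(clean + rng.normal(0, 0.02, t.shape), 0, 1)
            taus.append(fit_decay((t, y), None).tau_fs)
        assert np.median(taus) == pytest.approx(40.0, rel=0.10)

    def test_short_series_rejected(self):
        with pytest.raises(FitError):
            fit_decay((np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.5, 0.2])), None)


class TestLogLinearRate:
    def test_recovers_pure_exponential(self):
        from spinhop import fit_rate_loglinear
        t = np.linspace(0.0, 300.0, 601)
        y = 0.9 * np.exp(-t / 85.0)
        fit = fit_rate_loglinear((t, y), None)
        assert fit.tau_fs == pytest.approx(85.0, rel=1e-10)

    def test_window_and_skip_respected(self):
        from spinhop import fit_rate_loglinear
        t = np.linspace(0.0, 400.0, 801)
        # transient then clean exponential
        y = np.where(t < 40, 0.95, 0.9 * np.exp(-(t - 40) / 60.0))
        y = np.clip(y, 1e-12, 1)
        fit = fit_rate_loglinear((t, y), None, t_max_fs=400.0, skip_fraction=0.25)
        assert fit.tau_fs == pytest.approx(60.0, rel=1e-6)

    def test_non_decaying_series_rejected(self):
        from spinhop import fit_rate_loglinear
        from spinhop.kinetics import FitError
        t = np.linspace(0.0, 100.0, 201)
        with pytest.raises(FitError):
            fit_rate_loglinear((t, np.full_like(t, 0.5)), None)


class TestExtrapolation:
    @pytest.mark.parametrize(
        "taus, expected_ps",
        [
            ((441.66, 28.44, 12.44), 6.06),
            ((179.1, 26.3, 8.8), 1.73),
            ((232.8, 27.9, 13.2), 1.93),
        ],
    )
    def test_reference_lifetime_triples(self, taus, expected_ps):
        """Free-slope log-log extrapolation reproduces the published tau_1."""
        res = extrapolate_to_unit_alpha([2.0, 3.5, 5.0], taus)
        assert res.tau1_fs / 1000.0 == pytest.approx(expected_ps, abs=0.01)

    def test_exact_alpha_squared_law(self):
        alphas = np.array([2.0, 3.5, 5.0])
        res = extrapolate_to_unit_alpha(alphas, 100.0 * alphas**-2.0)
        assert res.tau1_fs == pytest.approx(100.0, rel=1e-10)
        assert res.slope == pytest.approx(-2.0, abs=1e-10)

    def test_log_base_invariance(self):
        """Natural-log fit gives the same tau1 as the base-10 fit."""
        alphas = np.array([2.0, 3.5, 5.0])
        taus = np.array([441.66, 28.44, 12.44])
        res = extrapolate_to_unit_alpha(alphas, taus)
        slope_n, inter_n = np.polyfit(np.log(alphas), np.log(taus), 1)
        assert np.exp(inter_n) == pytest.approx(res.tau1_fs, rel=1e-12)

    def test_roundtrip_through_fitted_line(self):
        res = extrapolate_to_unit_alpha([2.0, 3.5, 5.0], [441.66, 28.44, 12.44])
        # the fitted line evaluated back at the inputs stays within the
        # scatter of the inputs around the line
        for a, tau in zip(res.alphas_used, res.taus_used_fs):
            assert res.tau_at(a) == pytest.approx(tau, rel=0.65)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            extrapolate_to_unit_alpha([2.0], [10.0])
        with pytest.raises(ValueError):
            extrapolate_to_unit_alpha([2.0, 2.0], [10.0, 5.0])
        with pytest.raises(ValueError):
            extrapolate_to_unit_alpha([0.5, 2.0], [10.0, 5.0])


class TestRates:
    def test_one_nanosecond(self):
        assert rate_from_lifetime(1e6) == pytest.approx(1e9)

    def test_inverse_of_extrapolated_lifetime(self):
        # 6.06 ps -> 1.650e11 s^-1 (the strict inverse)
        assert rate_from_lifetime(6060.0) == pytest.approx(1.650e11, rel=1e-3)

    def test_monotone_decreasing(self):
        assert rate_from_lifetime(10.0) > rate_from_lifetime(20.0)

    def test_einstein_rate_reference_value(self):
        """Closed-form CODATA evaluation at E_F = 2.56 eV, f = 0.58."""
        assert einstein_rate(2.56, 0.58) == pytest.approx(1.649e8, rel=5e-4)

    def test_einstein_rate_scaling_laws(self):
        base = einstein_rate(2.0, 0.3)
        assert einstein_rate(4.0, 0.3) == pytest.approx(4 * base, rel=1e-12)
        assert einstein_rate(2.0, 0.6) == pytest.approx(2 * base, rel=1e-12)
        assert einstein_rate(2.0, 0.0) == 0.0

    def test_einstein_rate_rejects_negative_f(self):
        with pytest.raises(ValueError):
            einstein_rate(2.0, -0.1)


class TestTripletYield:
    def test_limits_and_arithmetic(self):
        assert triplet_quantum_yield(5.0, 0.0, 0.0) == 1.0
        assert triplet_quantum_yield(1.0, 1.0, 1.0) == pytest.approx(1.0 / 3.0)
        assert triplet_quantum_yield(4.0, 1.0, 0.0) == pytest.approx(0.8)

    @settings(deadline=None, derandomize=True)
    @given(
        k=st.tuples(*[st.floats(1e-3, 1e3)] * 3),
        scale=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, k, scale):
        a = triplet_quantum_yield(*k)
        b = triplet_quantum_yield(*(scale * x for x in k))
        assert a == pytest.approx(b, rel=1e-9)
        assert 0.0 <= a <= 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            triplet_quantum_yield(0.0, 0.0, 0.0)
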