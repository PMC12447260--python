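"""ADC/kurtosis representation, the exchange-time model and the
kurtosis-peak (radius/fraction) analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from steamdiff import (
    CONTROL_PRESET,
    ExchangeKurtosisParams,
    KurtosisPoint,
    exchange_rate_from_tau,
    find_kurtosis_peak,
    fit_adc_kurtosis,
    fit_kurtosis_exchange,
    kurtosis_exchange_model,
    kurtosis_series,
    lee_fraction,
    lee_radius,
)

B_NONZERO = np.linspace(0.8333, 5.0, 6)


def cumulant_signal(b, s0, d, k):
    return s0 * np.exp(-b * d + b**2 * d**2 * k / 6.0)


class TestAdcKurtosisFit:
    def test_self_consistency(self):
        """Signals generated by the cumulant form are recovered exactly."""
        s = cumulant_signal(B_NONZERO, 2.0, 1.0, 0.8)
        pt = fit_adc_kurtosis(s, B_NONZERO)
        assert pt.adc == pytest.approx(1.0, rel=1e-10)
        assert pt.kurtosis == pytest.approx(0.8, rel=1e-8)
        assert pt.s0_fit == pytest.approx(2.0, rel=1e-10)

    def test_zero_kurtosis_log_linear(self):
        s = cumulant_signal(B_NONZERO, 1.0, 0.7, 0.0)
        pt = fit_adc_kurtosis(s, B_NONZERO)
        assert pt.kurtosis == pytest.approx(0.0, abs=1e-10)

    def test_b0_rows_ignored(self):
        b = np.concatenate([[0.0], B_NONZERO])
        s = np.concatenate([[0.5], cumulant_signal(B_NONZERO, 2.0, 1.0, 0.5)])
        pt = fit_adc_kurtosis(s, b)  # corrupted b0 must not perturb the fit
        assert pt.adc == pytest.approx(1.0, rel=1e-10)

    def test_needs_three_distinct_b(self):
        with pytest.raises(ValueError):
            fit_adc_kurtosis(np.ones(2), np.array([1.0, 2.0]))

    def test_adc_decreases_with_separation(self, control_clean):
        """Two-pool signals show the measured ADC decrease with separation:
        strictly falling from Δ = 16 to 150 ms and far below the short-Δ
        value at 250 ms (the exchange plateau makes the tail only
        approximately flat, not strictly monotone)."""
        pts = kurtosis_series(control_clean)
        by_delta = {p.delta_sep: p.adc for p in pts}
        falling = [by_delta[d] for d in (16.0, 30.0, 50.0, 80.0, 150.0)]
        assert np.all(np.diff(falling) < 0)
        assert by_delta[250.0] < 0.75 * by_delta[16.0]


class TestExchangeModel:
    def test_long_time_limit(self):
        p = ExchangeKurtosisParams(k0=2.3, tau_ex=210.0, k_inf=0.4)
        assert kurtosis_exchange_model(1e9, p) == pytest.approx(0.4, abs=1e-6)

    def test_short_time_limit(self):
        p = ExchangeKurtosisParams(k0=2.3, tau_ex=210.0, k_inf=0.4)
        assert kurtosis_exchange_model(210.0 * 1e-6, p) == pytest.approx(
            2.3 + 0.4, rel=1e-5
        )

    def test_value_at_t_equal_tau(self):
        """K(τ) = 2e⁻¹·K0 + K∞."""
        p = ExchangeKurtosisParams(k0=2.3, tau_ex=210.0, k_inf=0.1)
        expected = 2.0 * np.exp(-1.0) * 2.3 + 0.1
        assert kurtosis_exchange_model(210.0, p) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(
        k0=st.floats(0.1, 5.0),
        tau=st.floats(10.0, 1000.0),
        kinf=st.floats(-0.5, 0.5),
    )
    def test_exchange_part_positive_and_decaying_at_long_times(self, k0, tau, kinf):
        p = ExchangeKurtosisParams(k0=k0, tau_ex=tau, k_inf=kinf)
        t = np.geomspace(2.0 * tau, 100.0 * tau, 30)
        k = np.asarray(kurtosis_exchange_model(t, p)) - kinf
        assert np.all(k >= 0)
        assert np.all(np.diff(k) <= 1e-12)


class TestExchangeFit:
    def test_control_parameters_recovered(self):
        truth = ExchangeKurtosisParams(k0=2.3, tau_ex=210.0, k_inf=0.0)
        td = np.array([200.0, 250.0, 500.0, 800.0]) - 4.0 / 3.0
        pts = [
            KurtosisPoint(delta_sep=d + 4.0 / 3.0, t_d=d, adc=0.3,
                          kurtosis=float(kurtosis_exchange_model(d, truth)),
                          s0_fit=1.0)
            for d in td
        ]
        fit = fit_kurtosis_exchange(pts)
        assert fit.tau_ex == pytest.approx(210.0, rel=1e-4)
        assert fit.k0 == pytest.approx(2.3, rel=1e-4)
        assert fit.k_inf == pytest.approx(0.0, abs=1e-6)

    def test_apoptotic_parameters_recovered(self):
        truth = ExchangeKurtosisParams(k0=1.2, tau_ex=130.0, k_inf=0.1)
        td = np.array([198.667, 248.667, 498.667, 798.667])
        pts = [
            KurtosisPoint(delta_sep=d, t_d=d, adc=0.3,
                          kurtosis=float(kurtosis_exchange_model(d, truth)),
                          s0_fit=1.0)
            for d in td
        ]
        fit = fit_kurtosis_exchange(pts)
        assert fit.tau_ex == pytest.approx(130.0, rel=1e-3)
        assert fit.k0 == pytest.approx(1.2, rel=1e-3)

    def test_flat_series_gives_zero_amplitude(self):
        pts = [
            KurtosisPoint(delta_sep=d, t_d=d, adc=0.3, kurtosis=0.9, s0_fit=1.0)
            for d in (200.0, 250.0, 500.0, 800.0)
        ]
        fit = fit_kurtosis_exchange(pts)
        assert fit.k0 * 2.0 * fit.tau_ex / 800.0 == pytest.approx(0.0, abs=1e-3)
        assert fit.k_inf == pytest.approx(0.9, abs=1e-3)

    def test_too_few_points(self):
        pts = [
            KurtosisPoint(delta_sep=d, t_d=d, adc=0.3, kurtosis=1.0, s0_fit=1.0)
            for d in (500.0, 800.0)
        ]
        with pytest.raises(ValueError):
            fit_kurtosis_exchange(pts, use="all")

    def test_bridge_to_two_pool_exchange_rate(self, control_clean):
        """Total rate from the kurtosis-time fit of two-pool signals agrees
        with the generator's k_IE + k_EI to within a factor of ~2–3."""
        pts = kurtosis_series(control_clean)
        fit = fit_kurtosis_exchange(pts)
        rate_kurt = exchange_rate_from_tau(fit.tau_ex)
        p = CONTROL_PRESET.params
        rate_gen = p.k_ie + p.k_ei
        ratio = rate_gen / rate_kurt
        assert 1.0 / 3.0 < ratio < 3.0


class TestRateInversion:
    @pytest.mark.parametrize(
        "tau, rate, rounded", [(130.0, 7.692, 8), (210.0, 4.762, 5)]
    )
    def test_printed_rates(self, tau, rate, rounded):
        got = exchange_rate_from_tau(tau)
        assert got == pytest.approx(rate, abs=5e-3)
        assert round(got) == rounded

    def test_infinite_tau(self):
        assert exchange_rate_from_tau(1e12) == pytest.approx(0.0, abs=1e-9)


class TestLeeAnalysis:
    def test_fraction_values(self):
        assert lee_fraction(2.3) == pytest.approx(2.3 / 5.3, rel=1e-12)
        assert round(lee_fraction(2.3), 2) == 0.43
        assert lee_fraction(0.0) == 0.0
        assert lee_fraction(1.2) == pytest.approx(0.285714, rel=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(f=st.floats(0.0, 0.99))
    def test_fraction_inverse_identity(self, f):
        assert lee_fraction(3.0 * f / (1.0 - f)) == pytest.approx(f, abs=1e-12)

    def test_radius_chain(self):
        """t_peak=150, τ=210, f from K0=2.3, D_I=1.7 give r ≈ 8.46 μm
        (the arithmetic chain; see the methods note on the discrepancy with
        larger published round-offs)."""
        f = lee_fraction(2.3)
        res = lee_radius(t_peak=150.0, tau_ex=210.0, f=f, d_i=1.7)
        t_r = 210.0 / (1.0 - f)
        t_c = (5.0 * 150.0 / 6.0) ** 2 / t_r
        assert res.t_r == pytest.approx(t_r, rel=1e-12)
        assert res.t_c == pytest.approx(t_c, rel=1e-12)
        assert res.radius == pytest.approx(np.sqrt(t_c * 1.7), rel=1e-12)
        assert res.radius == pytest.approx(8.46, abs=0.01)

    def test_zero_fraction_residence_equals_tau(self):
        res = lee_radius(t_peak=100.0, tau_ex=210.0, f=0.0, d_i=1.7)
        assert res.t_r == 210.0

    def test_peak_time_scaling(self):
        a = lee_radius(t_peak=100.0, tau_ex=210.0, f=0.4, d_i=1.7)
        b = lee_radius(t_peak=200.0, tau_ex=210.0, f=0.4, d_i=1.7)
        assert b.t_c == pytest.approx(4.0 * a.t_c, rel=1e-12)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            lee_radius(t_peak=150.0, tau_ex=210.0, f=1.0, d_i=1.7)


class TestPeakFinding:
    @staticmethod
    def series(deltas, kurt):
        return [
            KurtosisPoint(delta_sep=d, t_d=d - 4.0 / 3.0, adc=0.3,
                          kurtosis=k, s0_fit=1.0)
            for d, k in zip(deltas, kurt)
        ]

    def test_interior_maximum_on_grid(self):
        deltas = (16.0, 80.0, 150.0, 250.0, 800.0)
        pts = self.series(deltas, (0.5, 1.5, 2.0, 1.8, 1.0))
        t_peak, boundary = find_kurtosis_peak(pts)
        assert t_peak == 150.0 and not boundary

    def test_monotone_series_flags_boundary(self):
        pts = self.series((16.0, 150.0, 800.0), (0.1, 0.5, 0.9))
        with pytest.warns(UserWarning, match="monotone"):
            t_peak, boundary = find_kurtosis_peak(pts)
        assert boundary and t_peak == 800.0

    def test_control_preset_peak_is_interior(self, control_clean):
        """Two-pool control signals peak at a mid-grid separation."""
        pts = kurtosis_series(control_clean)
        t_peak, boundary = find_kurtosis_peak(pts)
        assert not boundary
        assert 16.0 < t_peak < 800.0
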