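"""Two-pool fitting: recovery, χ² metric, contour intervals, relaxometry."""

import numpy as np
import pytest

from steamdiff import (
    APOPTOTIC_PRESET,
    CONTROL_PRESET,
    CpmgT2,
    InversionRecoveryT1,
    NoiseSpec,
    RelaxometrySeries,
    TwoPoolExchangeRegressor,
    TwoPoolParams,
    contour_interval,
    fit_cpmg_t2,
    fit_ir_t1,
    fit_two_pool,
    generate_dataset,
    reduced_chi2,
)
from steamdiff.fitting import chi2_threshold, profile_contour


class TestReducedChi2:
    def test_zero_residuals(self):
        assert reduced_chi2(np.zeros(10), np.ones(10), 3) == 0.0

    def test_residuals_equal_sigma(self):
        # each standardized residual is 1: χ²_red = N/(N − n_free)
        sigma = np.linspace(0.5, 2.0, 12)
        assert reduced_chi2(sigma, sigma, 4) == pytest.approx(12 / 8)

    def test_requires_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            reduced_chi2(np.ones(3), np.ones(3), 3)


class TestTwoPoolRecovery:
    def test_noiseless_control_recovery(self, control_clean):
        res = fit_two_pool(control_clean, n_starts=8, seed=1)
        p = res.params
        assert p.m_i0 == pytest.approx(0.55, rel=1e-2)
        assert p.r == pytest.approx(4.2, rel=1e-2)
        assert p.k_ie == pytest.approx(4.0, rel=1e-2)
        assert p.d_e_app == pytest.approx(0.95, rel=1e-2)
        assert p.r1_e == pytest.approx(2.9, rel=1e-2)
        assert res.chi2_reduced < 1e-12
        assert res.fixed == {"d_i": 1.7}

    def test_noiseless_apoptotic_recovery(self, apoptotic_clean):
        res = fit_two_pool(apoptotic_clean, n_starts=8, seed=1)
        p = res.params
        assert p.m_i0 == pytest.approx(0.32, rel=1e-2)
        assert p.r == pytest.approx(3.6, rel=1e-2)
        assert p.k_ie == pytest.approx(6.0, rel=1e-2)

    def test_b0_points_excluded(self, control_clean):
        res = fit_two_pool(control_clean, n_starts=4, seed=0)
        n_nonzero = int((control_clean.protocol.b > 0).sum())
        assert res.n_points == n_nonzero

    def test_scale_invariance(self, control_clean):
        """Rescaling signal and σ together scales s0 only."""
        from dataclasses import replace as drep

        scaled = generate_dataset(
            CONTROL_PRESET, control_clean.protocol, NoiseSpec(snr=np.inf),
            params=CONTROL_PRESET.params.replace(s0=100.0),
        )
        res0 = fit_two_pool(control_clean, n_starts=6, seed=2)
        res1 = fit_two_pool(scaled, n_starts=6, seed=2)
        assert res1.params.s0 == pytest.approx(100.0 * res0.params.s0, rel=1e-4)
        assert res1.params.m_i0 == pytest.approx(res0.params.m_i0, rel=1e-4)
        assert res1.params.r == pytest.approx(res0.params.r, rel=1e-4)

    def test_best_start_wins(self, control_clean):
        res = fit_two_pool(control_clean, n_starts=8, seed=1)
        finite = [o for o in res.start_objectives if np.isfinite(o)]
        assert res.objective <= min(finite) + 1e-9

    def test_single_pool_data_flags_unidentifiable_exchange(self, protocol):
        """Data from an m_i0 = 1 generator leaves exchange unidentifiable:
        some parameter is pinned at a bound and flagged."""
        single = TwoPoolParams(r=4.2, k_ie=4.0, m_i0=1.0, r1_e=0.0)
        with pytest.warns(UserWarning, match="exchange is disabled"):
            ds = generate_dataset(CONTROL_PRESET, protocol, NoiseSpec(snr=np.inf),
                                  params=single)
        res = fit_two_pool(ds, n_starts=8, seed=3)
        assert any(name in res.at_bounds for name in ("k_ie", "m_i0", "r1_i"))

    def test_estimator_sklearn_contract(self, control_clean):
        from sklearn.base import clone

        est = TwoPoolExchangeRegressor(n_starts=4, random_state=0)
        est2 = clone(est)
        assert est2.get_params()["n_starts"] == 4
        est2.set_params(n_starts=6)
        assert est2.n_starts == 6
        est.fit_dataset(control_clean)
        X = np.column_stack([
            control_clean.protocol.b,
            control_clean.protocol.delta_sep,
            [p.delta_pulse for p in control_clean.protocol],
        ])
        pred = est.predict(X)
        nz = control_clean.nonzero_b
        assert np.allclose(pred[nz], control_clean.signal[nz], rtol=1e-6)


class TestContourIntervals:
    def test_linear_model_matches_analytic_ellipse(self):
        """On a weighted linear model the marched contour must agree with the
        closed-form F-based confidence ellipse to < 1%."""
        rng = np.random.default_rng(0)
        n, sigma = 30, 0.1
        x = np.linspace(0, 1, n)
        A = np.column_stack([np.ones(n), x])
        y = 1.0 + 2.0 * x + rng.normal(0, sigma, n)
        beta = np.linalg.lstsq(A / sigma, y / sigma, rcond=None)[0]
        rss0 = float(np.sum(((y - A @ beta) / sigma) ** 2))
        nP = 2
        chi0 = rss0 / (n - nP)

        def constrained(b0, b1):
            return float(np.sum(((y - A @ [b0, b1]) / sigma) ** 2)) / (n - nP)

        thr = chi2_threshold(chi0, nP, n, 0.68)
        trace, n_open = profile_contour(
            constrained, (beta[0], beta[1]), thr, (0.1, 0.1),
            ((-10, 10), (-10, 10)), n_directions=64, tol=1e-5,
        )
        assert n_open == 0
        from scipy import stats

        rhs = rss0 * nP * stats.f.ppf(0.68, nP, n - nP) / (n - nP)
        M = (A.T @ A) / sigma**2
        half_widths = np.sqrt(np.diag(np.linalg.inv(M) * rhs))
        got = [trace[:, 0].max() - beta[0], trace[:, 1].max() - beta[1]]
        assert got[0] == pytest.approx(half_widths[0], rel=1e-2)
        assert got[1] == pytest.approx(half_widths[1], rel=1e-2)

    def test_noiseless_interval_collapses(self, protocol):
        ds = generate_dataset(CONTROL_PRESET, protocol, NoiseSpec(snr=np.inf))
        ds.sigma[:] = 1e-6
        res = fit_two_pool(ds, fixed={"d_i": 1.7, "r1_i": 0.0}, n_starts=6, seed=3)
        c = contour_interval(res, ds, ("m_i0", "k_ie"), confidence=0.68,
                             n_directions=8)
        assert c.intervals["m_i0"][1] - c.intervals["m_i0"][0] < 1e-4
        assert c.intervals["k_ie"][1] - c.intervals["k_ie"][0] < 1e-3

    def test_contour_closed_and_covers_truth(self, protocol):
        """95% (m_i0, k_ie) contour on noisy control data: closed, contains
        the generating values in most seeds (9-ish of 10 expected)."""
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            ds = generate_dataset(
                CONTROL_PRESET, protocol,
                NoiseSpec(model="gaussian", snr=50.0, seed=seed),
            )
            res = fit_two_pool(ds, fixed={"d_i": 1.7, "r1_i": 0.0},
                               n_starts=8, seed=7)
            c = contour_interval(res, ds, ("m_i0", "k_ie"), confidence=0.95,
                                 n_directions=8)
            assert not c.is_open
            inside = (
                c.intervals["m_i0"][0] <= 0.55 <= c.intervals["m_i0"][1]
                and c.intervals["k_ie"][0] <= 4.0 <= c.intervals["k_ie"][1]
            )
            hits += inside
        assert hits >= n_seeds - 2  # binomial slack at 95% coverage


class TestRelaxometry:
    @pytest.mark.parametrize("t1_true", [1540.0, 1560.0])
    def test_ir_t1_recovery(self, t1_true):
        """Noiseless magnitude IR at the five inversion times 20 ms – 8 s."""
        ti = np.array([20.0, 150.0, 1000.0, 4000.0, 8000.0])
        s = 10.0 * np.abs(1.0 - 2.0 * np.exp(-ti / t1_true))
        series = RelaxometrySeries(times=ti, signal=s)
        assert fit_ir_t1(series) == pytest.approx(t1_true, rel=1e-6)

    def test_ir_t1_degenerate_design_flagged(self):
        ti = np.array([5000.0, 6000.0, 8000.0])  # all TI >> T1
        s = np.full(3, 7.0)
        est = InversionRecoveryT1().fit(ti, s)
        assert est.flagged_
        with pytest.raises(RuntimeError, match="unidentifiable"):
            fit_ir_t1(RelaxometrySeries(times=ti, signal=s))

    @pytest.mark.parametrize("t2_true", [68.0, 78.0])
    def test_cpmg_t2_recovery(self, t2_true):
        """Noiseless CPMG, 7 ms echo spacing × 180 echoes."""
        te = 7.0 * np.arange(1, 181)
        s = 5.0 * np.exp(-te / t2_true)
        assert fit_cpmg_t2(RelaxometrySeries(te, s)) == pytest.approx(t2_true, rel=1e-8)

    def test_cpmg_constant_signal_flagged(self):
        te = 7.0 * np.arange(1, 10)
        est = CpmgT2().fit(te, np.full(9, 3.0))
        assert est.flagged_ and est.t2_ == np.inf

    def test_series_validation(self):
        with pytest.raises(ValueError):
            RelaxometrySeries(np.array([3.0, 2.0, 1.0]), np.ones(3))
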