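"""Signal-representation analyses: ADC/kurtosis per diffusion time, the
time-dependent kurtosis exchange model, and the kurtosis-peak (Lee)
radius/water-fraction analysis.

Per gradient separation the cumulant representation

    S(b) = S0 · exp(−b·D + b²·D²·K/6)

is fitted over the nonzero b-values (log-domain polynomial least squares).
Across diffusion times, transmembrane water exchange makes the kurtosis
time-dependent:

    K(t) = K0 · (2τ/t) · [1 − (τ/t)(1 − e^{−t/τ})] + K∞,

where K0 is the kurtosis amplitude participating in exchange, τ (tau_ex)
the water exchange time with 1/τ = k_IE + k_EI, and K∞ the non-exchanging
residual.  The kurtosis-peak analysis disentangles radius from exchange:
f = K0/(3+K0), t_r = τ/(1−f), t_peak = (6/5)·sqrt(t_r·t_c), t_c = r²/D_I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .protocol import SignalDataset

__all__ = [
    "KurtosisPoint",
    "ExchangeKurtosisParams",
    "LeeResult",
    "AdcKurtosisRegressor",
    "KurtosisExchangeRegressor",
    "fit_adc_kurtosis",
    "kurtosis_series",
    "kurtosis_exchange_model",
    "fit_kurtosis_exchange",
    "exchange_rate_from_tau",
    "lee_fraction",
    "lee_radius",
    "find_kurtosis_peak",
]


@dataclass(frozen=True)
class KurtosisPoint:
    """Cumulant-fit result at one gradient separation."""

    delta_sep: float  # Δ (ms)
    t_d: float        # diffusion time Δ − δ/3 (ms)
    adc: float        # μm²/ms
    kurtosis: float   # unitless
    s0_fit: float

    def __post_init__(self) -> None:
        if self.adc <= 0:
            raise ValueError("ADC must be positive")
        if not np.isfinite(self.kurtosis):
            raise ValueError("kurtosis must be finite")


@dataclass(frozen=True)
class ExchangeKurtosisParams:
    """Parameters of the time-dependent kurtosis exchange model."""

    k0: float       # exchanging kurtosis amplitude
    tau_ex: float   # water exchange time (ms)
    k_inf: float    # non-exchanging kurtosis

    def __post_init__(self) -> None:
        if self.tau_ex <= 0:
            raise ValueError("tau_ex must be positive")
        if self.k0 < 0:
            raise ValueError("k0 must be non-negative")


@dataclass(frozen=True)
class LeeResult:
    """Kurtosis-peak analysis output."""

    f: float        # intracellular water fraction
    t_r: float      # intracellular residence time (ms)
    t_c: float      # correlation time r²/D_I (ms)
    radius: float   # μm
    t_peak: float   # ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise ValueError("f must lie in [0, 1)")
        if min(self.t_r, self.t_c, self.radius, self.t_peak) <= 0:
            raise ValueError("times and radius must be positive")


class AdcKurtosisRegressor(RegressorMixin, BaseEstimator):
    """Cumulant (ADC + kurtosis) fit of ln S over nonzero b-values.

    ln S = ln S0 − b·D + b²·D²·K/6 is quadratic in b, so the fit is an
    exact polynomial least squares in the log domain; D ≡ ADC and
    K = 6·a₂/D² from the quadratic coefficient a₂.

    Attributes: ``adc_`` (μm²/ms), ``kurtosis_``, ``s0_``.
    """

    def fit(self, X, y):
        b = np.asarray(X, dtype=float).reshape(-1)
        s = np.asarray(y, dtype=float).reshape(-1)
        mask = b > 0
        b, s = b[mask], s[mask]
        if np.unique(b).size < 3:
            raise ValueError("need at least 3 distinct nonzero b-values")
        if np.any(s <= 0):
            raise ValueError("signals must be positive for the log-domain fit")
        a2, a1, a0 = np.polyfit(b, np.log(s), 2)
        adc = -a1
        if adc <= 0:
            raise RuntimeError(f"non-positive fitted ADC ({adc:.3g})")
        self.adc_ = float(adc)
        self.kurtosis_ = float(6.0 * a2 / adc**2)
        self.s0_ = float(np.exp(a0))
        return self

    def predict(self, X) -> np.ndarray:
        b = np.asarray(X, dtype=float).reshape(-1)
        return self.s0_ * np.exp(
            -b * self.adc_ + b**2 * self.adc_**2 * self.kurtosis_ / 6.0
        )


def fit_adc_kurtosis(
    signals: np.ndarray,
    b: np.ndarray,
    delta_sep: float = np.nan,
    t_d: float = np.nan,
) -> KurtosisPoint:
    """ADC and kurtosis at one gradient separation (nonzero b only)."""
    est = AdcKurtosisRegressor().fit(b, signals)
    return KurtosisPoint(
        delta_sep=float(delta_sep),
        t_d=float(t_d),
        adc=est.adc_,
        kurtosis=est.kurtosis_,
        s0_fit=est.s0_,
    )


def kurtosis_series(dataset: SignalDataset) -> list[KurtosisPoint]:
    """Per-Δ cumulant fits across a whole dataset."""
    out = []
    for delta, idx in dataset.protocol.delta_groups().items():
        idx = np.asarray(idx)
        b = dataset.protocol.b[idx]
        t_d = dataset.protocol.diffusion_times[idx[0]]
        out.append(fit_adc_kurtosis(dataset.signal[idx], b, delta_sep=delta, t_d=t_d))
    return out


def kurtosis_exchange_model(
    t: np.ndarray | float, params: ExchangeKurtosisParams
) -> np.ndarray | float:
    """K(t) = K0·(2τ/t)·[1 − (τ/t)(1 − e^{−t/τ})] + K∞.

    Limits: K → K∞ as t → ∞ and K → K0 + K∞ as t → 0⁺.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise ValueError("t must be positive")
    x = t_arr / params.tau_ex
    # (2/x)[1 − (1 − e^{−x})/x]: series for small x to dodge cancellation
    g = np.empty_like(x)
    small = x < 1e-3
    xs = x[small]
    g[small] = 1.0 - xs / 3.0 + xs**2 / 12.0 - xs**3 / 60.0
    xl = x[~small]
    g[~small] = (2.0 / xl) * (1.0 + np.expm1(-xl) / xl)
    k = params.k0 * g + params.k_inf
    return k if np.ndim(t) else float(k[0])


class KurtosisExchangeRegressor(RegressorMixin, BaseEstimator):
    """Bounded least-squares fit of the kurtosis exchange model to
    (diffusion time, kurtosis) pairs.

    Parameters
    ----------
    constrain_k_inf : bool, default False
        Require K∞ ≥ 0 (unconstrained by default).
    n_starts : int, default 8
        Randomized τ initializations across the observed time range.
    random_state : int or None
    """

    def __init__(self, constrain_k_inf: bool = False, n_starts: int = 8,
                 random_state: int | None = 0):
        self.constrain_k_inf = constrain_k_inf
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y, sigma=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 3:
            raise ValueError("need at least 3 (t, K) points")
        w = np.ones_like(k) if sigma is None else 1.0 / np.asarray(sigma, float)
        # physical ranges: tissue kurtosis amplitudes are O(1), exchange
        # times tens of ms to tens of s; a small negative K∞ is allowed
        # unless constrained
        k_inf_lo = 0.0 if self.constrain_k_inf else -2.0
        lo = np.array([0.0, 1.0, k_inf_lo])
        hi = np.array([20.0, 2e4, 2.0])

        def residual(p):
            return w * (
                kurtosis_exchange_model(t, ExchangeKurtosisParams(p[0], p[1], p[2])) - k
            )

        rng = np.random.default_rng(self.random_state)
        k_span = max(float(np.max(k) - np.min(k)), 1e-6)
        best = None
        for i in range(self.n_starts):
            tau0 = np.exp(rng.uniform(np.log(0.1 * t.min()), np.log(10.0 * t.max())))
            x0 = np.clip(
                [max(2.0 * k_span, 0.1), tau0, float(np.min(k))], lo, hi
            )
            sol = optimize.least_squares(
                residual, x0, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-10,
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError("kurtosis exchange fit failed to converge")
        self.params_ = ExchangeKurtosisParams(*map(float, best.x))
        self.cost_ = float(2.0 * best.cost)
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(
            kurtosis_exchange_model(np.asarray(X, dtype=float).reshape(-1), self.params_)
        )


def fit_kurtosis_exchange(
    points: list[KurtosisPoint],
    use: str | int = "four-longest",
    constrain_k_inf: bool = False,
    seed: int | None = 0,
    sigma: np.ndarray | None = None,
) -> ExchangeKurtosisParams:
    """Fit the exchange model to a kurtosis series.

    ``use`` selects the points: ``"four-longest"`` (default, the four
    longest gradient separations), ``"all"``, or an integer n for the n
    longest.  ``sigma`` (aligned with the selected points after sorting by
    Δ) weights the residuals, e.g. by the between-sample SEM of a
    group-mean curve.
    """
    pts = sorted(points, key=lambda p: p.delta_sep)
    order = np.argsort([p.delta_sep for p in points])
    if use == "all":
        sel = pts
        sel_sigma = None if sigma is None else np.asarray(sigma, float)[order]
    else:
        n = 4 if use == "four-longest" else int(use)
        sel = pts[-n:]
        sel_sigma = None if sigma is None else np.asarray(sigma, float)[order][-n:]
    if len(sel) < 3:
        raise ValueError("need at least 3 selected kurtosis points")
    t = np.array([p.t_d for p in sel])
    k = np.array([p.kurtosis for p in sel])
    est = KurtosisExchangeRegressor(
        constrain_k_inf=constrain_k_inf, random_state=seed
    ).fit(t, k, sigma=sel_sigma)
    return est.params_


def exchange_rate_from_tau(tau_ex: float) -> float:
    """Total exchange rate 1/τ = k_IE + k_EI in s⁻¹ from τ in ms.

    Rounding to the nearest integer happens only in the report layer.
    """
    if tau_ex <= 0:
        raise ValueError("tau_ex must be positive")
    return 1000.0 / tau_ex


def lee_fraction(k0: float) -> float:
    """Intracellular water fraction from the exchanging kurtosis amplitude:
    f = K0 / (3 + K0)."""
    if k0 < 0:
        raise ValueError("k0 must be non-negative")
    return k0 / (3.0 + k0)


def lee_radius(t_peak: float, tau_ex: float, f: float, d_i: float) -> LeeResult:
    """Radius and time scales from the kurtosis peak.

    t_r = τ/(1−f);  t_c = (5·t_peak/6)²/t_r;  r = sqrt(t_c·D_I),
    inverting t_peak = (6/5)·sqrt(t_r·t_c) with t_c = r²/D_I.
    """
    if min(t_peak, tau_ex, d_i) <= 0 or f < 0:
        raise ValueError("inputs must be positive")
    if f >= 1.0:
        raise ValueError("f must be < 1")
    t_r = tau_ex / (1.0 - f)
    t_c = (5.0 * t_peak / 6.0) ** 2 / t_r
    radius = float(np.sqrt(t_c * d_i))
    return LeeResult(f=f, t_r=t_r, t_c=t_c, radius=radius, t_peak=t_peak)


def find_kurtosis_peak(
    points: list[KurtosisPoint], refine: bool = False
) -> tuple[float, bool]:
    """Gradient separation of maximal kurtosis on the measured grid.

    Returns ``(t_peak, is_boundary)``.  No interpolation by default (the
    grid values are what is reported); ``refine=True`` applies a quadratic
    refinement through the peak and its neighbours.  A monotone series has
    no interior peak: the boundary Δ is returned with a warning and the
    flag set.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points to locate a peak")
    pts = sorted(points, key=lambda p: p.delta_sep)
    k = np.array([p.kurtosis for p in pts])
    d = np.array([p.delta_sep for p in pts])
    i = int(np.argmax(k))
    if i == 0 or i == len(pts) - 1:
        warnings.warn(
            "kurtosis series is monotone: no interior peak; returning boundary",
            stacklevel=2,
        )
        return float(d[i]), True
    if refine:
        x, yv = d[i - 1 : i + 2], k[i - 1 : i + 2]
        a, b_, _ = np.polyfit(x, yv, 2)
        if a < 0:
            return float(-b_ / (2.0 * a)), False
    return float(d[i]), False
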