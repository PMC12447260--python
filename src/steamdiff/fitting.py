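"""Joint nonlinear least-squares fitting of the two-pool exchange model.

The central estimator, :class:`TwoPoolExchangeRegressor`, follows the
scikit-learn fit/predict contract: the design matrix holds the acquisition
coordinates ``(b, Δ, δ)`` in canonical units (ms/μm², ms, ms) and the target
is the measured signal.  All b-values and all diffusion times are fitted
jointly with one parameter set; b = 0 rows are excluded by default (their
images lack crusher gradients and carry artifacts).  The optimizer is
bounded trust-region-reflective least squares with seeded multi-start
initialization, and fit quality is the reduced χ² of σ-weighted residuals.

Confidence intervals come from χ² contours: a pair of parameters is fixed
and moved away from the optimum, the remaining parameters re-optimized at
every step, until the constrained reduced χ² exceeds

    χ₀² · (1 + n_P F(n_P, N − n_P) / (N − n_P)),

with F the quantile of the F-distribution at the requested confidence
level, n_P the number of free parameters of the unconstrained fit and N
the number of fitted points.

Mono-exponential relaxometry fits (inversion-recovery T1, CPMG T2) live
here too; they share the estimator idiom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .model import TwoPoolParams, steam_signal
from .protocol import AcquisitionPoint, AcquisitionProtocol, SignalDataset

__all__ = [
    "FitResult",
    "RelaxometrySeries",
    "TwoPoolExchangeRegressor",
    "InversionRecoveryT1",
    "CpmgT2",
    "fit_two_pool",
    "reduced_chi2",
    "contour_interval",
    "profile_contour",
    "fit_ir_t1",
    "fit_cpmg_t2",
    "ContourResult",
]

#: full parameter order of the two-pool model
PARAM_NAMES = ("r", "k_ie", "m_i0", "d_i", "d_e_app", "s0", "r1_i", "r1_e")

#: default physiological bounds; s0 bounds are data-dependent
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r": (0.5, 15.0),
    "k_ie": (0.0, 100.0),
    "m_i0": (0.0, 1.0),
    "d_i": (0.1, 3.0),
    "d_e_app": (0.05, 3.0),
    "r1_i": (0.0, 10.0),
    "r1_e": (0.0, 10.0),
}

#: rates are drawn log-uniformly at initialization
LOG_UNIFORM = {"k_ie", "r1_i", "r1_e"}


def reduced_chi2(residuals: np.ndarray, sigma: np.ndarray, n_free: int) -> float:
    """Σ((residual/σ)²) / (N − n_free).

    Raises ``ValueError`` when N ≤ n_free (no degrees of freedom).
    """
    residuals = np.asarray(residuals, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = residuals.size
    if n <= n_free:
        raise ValueError(f"need more points ({n}) than free parameters ({n_free})")
    return float(np.sum((residuals / sigma) ** 2) / (n - n_free))


@dataclass
class FitResult:
    """Outcome of a joint two-pool fit."""

    params: TwoPoolParams
    fixed: dict[str, float]
    chi2_reduced: float
    n_points: int
    n_free: int
    start_used: int
    objective: float
    at_bounds: tuple[str, ...] = ()
    per_parameter_interval: dict[str, tuple[float, float]] = field(default_factory=dict)
    start_objectives: tuple[float, ...] = ()

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.fixed)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "fixed": dict(self.fixed),
            "chi2_reduced": self.chi2_reduced,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "start_used": self.start_used,
            "objective": self.objective,
            "at_bounds": list(self.at_bounds),
            "per_parameter_interval": {
                k: list(v) for k, v in self.per_parameter_interval.items()
            },
        }


@dataclass(frozen=True)
class RelaxometrySeries:
    """Inversion-time or echo-time series of magnitude signals."""

    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and signal must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)


class TwoPoolExchangeRegressor(RegressorMixin, BaseEstimator):
    """Joint two-pool exchange model fit over b-values and diffusion times.

    Parameters
    ----------
    fixed : dict, default ``{"d_i": 1.7}``
        Parameters held constant during the fit.  The intracellular
        diffusivity is fixed by default because the measured diffusion
        times are too long to sensitize to it.
    n_starts : int, default 20
        Number of randomized initializations; the lowest converged
        objective wins.  Rates are drawn log-uniformly within bounds,
        other parameters uniformly.
    random_state : int or None
        Seed for the multi-start draws.
    bounds : dict or None
        Per-parameter ``(low, high)`` overrides of the defaults.
    exclude_b0 : bool, default True
        Drop b = 0 rows before fitting (crusher-artifact policy).
    include_relaxation : bool, default True
        Model longitudinal relaxation during the evolution time.

    Attributes
    ----------
    params_ : TwoPoolParams
        Best-fit parameters.
    result_ : FitResult
        Full fit record (χ², winning start, bound flags).
    chi2_reduced_ : float
    """

    def __init__(
        self,
        fixed: dict[str, float] | None = None,
        n_starts: int = 20,
        random_state: int | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        exclude_b0: bool = True,
        include_relaxation: bool = True,
    ):
        self.fixed = fixed
        self.n_starts = n_starts
        self.random_state = random_state
        self.bounds = bounds
        self.exclude_b0 = exclude_b0
        self.include_relaxation = include_relaxation

    # -- plumbing -----------------------------------------------------------

    def _effective_fixed(self) -> dict[str, float]:
        return {"d_i": 1.7} if self.fixed is None else dict(self.fixed)

    def _effective_bounds(self, y: np.ndarray) -> dict[str, tuple[float, float]]:
        bounds = dict(DEFAULT_BOUNDS)
        bounds["s0"] = (1e-9 * float(np.max(y)), 10.0 * float(np.max(y)))
        if self.bounds:
            bounds.update(self.bounds)
        return bounds

    @staticmethod
    def _protocol_from_X(X: np.ndarray) -> AcquisitionProtocol:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 3:
            raise ValueError("X must be (n_points, 3): columns b [ms/μm²], Δ [ms], δ [ms]")
        points = tuple(
            AcquisitionPoint(
                b=row[0], delta_sep=row[1], delta_pulse=row[2],
                mixing_time=max(row[1] - 17.5, 0.001), echo_time=35.0,
            )
            for row in X
        )
        return AcquisitionProtocol(points=points, name="X")

    def _build_params(self, theta: np.ndarray) -> TwoPoolParams:
        values = dict(self._fixed_)
        for name, val in zip(self._free_names_, theta):
            values[name] = float(val)
        return TwoPoolParams(**values)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, sigma: np.ndarray | None = None):
        """Fit the model.

        ``X``: (n, 3) acquisition coordinates (b in ms/μm², Δ and δ in ms);
        ``y``: measured signal; ``sigma``: per-point noise std used as
        weights (uniform if omitted).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if sigma is None:
            sigma = np.ones_like(y)
        sigma = np.asarray(sigma, dtype=float)
        if y.shape[0] != X.shape[0] or sigma.shape != y.shape:
            raise ValueError("X, y and sigma must agree in length")

        keep = X[:, 0] > 0 if self.exclude_b0 else np.ones(len(y), bool)
        Xf, yf, sf = X[keep], y[keep], sigma[keep]
        if len(np.unique(Xf[:, 1])) < 2:
            raise ValueError("need at least two distinct gradient separations")

        protocol = self._protocol_from_X(Xf)
        self._fixed_ = self._effective_fixed()
        self._free_names_ = tuple(n for n in PARAM_NAMES if n not in self._fixed_)
        bounds = self._effective_bounds(yf)
        lo = np.array([bounds[n][0] for n in self._free_names_])
        hi = np.array([bounds[n][1] for n in self._free_names_])
        n_free = len(self._free_names_)
        if len(yf) <= n_free:
            raise ValueError("more free parameters than fitted points")

        def residual(theta: np.ndarray) -> np.ndarray:
            model = steam_signal(
                self._build_params(theta), protocol,
                include_relaxation=self.include_relaxation,
            )
            return (model - yf) / sf

        rng = np.random.default_rng(self.random_state)
        starts = self._draw_starts(rng, lo, hi, float(np.max(yf)))
        best, best_idx, objectives = None, -1, []
        for i, x0 in enumerate(starts):
            try:
                sol = optimize.least_squares(
                    residual, x0, bounds=(lo, hi), method="trf",
                    ftol=1e-10, xtol=1e-8, gtol=1e-10,
                )
            except Exception:
                objectives.append(np.inf)
                continue
            objectives.append(2.0 * sol.cost)
            if sol.success and (best is None or sol.cost < best.cost):
                best, best_idx = sol, i
        if best is None:
            raise RuntimeError(
                f"all {len(starts)} starts failed to converge; objectives={objectives}"
            )

        theta = best.x
        scale = hi - lo
        at_bounds = tuple(
            n for n, v, l, h, s in zip(self._free_names_, theta, lo, hi, scale)
            if v - l < 1e-6 * s or h - v < 1e-6 * s
        )
        # only flag upper-bound / interior-collapse pathologies that matter:
        # a rate pinned at 0 on noiseless single-pool data is the documented
        # non-identifiability signal as well
        objective = float(2.0 * best.cost)
        self.params_ = self._build_params(theta)
        self.chi2_reduced_ = objective / (len(yf) - n_free)
        self.result_ = FitResult(
            params=self.params_,
            fixed=dict(self._fixed_),
            chi2_reduced=self.chi2_reduced_,
            n_points=int(len(yf)),
            n_free=n_free,
            start_used=best_idx,
            objective=objective,
            at_bounds=at_bounds,
            start_objectives=tuple(objectives),
        )
        self.n_features_in_ = X.shape[1]
        self._bounds_ = bounds
        self._train_ = (Xf, yf, sf)
        return self

    def _draw_starts(self, rng, lo, hi, y_max) -> np.ndarray:
        starts = np.empty((self.n_starts, len(lo)))
        for j, name in enumerate(self._free_names_):
            l, h = lo[j], hi[j]
            if name in LOG_UNIFORM:
                l_pos = max(l, 1e-3 * h)
                starts[:, j] = np.exp(rng.uniform(np.log(l_pos), np.log(h), self.n_starts))
            elif name == "s0":
                starts[:, j] = rng.uniform(0.5 * y_max, 2.0 * y_max, self.n_starts)
            else:
                starts[:, j] = rng.uniform(l, h, self.n_starts)
        return starts

    def predict(self, X) -> np.ndarray:
        """Model signal at the given acquisition coordinates."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        protocol = self._protocol_from_X(np.asarray(X, dtype=float))
        return steam_signal(self.params_, protocol, include_relaxation=self.include_relaxation)

    # -- dataset convenience -------------------------------------------------

    def fit_dataset(self, dataset: SignalDataset):
        """Fit directly from a :class:`SignalDataset`."""
        X = np.column_stack(
            [
                dataset.protocol.b,
                dataset.protocol.delta_sep,
                [p.delta_pulse for p in dataset.protocol],
            ]
        )
        return self.fit(X, dataset.signal, sigma=dataset.sigma)


def fit_two_pool(
    dataset: SignalDataset,
    fixed: dict[str, float] | None = None,
    n_starts: int = 20,
    seed: int | None = 0,
    **kwargs,
) -> FitResult:
    """Joint two-pool fit of a dataset; thin wrapper over the estimator."""
    est = TwoPoolExchangeRegressor(
        fixed=fixed, n_starts=n_starts, random_state=seed, **kwargs
    )
    est.fit_dataset(dataset)
    return est.result_


# -- χ²-contour confidence intervals ----------------------------------------


@dataclass
class ContourResult:
    """Contour trace and per-parameter interval for one parameter pair."""

    pair: tuple[str, str]
    intervals: dict[str, tuple[float, float]]
    trace: np.ndarray  # columns: p1, p2, constrained reduced χ²
    threshold: float
    confidence: float
    open_directions: int = 0

    @property
    def is_open(self) -> bool:
        return self.open_directions > 0


def chi2_threshold(chi2_0: float, n_free: int, n_points: int, confidence: float) -> float:
    """Constrained-fit acceptance threshold on the reduced χ² scale."""
    dof = n_points - n_free
    f_q = stats.f.ppf(confidence, n_free, dof)
    return chi2_0 * (1.0 + n_free * f_q / dof)


def profile_contour(
    constrained_chi2: Callable[[float, float], float],
    center: tuple[float, float],
    threshold: float,
    scales: tuple[float, float],
    bounds: tuple[tuple[float, float], tuple[float, float]],
    n_directions: int = 16,
    r_max: float = 50.0,
    tol: float = 1e-3,
) -> tuple[np.ndarray, int]:
    """March radially from the optimum until the constrained χ² crosses
    ``threshold``; bisect each crossing.

    ``constrained_chi2(p1, p2)`` must return the reduced χ² after
    re-optimizing all nuisance parameters with the pair held fixed.
    Returns the contour points (p1, p2, χ²) and the number of directions
    where a parameter bound was hit before the threshold (open contour).
    """
    c1, c2 = center
    s1, s2 = scales
    (lo1, hi1), (lo2, hi2) = bounds
    pts = []
    n_open = 0
    for theta in np.linspace(0.0, 2.0 * np.pi, n_directions, endpoint=False):
        u1, u2 = np.cos(theta), np.sin(theta)

        def point(rad: float) -> tuple[float, float]:
            return c1 + rad * u1 * s1, c2 + rad * u2 * s2

        def in_bounds(rad: float) -> bool:
            p1, p2 = point(rad)
            return lo1 <= p1 <= hi1 and lo2 <= p2 <= hi2

        # expand until crossing or bound
        r_lo, r_hi = 0.0, 1e-3
        crossed = False
        while r_hi <= r_max:
            if not in_bounds(r_hi):
                n_open += 1
                break
            val = constrained_chi2(*point(r_hi))
            if val >= threshold:
                crossed = True
                break
            r_lo, r_hi = r_hi, r_hi * 2.0
        if not crossed:
            if in_bounds(r_hi):  # r_max exhausted without bound hit
                n_open += 1
            r_edge = min(r_hi, r_max)
            p1, p2 = point(r_lo)
            pts.append((p1, p2, constrained_chi2(p1, p2)))
            continue
        while r_hi - r_lo > tol * max(r_hi, 1e-12):
            mid = 0.5 * (r_lo + r_hi)
            if constrained_chi2(*point(mid)) >= threshold:
                r_hi = mid
            else:
                r_lo = mid
        p1, p2 = point(0.5 * (r_lo + r_hi))
        pts.append((p1, p2, constrained_chi2(p1, p2)))
    return np.array(pts), n_open


def contour_interval(
    fit: FitResult,
    dataset: SignalDataset,
    pair: tuple[str, str],
    confidence: float = 0.68,
    n_directions: int = 16,
    exclude_b0: bool = True,
    include_relaxation: bool = True,
) -> ContourResult:
    """χ²-contour confidence intervals for a pair of fitted parameters.

    The pair is fixed on a radial march away from the optimum with all
    other free parameters re-optimized at each step, until the constrained
    reduced χ² reaches the F-based threshold.  The per-parameter interval
    is the extremal accepted value along the contour; a march that hits a
    parameter bound first marks the interval one-sided (open).
    """
    p1, p2 = pair
    free = fit.free_names
    if p1 not in free or p2 not in free:
        raise ValueError(f"{pair} must both be free parameters of the fit")

    est = TwoPoolExchangeRegressor(
        fixed=fit.fixed, exclude_b0=exclude_b0, include_relaxation=include_relaxation
    )
    X = np.column_stack(
        [
            dataset.protocol.b,
            dataset.protocol.delta_sep,
            [p.delta_pulse for p in dataset.protocol],
        ]
    )
    y, sig = dataset.signal, dataset.sigma
    keep = X[:, 0] > 0 if exclude_b0 else np.ones(len(y), bool)
    Xf, yf, sf = X[keep], y[keep], sig[keep]
    protocol = est._protocol_from_X(Xf)
    bounds = est._effective_bounds(yf)

    nuisance = tuple(n for n in free if n not in pair)
    lo = np.array([bounds[n][0] for n in nuisance])
    hi = np.array([bounds[n][1] for n in nuisance])
    base = fit.params.to_dict()
    warm = {"x": np.array([base[n] for n in nuisance])}
    dof = fit.n_points - fit.n_free

    def constrained_chi2(v1: float, v2: float) -> float:
        values = dict(base)
        values[p1], values[p2] = v1, v2

        def residual(theta):
            for name, val in zip(nuisance, theta):
                values[name] = float(val)
            return (
                steam_signal(TwoPoolParams(**values), protocol, include_relaxation)
                - yf
            ) / sf

        x0 = np.clip(warm["x"], lo, hi)
        sol = optimize.least_squares(
            residual, x0, bounds=(lo, hi), method="trf",
            ftol=1e-10, xtol=1e-8, gtol=1e-10,
        )
        warm["x"] = sol.x
        return float(2.0 * sol.cost / dof)

    threshold = chi2_threshold(fit.chi2_reduced, fit.n_free, fit.n_points, confidence)
    center = (base[p1], base[p2])
    scales = tuple(
        max(0.02 * (bounds[n][1] - bounds[n][0]), 1e-6) for n in pair
    )
    trace, n_open = profile_contour(
        constrained_chi2,
        center,
        threshold,
        scales,
        (bounds[p1], bounds[p2]),
        n_directions=n_directions,
    )
    intervals = {
        p1: (float(min(trace[:, 0].min(), center[0])), float(max(trace[:, 0].max(), center[0]))),
        p2: (float(min(trace[:, 1].min(), center[1])), float(max(trace[:, 1].max(), center[1]))),
    }
    fit.per_parameter_interval.update(intervals)
    return ContourResult(
        pair=(p1, p2),
        intervals=intervals,
        trace=trace,
        threshold=threshold,
        confidence=confidence,
        open_directions=n_open,
    )


# -- relaxometry -------------------------------------------------------------


class InversionRecoveryT1(RegressorMixin, BaseEstimator):
    """Magnitude inversion-recovery T1 fit: S(TI) = S0·|1 − 2·exp(−TI/T1)|.

    ``t1_`` is in ms.  A series with no inversion contrast (all TI ≫ T1,
    signal flat at S0) is flagged unidentifiable via ``flagged_``.
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        s = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 3:
            raise ValueError("need at least 3 inversion times")
        self.flagged_ = False
        s0_guess = float(np.max(s))
        rel_range = (np.max(s) - np.min(s)) / max(s0_guess, 1e-300)
        if rel_range < 1e-3:
            # no nulling visible: T1 unidentifiable from this design
            self.flagged_ = True
            self.t1_ = float(t[0] / np.log(2.0))
            self.s0_ = s0_guess
            return self
        t1_guess = float(t[np.argmin(s)] / np.log(2.0))

        def residual(p):
            s0, t1 = p
            return s0 * np.abs(1.0 - 2.0 * np.exp(-t / t1)) - s

        sol = optimize.least_squares(
            residual, [s0_guess, max(t1_guess, t[0])],
            bounds=([0.0, 1e-6], [np.inf, np.inf]), method="trf",
        )
        if not sol.success:
            raise RuntimeError("inversion-recovery fit failed to converge")
        self.s0_, self.t1_ = float(sol.x[0]), float(sol.x[1])
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.s0_ * np.abs(1.0 - 2.0 * np.exp(-t / self.t1_))


class CpmgT2(RegressorMixin, BaseEstimator):
    """Mono-exponential CPMG T2 fit: S(TE) = S0·exp(−TE/T2); ``t2_`` in ms.

    A non-decaying series yields ``t2_ = inf`` with ``flagged_`` set.
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        s = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 3:
            raise ValueError("need at least 3 echoes")
        if np.any(s <= 0):
            raise ValueError("CPMG magnitudes must be positive for the log fit")
        slope, intercept = np.polyfit(t, np.log(s), 1)
        self.flagged_ = False
        if slope >= -1e-12:
            self.flagged_ = True
            self.t2_ = np.inf
            self.s0_ = float(np.exp(intercept))
            return self

        def residual(p):
            s0, t2 = p
            return s0 * np.exp(-t / t2) - s

        sol = optimize.least_squares(
            residual, [np.exp(intercept), -1.0 / slope],
            bounds=([0.0, 1e-6], [np.inf, np.inf]), method="trf",
        )
        if not sol.success:
            raise RuntimeError("CPMG fit failed to converge")
        self.s0_, self.t2_ = float(sol.x[0]), float(sol.x[1])
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.s0_ * np.exp(-t / self.t2_)


def fit_ir_t1(series: RelaxometrySeries) -> float:
    """T1 (ms) from a magnitude inversion-recovery series."""
    est = InversionRecoveryT1().fit(series.times, series.signal)
    if est.flagged_:
        raise RuntimeError("T1 unidentifiable: no inversion contrast in the series")
    return est.t1_


def fit_cpmg_t2(series: RelaxometrySeries) -> float:
    """T2 (ms) from a CPMG echo train."""
    est = CpmgT2().fit(series.times, series.signal)
    if est.flagged_:
        raise RuntimeError("T2 unidentifiable: series does not decay")
    return est.t2_
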