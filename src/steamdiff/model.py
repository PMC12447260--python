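"""Two-pool exchange forward model for STEAM diffusion signals.

The longitudinal magnetizations of the intracellular (I) and extracellular
(E) water pools evolve, during the diffusion/mixing interval of a
stimulated-echo experiment, under diffusion attenuation, longitudinal
relaxation and first-order transmembrane exchange:

    dM_I/dt = −q² D_I^app M_I − R1_I M_I − k_IE M_I + k_EI M_E
    dM_E/dt = −q² D_E^app M_E − R1_E M_E − k_EI M_E + k_IE M_I

Only longitudinal relaxation appears because the magnetization is stored
along z during the mixing time; transverse decay over the fixed TE is
absorbed into the normalization S0.  The intracellular pool is a sphere of
radius r, so D_I^app is the time-dependent restricted diffusivity
``sphere_dapp(r, d_i, tD)``; the extracellular apparent diffusivity already
contains the tortuosity factor.  Detailed balance ties the return rate to
the equilibrium fractions: k_EI = k_IE · M_I0 / (1 − M_I0).

The 2×2 linear system is solved in closed form.  For a matrix A with trace
2μ and determinant Δ₀ the propagator is

    exp(A t) = e^{μt} [ cosh(s t) I + (sinh(s t)/s) (A − μ I) ],   s² = μ² − Δ₀,

with sinh(st)/s continued through s → 0 by its series (the degenerate
eigenvalue limit).  Here s² ≥ 0 always, since the off-diagonal product
k_IE·k_EI is non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np

from .protocol import AcquisitionProtocol
from .sphere import sphere_dapp

__all__ = ["TwoPoolParams", "karger_generator", "steam_signal"]

#: s⁻¹ → ms⁻¹
RATE_S_TO_MS = 1e-3


@dataclass(frozen=True)
class TwoPoolParams:
    """Parameters of the two-pool exchange model.

    Rates are user-facing in s⁻¹ (the reporting convention); lengths in μm,
    diffusivities in μm²/ms.

    Attributes
    ----------
    r : sphere radius of the intracellular pool (μm)
    k_ie : intracellular→extracellular exchange rate (s⁻¹)
    m_i0 : equilibrium intracellular water fraction (0–1)
    d_i : intrinsic intracellular diffusivity (μm²/ms)
    d_e_app : apparent extracellular diffusivity, tortuosity included (μm²/ms)
    s0 : signal normalization (proton density × scanner scaling)
    r1_i : intracellular longitudinal relaxation rate (s⁻¹)
    r1_e : extracellular longitudinal relaxation rate (s⁻¹)
    """

    r: float
    k_ie: float
    m_i0: float
    d_i: float = 1.7
    d_e_app: float = 0.95
    s0: float = 1.0
    r1_i: float = 0.0
    r1_e: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.m_i0 <= 1.0:
            raise ValueError("m_i0 must lie in [0, 1]")
        for name in ("k_ie", "r1_i", "r1_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.d_i <= 0 or self.d_e_app < 0:
            raise ValueError("diffusivities must be positive")

    @property
    def k_ei(self) -> float:
        """Extracellular→intracellular rate from detailed balance (s⁻¹).

        k_EI = k_IE·m_i0/(1−m_i0); defined as 0 when m_i0 = 1 (no
        extracellular pool to exchange with).
        """
        if self.m_i0 >= 1.0:
            if self.k_ie > 0:
                warnings.warn(
                    "m_i0 = 1: exchange is disabled (k_ei set to 0)", stacklevel=2
                )
            return 0.0
        return self.k_ie * self.m_i0 / (1.0 - self.m_i0)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "TwoPoolParams":
        return replace(self, **kw)


def karger_generator(
    params: TwoPoolParams,
    q: float,
    t_diff: float,
    include_relaxation: bool = True,
) -> np.ndarray:
    """2×2 evolution matrix A (ms⁻¹) acting on (M_I, M_E).

    The intracellular attenuation rate is q²·Dapp(r, d_i, t_diff) with the
    restricted-sphere apparent diffusivity evaluated at the evolution time.
    With q = 0 and relaxation off the columns sum to zero (pure exchange
    conserves total magnetization).
    """
    di_app = sphere_dapp(params.r, params.d_i, t_diff)
    k_ei = params.k_ei * RATE_S_TO_MS
    # m_i0 = 1: no extracellular pool, exchange disabled for stationarity
    k_ie = params.k_ie * RATE_S_TO_MS if params.m_i0 < 1.0 else 0.0
    r1_i = params.r1_i * RATE_S_TO_MS if include_relaxation else 0.0
    r1_e = params.r1_e * RATE_S_TO_MS if include_relaxation else 0.0
    q2 = q * q
    return np.array(
        [
            [-q2 * di_app - r1_i - k_ie, k_ei],
            [k_ie, -q2 * params.d_e_app - r1_e - k_ei],
        ]
    )


def _sinhc(x: np.ndarray) -> np.ndarray:
    """sinh(x)/x, continued through x = 0."""
    out = np.ones_like(x)
    small = np.abs(x) < 1e-6
    xs = x[~small]
    out[~small] = np.sinh(xs) / xs
    out[small] = 1.0 + x[small] ** 2 / 6.0
    return out


def steam_signal(
    params: TwoPoolParams,
    protocol: AcquisitionProtocol,
    include_relaxation: bool = True,
) -> np.ndarray:
    """Total signal M_I + M_E for every protocol point.

    For each point the initial state s0·(m_i0, 1−m_i0) is propagated over
    the diffusion time tD = Δ − δ/3 by the closed-form matrix exponential
    of the exchange generator, with q² = b/tD so that q²·D·tD = b·D.
    Vectorised over the protocol; all 2×2 algebra is explicit.
    """
    b = protocol.b
    td = protocol.diffusion_times
    # unique evolution times: the sphere series is evaluated once per Δ
    td_unique, inv = np.unique(td, return_inverse=True)
    di_app = np.asarray(sphere_dapp(params.r, params.d_i, td_unique))[inv]

    k_ei = params.k_ei * RATE_S_TO_MS
    k_ie = params.k_ie * RATE_S_TO_MS if params.m_i0 < 1.0 else 0.0
    r1_i = params.r1_i * RATE_S_TO_MS if include_relaxation else 0.0
    r1_e = params.r1_e * RATE_S_TO_MS if include_relaxation else 0.0
    q2 = b / td

    a11 = -q2 * di_app - r1_i - k_ie
    a22 = -q2 * params.d_e_app - r1_e - k_ei
    a12 = np.full_like(a11, k_ei)
    a21 = np.full_like(a11, k_ie)

    mu = 0.5 * (a11 + a22)
    # s² = μ² − det(A) = ((a11−a22)/2)² + a12·a21 ≥ 0 here
    s2 = 0.25 * (a11 - a22) ** 2 + a12 * a21
    s = np.sqrt(np.maximum(s2, 0.0))
    st = s * td
    ch = np.cosh(st)
    shc = _sinhc(st) * td  # sinh(s t)/s

    m0 = params.s0 * np.array([params.m_i0, 1.0 - params.m_i0])
    # exp(A t) m0, with exp(A t) = e^{μt}[cosh(st) I + shc (A − μ I)]
    e = np.exp(mu * td)
    mi = e * (ch * m0[0] + shc * ((a11 - mu) * m0[0] + a12 * m0[1]))
    me = e * (ch * m0[1] + shc * (a21 * m0[0] + (a22 - mu) * m0[1]))
    return mi + me
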