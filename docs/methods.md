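# Methods

This note records the model, its assumptions, the defaults that matter,
the numerical choices, and what the synthetic studies do and do not
establish.

## Two-pool exchange model

Water is divided into an intracellular pool (fraction M_I0, sphere radius
r, intrinsic diffusivity D_I, longitudinal rate R1_I) and an extracellular
pool (apparent diffusivity D_E^app with the tortuosity factor absorbed,
rate R1_E), exchanging with first-order kinetics.  During the diffusion
interval of a stimulated-echo measurement the pool magnetizations obey

    dM_I/dt = −q² D_I^app M_I − R1_I M_I − k_IE M_I + k_EI M_E
    dM_E/dt = −q² D_E^app M_E − R1_E M_E − k_EI M_E + k_IE M_I

Assumptions, and why they are acceptable here:

- **Longitudinal relaxation only.** STEAM stores magnetization along z for
  the mixing time, and only TM varies across the protocol; transverse decay
  over the fixed TE is a constant factor absorbed into S0.
- **Single evolution time.** Attenuation, relaxation and exchange all act
  over t_D = Δ − δ/3.  Δ − δ/3 is exact for rectangular pulses and reduces
  to Δ as δ → 0; with δ = 4 ms it differs from Δ by at most 8% (shortest
  separation).  The alternative of applying R1 over TM alone is not
  distinguishable from this choice by the fit — the effective R1_E soaks up
  the difference — so the fitted relaxation rates are *effective* rates and
  are not interpreted against independently measured T1.
- **Narrow-pulse restricted pool.** The intracellular apparent diffusivity
  is the narrow-pulse ⟨z²(t)⟩/2t of an impermeable sphere.  δ = 4 ms is in
  fact comparable to the intracellular correlation time r²/D_I ≈ 10 ms, so
  the model sits in a crossover regime; wide-pulse corrections are out of
  scope and the radius should be read as an effective narrow-pulse radius.
- **Detailed balance.** k_EI = k_IE·M_I0/(1 − M_I0) so that the equilibrium
  fractions are stationary under exchange.  At M_I0 = 1 exchange is
  disabled entirely (a one-sided rate would drain the pool) and a warning
  is emitted.
- **Constant extracellular diffusivity.** Tortuosity is treated as
  time-independent; at these long diffusion times the extracellular pool is
  in its tortuosity asymptote.

### Restricted-sphere diffusivity

The one-axis position autocorrelation in a reflecting sphere of radius R is

    ⟨z(0)z(t)⟩ = Σ_n 2R²/(α_n²(α_n²−2)) · exp(−α_n² D t/R²),

over the positive roots α_n of j₁′(α) = 0; the amplitudes sum to the
stationary variance R²/5, giving ⟨z²(t)⟩ = 2R²/5 − 2⟨z(0)z(t)⟩ and
D_app = ⟨z²⟩/2t.  64 modes are retained (roots found by bracketed Brent
iteration and cached).  The truncation error carries a rigorous bound —
every dropped mode decays at least as fast as the last retained one and the
dropped amplitudes sum to R²/5 − Σamp — which is below 10⁻⁹ μm²/ms for all
t ≳ 10⁻²·R²/D and below 10⁻³⁰ at every protocol time.  In the extreme
short-time window the free-diffusion value D_I is returned whenever its
surface-to-volume (Mitra) error bound beats the series bound; only if both
bounds exceed 1% of D_I does the function raise.  The series is validated
against a Monte-Carlo reflecting random walk (below) and both analytic
limits.

### Closed-form propagator

For the 2×2 generator A with μ = tr A/2 and s² = μ² − det A (always ≥ 0
here, since the off-diagonal product is non-negative),

    exp(At) = e^{μt}[cosh(st)·I + (sinh(st)/s)(A − μI)],

with sinh(st)/s continued through s = 0 by its series — the degenerate
eigenvalue case is a formula, not a failure branch.  The propagator is
verified against adaptive ODE integration (DOP853, rtol 10⁻¹²) to relative
error below 10⁻⁸ over randomized parameter draws.

## Fitting

- **Estimator.** `TwoPoolExchangeRegressor`: bounded trust-region
  least squares (scipy `least_squares`, method `trf`; ftol 10⁻¹⁰,
  xtol 10⁻⁸) on σ-weighted residuals, all separations and b-values jointly.
  b = 0 rows are excluded by default: unweighted images lack crusher
  gradients and are systematically low.
- **Bounds** (physiological, bracketing all plausible values):
  r ∈ [0.5, 15] μm, k_IE ∈ [0, 100] s⁻¹, M_I0 ∈ [0, 1],
  D_E^app ∈ [0.05, 3] μm²/ms, R1 ∈ [0, 10] s⁻¹, S0 ∈ (0, 10·max signal].
- **Multi-start.** Default 20 seeded draws; rates log-uniform within
  bounds, other parameters uniform, S0 uniform in [0.5, 2]×max signal.
  The lowest converged objective wins; per-start objectives are recorded.
  Parameters within 10⁻⁶ of a bound are flagged.
- **Fixed parameters.** D_I = 1.7 μm²/ms by default: the measured
  diffusion times are too long to sensitize to the intrinsic intracellular
  diffusivity.  For *study-level* analyses the non-identifiable R1_I is
  additionally fixed at 0.  Rationale: noiseless recovery shows R1_I
  collapsing to zero, and with R1_I free the k_IE information content at
  study noise levels is degraded by the R1_I↔k_IE degeneracy (the
  Cramér–Rao bound on k_IE at SNR 50 is ≈2.2 s⁻¹ with R1_I free versus
  ≈0.7 s⁻¹ with it fixed) — fixing a parameter the model cannot resolve is
  the standard cure.
- **χ²-contour intervals.** A parameter pair is fixed on a radial march
  from the optimum (all other parameters re-optimized, warm-started) and
  bisected to the threshold χ₀²·(1 + n_P·F(n_P, N−n_P)/(N−n_P)), with n_P
  the free-parameter count of the unconstrained fit and both reduced χ²
  values sharing the unconstrained dof N − n_P.  Confidence level defaults
  to 0.68 (0.95 selectable) and is recorded in the output.  A march that
  hits a parameter bound first marks the interval one-sided.  The
  machinery reproduces the analytic F-ellipse of a linear model to <1%.

## Kurtosis analyses

- The per-separation cumulant fit is an exact polynomial least squares of
  ln S in b over the nonzero b-values: D ≡ ADC from the linear
  coefficient, K = 6a₂/D² from the quadratic one.
- The exchange model K(t) = K0·(2τ/t)[1 − (τ/t)(1 − e^{−t/τ})] + K∞ is
  fitted by bounded least squares to the four longest separations by
  default (the model is a long-time, coarse-grained description).  The
  small-x bracket is evaluated by series below t/τ = 10⁻³ to avoid
  cancellation.  Bounds are physical: K0 ∈ [0, 20], τ ∈ [1, 2·10⁴] ms,
  K∞ ∈ [−2, 2] (non-negative K∞ selectable).
- Peak location defaults to grid argmax — reported peaks are grid values —
  with optional quadratic refinement.
- The kurtosis-peak analysis computes f = K0/(3+K0), t_r = τ/(1−f),
  t_c = (5·t_peak/6)²/t_r, r = √(t_c·D_I).  Note a worked-example check:
  with t_peak = 150 ms, τ = 210 ms, K0 = 2.3 and D_I = 1.7 μm²/ms the
  chain gives r ≈ 8.46 μm; published round-ups of the same arithmetic to
  ≈9.3 μm are not reproducible from these inputs (per-sample inputs were
  presumably used) and the package reports the chain value only.

## Synthetic data

The generator emulates the cell-pellet STEAM experiment: 9 separations
(16, 30, 50, 80, 150, 200, 250, 500, 800 ms), 7 b-values linearly spaced
0–5000 s/mm² (the instrument's exact b table is unpublished; the list is
configurable and recorded in outputs), δ = 4 ms, TE = 35 ms, TM = Δ − TE/2
clipped to 3–785 ms.  Group presets are the fitted two-pool values for
untreated and cisplatin-treated AML pellets — control: M_I0 0.55, r 4.2 μm,
k_IE 4.0 s⁻¹, D_E 0.95 μm²/ms, R1_E 2.9 s⁻¹; apoptotic: 0.32, 3.6 μm,
6 s⁻¹, 0.85 μm²/ms, 1.7 s⁻¹; D_I 1.7, R1_I 0 for both.  Between-sample
jitter defaults to the published between-sample SDs.  Noise is Rician
(magnitude of complex Gaussian, σ = S0/SNR) with Gaussian available for
analytic checks; everything is bit-reproducible given seeds.

The Monte-Carlo oracle is a reflecting random walk in a sphere: Gaussian
steps (the step constraint √(6 D dt) < r/10 is enforced), elastic specular
reflection across the tangent plane at the boundary-crossing point
(radial folding leaves an O(step) MSD bias), walkers started from the
uniform stationary distribution, numba-compiled.  The acceptance check
uses dt = 6 μs and 6000 walkers over t ∈ [1, 800] ms, agreeing with the
eigen-series within 3 MC standard errors.

**What the synthetic studies do not show.**  Real data differ in ways the
generator ignores: ROI means over many pixels (much higher effective SNR
than the per-pixel σ suggests), B1/B0 inhomogeneity, imperfect crushers,
partial-volume media signal, non-spherical and polydisperse cells, and
wide-pulse effects.  Passing recovery tests demonstrates the pipeline's
correctness and its statistical behaviour under the stated noise model,
not scanner-level validity.  Notably, at a per-point SNR of 50 the
kurtosis estimates at the two longest separations sit at the noise floor
(signals at b = 5000 s/mm², Δ ≥ 500 ms are below σ), so per-sample
exchange-time fits are ill-conditioned there; the report therefore also
fits the SEM-weighted group-mean kurtosis curve, which is the
better-conditioned quantity (and still honest about the apoptotic group,
whose long-Δ curve carries little information at this SNR).

## Study-level statistics

Pooled-variance two-sided two-sample t-tests per parameter (Welch
selectable); no multiple-testing correction across the handful of
parameters, stated in the report header.  Percent changes are reported
under two conventions — change of group means, and mean of
per-sample-pair changes — because they genuinely differ; neither is
preferred silently.

## Problem sizes and runtimes

Noiseless recovery fits (20 starts) take ~1 s each; a full 20-sample study
with 20 starts per sample fits in ~15 s; the ODE-oracle sweep uses 100
parameter draws × 13 protocol points; the MC-vs-series acceptance check
(6000 walkers, dt = 6 μs, 800 ms) runs in ~2 min.  These sizes were chosen
so the whole suite runs comfortably on one CPU while keeping every
statistical assertion well-powered.

## Known limitations

- Narrow-pulse sphere model in a crossover regime (δ ~ r²/D_I): radii are
  effective values.
- Effective relaxation rates (single-evolution-time convention).
- The exchange-time ↔ two-pool-rate bridge is approximate by construction
  (factor ~2 at the control condition), consistent with the two
  descriptions' differing validity regimes.
- The acquisition's published point count (49/42) is internally
  inconsistent with its printed 9-separation × 7-b grid; the package
  follows the printed grid (63 points, 54 fitted after b = 0 exclusion).
- Per-sample exchange-time fits from 4 kurtosis points are ill-conditioned
  at realistic noise; prefer the group-mean fit the report provides.
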