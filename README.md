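# steamdiff

Two-pool water-exchange modelling of long-diffusion-time stimulated-echo
(STEAM) diffusion MRI.

## The problem

Apoptosis — the programmed cell death that most chemo- and radiotherapies
try to induce — shrinks cells, lowers the intracellular water fraction and
makes membranes leakier, all well before a tumour changes size.  Diffusion
MRI at long diffusion times is sensitive to exactly these microstructural
quantities: water molecules have time to explore whole cells and to cross
membranes, so the signal carries information about cell radius *r*,
intracellular water fraction *M*<sub>I0</sub>, and the transmembrane
exchange rate *k*<sub>IE</sub>.  STEAM stores magnetization longitudinally
during the mixing time, which makes diffusion times up to hundreds of
milliseconds practical (conventional spin-echo would have lost the signal
to T2 decay long before).

`steamdiff` implements the quantitative analysis for this kind of
experiment — in-vitro cell-pellet studies with a control and an apoptotic
group — as a tested, reusable pipeline, together with a synthetic-data
generator that emulates the acquisition (9 gradient separations from 16 to
800 ms, 7 b-values from 0 to 5000 s/mm², δ = 4 ms, TE = 35 ms, Rician
magnitude noise).

## The model

The longitudinal magnetizations of the intracellular (I) and extracellular
(E) pools evolve during the diffusion interval under the Kärger-type
coupled equations

```
dM_I/dt = −q² D_I^app(t_D) M_I − R1_I M_I − k_IE M_I + k_EI M_E
dM_E/dt = −q² D_E^app       M_E − R1_E M_E − k_EI M_E + k_IE M_I
```

with q² = b/t_D, diffusion time t_D = Δ − δ/3, detailed balance
k_EI = k_IE·M_I0/(1 − M_I0), and the intracellular pool modelled as an
impermeable sphere of radius *r*: D_I^app(t) is the narrow-pulse apparent
diffusivity ⟨z²(t)⟩/2t from the eigenmode expansion over roots of
j₁′(α) = 0, which runs from the intrinsic D_I at t → 0 to the
r²/5t plateau at long times.  The 2×2 system is solved in closed form
(matrix exponential), and all b-values and diffusion times are fitted
jointly — eight parameters, with D_I conventionally fixed at 1.7 μm²/ms —
by bounded trust-region least squares with seeded multi-starts, weighted
by the per-point noise σ; fit quality is the reduced χ².

Two complementary signal representations are included:

* per-separation cumulant fits `S = S0·exp(−b·D + b²D²K/6)` giving ADC and
  kurtosis *K* versus diffusion time;
* the time-dependent kurtosis exchange model
  `K(t) = K0·(2τ/t)·[1 − (τ/t)(1 − e^(−t/τ))] + K∞` with
  1/τ_ex = k_IE + k_EI, fitted to the longest separations, plus the
  kurtosis-peak relations `f = K0/(3+K0)`,
  `t_peak = (6/5)√(t_r·t_c)`, `t_c = r²/D_I`, `t_r = τ_ex/(1−f)` that
  disentangle radius from exchange.

Confidence intervals come from χ² contours: a parameter pair is fixed and
marched away from the optimum, re-optimizing the rest, until the
constrained reduced χ² crosses the F-distribution threshold.

## Worked example

Generate a noiseless control-condition dataset on the full 9×7 STEAM grid,
fit the two-pool model, and run the kurtosis chain:

```python
import numpy as np
from steamdiff import *

ds = generate_dataset(CONTROL_PRESET, default_protocol(), NoiseSpec(snr=np.inf))
res = fit_two_pool(ds, fixed={"d_i": 1.7}, n_starts=20, seed=1)
p = res.params
print(f"m_i0 = {p.m_i0:.3f}   r = {p.r:.2f} um   k_ie = {p.k_ie:.2f} s^-1")

pts = kurtosis_series(ds)
exch = fit_kurtosis_exchange(pts)
t_peak, _ = find_kurtosis_peak(pts)
print(f"K0 = {exch.k0:.2f}   tau_ex = {exch.tau_ex:.0f} ms")
print(f"total exchange rate 1/tau = {exchange_rate_from_tau(exch.tau_ex):.1f} s^-1"
      f"   kurtosis peak at Delta = {t_peak:.0f} ms")
```

prints

```
m_i0 = 0.550   r = 4.20 um   k_ie = 4.00 s^-1
K0 = 2.23   tau_ex = 242 ms
total exchange rate 1/tau = 4.1 s^-1   kurtosis peak at Delta = 150 ms
```

The joint fit recovers the generating parameters exactly (intracellular
fraction 0.55, radius 4.2 μm, exchange rate 4 s⁻¹).  The kurtosis route,
fitted to the same signals, sees the *total* exchange rate
k_IE + k_EI ≈ 8.9 s⁻¹ only approximately (4.1 s⁻¹, within its expected
factor-of-two agreement) and places the kurtosis peak at Δ = 150 ms —
longer cells-worth of diffusion in the control condition than in the
apoptotic one, whose peak sits at 80 ms.

A full two-group study (simulate → fit → compare, with tables, figures and
a JSON report) runs from a config file:

```sh
steamdiff all config.yaml --out results_dir
```

```yaml
# config.yaml
study:
  synthetic: {n_per_group: 10, snr: 50, seed: 1, noise: rician}
fit:
  n_starts: 20
  seed: 0
  fixed: {d_i: 1.7, r1_i: 0.0}
kurtosis: {use: four-longest}
```

Group comparisons use a pooled-variance two-sample t-test; percent changes
are reported both from group means and as means of per-sample-pair
changes.

## Layout

- `steamdiff.protocol` — acquisition/dataset types, units, CSV/JSON I/O
- `steamdiff.sphere` — restricted-sphere apparent diffusivity (eigen-series)
- `steamdiff.model` — two-pool exchange forward model (closed-form propagator)
- `steamdiff.fitting` — joint fit, χ²-contour intervals, IR-T1/CPMG-T2
- `steamdiff.kurtosis` — ADC/kurtosis chain, exchange-time and peak analysis
- `steamdiff.synthetic` — protocol/presets, Rician generator, MC sphere walk
- `steamdiff.reporting`, `steamdiff.cli` — study pipeline, stats, CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults,
numerical choices and known limitations.
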