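# ptirf

Single-vesicle fusion pore analysis for polarized TIRF microscopy.

`ptirf` analyzes fluorescence movies of single small unilamellar vesicles
(SUVs) docking onto and fusing with a supported lipid bilayer (SBL) under
total internal reflection fluorescence (TIRF) excitation. From the
intensity time course of each fusion event it recovers the lipid release
kinetics, the size of the fusing vesicle, and the *pore openness*
`Po` — the fraction of time the flickering fusion pore spends open — and
it calibrates the pure-polarization contribution to the intensity change
upon fusion. It is aimed at researchers running SUV–SBL (or virus–SBL)
fusion assays who want per-event pore kinetics without single-particle
tracking of individual lipids.

## The model

A docked vesicle appears as a diffraction-limited spot of intensity
`I_dock`. At fusion the dye gains brightness by a factor `G = 1/λ_TIRF`
(the dye sits closer to the interface in the SBL and may be excited more
efficiently depending on the excitation polarization), is released with
time constant `τ_release`, spreads by 2D diffusion (`D_lip`), and
photobleaches (`τ_bleach`, proportional to excitation). The total
intensity inside a circle of radius `R`, normalized by `I_dock`, is

```
I(R,t) = I_docked(R,t) + I_release(R,t)

I_docked  = e^-(t-t_dock)/τ_bleach · F_psf(R)        · {0; 1; e^-(t-t_fus)/τ_release}
I_release = G e^-G(t-t_fus)/τ_bleach · F_spread(R,Δt) · {0; 1 - e^-(t-t_fus)/τ_release}
```

where `F_psf(R) = 1 - exp(-R²/2σ²)` is the encircled energy of a Gaussian
PSF and `F_spread(R,Δt) = 1 - exp(-R²/(2σ² + 4 D_lip Δt))` its
convolution with the 2D diffusion Green's function. Five nested circular
ROIs (radii 3, 5, 7, 9, 11 px) are fitted simultaneously by weighted
least squares with free parameters `(G, D_lip, τ_release, τ_bleach)`.

Per-event physics then follow from exact algebra:

* vesicle area `A_ves = I_dock / (λ_TIRF · I_lip · 2ρ_lip)` with `I_lip`
  the single-lipid intensity in the SBL and `ρ_lip` the label density;
* diffusive dwell time `τ_ves = A_ves / D_lip`;
* pore openness `Po = g · τ_ves / τ_release` with the geometry factor
  `g = b / (2π r_p)` (pore height `b` = 15 nm, open-pore radius `r_p` =
  3 nm); `Po ≥ 1` marks diffusion-limited release;
* SNARE copies `N_SNARE = A_ves / (LP · a_lip)` and curvature `C = 2/R_ves`.

A population calibration fits `λ_TIRF` vs. vesicle radius and
extrapolates to zero size with the x-intercept constrained at the
evanescent depth `δ_TIRF = λ₀/4π (n_g² sin²θ − n_w²)^{-1/2}`, isolating
the pure polarization factor `λ_TIRF0`.

A seeded simulator generates the same experiment at two fidelities —
closed-form noisy traces, and particle-level movies in which every
labeled lipid is an individual emitter escaping through an explicitly
flickering two-state pore, walking in the bilayer, and bleaching — so
every stage of the pipeline can be validated against known ground truth.

## Worked example

```python
import numpy as np
from ptirf import (OpticalConfig, SimulationConfig, sample_population,
                   simulate_trace, extract_event_anchors, fit_event,
                   EventSummary)

cfg = SimulationConfig(n_events=1, seed=42)
event = sample_population(cfg)[0]          # ground truth
trace = simulate_trace(event, cfg)         # noisy five-ROI traces
anchors = extract_event_anchors(trace)
result = fit_event(trace, anchors, cfg.optics)
print(result.summary())
summary = EventSummary.from_fit(
    0, anchors.i_dock, result.params.gain, result.params.d_lip_um2_s,
    result.params.tau_release_s, result.params.tau_bleach_s, i_lip=50.0)
print(f"R_ves = {summary.r_ves_nm:.1f} nm   Po = {summary.po:.3f} "
      f"({summary.release_class})   true Po = {event.po:.3f}")
```

prints

```
Radial fusion trace fit
======================================================
event id           0
observations       650 (5 ROIs x frames)
reduced chi-square 1.225e-05
R-squared          1.0000
status             accepted
------------------------------------------------------
parameter           estimate     std err
G (gain)               2.199    0.000847
D_lip [um2/s]          1.106     0.00115
tau_release [s]      0.02982    6.71e-05
tau_bleach [s]         2.029     0.00129
------------------------------------------------------
lambda_TIRF = 1/G  0.4548
R_ves = 50.9 nm   Po = 0.785 (pore_limited)   true Po = 0.787
```

(the default configuration adds no read noise; the residual ~1%
parameter deviation comes from anchoring `I_dock` on the first three
docked frames, which already carry a little bleach — set e.g.
`cfg.gaussian_sd = 500` for a realistically noisy trace). `G = 2.20`
means each dye brightens 2.2-fold on transfer into the bilayer;
`Po = 0.79` means the pore was effectively open 79% of the time while
the labels escaped.

The same pipeline is available from the shell:

```
ptirf depth --incidence-deg 72.2          # evanescent depth: 78.2 nm
ptirf simulate-stack --seed 3 --out run/  # particle-level movie + tracks
ptirf fit --stack run/stack.tif --tracks run/tracks.csv --out run/fits.csv
ptirf metrics --fits run/fits.csv --out run/results/
ptirf calibrate --events run/results/events.csv --out run/calibration.json
```

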