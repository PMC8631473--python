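# Methods

## Scope and model

`ptirf` implements a quantitative analysis of single SUV–SBL fusion
events imaged by (polarized) TIRF microscopy. The measured quantity is
the background-subtracted total intensity in five nested circular ROIs
around a docked vesicle, from 10 frames before docking to 50 frames
after fusion. The generative model for the normalized trace family is
the sum of a vesicle-retained and a released component:

* **Docked component.** A stationary point source blurred by the PSF,
  with encircled energy `F_psf(R) = 1 − exp(−R²/2σ²)` for an isotropic
  Gaussian PSF of width σ. It bleaches with time constant `τ_bleach`
  from docking and, after fusion, drains into the bilayer with release
  time `τ_release` (pore-limited, exponential kinetics).
* **Released component.** Carries the per-dye gain `G = 1/λ_TIRF` (dye
  in the bilayer sits closer to the interface and, depending on the
  excitation polarization, is excited more or less efficiently than in
  the vesicle), bleaches `G` times faster (bleaching ∝ excitation), and
  spreads radially as the PSF convolved with the 2D diffusion Green's
  function `(1/4πDt) exp(−r²/4Dt)`. Gaussian ⊗ Gaussian is Gaussian, so
  the encircled energy stays closed-form:
  `F_spread(R,Δt) = 1 − exp(−R²/(2σ² + 4 D_lip Δt))`.

An alternative `inverse_time` kinetics mode replaces the exponential
retained fraction with `min(1, τ_ves/Δt)`, the diffusion-limited law for
an unrestricted pore; the cap at 1 removes the 1/t divergence at short
times. The default pipeline fits the pore-limited (exponential) form and
flags events whose derived openness reaches 1 as diffusion-limited,
mirroring how such events are classified in practice.

**Known approximation.** The released term starts "fresh" at the fusion
time: the model does not book the docked-phase bleaching history of dye
that is later released, and the released pool's bleach clock runs from
fusion rather than from each molecule's own escape. For long
docking-to-fusion delays this overestimates the released amplitude by
roughly `exp(τ_dock/τ_bleach)`; equivalently, fits to data in which the
released dye *did* bleach while docked underestimate `G` by the inverse
factor. The particle simulator exposes both conventions (see below).

## Fitting

The five ROI traces are normalized by `I_dock` (mean of the first three
docked frames of the largest ROI, background-subtracted; the window
trades shot noise against bleach bias and is configurable) and fitted
simultaneously by weighted least squares with free parameters
`(G, D_lip, τ_release, τ_bleach)`; docking and fusion times are held at
their annotated frames (an optional ±1-frame refinement by best
chi-square exists and is off by default). Weights are `1/σ_i²` per ROI
with `σ_i` the pre-dock sample SD; for noiseless synthetic traces the
weights fall back to unity. The nested ROIs are correlated (the smaller
ROI is a subset of the larger); no whitening is attempted, matching the
simultaneous-fit convention of the assay, so the reported standard
errors are approximate.

Numerics: trust-region-reflective least squares with bounds
`G ∈ [0.05, 20]`, `D_lip ∈ [0.01, 20] µm²/s`, `τ_release ∈ [1 ms, 60 s]`,
`τ_bleach ∈ [10 ms, 600 s]`; multi-start over the release timescale
(1.5, 5 and 25 frames) because sub-frame release and dimming events
(`G < 1`) otherwise strand the optimizer in a local minimum; covariance
from the weighted Jacobian scaled by the residual variance. Events with
docking-to-fusion delays under 4 frames are excluded (`short_dock`), and
fits are flagged `poor_fit` when they fail to converge, pin a parameter
at a bound, exceed reduced chi-square 3, or return a release-time
standard error above 100% — an explicit, configurable stand-in for
visual fit triage. Note the chi-square gate is calibrated for traces
whose noise matches the pre-dock level; on shot-noise-limited movies the
bright phase is necessarily over-dispersed relative to the dark pre-dock
window and the gate threshold should be raised (the validation studies
disable it).

## Per-event physics

Exact algebra converts the fit into physics: `A_ves = I_dock /
(λ_TIRF · I_lip · 2ρ_lip)` (both leaflets carry label),
`R_ves = √(A_ves/4π)`, `τ_ves = A_ves/D_lip`,
`Po = g·τ_ves/τ_release` with `g = b/(2π r_p)` (defaults b = 15 nm,
r_p = 3 nm, so g ≈ 0.80; r_p includes half the bilayer thickness),
`N_SNARE = A_ves/(LP·a_lip)` with `a_lip` = 0.70 nm², and curvature
`C = 2/R_ves`. Raw `Po ≥ 1` is reported as `Po = 1` with the raw value
kept in a diagnostic column. Defaults describe 1 mol% labeling and
LP = 400 (≈3600 SNARE copies/µm²; about half face outward because
reconstitution orientation is random).

Population trends (open-pore fraction vs. SNARE copies or curvature,
and the flickering-branch moving-average + OLS line with 95% t-based
CIs) smooth *both* coordinates with the same span-5 moving average so an
exactly linear relation survives smoothing.

## Calibration

Three empirical population relations are fitted by unweighted nonlinear
least squares in natural space — `λ = a₁e^{−b₁x}` and `R = a₂x^{b₂}`
against the normalized docked intensity `x = I_dock/I_lip`, and
`λ = a₃e^{−b₃R}` against radius — with binned mean ± SD overlays (bin
width 2 on intensity axes, 1 nm on radius) that never enter the fits.
The pure polarization factor comes from a one-parameter line
`λ = s(R − δ_TIRF)` fitted to events with `R ≤ 35 nm`, giving
`λ_TIRF0 = −s·δ_TIRF` with a CI propagated from the slope's t-interval
(δ treated as exact). This line is the tangent of the size–excitation
curve at the origin: the curve
`λ(R) = λ₀ (δ/2R)(1 − e^{−2R/δ})` — the surface average of the
evanescent intensity over a sphere tangent to the bilayer plane — is
convex, so the estimate carries a small positive truncation bias
(≈ +1.5% at a 20 nm cutoff, ≈ +4% at the default 35 nm, ≈ +5% at δ/2)
that vanishes as the cutoff shrinks. Where `λ_TIRF0 > 1` the
polarization and field-decay contributions cancel at
`R* = ln(a₃)/b₃`; for `a₃ ≤ 1` no crossing exists and `R*` is reported
as absent. Single-lipid intensities at polarizations where tracking is
impractical are transferred by the ratio of the fitted mean-SBL
sinusoid `A + B cos 2(θ − θ₀)`.

Optics constants: `δ_TIRF = λ₀/4π (n_g² sin²θ − n_w²)^{−1/2}`
(561 nm, n_g = 1.52, n_w = 1.33 by default; 78 nm at θ = 72.2°). The
PSF width defaults to `0.21·λ_em/NA ≈ 85 nm` (590 nm emission, NA 1.45)
and is configurable; angles are degrees at every interface, lengths nm,
times s, diffusivities µm²/s.

## Simulator

The simulator defines the validation conditions of the package.

* **Population.** Vesicle radii log-normal, median 45 nm, geometric SD
  1.5, truncated to 10–100 nm (the 20–200 nm diameter range of extruded
  SUVs); openness uniform on [0.1, 0.9] by default (events outside that
  range are either unresolvable within a frame time or degenerate with
  the capped class); `D_lip` = 1.1 µm²/s, `τ_bleach` = 2 s, single-lipid
  intensity 50 counts/frame, 265 nm pixels, 18.3 ms frames. Everything
  downstream follows from the forward model: `λ_TIRF` from the tangent-
  sphere average, `I_dock` from the area and label density,
  `τ_release = g·τ_ves/Po`. One root seed spawns per-event child seeds;
  identical configuration ⇒ byte-identical output.
* **Trace level** evaluates the closed-form model exactly (bit-matching
  in noiseless mode) and adds per-ROI Gaussian noise scaled by
  √(pixel count) from the configured SD at the largest ROI, plus
  optional Poisson shot noise on total counts.
* **Particle level** renders every labeled lipid: a docked spot of
  `n_alive·λ_TIRF·I_lip`, then independent emitters of `I_lip`
  performing Brownian walks (per-frame displacement SD `√(2DΔt)` per
  axis) after their escape times, with pixel-integrated Gaussian spots,
  Poisson shot noise, camera gain and Gaussian read noise. Escape times
  are exponential by default, or generated by the explicit two-state
  flickering pore: exponentially distributed open/closed periods (means
  `τ_o`, `τ_c`, starting open), escape as a Poisson process with rate
  `1/(g·τ_ves)` while open, so the openness law holds exactly in the
  fast-flicker limit. The default flicker period is 5 ms — the
  micro-rates are not observable in this assay and only the duty cycle
  matters for the traces. All lipids of one event share one pore
  sequence, so ensemble statistics must pool over events.
* **Bleach bookkeeping.** `bleach_mode="model"` (default) realizes the
  closed-form model exactly (released survival referenced to fusion, no
  docked-history carryover), making rendered stacks unbiased ground
  truth for the fitter. `bleach_mode="physical"` carries each lipid's
  docked bleach fate into the released phase; fitting such stacks shows
  the `exp(−τ_dock/τ_bleach)` bias of the model's release term.

What the simulator does **not** emulate — and hence what passing
validation does not demonstrate about laboratory data: dequenching at
high label density, elliptical/vectorial evanescent polarization and
dipole-orientation photoselection (polarization enters only through the
scalar `λ_TIRF0` and the single-lipid intensity), EMCCD excess noise,
focus drift, vesicle mobility before docking, hemifusion, annotation
error in the docking/fusion frames (held fixed in fits), and event
detection itself (events are given, as in the visually-annotated assay).

## Validation studies and problem sizes

The studies behind `scripts/acceptance.py` (and mirrored in the test
suite) use problem sizes chosen to make their statistical targets
measurable at desk scale: a 10×10×5 grid for the closed-form vs.
numeric-convolution oracle (FFT on a 1024² grid, max |Δ| < 10⁻³); 20
noiseless round trips (max relative error ~10⁻¹⁵); 200 noisy traces at
peak SNR 20 (median errors ~4% for G and τ_release); 50 particle-level
64×64×200 stacks through the full pipeline (Po median absolute error
~0.07, R_ves ~2%); and ≥10⁴ flicker escapes per branch. Population-scale
quantities that depend on the laboratory event set (the observed Po
distribution, the published per-polarization calibration coefficients
and equal-contribution radii) are *not* reproduced by simulation; the
same functional forms are instead verified by exact noiseless-recovery
tests.

## Design choices

* Gaussian PSF so the five-ROI model stays analytic; a numeric-PSF path
  (rasterized convolution) exists for validation and for tabulated
  profiles.
* "Integral of the PSF to radius R" is interpreted as encircled energy
  (2πr-weighted), the total of a radially symmetric image over a disk.
* ROI membership is by pixel-center distance (no partial-area
  weighting): a radius-3 disk contains 29 pixels.
* The vesicle is tangent to the bilayer plane (closest approach z = 0);
  the PEG cushion offset is ignored, consistent with treating R → 0 as
  the zero-decay limit.
* Frames are 0-based, `t = frame × frame_interval`; pixel coordinates
  are 0-based at pixel centers.
* Normalization uses `I_dock` as measured at docking (not a bleach-free
  extrapolation); the resulting ~1% bias at default conditions is below
  the noise floor of realistic traces.
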