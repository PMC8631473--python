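"""Closed-form forward model of a docking -> fusion -> release -> bleach event.

The total background-subtracted intensity inside a circle of radius R,
normalized by the docked-vesicle intensity, is the sum of a vesicle-retained
component and a released component:

``I(R, t) = I_docked(R, t) + I_release(R, t)``

The docked component is a stationary point source blurred by the microscope
PSF, bleaching at rate 1/tau_bleach and losing label to the bilayer with
release time tau_release after fusion.  The released component carries the
gain G = 1/lambda_TIRF (a dye is brighter in the bilayer than in the
vesicle), bleaches G times faster (bleaching is proportional to excitation),
and spreads radially as the PSF convolved with the 2D diffusion Green's
function ``(1/(4 pi D t)) exp(-r^2 / (4 D t))``.

With an isotropic Gaussian PSF of width sigma, both encircled energies are
analytic: Gaussian (+) Gaussian convolution is Gaussian, so the released
profile at delay dt has per-axis variance ``sigma^2 + 2 D dt``.

Units: lengths nm, times s, diffusivity um^2/s (converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "EventTimes",
    "FitParams",
    "psf_encircled_fraction",
    "spread_encircled_fraction",
    "numeric_spread_encircled_fraction",
    "model_total",
]

UM2_PER_S_TO_NM2_PER_S = 1.0e6

Kinetics = Literal["exponential", "inverse_time"]


@dataclass
class EventTimes:
    """Docking and fusion instants of one event, in seconds."""

    t_dock: float
    t_fusion: float

    def __post_init__(self) -> None:
        if self.t_fusion < self.t_dock:
            raise ValueError("t_fusion must be >= t_dock")

    @property
    def dock_to_fusion_delay(self) -> float:
        return self.t_fusion - self.t_dock


@dataclass
class FitParams:
    """Free parameters of the radial trace model with uncertainties.

    ``gain`` is G = 1/lambda_TIRF, the per-dye intensity gain upon transfer
    from vesicle to bilayer.  ``tau_release_s`` is the exponential lipid
    release time (the diffusive dwell time tau_ves in inverse-time mode).
    Standard errors and fit diagnostics are populated by the fitter and
    default to NaN for hand-constructed parameter sets.
    """

    gain: float
    d_lip_um2_s: float
    tau_release_s: float
    tau_bleach_s: float
    gain_stderr: float = float("nan")
    d_lip_stderr: float = float("nan")
    tau_release_stderr: float = float("nan")
    tau_bleach_stderr: float = float("nan")
    red_chi2: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("gain", "d_lip_um2_s", "tau_release_s", "tau_bleach_s"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite")

    @property
    def lambda_tirf(self) -> float:
        return 1.0 / self.gain


def psf_encircled_fraction(radius_nm, psf_sigma_nm: float):
    """Fraction of a Gaussian PSF's energy inside a circle of radius R.

    ``1 - exp(-R^2 / (2 sigma^2))``, in [0, 1), monotone in R.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be > 0")
    r = np.asarray(radius_nm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius_nm must be >= 0")
    out = -np.expm1(-(r * r) / (2.0 * psf_sigma_nm**2))
    return float(out) if np.isscalar(radius_nm) else out


def spread_encircled_fraction(
    radius_nm, dt_s, d_lip_um2_s: float, psf_sigma_nm: float
):
    """Encircled energy of the PSF convolved with the diffusion kernel.

    At delay dt after release the radial profile is Gaussian with per-axis
    variance ``sigma^2 + 2 D dt``, so the encircled fraction is
    ``1 - exp(-R^2 / (2 sigma^2 + 4 D dt))``.  Reduces to
    :func:`psf_encircled_fraction` at dt = 0 and decreases with dt at
    fixed R.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be > 0")
    if d_lip_um2_s <= 0:
        raise ValueError("d_lip_um2_s must be > 0")
    r = np.asarray(radius_nm, dtype=float)
    dt = np.asarray(dt_s, dtype=float)
    if np.any(r < 0) or np.any(dt < 0):
        raise ValueError("radius and dt must be >= 0")
    d_nm2 = d_lip_um2_s * UM2_PER_S_TO_NM2_PER_S
    var2 = 2.0 * psf_sigma_nm**2 + 4.0 * d_nm2 * dt
    out = -np.expm1(-(r * r) / var2)
    if np.isscalar(radius_nm) and np.isscalar(dt_s):
        return float(out)
    return out


def numeric_spread_encircled_fraction(
    radius_nm: float,
    dt_s: float,
    d_lip_um2_s: float,
    psf_sigma_nm: float,
    grid_half_width_nm: float | None = None,
    n_grid: int = 1024,
) -> float:
    """Numeric-PSF validation path: FFT convolution plus disk integration.

    Rasterizes the PSF and the diffusion Green's function on a square grid,
    convolves them by FFT, and sums pixels whose centers fall inside the
    disk.  Intended as an independent check of the closed form (and as a
    hook for tabulated, non-Gaussian PSF profiles); it is far too slow for
    fitting.
    """
    d_nm2 = d_lip_um2_s * UM2_PER_S_TO_NM2_PER_S
    sigma_eff = np.sqrt(psf_sigma_nm**2 + 2.0 * d_nm2 * dt_s)
    if grid_half_width_nm is None:
        grid_half_width_nm = max(6.0 * sigma_eff, 1.5 * radius_nm, 100.0)
    x = np.linspace(-grid_half_width_nm, grid_half_width_nm, n_grid)
    dx = x[1] - x[0]
    xx, yy = np.meshgrid(x, x, indexing="ij")
    rr2 = xx * xx + yy * yy
    psf = np.exp(-rr2 / (2.0 * psf_sigma_nm**2))
    psf /= psf.sum()
    if dt_s > 0:
        kern = np.exp(-rr2 / (4.0 * d_nm2 * dt_s))
        ks = kern.sum()
        if ks == 0:
            raise ValueError("diffusion kernel underflows the grid; widen it")
        kern /= ks
        img = np.fft.fftshift(
            np.fft.irfft2(
                np.fft.rfft2(np.fft.ifftshift(psf))
                * np.fft.rfft2(np.fft.ifftshift(kern)),
                s=psf.shape,
            )
        )
    else:
        img = psf
    return float(img[rr2 <= radius_nm**2].sum())


def _retained_fraction(dt, tau: float, kinetics: Kinetics):
    """Fraction of label still in the vesicle a time dt after pore opening."""
    if kinetics == "exponential":
        return np.exp(-dt / tau)
    if kinetics == "inverse_time":
        # diffusion-limited law phi = tau_ves / t, capped at 1 for t <= tau_ves
        with np.errstate(divide="ignore"):
            return np.minimum(1.0, np.where(dt > 0, tau / np.where(dt > 0, dt, 1.0), 1.0))
    raise ValueError(f"unknown kinetics {kinetics!r}")


def model_total(
    radius_nm,
    t_s,
    times: EventTimes,
    params: FitParams,
    psf_sigma_nm: float,
    kinetics: Kinetics = "exponential",
):
    """Normalized total intensity inside radius R at time t.

    The docked amplitude is normalized to 1 at ``t_dock`` (R -> infinity),
    so the model is directly comparable to traces divided by the docked
    intensity I_dock.  Zero before docking by contract.

    Parameters broadcast: ``radius_nm`` and ``t_s`` may be arrays
    (broadcast against each other).
    """
    r = np.asarray(radius_nm, dtype=float)
    t = np.asarray(t_s, dtype=float)
    g = params.gain
    tau_b = params.tau_bleach_s
    tau_r = params.tau_release_s

    dt_dock = t - times.t_dock
    dt_fus = t - times.t_fusion
    docked_mask = dt_dock >= 0
    fused_mask = dt_fus >= 0

    # vesicle-retained: bleach from docking, release drain after fusion
    retained = np.where(fused_mask, _retained_fraction(np.maximum(dt_fus, 0.0), tau_r, kinetics), 1.0)
    docked = (
        np.where(docked_mask, np.exp(-np.maximum(dt_dock, 0.0) / tau_b), 0.0)
        * psf_encircled_fraction(r, psf_sigma_nm)
        * retained
    )

    # released: appears at fusion with gain G, bleaches G-fold faster, spreads
    released_frac = np.where(fused_mask, 1.0 - retained, 0.0)
    spread = spread_encircled_fraction(
        r, np.maximum(dt_fus, 0.0), params.d_lip_um2_s, psf_sigma_nm
    )
    released = (
        g
        * np.where(fused_mask, np.exp(-g * np.maximum(dt_fus, 0.0) / tau_b), 0.0)
        * spread
        * released_frac
    )

    out = docked + released
    if np.isscalar(radius_nm) and np.isscalar(t_s):
        return float(out)
    return out
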