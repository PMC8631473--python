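"""Evanescent-field optics for objective-type TIRF excitation.

The excitation intensity of a totally internally reflected beam decays
exponentially away from the glass-water interface with a characteristic
depth ``delta_TIRF`` set by the wavelength, the two refractive indices and
the incidence angle.  A docked vesicle therefore samples a weaker field
than a fluorophore resident in the supported bilayer, and the reduction
grows with vesicle size.  This module provides the depth formula, the
size-dependent mean excitation of a sphere tangent to the bilayer plane,
and the sinusoidal polarization response of the mean bilayer intensity.

All angles are accepted in degrees; lengths in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "PolarizationSetting",
    "evanescent_depth",
    "vesicle_mean_excitation",
    "sbl_polarization_response",
    "fit_sbl_polarization_response",
]

#: Default Gaussian PSF width: 0.21 * lambda_em / NA with lambda_em = 590 nm
#: (lissamine rhodamine emission) and NA = 1.45.
DEFAULT_PSF_SIGMA_NM = 0.21 * 590.0 / 1.45


def evanescent_depth(
    wavelength_nm: float,
    n_glass: float = 1.52,
    n_water: float = 1.33,
    incidence_deg: float = 72.2,
) -> float:
    """Evanescent-field 1/e intensity decay depth in nm.

    ``delta = lambda0 / (4 pi) * (ng^2 sin^2(theta) - nw^2)^(-1/2)``

    Parameters
    ----------
    wavelength_nm : float
        Vacuum excitation wavelength (nm).
    n_glass, n_water : float
        Refractive indices of the substrate and the aqueous medium.
    incidence_deg : float
        Beam incidence angle measured from the interface normal, degrees.
        Must exceed the critical angle ``arcsin(nw/ng)``.

    Returns
    -------
    float
        Penetration depth in nm; diverges as the angle approaches the
        critical angle from above.
    """
    if not (n_glass > n_water > 1.0):
        raise ValueError("require n_glass > n_water > 1")
    critical_deg = math.degrees(math.asin(n_water / n_glass))
    if incidence_deg <= critical_deg:
        raise ValueError(
            f"incidence angle {incidence_deg:.3f} deg does not exceed the "
            f"critical angle {critical_deg:.3f} deg: no total internal "
            "reflection"
        )
    if incidence_deg > 90.0:
        raise ValueError("incidence angle must be <= 90 deg")
    s = n_glass * math.sin(math.radians(incidence_deg))
    return wavelength_nm / (4.0 * math.pi) / math.sqrt(s * s - n_water**2)


@dataclass
class OpticalConfig:
    """Optical and acquisition constants of the TIRF setup.

    Defaults follow a 561 nm objective-type configuration on glass/water
    with a 265 nm pixel and ~56 Hz streaming acquisition.
    """

    excitation_wavelength_nm: float = 561.0
    n_glass: float = 1.52
    n_water: float = 1.33
    incidence_deg: float = 72.2
    pixel_size_nm: float = 265.0
    frame_interval_s: float = 0.0183
    exposure_s: float = 0.0178
    psf_sigma_nm: float = DEFAULT_PSF_SIGMA_NM
    evanescent_depth_nm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not (self.frame_interval_s >= self.exposure_s > 0):
            raise ValueError("require frame_interval_s >= exposure_s > 0")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        # raises below the critical angle, enforcing the TIR invariant
        self.evanescent_depth_nm = evanescent_depth(
            self.excitation_wavelength_nm,
            self.n_glass,
            self.n_water,
            self.incidence_deg,
        )

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.excitation_wavelength_nm,
            "n_glass": self.n_glass,
            "n_water": self.n_water,
            "incidence_deg": self.incidence_deg,
            "pixel_nm": self.pixel_size_nm,
            "frame_interval_s": self.frame_interval_s,
            "exposure_s": self.exposure_s,
            "psf_sigma_nm": self.psf_sigma_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(
            excitation_wavelength_nm=d.get("wavelength_nm", 561.0),
            n_glass=d.get("n_glass", 1.52),
            n_water=d.get("n_water", 1.33),
            incidence_deg=d.get("incidence_deg", 72.2),
            pixel_size_nm=d.get("pixel_nm", 265.0),
            frame_interval_s=d.get("frame_interval_s", 0.0183),
            exposure_s=d.get("exposure_s", 0.0178),
            psf_sigma_nm=d.get("psf_sigma_nm", DEFAULT_PSF_SIGMA_NM),
        )


@dataclass
class PolarizationSetting:
    """Excitation polarization state and its calibrated quantities.

    ``polarization_deg`` is 0 for s-pol (field perpendicular to the plane
    of incidence) and 90 for p-pol.  ``lambda0_pol`` is the pure
    polarization contribution to the intensity reduction factor at zero
    vesicle size; ``single_lipid_intensity`` is the mean per-frame counts
    of one lipid label resident in the supported bilayer at this angle.
    """

    polarization_deg: float = 0.0
    lambda0_pol: float = 0.82
    single_lipid_intensity: float = 50.0

    def __post_init__(self) -> None:
        if self.lambda0_pol <= 0:
            raise ValueError("lambda0_pol must be > 0")
        if self.single_lipid_intensity <= 0:
            raise ValueError("single_lipid_intensity must be > 0")


def vesicle_mean_excitation(
    radius_nm, depth_nm: float, lambda0: float = 1.0
):
    """Mean excitation of a spherical vesicle tangent to the bilayer plane.

    The vesicle surface samples the evanescent intensity ``exp(-z/delta)``
    uniformly in height z over [0, 2R] (area element of a sphere is uniform
    in z), giving

    ``lambda(R) = lambda0 * (delta / 2R) * (1 - exp(-2R/delta))``

    which tends to ``lambda0`` as R -> 0 with initial slope
    ``-lambda0/delta``, and decreases monotonically with R.

    Parameters
    ----------
    radius_nm : float or array
        Vesicle radius (nm), >= 0.
    depth_nm : float
        Evanescent depth (nm).
    lambda0 : float
        Pure polarization factor multiplying the geometric average.
    """
    if depth_nm <= 0:
        raise ValueError("depth_nm must be > 0")
    if lambda0 <= 0:
        raise ValueError("lambda0 must be > 0")
    r = np.asarray(radius_nm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius_nm must be >= 0")
    x = 2.0 * r / depth_nm
    # -expm1(-x)/x is accurate for small x; limit 1 at x=0
    with np.errstate(invalid="ignore"):
        out = np.where(x > 0, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0)
    result = lambda0 * out
    return float(result) if np.isscalar(radius_nm) else result


def sbl_polarization_response(
    polarization_deg, amplitude: float, modulation: float, phase_deg: float
):
    """Mean bilayer intensity vs excitation polarization angle.

    A two-fold symmetric sinusoid ``A + B cos(2 (theta - theta0))`` with a
    180-degree period: rotating the excitation field by half a turn leaves
    the intensity of an in-plane dipole population unchanged.
    """
    if not (amplitude > abs(modulation)):
        raise ValueError("require amplitude > |modulation|")
    th = np.radians(np.asarray(polarization_deg, dtype=float))
    th0 = math.radians(phase_deg)
    out = amplitude + modulation * np.cos(2.0 * (th - th0))
    return float(out) if np.isscalar(polarization_deg) else out


def fit_sbl_polarization_response(polarization_deg, intensity):
    """Recover (A, B, theta0) of the polarization sinusoid from samples.

    Linearizes ``A + B cos(2(theta - theta0))`` as
    ``A + c cos(2 theta) + s sin(2 theta)`` and solves by least squares;
    exact on noiseless data at >= 3 distinct angles.

    Returns
    -------
    (amplitude, modulation, phase_deg) : tuple of float
        ``modulation >= 0`` and ``phase_deg`` in [0, 180).
    """
    th = np.radians(np.asarray(polarization_deg, dtype=float))
    y = np.asarray(intensity, dtype=float)
    if th.shape != y.shape:
        raise ValueError("angle and intensity arrays must match in shape")
    if np.unique(np.round(th, 12)).size < 3:
        raise ValueError(
            "need at least 3 distinct polarization angles to fit the sinusoid"
        )
    X = np.column_stack([np.ones_like(th), np.cos(2 * th), np.sin(2 * th)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, c, s = coef
    b = math.hypot(c, s)
    th0 = 0.5 * math.atan2(s, c)
    phase_deg = math.degrees(th0) % 180.0
    return float(a), float(b), phase_deg
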