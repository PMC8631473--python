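"""Population calibration: empirical size-intensity relations and the
zero-size extrapolation of the pure polarization factor.

Across a population of fusion events, the intensity reduction factor
``lambda_TIRF`` and the normalized docked intensity ``I_dock / I_lip``
are linked through vesicle size.  Three empirical relations are fitted:

* ``lambda = a1 * exp(-b1 * I_dock/I_lip)``
* ``R_ves  = a2 * (I_dock/I_lip)^b2``
* ``lambda = a3 * exp(-b3 * R_ves)``

The evanescent-decay contribution vanishes as R_ves -> 0, so the pure
polarization factor ``lambda_TIRF0`` is obtained by fitting a line to
small-vesicle events (R_ves <= 35 nm by default) with the x-intercept
constrained at the independently measured evanescent depth:
``lambda = s * (R_ves - delta)`` giving ``lambda_TIRF0 = -s * delta``.

Where ``lambda_TIRF0 > 1`` (polarization reduces intensity on transfer),
the polarization and field-decay contributions cancel at the
equal-contribution radius R_ves* solving ``lambda(R) = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationResult",
    "fit_population_relations",
    "extrapolate_lambda0",
    "equal_contribution_radius",
    "polarization_correction",
]


@dataclass
class CalibrationResult:
    """Coefficients of the population fits with 95% confidence intervals."""

    a1: float = float("nan")
    b1: float = float("nan")
    a2: float = float("nan")
    b2: float = float("nan")
    a3: float = float("nan")
    b3: float = float("nan")
    ci: dict = field(default_factory=dict)  # name -> (lo, hi)
    constrained_slope_per_nm: float = float("nan")
    lambda_tirf0: float = float("nan")
    lambda_tirf0_ci: tuple[float, float] = (float("nan"), float("nan"))
    r_ves_star_nm: float | None = None
    n_events: int = 0
    n_small: int = 0
    binned: dict = field(default_factory=dict)  # relation -> DataFrame

    def to_dict(self) -> dict:
        return {
            "a1": self.a1, "b1": self.b1, "a2": self.a2, "b2": self.b2,
            "a3": self.a3, "b3": self.b3,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "constrained_slope_per_nm": self.constrained_slope_per_nm,
            "lambda_tirf0": self.lambda_tirf0,
            "lambda_tirf0_ci": list(self.lambda_tirf0_ci),
            "r_ves_star_nm": self.r_ves_star_nm,
            "n_events": self.n_events,
            "n_small": self.n_small,
        }

    def summary(self) -> str:
        def fmt_ci(name):
            lo, hi = self.ci.get(name, (float("nan"),) * 2)
            return f"({lo:.4g}, {hi:.4g})"

        star = f"{self.r_ves_star_nm:.1f} nm" if self.r_ves_star_nm else "none"
        return "\n".join([
            "Population calibration",
            "=" * 56,
            f"events: {self.n_events} (small-vesicle branch: {self.n_small})",
            f"lambda vs Idock/Ilip : a1={self.a1:.4g} {fmt_ci('a1')}, "
            f"b1={self.b1:.4g} {fmt_ci('b1')}",
            f"Rves   vs Idock/Ilip : a2={self.a2:.4g} {fmt_ci('a2')}, "
            f"b2={self.b2:.4g} {fmt_ci('b2')}",
            f"lambda vs Rves       : a3={self.a3:.4g} {fmt_ci('a3')}, "
            f"b3={self.b3:.4g} {fmt_ci('b3')}",
            f"constrained slope    : {self.constrained_slope_per_nm:.4g} /nm",
            f"lambda_TIRF0         : {self.lambda_tirf0:.4g} "
            f"(95% CI {self.lambda_tirf0_ci[0]:.4g}-{self.lambda_tirf0_ci[1]:.4g})",
            f"R_ves*               : {star}",
        ])


def _binned_summary(x: np.ndarray, y: np.ndarray, bin_size: float) -> pd.DataFrame:
    """Means +/- SD of y in fixed-width bins of x (reporting overlay only)."""
    lo = math.floor(x.min() / bin_size) * bin_size
    idx = np.floor((x - lo) / bin_size).astype(int)
    rows = []
    for b in np.unique(idx):
        m = idx == b
        rows.append({
            "bin_center": lo + (b + 0.5) * bin_size,
            "mean": float(y[m].mean()),
            "sd": float(y[m].std(ddof=1)) if m.sum() > 1 else 0.0,
            "n": int(m.sum()),
        })
    return pd.DataFrame(rows)


def _fit_with_ci(func, x, y, p0):
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: no spread in x")
    popt, pcov = curve_fit(func, x, y, p0=p0, maxfev=20000)
    dof = max(x.size - len(popt), 1)
    tval = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    cis = [(p - tval * s, p + tval * s) for p, s in zip(popt, se)]
    return popt, cis


def fit_population_relations(
    idock_over_ilip: Sequence[float],
    lambda_tirf: Sequence[float],
    r_ves_nm: Sequence[float],
    intensity_bin: float = 2.0,
    radius_bin_nm: float = 1.0,
) -> CalibrationResult:
    """Fit the three empirical population relations of the calibration.

    Nonlinear least squares in natural space with unit weights.  Binned
    means +/- SD (bin width 2 on the normalized-intensity axes, 1 nm on
    the radius axis) are attached as reporting overlays and never enter
    the fits.  Requires >= 10 events.
    """
    x = np.asarray(idock_over_ilip, dtype=float)
    lam = np.asarray(lambda_tirf, dtype=float)
    r = np.asarray(r_ves_nm, dtype=float)
    if not (x.size == lam.size == r.size):
        raise ValueError("input arrays must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 events for population fits")

    res = CalibrationResult(n_events=int(x.size))

    expo = lambda t, a, b: a * np.exp(-b * t)
    power = lambda t, a, b: a * np.power(t, b)

    (res.a1, res.b1), ci1 = _fit_with_ci(expo, x, lam, p0=(lam.max(), 1e-3))
    res.ci["a1"], res.ci["b1"] = ci1
    (res.a2, res.b2), ci2 = _fit_with_ci(power, x, r, p0=(1.0, 0.5))
    res.ci["a2"], res.ci["b2"] = ci2
    (res.a3, res.b3), ci3 = _fit_with_ci(expo, r, lam, p0=(lam.max(), 0.01))
    res.ci["a3"], res.ci["b3"] = ci3

    res.binned["lambda_vs_intensity"] = _binned_summary(x, lam, intensity_bin)
    res.binned["radius_vs_intensity"] = _binned_summary(x, r, intensity_bin)
    res.binned["lambda_vs_radius"] = _binned_summary(r, lam, radius_bin_nm)
    res.r_ves_star_nm = equal_contribution_radius(res.a3, res.b3)
    return res


def extrapolate_lambda0(
    r_ves_nm: Sequence[float],
    lambda_tirf: Sequence[float],
    depth_nm: float,
    r_max_nm: float = 35.0,
) -> tuple[float, float, tuple[float, float]]:
    """Constrained-line extrapolation of the pure polarization factor.

    Fits ``lambda = s * (R_ves - delta)`` (x-intercept pinned at the
    evanescent depth) to events with ``R_ves <= r_max_nm`` and returns
    ``(slope [1/nm], lambda_TIRF0, 95% CI)`` with
    ``lambda_TIRF0 = -s * delta`` and the CI propagated from the slope's
    t-interval (delta treated as exact).
    """
    r = np.asarray(r_ves_nm, dtype=float)
    lam = np.asarray(lambda_tirf, dtype=float)
    if depth_nm <= r_max_nm:
        raise ValueError("depth_nm must exceed r_max_nm")
    m = r <= r_max_nm
    if m.sum() < 5:
        raise ValueError(
            f"insufficient data: {int(m.sum())} events with R_ves <= {r_max_nm} nm "
            "(need >= 5)"
        )
    u = r[m] - depth_nm  # regressor through the origin
    y = lam[m]
    s = float(np.dot(u, y) / np.dot(u, u))
    resid = y - s * u
    dof = max(u.size - 1, 1)
    se = math.sqrt(float(resid @ resid) / dof / float(u @ u))
    tval = stats.t.ppf(0.975, dof)
    lam0 = -s * depth_nm
    ci = (lam0 - tval * se * depth_nm, lam0 + tval * se * depth_nm)
    return s, lam0, ci


def equal_contribution_radius(
    a3: float, b3: float, r_max_nm: float = 200.0
) -> float | None:
    """Radius where polarization and field-decay effects cancel.

    Root of ``a3 * exp(-b3 * R) = 1``: ``R* = ln(a3) / b3``.  Returns
    ``None`` when the fitted curve never crosses 1 from above
    (``a3 <= 1``) or the root exceeds ``r_max_nm``.
    """
    if b3 <= 0 or a3 <= 1.0:
        return None
    r_star = math.log(a3) / b3
    return r_star if r_star <= r_max_nm else None


def polarization_correction(
    ilip_ref: float,
    sbl_response,
    theta_ref_deg: float,
    theta_target_deg: float,
) -> float:
    """Transfer the single-lipid intensity to another polarization angle.

    ``I_lip(theta) = I_lip(theta_ref) * S(theta) / S(theta_ref)`` with S
    the fitted mean-bilayer-intensity sinusoid (a callable of the angle
    in degrees).
    """
    if ilip_ref <= 0:
        raise ValueError("ilip_ref must be positive")
    s_ref = float(sbl_response(theta_ref_deg))
    if s_ref <= 0:
        raise ValueError("sinusoid non-positive at the reference angle")
    return ilip_ref * float(sbl_response(theta_target_deg)) / s_ref
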