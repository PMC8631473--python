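"""Per-event fusion-pore physics and population trend summaries.

From the fitted trace parameters and the single-lipid calibration, each
event yields:

* vesicle area ``A_ves = I_dock / (lambda_TIRF * I_lip * 2 rho_lip)``
  (both leaflets carry label, hence the factor 2), radius
  ``R_ves = sqrt(A_ves / 4 pi)`` and diffusive dwell time
  ``tau_ves = A_ves / D_lip``;
* pore openness ``Po = g * tau_ves / tau_release`` with the geometry
  factor ``g = b / (2 pi r_p)`` (pore height b, fully open pore radius
  r_p), capped at 1 — values >= 1 mean release was as fast as free
  diffusion through an open pore permits (diffusion-limited);
* SNARE copy estimates ``N_SNARE = A_ves * Gamma_SNARE`` with
  ``Gamma_SNARE = 1 / (LP * a_lip)``, of which about half face outward;
* membrane curvature ``C = 2 / R_ves``.

Population trends (open-pore fraction and flickering-pore Po vs SNARE
copies or curvature) are summarized with binned fractions, a moving
average, and an OLS linear fit with 95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MembraneComposition",
    "PoreGeometry",
    "EventSummary",
    "vesicle_geometry",
    "pore_openness",
    "snare_metrics",
    "summarize_trends",
    "summaries_to_frame",
]

ReleaseClass = Literal["pore_limited", "diffusion_limited"]


@dataclass
class MembraneComposition:
    """Labeling and protein densities of the vesicle membrane.

    ``label_mole_fraction`` is the dye mole fraction (1 mol% keeps
    self-quenching negligible); ``area_per_lipid_nm2`` the mean headgroup
    area; ``lipid_to_protein`` the measured lipid-to-SNARE ratio.
    """

    label_mole_fraction: float = 0.01
    area_per_lipid_nm2: float = 0.70
    lipid_to_protein: float = 400.0

    def __post_init__(self) -> None:
        if not (0 < self.label_mole_fraction < 1):
            raise ValueError("label_mole_fraction must be in (0, 1)")
        if self.area_per_lipid_nm2 <= 0 or self.lipid_to_protein <= 0:
            raise ValueError("areas and ratios must be positive")

    @property
    def label_density_per_nm2(self) -> float:
        """Labeled lipids per nm^2 of one leaflet."""
        return self.label_mole_fraction / self.area_per_lipid_nm2

    @property
    def snare_density_per_nm2(self) -> float:
        return 1.0 / (self.lipid_to_protein * self.area_per_lipid_nm2)


@dataclass
class PoreGeometry:
    """Fusion pore height and fully-open radius; r_p includes half the
    bilayer thickness (the aqueous lumen is ~1 nm for r_p = 3 nm)."""

    pore_height_nm: float = 15.0
    open_pore_radius_nm: float = 3.0

    def __post_init__(self) -> None:
        if self.pore_height_nm <= 0 or self.open_pore_radius_nm <= 0:
            raise ValueError("pore dimensions must be positive")

    @property
    def geometry_factor(self) -> float:
        """g = b / (2 pi r_p); order unity for typical pores."""
        return self.pore_height_nm / (2.0 * math.pi * self.open_pore_radius_nm)


def vesicle_geometry(
    i_dock: float,
    lambda_tirf: float,
    i_lip: float,
    rho_lip_per_nm2: float,
    d_lip_um2_s: float,
) -> tuple[float, float, float]:
    """Vesicle area, radius and diffusive dwell time from intensities.

    Returns ``(A_ves [nm^2], R_ves [nm], tau_ves [s])`` where
    ``A_ves = I_dock / (lambda_TIRF * I_lip * 2 rho_lip)`` and
    ``tau_ves = A_ves / D_lip``.
    """
    if lambda_tirf <= 0 or i_lip <= 0:
        raise ZeroDivisionError("lambda_tirf and i_lip must be positive")
    if i_dock <= 0 or rho_lip_per_nm2 <= 0 or d_lip_um2_s <= 0:
        raise ValueError("all inputs must be positive")
    a_ves = i_dock / (lambda_tirf * i_lip * 2.0 * rho_lip_per_nm2)
    r_ves = math.sqrt(a_ves / (4.0 * math.pi))
    tau_ves = a_ves / (d_lip_um2_s * 1.0e6)  # nm^2 / (nm^2/s)
    return a_ves, r_ves, tau_ves


def pore_openness(
    tau_ves_s: float, tau_release_s: float, geometry: PoreGeometry | None = None
) -> tuple[float, ReleaseClass, float]:
    """Pore openness Po = g tau_ves / tau_release, capped at 1.

    Returns ``(Po, release_class, raw)``.  A raw value >= 1 means release
    was at least as fast as diffusion through a fully open pore permits;
    the event is classed ``diffusion_limited`` and Po reported as 1.
    """
    if tau_ves_s <= 0 or tau_release_s <= 0:
        raise ValueError("times must be positive")
    g = (geometry or PoreGeometry()).geometry_factor
    raw = g * tau_ves_s / tau_release_s
    if raw >= 1.0:
        return 1.0, "diffusion_limited", raw
    return raw, "pore_limited", raw


def snare_metrics(
    a_ves_nm2: float, comp: MembraneComposition | None = None
) -> tuple[float, float, float]:
    """SNARE density and copy numbers for a vesicle of given area.

    Returns ``(Gamma_SNARE [1/nm^2], N_SNARE, N_SNARE_out)`` where the
    outward-facing count is half the total (random reconstitution
    orientation).
    """
    comp = comp or MembraneComposition()
    if a_ves_nm2 <= 0:
        raise ValueError("a_ves_nm2 must be positive")
    gamma = comp.snare_density_per_nm2
    n = a_ves_nm2 * gamma
    return gamma, n, n / 2.0


@dataclass
class EventSummary:
    """Derived per-event physics, one row of the results table."""

    event_id: int
    i_dock: float
    lambda_tirf: float
    gain: float
    d_lip_um2_s: float
    tau_release_s: float
    tau_bleach_s: float
    a_ves_nm2: float
    r_ves_nm: float
    tau_ves_s: float
    po: float
    po_raw: float
    release_class: str
    n_snare: float
    n_snare_out: float
    curvature_per_nm: float
    tau_dock_s: float = float("nan")
    rejected: bool = False
    reason: str = ""

    @classmethod
    def from_fit(
        cls,
        event_id: int,
        i_dock: float,
        gain: float,
        d_lip_um2_s: float,
        tau_release_s: float,
        tau_bleach_s: float,
        i_lip: float,
        comp: MembraneComposition | None = None,
        geometry: PoreGeometry | None = None,
        tau_dock_s: float = float("nan"),
        rejected: bool = False,
        reason: str = "",
    ) -> "EventSummary":
        comp = comp or MembraneComposition()
        lam = 1.0 / gain
        a_ves, r_ves, tau_ves = vesicle_geometry(
            i_dock, lam, i_lip, comp.label_density_per_nm2, d_lip_um2_s
        )
        po, rel_class, raw = pore_openness(tau_ves, tau_release_s, geometry)
        _, n_snare, n_out = snare_metrics(a_ves, comp)
        return cls(
            event_id=event_id,
            i_dock=i_dock,
            lambda_tirf=lam,
            gain=gain,
            d_lip_um2_s=d_lip_um2_s,
            tau_release_s=tau_release_s,
            tau_bleach_s=tau_bleach_s,
            a_ves_nm2=a_ves,
            r_ves_nm=r_ves,
            tau_ves_s=tau_ves,
            po=po,
            po_raw=raw,
            release_class=rel_class,
            n_snare=n_snare,
            n_snare_out=n_out,
            curvature_per_nm=2.0 / r_ves,
            tau_dock_s=tau_dock_s,
            rejected=rejected,
            reason=reason,
        )


RESULT_COLUMNS = [
    "event_id", "Idock", "lambda_tirf", "G", "D_lip_um2s", "tau_release_s",
    "tau_bleach_s", "A_ves_nm2", "R_ves_nm", "tau_ves_s", "Po", "Po_raw",
    "release_class", "N_snare", "N_snare_out", "curvature_per_nm",
    "tau_dock_s", "rejected", "reason",
]


def summaries_to_frame(events: Sequence[EventSummary]) -> pd.DataFrame:
    rows = [
        [
            e.event_id, e.i_dock, e.lambda_tirf, e.gain, e.d_lip_um2_s,
            e.tau_release_s, e.tau_bleach_s, e.a_ves_nm2, e.r_ves_nm,
            e.tau_ves_s, e.po, e.po_raw, e.release_class, e.n_snare,
            e.n_snare_out, e.curvature_per_nm, e.tau_dock_s, e.rejected,
            e.reason,
        ]
        for e in events
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass
class TrendReport:
    """Open-pore fraction and flickering-branch trend vs one predictor."""

    predictor: str
    open_threshold: float
    bin_centers: np.ndarray
    open_fraction: np.ndarray
    bin_counts: np.ndarray
    flicker_predictor: np.ndarray
    flicker_po_smoothed: np.ndarray
    slope: float = float("nan")
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))
    intercept: float = float("nan")
    r_squared: float = float("nan")
    n_open_branch: int = 0
    n_flicker_branch: int = 0


def _moving_average(y: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges
    (span//2 neighbours each side where available)."""
    half = span // 2
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        lo = max(0, i - half)
        hi = min(y.size, i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def summarize_trends(
    events: Sequence[EventSummary],
    predictor: Literal["n_snare", "curvature"] = "n_snare",
    open_threshold: float = 0.90,
    span: int = 5,
    n_bins: int = 8,
) -> TrendReport:
    """Population trend of pore openness against SNARE copies or curvature.

    (a) Fraction of open pores (Po >= threshold) in equal-width predictor
    bins.  (b) For flickering pores (Po < threshold): predictor-sorted
    moving average (given span) and an OLS line on the smoothed values
    with slope, 95% CI and R^2.
    """
    key = {"n_snare": "n_snare", "curvature": "curvature_per_nm"}[predictor]
    acc = [e for e in events if not e.rejected]
    x = np.array([getattr(e, key) for e in acc])
    po = np.array([e.po for e in acc])

    report = TrendReport(
        predictor=predictor,
        open_threshold=open_threshold,
        bin_centers=np.array([]),
        open_fraction=np.array([]),
        bin_counts=np.array([]),
        flicker_predictor=np.array([]),
        flicker_po_smoothed=np.array([]),
    )
    if x.size == 0:
        return report

    edges = np.linspace(x.min(), x.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    centers, fracs, counts = [], [], []
    for b in range(n_bins):
        m = idx == b
        if not np.any(m):
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        fracs.append(float(np.mean(po[m] >= open_threshold)))
        counts.append(int(m.sum()))
    report.bin_centers = np.array(centers)
    report.open_fraction = np.array(fracs)
    report.bin_counts = np.array(counts)
    report.n_open_branch = int(x.size)

    flick = po < open_threshold
    report.n_flicker_branch = int(flick.sum())
    if flick.sum() >= span:
        order = np.argsort(x[flick])
        xf = x[flick][order]
        pf = po[flick][order]
        # both coordinates pass the same filter so an exactly linear
        # relation survives smoothing (edge windows shrink symmetrically)
        smooth = _moving_average(pf, span)
        xs = _moving_average(xf, span)
        report.flicker_predictor = xs
        report.flicker_po_smoothed = smooth
        ols = sm.OLS(smooth, sm.add_constant(xs)).fit()
        report.intercept = float(ols.params[0])
        report.slope = float(ols.params[1])
        ci = ols.conf_int(alpha=0.05)
        report.slope_ci = (float(ci[1][0]), float(ci[1][1]))
        report.r_squared = float(ols.rsquared)
    return report
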