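"""Seeded synthetic fusion events at two fidelities.

Trace level: events are drawn from the forward population model (vesicle
size -> mean excitation -> docked intensity -> dwell time -> release time)
and rendered as five nested-ROI intensity traces by direct evaluation of
the closed-form trace model, plus background and camera noise.

Particle level: each labeled lipid is an individual emitter.  A docked
vesicle is a stationary diffraction-limited spot; after its escape time
(exponential release, or the explicit flickering-pore process of
:func:`simulate_flicker_release`), each lipid performs an independent 2D
Brownian walk in the bilayer with stronger photobleaching (the per-dye
excitation is G-fold higher there).  Frames pass through shot noise,
camera gain and Gaussian read noise.

All randomness flows from one root seed through per-event child seeds, so
a configuration reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .fitting import EventTrace
from .optics import OpticalConfig, PolarizationSetting, vesicle_mean_excitation
from .pore_metrics import MembraneComposition, PoreGeometry
from .trace_model import EventTimes, FitParams, model_total

__all__ = [
    "SimulationConfig",
    "GroundTruthEvent",
    "ImageStack",
    "sample_population",
    "simulate_trace",
    "simulate_flicker_release",
    "render_stack",
    "roi_pixel_count",
]


def roi_pixel_count(radius_px: float) -> int:
    """Number of lattice pixels whose centers lie within the ROI radius."""
    r = int(math.floor(radius_px))
    n = 0
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            if dx * dx + dy * dy <= radius_px * radius_px:
                n += 1
    return n


@dataclass
class GroundTruthEvent:
    """One simulated event's generating parameters."""

    event_id: int
    r_ves_nm: float
    a_ves_nm2: float
    lambda_tirf: float
    gain: float
    i_dock: float
    tau_ves_s: float
    po: float
    tau_release_s: float
    tau_bleach_s: float
    d_lip_um2_s: float
    n_lip: int
    n_snare: float
    dock_frame: int
    fusion_frame: int
    x_px: float = float("nan")
    y_px: float = float("nan")
    seed: int = 0


@dataclass
class ImageStack:
    """Rendered movie with its acquisition metadata and ground truth."""

    data: np.ndarray  # (frames, ny, nx) counts
    pixel_size_nm: float
    frame_interval_s: float
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any(self.data < 0):
            raise ValueError("stack counts must be non-negative")


@dataclass
class SimulationConfig:
    """Population parameters, noise model and acquisition geometry.

    Vesicle radii are log-normal (median / geometric SD), truncated to
    [10, 100] nm — diameters 20-200 nm, the size range of extruded SUVs.
    Pore openness is uniform over ``po_range``; the release time follows
    as ``tau_release = g * tau_ves / Po``.  The flicker micro-times
    ``tau_open_s``/``tau_closed_s`` parameterize the explicit two-state
    pore (defaults give a fast, 5 ms flicker period at Po = 0.5).
    """

    n_events: int = 50
    r_ves_median_nm: float = 45.0
    r_ves_geo_sd: float = 1.5
    r_ves_bounds_nm: tuple[float, float] = (10.0, 100.0)
    po_range: tuple[float, float] = (0.1, 0.9)
    tau_open_s: float = 0.0025
    tau_closed_s: float = 0.0025
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    polarization: PolarizationSetting = field(default_factory=PolarizationSetting)
    composition: MembraneComposition = field(default_factory=MembraneComposition)
    geometry: PoreGeometry = field(default_factory=PoreGeometry)
    d_lip_um2_s: float = 1.1
    tau_bleach_s: float = 2.0
    background_per_px: float = 20.0
    gaussian_sd: float = 0.0  # read-noise SD at the largest ROI (traces)
    use_shot_noise: bool = False
    camera_gain: float = 1.0
    read_noise: float = 0.0  # per-pixel SD (stacks)
    n_frames: int = 130
    dock_frame: int = 20
    fusion_frame: int = 60
    roi_radii_px: tuple = (3, 5, 7, 9, 11)
    frame_size_px: int = 64
    seed: int = 0

    @property
    def flicker_po(self) -> float:
        return self.tau_open_s / (self.tau_open_s + self.tau_closed_s)


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, geo_sd: float, lo: float, hi: float
) -> np.ndarray:
    """Log-normal draws by rejection, truncated to [lo, hi]."""
    mu, sigma = math.log(median), math.log(geo_sd)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_population(config: SimulationConfig) -> list[GroundTruthEvent]:
    """Draw a ground-truth event population from the forward model.

    Per event: radius -> area -> mean excitation (lambda_TIRF) -> docked
    intensity (area x both-leaflet label density x lambda x single-lipid
    intensity) -> dwell time -> openness -> release time; label and SNARE
    copy numbers follow from the membrane composition.
    """
    root = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(root))
    child_seeds = root.spawn(config.n_events)

    lo, hi = config.r_ves_bounds_nm
    r = _truncated_lognormal(
        rng, config.n_events, config.r_ves_median_nm, config.r_ves_geo_sd, lo, hi
    )
    po = rng.uniform(*config.po_range, size=config.n_events)

    depth = config.optics.evanescent_depth_nm
    lam0 = config.polarization.lambda0_pol
    ilip = config.polarization.single_lipid_intensity
    rho = config.composition.label_density_per_nm2
    g = config.geometry.geometry_factor

    events = []
    for i in range(config.n_events):
        a = 4.0 * math.pi * r[i] ** 2
        lam = float(vesicle_mean_excitation(r[i], depth, lam0))
        i_dock = a * 2.0 * rho * lam * ilip
        tau_ves = a / (config.d_lip_um2_s * 1e6)
        tau_rel = g * tau_ves / po[i]
        events.append(
            GroundTruthEvent(
                event_id=i,
                r_ves_nm=float(r[i]),
                a_ves_nm2=a,
                lambda_tirf=lam,
                gain=1.0 / lam,
                i_dock=i_dock,
                tau_ves_s=tau_ves,
                po=float(po[i]),
                tau_release_s=tau_rel,
                tau_bleach_s=config.tau_bleach_s,
                d_lip_um2_s=config.d_lip_um2_s,
                n_lip=int(round(2.0 * rho * a)),
                n_snare=a * config.composition.snare_density_per_nm2,
                dock_frame=config.dock_frame,
                fusion_frame=config.fusion_frame,
                seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            )
        )
    return events


def truth_to_frame(events: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


def simulate_trace(
    truth: GroundTruthEvent,
    config: SimulationConfig,
    noise: bool = True,
) -> EventTrace:
    """Render one event as five nested-ROI traces on the frame grid.

    Noiseless mode evaluates ``I_dock * model_total`` exactly (background
    still added, so the extraction path is exercised).  With noise, the
    per-ROI Gaussian SD scales as sqrt(pixel count) from the configured
    SD at the largest ROI; optional shot noise applies Poisson statistics
    to total counts including background.
    """
    opt = config.optics
    radii_nm = np.asarray(config.roi_radii_px, dtype=float) * opt.pixel_size_nm
    frames = np.arange(config.n_frames)
    t = frames * opt.frame_interval_s
    times = EventTimes(
        t_dock=truth.dock_frame * opt.frame_interval_s,
        t_fusion=truth.fusion_frame * opt.frame_interval_s,
    )
    params = FitParams(
        gain=truth.gain,
        d_lip_um2_s=truth.d_lip_um2_s,
        tau_release_s=truth.tau_release_s,
        tau_bleach_s=truth.tau_bleach_s,
    )
    signal = truth.i_dock * model_total(
        radii_nm[:, None], t[None, :], times, params, opt.psf_sigma_nm
    )
    npix = np.array([roi_pixel_count(r) for r in config.roi_radii_px], dtype=float)
    background = config.background_per_px * npix
    total = signal + background[:, None]

    if noise:
        rng = np.random.Generator(np.random.PCG64(truth.seed))
        if config.use_shot_noise:
            total = rng.poisson(np.maximum(total, 0)).astype(float) * config.camera_gain
        if config.gaussian_sd > 0:
            sd = config.gaussian_sd * np.sqrt(npix / npix[-1])
            total = total + rng.normal(0.0, 1.0, size=total.shape) * sd[:, None]

    return EventTrace(
        event_id=truth.event_id,
        roi_radii_px=np.asarray(config.roi_radii_px, dtype=float),
        frame_times_s=t,
        intensity=total,
        raw_background=np.zeros(len(config.roi_radii_px)),
        dock_frame=truth.dock_frame,
        fusion_frame=truth.fusion_frame,
        frame_indices=frames,
    )


def simulate_flicker_release(
    n_lip: int,
    tau_ves_s: float,
    geometry: PoreGeometry,
    tau_open_s: float,
    tau_closed_s: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Escape times of individual lipids through a two-state flickering pore.

    The pore alternates exponentially distributed open (mean ``tau_open``)
    and closed (mean ``tau_closed``) periods, starting open at fusion.
    While the pore is open each unreleased lipid escapes as a Poisson
    process with rate ``1/(g tau_ves)``, so the required cumulative open
    time per lipid is exponential with mean ``g tau_ves``; mapping it
    through the flicker sequence yields wall-clock escape times whose
    ensemble mean tends to ``g tau_ves / Po`` in the fast-flicker limit.
    """
    if tau_ves_s <= 0 or tau_open_s <= 0 or tau_closed_s < 0:
        raise ValueError("times must be positive (tau_closed may be 0)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(seed))
    )
    mean_open_needed = geometry.geometry_factor * tau_ves_s
    required = rng.exponential(mean_open_needed, size=n_lip)
    if tau_closed_s == 0:
        return required  # pore continuously open

    max_req = required.max()
    # grow the flicker sequence until it covers the largest requirement
    n_cycles = max(16, int(2 * max_req / tau_open_s) + 8)
    open_dur = rng.exponential(tau_open_s, size=n_cycles)
    closed_dur = rng.exponential(tau_closed_s, size=n_cycles)
    while open_dur.sum() < max_req:
        open_dur = np.concatenate([open_dur, rng.exponential(tau_open_s, size=n_cycles)])
        closed_dur = np.concatenate(
            [closed_dur, rng.exponential(tau_closed_s, size=n_cycles)]
        )
    cum_open = np.cumsum(open_dur)
    cum_closed_before = np.concatenate([[0.0], np.cumsum(closed_dur)[:-1]])
    k = np.searchsorted(cum_open, required)
    return required + cum_closed_before[k]


def _pixel_integrated_psf(
    positions_px: np.ndarray,
    amplitudes: np.ndarray,
    image: np.ndarray,
    sigma_px: float,
    patch_half: int = 3,
) -> None:
    """Accumulate pixel-integrated Gaussian spots into ``image`` in place.

    Each spot deposits ``amplitude`` total counts distributed over a
    (2*patch_half+1)^2 patch by the product of per-axis erf differences.
    """
    ny, nx = image.shape
    n = positions_px.shape[0]
    if n == 0:
        return
    cx = positions_px[:, 0]
    cy = positions_px[:, 1]
    ix = np.round(cx).astype(int)
    iy = np.round(cy).astype(int)
    offs = np.arange(-patch_half, patch_half + 1)
    root2s = math.sqrt(2.0) * sigma_px
    # per-axis integrals over pixel [m-0.5, m+0.5]
    ex_hi = erf((ix[:, None] + offs[None, :] + 0.5 - cx[:, None]) / root2s)
    ex_lo = erf((ix[:, None] + offs[None, :] - 0.5 - cx[:, None]) / root2s)
    ey_hi = erf((iy[:, None] + offs[None, :] + 0.5 - cy[:, None]) / root2s)
    ey_lo = erf((iy[:, None] + offs[None, :] - 0.5 - cy[:, None]) / root2s)
    wx = 0.5 * (ex_hi - ex_lo)
    wy = 0.5 * (ey_hi - ey_lo)
    patches = amplitudes[:, None, None] * wy[:, :, None] * wx[:, None, :]
    xs = ix[:, None, None] + offs[None, None, :]
    ys = iy[:, None, None] + offs[None, :, None]
    xs = np.broadcast_to(xs, patches.shape)
    ys = np.broadcast_to(ys, patches.shape)
    inside = (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny)
    np.add.at(image, (ys[inside], xs[inside]), patches[inside])


def render_stack(
    events: Sequence[GroundTruthEvent],
    config: SimulationConfig,
    noise: bool = True,
    bleach: bool = True,
    escape_times: dict[int, np.ndarray] | None = None,
    bleach_mode: str = "model",
) -> ImageStack:
    """Render a particle-level movie of docked-then-fusing vesicles.

    Events without positions are placed on a grid with non-overlapping
    largest-ROI footprints (a collision raises).  Per lipid, a bleach
    clock runs at rate ``1/tau_bleach`` while docked and ``G/tau_bleach``
    after escape; escaped lipids walk with per-frame displacement SD
    ``sqrt(2 D dt)`` per axis and are rendered as individual emitters of
    intensity I_lip.  ``escape_times`` (relative to fusion, per event id)
    overrides the default exponential release draw.

    ``bleach_mode`` controls the released component's bleach history.
    The closed-form trace model books the released dye as starting fresh
    at fusion, without its docked-phase bleach history; ``"model"``
    (default) reproduces that bookkeeping exactly, so rendered stacks are
    unbiased ground truth for the fitter.  ``"physical"`` carries each
    lipid's docked-phase bleach fate into the released phase (a lipid
    bleached while docked never reappears), exposing the approximation:
    fits to physical-mode stacks underestimate G by roughly
    ``exp(-tau_dock / tau_bleach)``.
    """
    if bleach_mode not in ("model", "physical"):
        raise ValueError("bleach_mode must be 'model' or 'physical'")
    opt = config.optics
    n = config.frame_size_px
    n_frames = config.n_frames
    dt = opt.frame_interval_s
    sigma_px = opt.psf_sigma_nm / opt.pixel_size_nm
    d_nm2 = config.d_lip_um2_s * 1e6
    step_sd_px = math.sqrt(2.0 * d_nm2 * dt) / opt.pixel_size_nm
    ilip = config.polarization.single_lipid_intensity

    events = list(events)
    margin = max(config.roi_radii_px) + 4
    placed = []
    if any(not np.isfinite(e.x_px) for e in events):
        per_row = max(1, (n - 2 * margin) // (2 * margin) + 1)
        for j, e in enumerate(events):
            gx = margin + (j % per_row) * 2 * margin
            gy = margin + (j // per_row) * 2 * margin
            if gy > n - margin:
                raise ValueError("too many events for the frame: ROI collision")
            placed.append(replace(e, x_px=float(gx), y_px=float(gy)))
    else:
        placed = events
        pos = np.array([[e.x_px, e.y_px] for e in placed])
        for i in range(len(placed)):
            for j in range(i + 1, len(placed)):
                if np.hypot(*(pos[i] - pos[j])) < 2 * max(config.roi_radii_px):
                    raise ValueError(
                        f"events {placed[i].event_id} and {placed[j].event_id} "
                        "have overlapping ROIs"
                    )

    stack = np.zeros((n_frames, n, n))
    frame_t = np.arange(n_frames) * dt
    truth_rows = []

    for e in placed:
        rng = np.random.Generator(np.random.PCG64(e.seed))
        t_dock = e.dock_frame * dt
        t_fus = e.fusion_frame * dt
        if escape_times is not None and e.event_id in escape_times:
            esc = np.asarray(escape_times[e.event_id], dtype=float)
        else:
            esc = rng.exponential(e.tau_release_s, size=e.n_lip)
        esc_abs = t_fus + esc
        nl = esc.size

        if bleach:
            bleach_docked = t_dock + rng.exponential(e.tau_bleach_s, size=nl)
            # model mode: released survival clock runs from fusion at rate
            # G/tau_bleach, the exact particle realization of the closed-form
            # release term; physical mode: from each lipid's own escape
            origin = t_fus if bleach_mode == "model" else esc_abs
            bleach_released = origin + rng.exponential(
                e.tau_bleach_s / e.gain, size=nl
            )
        else:
            bleach_docked = np.full(nl, np.inf)
            bleach_released = np.full(nl, np.inf)
        # lipids bleached while docked never reappear in physical mode;
        # in model mode the released pool starts fresh at its escape time
        died_docked = (
            bleach_docked < esc_abs
            if bleach_mode == "physical"
            else np.zeros(nl, dtype=bool)
        )

        # brightness of one lipid while in the vesicle
        amp_docked = e.lambda_tirf * ilip

        # Brownian paths of released lipids, one row per frame
        first_frame = np.clip(np.ceil(esc_abs / dt).astype(int), 0, n_frames)
        x = np.full((n_frames, nl), np.nan)
        y = np.full((n_frames, nl), np.nan)
        for i in range(nl):
            if died_docked[i] or first_frame[i] >= n_frames:
                continue
            f0 = first_frame[i]
            m = n_frames - f0
            # partial first interval from the escape instant to frame f0
            sd0 = math.sqrt(max(2.0 * d_nm2 * (frame_t[f0] - esc_abs[i]), 0.0)) / opt.pixel_size_nm
            steps = rng.normal(0.0, step_sd_px, size=(m, 2))
            steps[0] = rng.normal(0.0, 1.0, size=2) * sd0
            path = np.cumsum(steps, axis=0)
            x[f0:, i] = e.x_px + path[:, 0]
            y[f0:, i] = e.y_px + path[:, 1]

        for f in range(n_frames):
            t = frame_t[f]
            if t < t_dock:
                continue
            docked_alive = (esc_abs > t) & (bleach_docked > t)
            nd = int(docked_alive.sum())
            if nd:
                _pixel_integrated_psf(
                    np.array([[e.x_px, e.y_px]]),
                    np.array([nd * amp_docked]),
                    stack[f],
                    sigma_px,
                )
            rel = (~died_docked) & (esc_abs <= t) & (bleach_released > t) & (
                first_frame <= f
            )
            if np.any(rel):
                pts = np.column_stack([x[f, rel], y[f, rel]])
                _pixel_integrated_psf(
                    pts, np.full(int(rel.sum()), ilip), stack[f], sigma_px
                )
        truth_rows.append(vars(e))

    stack += config.background_per_px
    if noise:
        rng_cam = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([config.seed, 0xCA3E]))
        )
        if config.use_shot_noise:
            stack = rng_cam.poisson(np.maximum(stack, 0)).astype(float)
        stack *= config.camera_gain
        if config.read_noise > 0:
            stack = stack + rng_cam.normal(0.0, config.read_noise, size=stack.shape)
        stack = np.maximum(stack, 0.0)

    return ImageStack(
        data=stack,
        pixel_size_nm=opt.pixel_size_nm,
        frame_interval_s=dt,
        truth=pd.DataFrame(truth_rows),
    )
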