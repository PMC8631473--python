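"""Synthetic populations, traces, flickering-pore release and rendered stacks."""

import numpy as np
import pandas as pd
import pytest

from ptirf.fitting import extract_event_anchors, extract_radial_traces
from ptirf.pore_metrics import PoreGeometry
from ptirf.simulate import (
    SimulationConfig,
    render_stack,
    roi_pixel_count,
    sample_population,
    simulate_flicker_release,
    simulate_trace,
)
from ptirf.trace_model import EventTimes, FitParams, model_total


class TestSamplePopulation:
    def test_same_seed_identical_population(self):
        cfg = SimulationConfig(n_events=20, seed=3)
        a = pd.DataFrame([vars(e) for e in sample_population(cfg)])
        b = pd.DataFrame([vars(e) for e in sample_population(cfg)])
        pd.testing.assert_frame_equal(a, b)

    def test_label_count_from_area(self):
        cfg = SimulationConfig(n_events=5, seed=0)
        ev = sample_population(cfg)[0]
        rho = cfg.composition.label_density_per_nm2
        assert ev.n_lip == round(2 * rho * ev.a_ves_nm2)
        # reference arithmetic: 5000 nm^2 at 1 mol% / 0.70 nm^2 -> 143 labels
        assert round(2 * rho * 5000) == 143

    def test_radius_truncation_honored(self):
        cfg = SimulationConfig(n_events=300, seed=1, r_ves_geo_sd=2.5)
        r = np.array([e.r_ves_nm for e in sample_population(cfg)])
        assert r.min() >= cfg.r_ves_bounds_nm[0]
        assert r.max() <= cfg.r_ves_bounds_nm[1]

    def test_forward_model_consistency(self):
        cfg = SimulationConfig(n_events=10, seed=2)
        g = cfg.geometry.geometry_factor
        for e in sample_population(cfg):
            assert e.a_ves_nm2 == pytest.approx(4 * np.pi * e.r_ves_nm**2)
            assert e.tau_release_s == pytest.approx(g * e.tau_ves_s / e.po)
            assert e.gain == pytest.approx(1 / e.lambda_tirf)


class TestSimulateTrace:
    def test_noiseless_trace_bit_matches_model(self, optics):
        cfg = SimulationConfig(n_events=1, seed=4)
        e = sample_population(cfg)[0]
        tr = simulate_trace(e, cfg, noise=False)
        radii_nm = tr.roi_radii_px * optics.pixel_size_nm
        times = EventTimes(
            e.dock_frame * optics.frame_interval_s,
            e.fusion_frame * optics.frame_interval_s,
        )
        params = FitParams(e.gain, e.d_lip_um2_s, e.tau_release_s, e.tau_bleach_s)
        expected = e.i_dock * model_total(
            radii_nm[:, None], tr.frame_times_s[None, :], times, params,
            optics.psf_sigma_nm,
        )
        npix = np.array([roi_pixel_count(r) for r in tr.roi_radii_px])
        expected = expected + cfg.background_per_px * npix[:, None]
        np.testing.assert_array_equal(tr.intensity, expected)

    def test_same_seed_identical_trace(self):
        cfg = SimulationConfig(n_events=1, seed=4, gaussian_sd=50.0, use_shot_noise=True)
        e = sample_population(cfg)[0]
        t1 = simulate_trace(e, cfg)
        t2 = simulate_trace(e, cfg)
        np.testing.assert_array_equal(t1.intensity, t2.intensity)

    def test_noisy_mean_converges_to_noiseless(self):
        cfg = SimulationConfig(n_events=1, seed=4, gaussian_sd=200.0)
        e = sample_population(cfg)[0]
        clean = simulate_trace(e, cfg, noise=False).intensity
        reps = []
        for k in range(300):
            ek = type(e)(**{**vars(e), "seed": 10_000 + k})
            reps.append(simulate_trace(ek, cfg).intensity)
        mean = np.mean(reps, axis=0)
        se = 200.0 / np.sqrt(300)
        assert np.max(np.abs(mean - clean)) < 4 * se


class TestFlickerRelease:
    geometry = PoreGeometry()

    def test_open_pore_mean_escape_time(self):
        tau_ves = 0.05
        g = self.geometry.geometry_factor
        esc = simulate_flicker_release(
            20_000, tau_ves, self.geometry, tau_open_s=1.0, tau_closed_s=1e-12, seed=1
        )
        se = esc.std() / np.sqrt(esc.size)
        assert abs(esc.mean() - g * tau_ves) < 3 * se

    def test_nearly_closed_pore_releases_nothing(self):
        esc = simulate_flicker_release(
            2_000, 0.05, self.geometry, tau_open_s=1e-7, tau_closed_s=10.0, seed=2
        )
        # open fraction ~1e-8: escapes pushed far beyond any finite horizon
        assert np.quantile(esc, 0.05) > 60.0

    def test_fast_flicker_survival_matches_effective_release_time(self):
        # pooled over independent pores: one event's lipids share a single
        # flicker sequence whose realization noise would dominate alone
        tau_ves, po = 0.05, 0.25
        g = self.geometry.geometry_factor
        period = 0.005
        esc = np.concatenate([
            simulate_flicker_release(
                200, tau_ves, self.geometry,
                tau_open_s=po * period, tau_closed_s=(1 - po) * period, seed=3 + k,
            )
            for k in range(200)
        ])
        ts = np.sort(esc)
        surv = 1.0 - np.arange(1, ts.size + 1) / ts.size
        keep = surv > 0.01
        slope = np.polyfit(ts[keep], np.log(surv[keep]), 1)[0]
        assert -1.0 / slope == pytest.approx(g * tau_ves / po, rel=0.10)

    def test_empirical_open_fraction_long_horizon(self, rng):
        # law of large numbers on the flicker duty cycle itself
        tau_o, tau_c = 0.002, 0.006
        n = 20_000
        open_d = rng.exponential(tau_o, n)
        closed_d = rng.exponential(tau_c, n)
        frac = open_d.sum() / (open_d.sum() + closed_d.sum())
        po = tau_o / (tau_o + tau_c)
        se = po * np.sqrt(2.0 / n)
        assert abs(frac - po) < 3 * se


class TestRenderStack:
    def test_single_emitter_encircled_energy(self, optics):
        """A stationary rendered spot reproduces the closed-form encircled
        energy after pixel integration."""
        from ptirf.simulate import _pixel_integrated_psf
        from ptirf.trace_model import psf_encircled_fraction

        img = np.zeros((41, 41))
        sigma_px = 300.0 / optics.pixel_size_nm  # broad PSF, a few pixels
        _pixel_integrated_psf(
            np.array([[20.0, 20.0]]), np.array([1000.0]), img, sigma_px, patch_half=12
        )
        yy, xx = np.mgrid[0:41, 0:41]
        d2 = (xx - 20.0) ** 2 + (yy - 20.0) ** 2
        for r_px in (3, 5, 7, 9, 11):
            rendered = img[d2 <= r_px**2].sum() / 1000.0
            closed = psf_encircled_fraction(r_px * optics.pixel_size_nm, 300.0)
            assert rendered == pytest.approx(closed, abs=0.01)

    def test_label_conservation_no_bleach_unit_gain(self):
        cfg = SimulationConfig(n_events=1, seed=6, n_frames=80, frame_size_px=96,
                               fusion_frame=30, background_per_px=0.0)
        ev = sample_population(cfg)
        # force G=1: lipid brightness identical docked and released
        ev[0].lambda_tirf = 1.0
        ev[0].gain = 1.0
        st = render_stack(ev, cfg, noise=False, bleach=False)
        tot = st.data.sum(axis=(1, 2))
        docked = tot[cfg.dock_frame + 1 : cfg.fusion_frame - 1].mean()
        after = tot[cfg.fusion_frame + 5 : cfg.fusion_frame + 15].mean()
        assert after == pytest.approx(docked, rel=0.02)

    def test_same_seed_identical_stack(self):
        cfg = SimulationConfig(n_events=2, seed=8, n_frames=30, use_shot_noise=True,
                               read_noise=3.0)
        ev = sample_population(cfg)
        a = render_stack(ev, cfg)
        b = render_stack(ev, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_roi_collision_raises(self):
        cfg = SimulationConfig(n_events=2, seed=8, n_frames=10)
        ev = sample_population(cfg)
        for e, x in zip(ev, (20.0, 25.0)):
            e.x_px = x
            e.y_px = 30.0
        with pytest.raises(ValueError, match="overlap"):
            render_stack(ev, cfg)

    def test_truth_table_carries_generating_parameters(self):
        cfg = SimulationConfig(n_events=3, seed=9, n_frames=15)
        st = render_stack(sample_population(cfg), cfg, noise=False)
        assert len(st.truth) == 3
        assert {"r_ves_nm", "po", "tau_release_s", "x_px"} <= set(st.truth.columns)
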