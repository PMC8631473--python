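"""ROI extraction, anchors, and the multi-ROI weighted least-squares fit."""

import logging
from dataclasses import replace

import numpy as np
import pytest

from ptirf.fitting import (
    EventAnchors,
    EventRejected,
    EventTrace,
    FitOptions,
    RadialFusionModel,
    extract_event_anchors,
    extract_radial_traces,
    fit_event,
)
from ptirf.optics import OpticalConfig
from ptirf.simulate import SimulationConfig, sample_population, simulate_trace
from ptirf.trace_model import EventTimes, FitParams, model_total


def make_model_trace(
    optics: OpticalConfig,
    params: FitParams,
    scale: float = 1000.0,
    dock_frame: int = 20,
    fusion_frame: int = 60,
    n_frames: int = 130,
):
    """EventTrace generated exactly by the closed-form model."""
    radii = np.array([3.0, 5, 7, 9, 11])
    t = np.arange(n_frames) * optics.frame_interval_s
    times = EventTimes(
        dock_frame * optics.frame_interval_s, fusion_frame * optics.frame_interval_s
    )
    y = scale * model_total(
        radii[:, None] * optics.pixel_size_nm,
        t[None, :],
        times,
        params,
        optics.psf_sigma_nm,
    )
    trace = EventTrace(0, radii, t, y, np.zeros(5), dock_frame, fusion_frame)
    anchors = EventAnchors(
        i_dock=scale,
        i_fus=float(y[-1, fusion_frame - 1]),
        i_max=float(y[-1, fusion_frame:].max()),
        background=np.zeros(5),
        predock_sd=np.zeros(5),
    )
    return trace, anchors


class TestExtractRadialTraces:
    def test_uniform_image_lattice_disk(self):
        # 29 lattice points satisfy dx^2 + dy^2 <= 9
        stack = np.ones((3, 21, 21))
        track = np.full((3, 2), 10.0)
        tr = extract_radial_traces(stack, track, 0, 1, radii_px=[3], pre_dock=0, post_fusion=1)
        assert np.all(tr.intensity == 29)

    def test_single_bright_pixel_under_centroid(self):
        stack = np.zeros((4, 31, 31))
        stack[:, 15, 15] = 7.0
        track = np.full((4, 2), 15.0)
        tr = extract_radial_traces(stack, track, 0, 2, radii_px=[3, 5, 7], pre_dock=0)
        assert np.all(tr.intensity == 7.0)

    def test_nesting_on_random_image(self, rng):
        stack = rng.random((5, 41, 41))
        track = np.full((5, 2), 20.0)
        tr = extract_radial_traces(stack, track, 1, 3, radii_px=[3, 5], pre_dock=1)
        assert np.all(tr.intensity[1] >= tr.intensity[0])

    def test_edge_event_rejected(self):
        stack = np.ones((3, 30, 30))
        track = np.full((3, 2), 5.0)  # 11 px ROI cannot fit
        with pytest.raises(EventRejected) as exc:
            extract_radial_traces(stack, track, 0, 1, pre_dock=0)
        assert exc.value.reason == "edge"

    def test_missing_track_frames_raise(self):
        stack = np.ones((20, 41, 41))
        track = np.full((20, 2), np.nan)
        track[5] = 20.0  # only the docking frame
        with pytest.raises(ValueError, match="missing"):
            extract_radial_traces(stack, track, 5, 12)


class TestExtractEventAnchors:
    @staticmethod
    def _flat_trace(pre_level, docked_level, n_pre=10):
        n = n_pre + 20
        y = np.full((2, n), float(pre_level))
        y[:, n_pre : n_pre + 10] = docked_level
        y[:, n_pre + 10 :] = docked_level * 2
        return EventTrace(
            0, np.array([3.0, 11.0]), np.arange(n) * 0.0183, y,
            np.zeros(2), n_pre, n_pre + 10,
            frame_indices=np.arange(n),
        )

    def test_background_and_idock_arithmetic(self):
        tr = self._flat_trace(100.0, 300.0)
        an = extract_event_anchors(tr)
        assert an.background == pytest.approx([100.0, 100.0])
        assert an.i_dock == pytest.approx(200.0)
        assert an.i_max == pytest.approx(500.0)

    def test_short_background_window_logs_warning(self, caplog):
        tr = self._flat_trace(100.0, 300.0, n_pre=6)
        with caplog.at_level(logging.WARNING):
            an = extract_event_anchors(tr)
        assert an.i_dock == pytest.approx(200.0)
        assert any("pre-dock" in r.message for r in caplog.records)

    def test_no_predock_frames_rejected(self):
        tr = self._flat_trace(100.0, 300.0, n_pre=1)
        tr.frame_indices = np.arange(1, tr.frame_times_s.size + 1)
        tr.dock_frame, tr.fusion_frame = 1, 11
        with pytest.raises(EventRejected) as exc:
            extract_event_anchors(tr)
        assert exc.value.reason == "no_background"


class TestFitEvent:
    @pytest.mark.parametrize(
        "truth",
        [
            FitParams(2.0, 1.1, 0.15, 2.0),
            FitParams(0.6, 0.4, 0.8, 5.0),
            FitParams(4.0, 3.0, 0.04, 1.0),
        ],
    )
    def test_noiseless_round_trip_is_exact(self, optics, truth):
        trace, anchors = make_model_trace(optics, truth)
        res = fit_event(trace, anchors, optics)
        assert not res.rejected
        for name in ("gain", "d_lip_um2_s", "tau_release_s", "tau_bleach_s"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-4
            )

    def test_gain_invariant_under_count_rescaling(self, optics):
        truth = FitParams(1.8, 1.1, 0.2, 2.0)
        t1, a1 = make_model_trace(optics, truth, scale=1000.0)
        t2, a2 = make_model_trace(optics, truth, scale=73000.0)
        g1 = fit_event(t1, a1, optics).params.gain
        g2 = fit_event(t2, a2, optics).params.gain
        assert g1 == pytest.approx(g2, rel=1e-8)

    def test_short_docking_delay_excluded(self, optics):
        truth = FitParams(2.0, 1.1, 0.15, 2.0)
        trace, anchors = make_model_trace(optics, truth, dock_frame=20, fusion_frame=23)
        with pytest.raises(EventRejected) as exc:
            RadialFusionModel(trace, anchors, optics)
        assert exc.value.reason == "short_dock"

    def test_summary_lists_all_parameters(self, optics):
        trace, anchors = make_model_trace(optics, FitParams(2.0, 1.1, 0.15, 2.0))
        res = fit_event(trace, anchors, optics)
        text = res.summary()
        for token in ("G (gain)", "D_lip", "tau_release", "tau_bleach", "lambda_TIRF"):
            assert token in text

    def test_stochastic_recovery_at_snr20(self):
        """Median relative errors on noisy traces stay well inside the
        fitter's working regime (full 200-trace study in the acceptance
        suite)."""
        cfg = SimulationConfig(n_events=40, seed=5)
        errs = {"gain": [], "tau_release_s": [], "d_lip_um2_s": []}
        for e in sample_population(cfg):
            c = replace(cfg, gaussian_sd=e.i_dock * e.gain / 20.0)
            tr = simulate_trace(e, c)
            an = extract_event_anchors(tr)
            p = fit_event(tr, an, c.optics).params
            for k in errs:
                errs[k].append(abs(getattr(p, k) - getattr(e, k)) / getattr(e, k))
        assert np.median(errs["gain"]) < 0.10
        assert np.median(errs["tau_release_s"]) < 0.10
        assert np.median(errs["d_lip_um2_s"]) < 0.25

    def test_quality_gate_flags_wrong_model_fit(self, optics, rng):
        """A trace that is not a fusion event at all is flagged, not returned
        silently."""
        radii = np.array([3.0, 5, 7, 9, 11])
        n = 130
        t = np.arange(n) * optics.frame_interval_s
        y = rng.normal(1000.0, 200.0, size=(5, n)).cumsum(axis=1) / 50.0 + 500.0
        trace = EventTrace(0, radii, t, y, np.zeros(5), 20, 60)
        anchors = extract_event_anchors(trace)
        res = fit_event(trace, anchors, optics)
        assert res.rejected
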