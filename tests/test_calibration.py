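"""Population calibration fits and the zero-size polarization extrapolation."""

import numpy as np
import pytest

from ptirf.calibration import (
    equal_contribution_radius,
    extrapolate_lambda0,
    fit_population_relations,
    polarization_correction,
)
from ptirf.optics import sbl_polarization_response, vesicle_mean_excitation


class TestPopulationRelations:
    x = np.linspace(10, 400, 40)

    def test_exponential_coefficients_recovered_exactly(self):
        lam = 0.69 * np.exp(-2.1e-3 * self.x)
        r = 2.1 * self.x**0.57
        res = fit_population_relations(self.x, lam, r)
        assert res.a1 == pytest.approx(0.69, rel=1e-6)
        assert res.b1 == pytest.approx(2.1e-3, rel=1e-6)

    def test_power_law_coefficients_recovered_exactly(self):
        lam = 0.69 * np.exp(-2.1e-3 * self.x)
        r = 2.1 * self.x**0.57
        res = fit_population_relations(self.x, lam, r)
        assert res.a2 == pytest.approx(2.1, rel=1e-6)
        assert res.b2 == pytest.approx(0.57, rel=1e-6)

    def test_lambda_vs_radius_and_binned_overlays(self):
        lam = 0.94 * np.exp(-0.023 * 2.1 * self.x**0.57)
        r = 2.1 * self.x**0.57
        res = fit_population_relations(self.x, lam, r)
        assert res.a3 == pytest.approx(0.94, rel=1e-5)
        assert res.b3 == pytest.approx(0.023, rel=1e-5)
        assert set(res.binned) == {
            "lambda_vs_intensity", "radius_vs_intensity", "lambda_vs_radius",
        }
        assert res.binned["lambda_vs_radius"]["n"].sum() == self.x.size

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_population_relations(
                np.full(12, 5.0), np.linspace(0.4, 0.8, 12), np.linspace(10, 60, 12)
            )

    def test_requires_minimum_population(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_population_relations([1, 2, 3], [0.5, 0.6, 0.7], [10, 20, 30])


class TestExtrapolateLambda0:
    def test_exact_constrained_line(self):
        r = np.linspace(5, 34, 12)
        lam = -0.0105 * (r - 78.0)
        s, lam0, ci = extrapolate_lambda0(r, lam, 78.0)
        assert s == pytest.approx(-0.0105, rel=1e-9)
        assert lam0 == pytest.approx(0.82, abs=0.005)

    def test_printed_consistency_check(self):
        # slope x depth: 0.0105 * 78 = 0.819, i.e. 0.82 to two decimals
        assert round(0.0105 * 78.0, 2) == 0.82

    def test_linearity_under_intensity_rescaling(self):
        r = np.linspace(5, 34, 12)
        lam = -0.0105 * (r - 78.0)
        _, lam0, _ = extrapolate_lambda0(r, lam, 78.0)
        _, lam0_scaled, _ = extrapolate_lambda0(r, 3.0 * lam, 78.0)
        assert lam0_scaled == pytest.approx(3.0 * lam0, rel=1e-9)

    def test_insufficient_small_vesicles(self):
        with pytest.raises(ValueError, match="insufficient"):
            extrapolate_lambda0([50.0, 60.0, 70.0], [0.4, 0.3, 0.2], 78.0)

    def test_recovery_from_forward_model_population(self):
        """Constrained-line estimate on a noisy forward-model population.

        The line is tangent to the curved size-excitation relation at the
        origin, so the default 35 nm cutoff carries a small (~4-5%) upward
        truncation bias that the tolerance accommodates.
        """
        rng = np.random.default_rng(99)
        depth, lam0_true = 78.0, 1.5
        r = rng.uniform(5, 90, size=100)
        lam = vesicle_mean_excitation(r, depth, lam0_true) * rng.normal(
            1.0, 0.05, size=100
        )
        _, lam0, _ = extrapolate_lambda0(r, lam, depth)
        assert lam0 == pytest.approx(lam0_true, rel=0.08)

    def test_truncation_bias_vanishes_with_cutoff(self):
        """Noiseless bias of the constrained line decreases with the radius
        cutoff and drops below 2% for cutoffs up to about a quarter of the
        evanescent depth."""
        depth, lam0_true = 78.0, 0.82
        r = np.linspace(1, depth / 2, 500)
        lam = vesicle_mean_excitation(r, depth, lam0_true)
        biases = []
        for rmax in (depth / 8, depth / 4, depth / 2):
            _, lam0, _ = extrapolate_lambda0(r, lam, depth, r_max_nm=rmax)
            biases.append((lam0 - lam0_true) / lam0_true)
        assert all(b > 0 for b in biases)  # curve lies above its tangent
        assert biases[0] < biases[1] < biases[2]
        assert biases[1] < 0.02


class TestEqualContributionRadius:
    def test_closed_form_root(self):
        assert equal_contribution_radius(1.5, 1 / 78.0) == pytest.approx(
            78.0 * np.log(1.5), rel=1e-9
        )

    def test_no_crossing_when_curve_below_one(self):
        assert equal_contribution_radius(0.82, 0.023) is None

    def test_monotone_in_amplitude(self):
        radii = [equal_contribution_radius(a, 0.023) for a in (1.2, 1.5, 2.0)]
        assert radii[0] < radii[1] < radii[2]


class TestPolarizationCorrection:
    sinusoid = staticmethod(lambda th: sbl_polarization_response(th, 100.0, 40.0, 0.0))

    def test_ratio_rule(self):
        def s(th):
            return {0.0: 50.0, 90.0: 20.0}[th]

        assert polarization_correction(50.0, s, 0.0, 90.0) == pytest.approx(20.0)

    def test_identity_at_reference_angle(self):
        assert polarization_correction(50.0, self.sinusoid, 30.0, 30.0) == pytest.approx(50.0)

    def test_multiplicative_composition(self):
        direct = polarization_correction(50.0, self.sinusoid, 0.0, 90.0)
        step1 = polarization_correction(50.0, self.sinusoid, 0.0, 60.0)
        step2 = polarization_correction(step1, self.sinusoid, 60.0, 90.0)
        assert step2 == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            polarization_correction(50.0, lambda th: -1.0, 0.0, 90.0)
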