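"""The tortuosity metric: per-vessel value, anatomical factor, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vesseltort as vt
from vesseltort.errors import (ContractViolationError, UndefinedScoreError)

from conftest import circle_arc, sinusoid


def quadrature_tau(amplitude, half_periods, x_span, n=200_000):
    """Independent oracle: (n-1)/L * sum(arc_i/chord_i - 1) for a sinusoid.

    Arc lengths by dense quadrature of sqrt(1 + y'^2); chords analytic
    (equal half-wave chords of x_span / half_periods each).
    """
    x = np.linspace(0.0, x_span, n)
    k = np.pi * half_periods / x_span
    dydx = amplitude * k * np.cos(k * x)
    total_arc = np.trapezoid(np.sqrt(1.0 + dydx**2), x)
    per_half_arc = total_arc / half_periods
    chord = x_span / half_periods
    return (half_periods - 1) / total_arc * half_periods * (per_half_arc / chord - 1.0)


def profile(av="artery", c_cal=0.0, c_dod=0.0, c_dfov=0.0, caliber=5.0):
    return vt.AnatomicalProfile(
        av_class=av, caliber_px=caliber, dist_od_px=10.0, dist_fovea_px=10.0,
        c_av=0.0 if av == "artery" else 1.0,
        c_caliber=c_cal, c_dod=c_dod, c_dfov=c_dfov,
    )


class TestGrisanTortuosity:
    def test_straight_vessel_scores_zero(self):
        c = vt.Centerline(np.column_stack([np.linspace(0, 10, 30), np.zeros(30)]))
        assert vt.grisan_tortuosity(c) == 0.0

    def test_single_constant_sign_arc_scores_zero(self):
        assert vt.grisan_tortuosity(vt.Centerline(circle_arc(500))) == 0.0

    def test_sinusoid_matches_quadrature_oracle(self):
        pts = sinusoid(4000, 2 * np.pi, 1.0, 2)
        tau = vt.grisan_tortuosity(vt.Centerline(pts))
        expected = quadrature_tau(1.0, 2, 2 * np.pi)
        assert tau == pytest.approx(expected, rel=5e-3)
        assert expected == pytest.approx(0.0565, abs=2e-4)

    def test_original_prefactor_divides_by_n(self):
        pts = sinusoid(2000, 2 * np.pi, 1.0, 2)
        c = vt.Centerline(pts)
        printed = vt.grisan_tortuosity(c)
        original = vt.grisan_tortuosity(
            c, vt.MetricConfig(prefactor="original"))
        assert original == pytest.approx(printed / 2, rel=1e-12)

    def test_uniform_scaling_divides_tau(self):
        pts = sinusoid(2000, 2 * np.pi, 1.0, 3)
        tau = vt.grisan_tortuosity(vt.Centerline(pts))
        tau_scaled = vt.grisan_tortuosity(vt.Centerline(pts * 7.0))
        assert tau_scaled == pytest.approx(tau / 7.0, rel=1e-6)

    def test_monotone_in_number_of_half_periods(self):
        taus = [
            vt.grisan_tortuosity(vt.Centerline(sinusoid(300 * k, 20.0, 1.0, k)))
            for k in (2, 3, 4, 6, 8)
        ]
        assert all(a < b for a, b in zip(taus[:-1], taus[1:]))


class TestWeightedFactor:
    def test_zero_weights_all_vein(self):
        w = vt.WeightConfig(0.0, 0.0, 0.0, 0.0, threshold=0.0)
        assert vt.weighted_factor(profile("vein"), w, L_c=10.0) == pytest.approx(10.0)

    def test_av_term_symmetric_at_half(self):
        w = vt.WeightConfig(w_av=0.5)
        fa = vt.weighted_factor(profile("artery"), w, L_c=3.0)
        fv = vt.weighted_factor(profile("vein"), w, L_c=3.0)
        assert fa == fv == pytest.approx(0.5 * 3.0)

    def test_hand_computed_example(self):
        w = vt.WeightConfig(0.2, 0.3, 0.4, 0.1)
        p = profile("artery", c_cal=0.5, c_dod=0.25, c_dfov=1.0)
        assert vt.weighted_factor(p, w, L_c=2.0) == pytest.approx(1.10)

    def test_unnormalized_profile_rejected_at_construction(self):
        with pytest.raises(ContractViolationError):
            profile("artery", c_cal=1.5)
        with pytest.raises(ContractViolationError):
            vt.AnatomicalProfile("artery", 5.0, 1.0, 1.0,
                                 c_av=0.5, c_caliber=0.0, c_dod=0.0, c_dfov=0.0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ContractViolationError):
            vt.weighted_factor(profile(), vt.WeightConfig(), L_c=0.0)


class TestLocalTortuosity:
    def test_annihilator_identity_product(self):
        assert vt.local_tortuosity(0.0, 5.0) == 0.0
        assert vt.local_tortuosity(0.3, 1.0) == 0.3
        assert vt.local_tortuosity(0.0565, 1.10) == pytest.approx(0.06215)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ContractViolationError):
            vt.local_tortuosity(-0.1, 1.0)


class TestComposition:
    def test_single_vessel_passthrough(self):
        assert vt.compose_global([0.3], [2.0]) == pytest.approx(0.3)

    def test_constant_tau_is_fixed_point(self):
        assert vt.compose_global([0.2, 0.2, 0.2], [1.0, 5.0, 2.5]) == pytest.approx(0.2)

    def test_hand_weighted_mean(self):
        assert vt.compose_global([0.1, 0.3], [1.0, 3.0]) == pytest.approx(0.25)

    def test_equal_weights_collapse_to_arithmetic_mean(self):
        tau = [0.1, 0.4, 0.7]
        assert vt.compose_global(tau, [2.0, 2.0, 2.0]) == pytest.approx(np.mean(tau))

    def test_bounded_by_constituents_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tau = rng.uniform(0, 1, 6)
            f = rng.uniform(0.1, 5, 6)
            out = vt.compose_global(tau, f)
            assert tau.min() - 1e-12 <= out <= tau.max() + 1e-12
            perm = rng.permutation(6)
            assert vt.compose_global(tau[perm], f[perm]) == pytest.approx(out, rel=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0.01, 10)),
                    min_size=1, max_size=12))
    def test_weighted_mean_bounds_hold_for_arbitrary_inputs(self, pairs):
        tau = np.array([p[0] for p in pairs])
        f = np.array([p[1] for p in pairs])
        out = vt.compose_global(tau, f)
        assert tau.min() - 1e-9 <= out <= tau.max() + 1e-9

    def test_literal_mode_applies_factor_twice(self):
        tau, f = [0.1, 0.3], [1.0, 3.0]
        assert vt.compose_global(tau, f, mode="literal") == pytest.approx(
            (0.1 * 1.0 * 1.0 + 0.3 * 3.0 * 3.0) / 4.0
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedScoreError):
            vt.compose_global([], [])
        with pytest.raises(UndefinedScoreError):
            vt.compose_global([0.1], [0.0])


class TestScoreRetina:
    @staticmethod
    def _retina(landmarks, amplitudes, av_classes):
        vessels = []
        for i, (a, av) in enumerate(zip(amplitudes, av_classes)):
            pts = sinusoid(400, 120.0, a, 4) + np.array([260.0, 300.0 + 40.0 * i])
            vessels.append(vt.Vessel(vessel_id=f"v{i}", points=pts, av_class=av,
                                     calibers=np.full(400, 5.0)))
        return vt.RetinaSample(retina_id="r", landmarks=landmarks, vessels=vessels)

    def test_straight_retina_scores_zero_in_both_modes(self, landmarks):
        sample = self._retina(landmarks, [0.0, 0.0], ["artery", "vein"])
        w = vt.WeightConfig(0.5, 0.5, 0.5, 0.5)
        assert vt.score_retina(sample, mode="baseline")[0] == 0.0
        assert vt.score_retina(sample, w, mode="proposed")[0] == 0.0

    def test_constant_av_factor_cancels_in_composition(self, landmarks):
        # all arteries, only the AV weight active: the bracket is the same
        # constant for every vessel, so it cancels in the weighted mean
        sample = self._retina(landmarks, [2.0, 6.0, 4.0], ["artery"] * 3)
        w = vt.WeightConfig(w_av=0.7)
        base, _ = vt.score_retina(sample, mode="baseline")
        prop, _ = vt.score_retina(sample, w, mode="proposed")
        assert prop == pytest.approx(base, rel=1e-12)

    def test_vessel_scores_satisfy_product_invariant(self, landmarks):
        sample = self._retina(landmarks, [3.0, 5.0], ["artery", "vein"])
        w = vt.WeightConfig(0.8, 0.1, 0.2, 0.6)
        _, scores = vt.score_retina(sample, w, mode="proposed")
        for s in scores:
            assert s.tau_c == pytest.approx(s.tau_g * s.f_c, rel=1e-12)
            assert s.tau_g >= 0 and s.f_c >= 0

    def test_proposed_requires_weights(self, landmarks):
        sample = self._retina(landmarks, [1.0], ["artery"])
        with pytest.raises(ContractViolationError):
            vt.score_retina(sample, mode="proposed")

    def test_features_match_direct_scoring(self, landmarks):
        sample = self._retina(landmarks, [2.0, 5.0, 0.0], ["artery", "vein", "vein"])
        w = vt.WeightConfig(0.9, 0.2, 0.1, 0.4)
        feats = vt.CohortFeatures.from_cohort([sample])
        direct, _ = vt.score_retina(sample, w, mode="proposed")
        assert feats.score_config(w)[0] == pytest.approx(direct, rel=1e-12)
        base_direct, _ = vt.score_retina(sample, mode="baseline")
        assert feats.baseline_scores()[0] == pytest.approx(base_direct, rel=1e-12)
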