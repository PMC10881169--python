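"""Phasor transform, calibration, lifetimes and fraction-bound tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimcyte import (CalibrationTransform, DecaySpec, DecayStack,
                      FreeNADHReference, apply_calibration, decay_to_phasor,
                      fit_calibration, fraction_bound, make_decay_histogram,
                      phasor_of_histogram, phasor_to_lifetimes,
                      simulate_reference, single_exp_phasor)


def _one_pixel_stack(hist, acq):
    return DecayStack(decay=np.asarray(hist).reshape(1, 1, 1, -1), acq=acq)


def _identity_cal(acq, tau_ns=4.04):
    """Calibration fitted on an ideal reference under the same binning."""
    h = simulate_reference(tau_ns, 1.0, acq, noiseless=True)
    return fit_calibration(phasor_of_histogram(h, acq), tau_ns * 1e-9, acq.omega)


class TestSingleExpPhasor:
    @pytest.mark.parametrize("tau_ns, expected", [
        (0.0, (1.0, 0.0)),
        (4.04, (0.1952, 0.3963)),
        (0.4, (0.9612, 0.1933)),
    ])
    def test_known_locations(self, acq, tau_ns, expected):
        g, s = single_exp_phasor(tau_ns * 1e-9, acq.omega)
        assert g == pytest.approx(expected[0], abs=1e-4)
        assert s == pytest.approx(expected[1], abs=1e-4)

    def test_apex_at_omega_tau_one(self, acq):
        g, s = single_exp_phasor(1.0 / acq.omega, acq.omega)
        assert (g, s) == pytest.approx((0.5, 0.5))

    def test_negative_tau_rejected(self, acq):
        with pytest.raises(ValueError):
            single_exp_phasor(-1e-9, acq.omega)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tau_ns=st.floats(0.01, 20.0))
    def test_always_on_semicircle(self, tau_ns):
        omega = 2 * np.pi * 80e6
        g, s = single_exp_phasor(tau_ns * 1e-9, omega)
        assert abs(s * s - g * (1 - g)) < 1e-12


class TestDecayToPhasor:
    def test_delta_decay_near_origin_of_phase(self, acq):
        counts = np.zeros(acq.n_time_bins)
        counts[0] = 100
        g, s = phasor_of_histogram(counts, acq)
        assert g == pytest.approx(1.0, abs=0.01)
        assert s == pytest.approx(0.0, abs=0.02)

    def test_uniform_decay_maps_to_origin(self, acq):
        counts = np.ones(acq.n_time_bins)
        g, s = phasor_of_histogram(counts, acq)
        assert abs(g) < 1e-12 and abs(s) < 1e-12

    def test_mono_exponential_matches_closed_form(self, acq):
        h = make_decay_histogram(DecaySpec(tau_free_ns=4.04, tau_bound_ns=5.0,
                                           alpha_bound=0.0, photons=1e6),
                                 acq, noiseless=True)
        g, s = phasor_of_histogram(h, acq)
        assert g == pytest.approx(0.1952, abs=2e-3)
        assert s == pytest.approx(0.3963, abs=2e-3)

    def test_zero_count_pixels_flagged_invalid(self, acq_small):
        decay = np.zeros((1, 2, 2, acq_small.n_time_bins))
        decay[0, 0, 0, :] = 1.0
        ph = decay_to_phasor(DecayStack(decay=decay, acq=acq_small))
        assert ph.valid[0, 0, 0]
        assert not ph.valid[0, 1, 1]
        assert ph.intensity[0, 0, 0] == pytest.approx(acq_small.n_time_bins)

    def test_discrete_transform_semicircle_tolerance(self, acq):
        rng = np.random.default_rng(0)
        for tau_ns in rng.uniform(0.1, 10.0, size=20):
            h = np.exp(-acq.bin_centers() / (tau_ns * 1e-9))
            g, s = phasor_of_histogram(h, acq)
            assert abs(s * s - g * (1 - g)) < 1e-3


class TestCalibration:
    def test_reference_at_analytic_location_gives_identity(self, acq):
        ga, sa = single_exp_phasor(4.04e-9, acq.omega)
        cal = fit_calibration((ga, sa), 4.04e-9, acq.omega)
        assert cal.phase_offset == pytest.approx(0.0, abs=1e-12)
        assert cal.modulation_factor == pytest.approx(1.0, abs=1e-12)

    def test_roundtrip_recovers_instrument_shift(self, acq):
        h = simulate_reference(4.04, 1e6, acq, (0.3, 0.9), noiseless=True)
        base = _identity_cal(acq)
        cal = fit_calibration(phasor_of_histogram(h, acq), 4.04e-9, acq.omega)
        # subtract the discretization part fitted from the ideal reference
        assert cal.phase_offset - base.phase_offset == pytest.approx(0.3, abs=0.01)
        assert cal.modulation_factor / base.modulation_factor == \
            pytest.approx(0.9, abs=1e-3)

    def test_calibrated_independent_monoexp_lands_on_semicircle(self, acq):
        h_ref = simulate_reference(4.04, 1e6, acq, (0.3, 0.9), noiseless=True)
        cal = fit_calibration(phasor_of_histogram(h_ref, acq), 4.04e-9, acq.omega)
        h = simulate_reference(1.5, 1e6, acq, (0.3, 0.9), noiseless=True)
        ph = apply_calibration(decay_to_phasor(_one_pixel_stack(h, acq)), cal)
        g, s = ph.g[0, 0, 0], ph.s[0, 0, 0]
        assert abs(s * s - g * (1 - g)) < 1e-3

    def test_zero_modulus_reference_rejected(self, acq):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration((0.0, 0.0), 4.04e-9, acq.omega)

    def test_apply_identity_is_noop_and_preserves_intensity(self, acq_small):
        rng = np.random.default_rng(3)
        decay = rng.poisson(50, size=(1, 4, 4, acq_small.n_time_bins))
        ph = decay_to_phasor(DecayStack(decay=decay, acq=acq_small))
        out = apply_calibration(ph, CalibrationTransform.identity())
        np.testing.assert_allclose(out.g, ph.g, atol=1e-14)
        np.testing.assert_allclose(out.s, ph.s, atol=1e-14)
        np.testing.assert_array_equal(out.intensity, ph.intensity)

    def test_rotation_then_calibration_inverts(self, acq_small):
        rng = np.random.default_rng(4)
        decay = rng.poisson(50, size=(1, 4, 4, acq_small.n_time_bins))
        ph = decay_to_phasor(DecayStack(decay=decay, acq=acq_small))
        theta = 0.25
        rotated = apply_calibration(ph, CalibrationTransform(-theta, 1.0))
        rotated.calibrated = False  # treat the rotated image as a fresh measurement
        back = apply_calibration(rotated, CalibrationTransform(theta, 1.0))
        np.testing.assert_allclose(back.g, ph.g, atol=1e-12)
        np.testing.assert_allclose(back.s, ph.s, atol=1e-12)

    def test_double_calibration_refused(self, acq_small):
        decay = np.ones((1, 2, 2, acq_small.n_time_bins))
        ph = apply_calibration(decay_to_phasor(DecayStack(decay=decay, acq=acq_small)),
                               CalibrationTransform.identity())
        with pytest.raises(ValueError, match="already calibrated"):
            apply_calibration(ph, CalibrationTransform.identity())

    def test_apply_then_invert_is_identity(self):
        cal = CalibrationTransform(0.37, 0.84)
        g, s = 0.3, 0.25
        c, si = np.cos(-cal.phase_offset), np.sin(-cal.phase_offset)
        g1 = (g * c - s * si) / cal.modulation_factor
        s1 = (g * si + s * c) / cal.modulation_factor
        c2, si2 = np.cos(cal.phase_offset), np.sin(cal.phase_offset)
        g2 = (g1 * c2 - s1 * si2) * cal.modulation_factor
        s2 = (g1 * si2 + s1 * c2) * cal.modulation_factor
        assert (g2, s2) == pytest.approx((g, s), abs=1e-12)


class TestLifetimes:
    def test_free_nadh_lifetime_recovered(self, acq):
        h = make_decay_histogram(DecaySpec(alpha_bound=0.0, photons=1e6), acq,
                                 noiseless=True)
        ph = apply_calibration(decay_to_phasor(_one_pixel_stack(h, acq)),
                               _identity_cal(acq))
        lt = phasor_to_lifetimes(ph)
        assert lt.tau_phase[0, 0, 0] == pytest.approx(0.4, rel=0.01)
        assert lt.tau_mod[0, 0, 0] == pytest.approx(0.4, rel=0.01)

    def test_mixture_has_taup_below_taum(self, acq):
        h = make_decay_histogram(DecaySpec(alpha_bound=0.5, photons=1e6), acq,
                                 noiseless=True)
        ph = apply_calibration(decay_to_phasor(_one_pixel_stack(h, acq)),
                               _identity_cal(acq))
        lt = phasor_to_lifetimes(ph)
        assert lt.tau_phase[0, 0, 0] < lt.tau_mod[0, 0, 0]

    def test_apex_gives_one_over_omega(self, acq_small):
        ph = decay_to_phasor(DecayStack(
            decay=np.ones((1, 1, 1, acq_small.n_time_bins)), acq=acq_small))
        ph.calibrated = True
        ph.g[:] = 0.5
        ph.s[:] = 0.5
        lt = phasor_to_lifetimes(ph)
        assert lt.tau_phase[0, 0, 0] * 1e-9 == pytest.approx(1 / acq_small.omega)
        assert lt.tau_mod[0, 0, 0] * 1e-9 == pytest.approx(1 / acq_small.omega)

    def test_unphysical_pixels_masked_not_raised(self, acq_small):
        ph = decay_to_phasor(DecayStack(
            decay=np.ones((1, 1, 2, acq_small.n_time_bins)), acq=acq_small))
        ph.calibrated = True
        ph.g[0, 0, 0], ph.s[0, 0, 0] = -0.1, 0.2   # g <= 0
        ph.g[0, 0, 1], ph.s[0, 0, 1] = 0.9, 0.9    # outside unit circle
        lt = phasor_to_lifetimes(ph)
        assert not lt.valid[0, 0, 0] and not lt.valid[0, 0, 1]
        assert np.isnan(lt.tau_phase[0, 0, 0])


class TestFractionBound:
    def test_distance_zero_at_reference(self, acq_small, free_ref_small):
        ph = decay_to_phasor(DecayStack(
            decay=np.ones((1, 1, 1, acq_small.n_time_bins)) * 10, acq=acq_small))
        ph.calibrated = True
        ph.g[:] = free_ref_small.g_free
        ph.s[:] = free_ref_small.s_free
        fb = fraction_bound(ph, free_ref_small, 5)
        assert fb.f_bound[0, 0, 0] == 0.0

    def test_threshold_is_strictly_above(self, acq_small, free_ref_small):
        decay = np.zeros((1, 1, 3, acq_small.n_time_bins))
        decay[0, 0, 0, 0] = 4
        decay[0, 0, 1, 0] = 5
        decay[0, 0, 2, 0] = 6
        ph = decay_to_phasor(DecayStack(decay=decay, acq=acq_small))
        ph.calibrated = True
        fb = fraction_bound(ph, free_ref_small, 5)
        assert list(fb.valid_mask[0, 0]) == [False, False, True]

    def test_chord_linearity(self, acq, free_ref, chord_length):
        cal = _identity_cal(acq)
        for alpha in np.arange(0, 1.01, 0.1):
            h = make_decay_histogram(DecaySpec(alpha_bound=alpha, photons=1e6),
                                     acq, noiseless=True)
            ph = apply_calibration(decay_to_phasor(_one_pixel_stack(h, acq)), cal)
            fb = fraction_bound(ph, free_ref, 5)
            assert fb.f_bound[0, 0, 0] == pytest.approx(alpha * chord_length,
                                                        abs=1e-3)

    def test_strictly_increasing_in_alpha(self, acq, free_ref):
        cal = _identity_cal(acq)
        vals = []
        for alpha in np.linspace(0, 1, 21):
            h = make_decay_histogram(DecaySpec(alpha_bound=alpha, photons=1e6),
                                     acq, noiseless=True)
            ph = apply_calibration(decay_to_phasor(_one_pixel_stack(h, acq)), cal)
            vals.append(fraction_bound(ph, free_ref, 5).f_bound[0, 0, 0])
        assert np.all(np.diff(vals) > 0)

    def test_intensity_scale_invariance(self, acq_small, free_ref_small):
        rng = np.random.default_rng(5)
        base = rng.poisson(100, size=(1, 4, 4, acq_small.n_time_bins)).astype(float)
        ph0 = decay_to_phasor(DecayStack(decay=base, acq=acq_small))
        ph0.calibrated = True
        fb0 = fraction_bound(ph0, free_ref_small, 0)
        for c in (0.5, 2.0, 10.0):
            ph = decay_to_phasor(DecayStack(decay=base * c, acq=acq_small))
            ph.calibrated = True
            fb = fraction_bound(ph, free_ref_small, 0)
            np.testing.assert_allclose(ph.g, ph0.g, rtol=1e-12, atol=1e-14)
            np.testing.assert_allclose(ph.s, ph0.s, rtol=1e-12, atol=1e-14)
            np.testing.assert_allclose(fb.f_bound, fb0.f_bound, rtol=1e-12,
                                       atol=1e-14)

    def test_noisy_field_mean_alpha_recovery(self, acq, free_ref, chord_length):
        """Poisson noise at 300 photons/pixel: the field mean of recovered
        alpha stays within 0.02 of truth (3 seeds, 128x128 field)."""
        cal = _identity_cal(acq)
        expected = make_decay_histogram(DecaySpec(alpha_bound=0.5, photons=300),
                                        acq, noiseless=True)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            decay = rng.poisson(np.broadcast_to(expected, (1, 128, 128, acq.n_time_bins)))
            ph = apply_calibration(decay_to_phasor(DecayStack(decay=decay, acq=acq)), cal)
            fb = fraction_bound(ph, free_ref, 5)
            alpha_rec = (fb.f_bound[fb.valid_mask] / chord_length).mean()
            assert alpha_rec == pytest.approx(0.5, abs=0.02)

    def test_region_average_order_agrees_when_homogeneous(self, acq, free_ref):
        """Averaging (g, s) then taking the distance vs averaging per-pixel
        distances: < 0.01 apart for a homogeneous Poisson-noise region."""
        cal = _identity_cal(acq)
        expected = make_decay_histogram(DecaySpec(alpha_bound=0.4, photons=300),
                                        acq, noiseless=True)
        rng = np.random.default_rng(1)
        decay = rng.poisson(np.broadcast_to(expected, (1, 32, 32, acq.n_time_bins)))
        ph = apply_calibration(decay_to_phasor(DecayStack(decay=decay, acq=acq)), cal)
        fb = fraction_bound(ph, free_ref, 5)
        per_pixel_mean = fb.f_bound[fb.valid_mask].mean()
        g_mean, s_mean = ph.g[fb.valid_mask].mean(), ph.s[fb.valid_mask].mean()
        phasor_avg = np.hypot(g_mean - free_ref.g_free, s_mean - free_ref.s_free)
        assert abs(per_pixel_mean - phasor_avg) < 0.01

    def test_reference_on_semicircle_and_max_distance(self, free_ref):
        g, s = free_ref.g_free, free_ref.s_free
        assert abs(s * s - g * (1 - g)) < 1e-12
        assert free_ref.max_distance() > np.hypot(1 - g, s) - 1e-9
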