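"""Unit tests for the cellular-component waveform generator."""

import numpy as np
import pytest

from ergtwin.forward_model import (
    StimulusSpec,
    add_noise,
    apply_lesion,
    bipolar_kernel,
    flicker_steady_state_amplitude,
    gamma_kernel,
    make_time_grid,
    off_bipolar_kernel,
    oscillatory_potentials,
    photoreceptor_piii,
    synthesize_flash_response,
    synthesize_flicker_response,
)
from ergtwin.processing import gradient_change_prominence


class TestPhotoreceptorPiii:
    def test_zero_before_transduction_delay(self):
        t = np.array([-5.0, 0.0, 1.9, 2.0])
        out = photoreceptor_piii(t, 4.0, 0.005, 100.0, 2.0)
        assert np.all(out == 0.0)

    def test_saturation_asymptote(self):
        out = photoreceptor_piii(np.array([1e4]), 4.0, 0.005, 100.0, 2.0)
        assert out[0] == pytest.approx(-100.0, abs=1e-9)

    def test_closed_form_value(self):
        # -100 * (1 - exp(-4.0 * 0.005 * (12-2)^2)) = -100 * (1 - e^-2)
        out = photoreceptor_piii(np.array([12.0]), 4.0, 0.005, 100.0, 2.0)
        assert out[0] == pytest.approx(-86.46647167633873, rel=1e-12)

    def test_monotone_in_time_and_strength(self):
        t = np.linspace(0, 100, 500)
        a = photoreceptor_piii(t, 1.0, 0.005, 100.0, 2.0)
        assert np.all(np.diff(a) <= 1e-12)  # magnitude nondecreasing
        b = photoreceptor_piii(t, 3.0, 0.005, 100.0, 2.0)
        assert np.all(b <= a + 1e-12)

    def test_rejects_bad_parameters(self):
        t = np.array([1.0])
        with pytest.raises(ValueError):
            photoreceptor_piii(t, -1.0, 0.005, 100.0, 2.0)
        with pytest.raises(ValueError):
            photoreceptor_piii(t, 1.0, 0.0, 100.0, 2.0)
        with pytest.raises(ValueError):
            photoreceptor_piii(t, 1.0, 0.005, -5.0, 2.0)


class TestBipolarKernels:
    def test_zero_gain_is_zero(self):
        t = np.linspace(0, 100, 200)
        assert np.all(bipolar_kernel(t, 0.0, 30.0, 3.0) == 0.0)

    def test_unit_peak_normalization(self):
        out = bipolar_kernel(np.array([30.0]), 42.0, 30.0, 3.0)
        assert out[0] == pytest.approx(42.0, rel=1e-12)
        out = bipolar_kernel(np.array([30.0]), 42.0, 30.0, 3.0, onset=10.0)
        assert out[0] == pytest.approx(42.0, rel=1e-12)

    def test_rejects_nonpositive_peak_time(self):
        with pytest.raises(ValueError):
            bipolar_kernel(np.array([1.0]), 1.0, 0.0, 3.0)
        with pytest.raises(ValueError):
            gamma_kernel(np.array([1.0]), 5.0, 3.0, onset=5.0)

    def test_off_kernel_lobe_order(self, gains):
        """The negative extremum of the biphasic OFF kernel precedes the
        positive extremum (dense-grid extremum search)."""
        t = np.arange(0.0, 250.0, 0.01)
        k = off_bipolar_kernel(
            t, 1.0, gains.off_pos_weight,
            gains.off_neg_peak, gains.off_pos_peak,
            gains.off_neg_shape, gains.off_pos_shape,
            gains.off_neg_onset, gains.off_pos_onset,
        )
        assert k.min() < 0 < k.max()
        assert t[k.argmin()] < t[k.argmax()]

    def test_off_kernel_rejects_bad_lobe_order(self):
        with pytest.raises(ValueError):
            off_bipolar_kernel(np.array([1.0]), 1, 1, 10, 30, 1, 4, 20.0, 5.0)


class TestOscillatoryPotentials:
    def test_zero_gain_and_onset_gate(self):
        t = np.linspace(0, 100, 400)
        assert np.all(oscillatory_potentials(t, 0.0) == 0.0)
        out = oscillatory_potentials(t, 5.0, onset=13.0)
        assert np.all(out[t <= 13.0] == 0.0)

    def test_damped_envelope(self):
        t = np.arange(0, 200, 0.01)
        out = oscillatory_potentials(t, 5.0, 120.0, 0.05, 10.0)
        # successive extrema decrease in magnitude
        idx = np.where((np.abs(out[1:-1]) > np.abs(out[:-2]))
                       & (np.abs(out[1:-1]) >= np.abs(out[2:])))[0] + 1
        mags = np.abs(out[idx])
        assert np.all(np.diff(mags) < 0)

    def test_peak_count_matches_dense_grid(self):
        """Maxima in 10-40 ms at defaults: brute-force count on a dense
        grid equals the count on the acquisition grid."""
        def count_maxima(dt):
            t = np.arange(0.0, 60.0, dt)
            v = oscillatory_potentials(t, 6.0)
            inner = (t[1:-1] >= 10.0) & (t[1:-1] <= 40.0)
            is_max = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
            return int(np.sum(is_max & inner))

        # dense-grid brute force: 4 maxima (damping pulls each peak ahead
        # of the undamped pi/2 phase, so the 4th lands just inside 40 ms)
        assert count_maxima(0.001) == count_maxima(0.5) == 4


class TestApplyLesion:
    def test_identity(self, gains):
        assert apply_lesion(gains, "none") is gains

    def test_crao_spares_photoreceptors(self, gains):
        out = apply_lesion(gains, "crao")
        assert out.on_bipolar_gain == out.off_bipolar_gain == out.op_gain == 0.0
        assert out.rod_pr_max == gains.rod_pr_max
        assert out.cone_pr_max == gains.cone_pr_max

    def test_ccsnb_zeroes_only_on_pathway(self, gains):
        out = apply_lesion(gains, "ccsnb")
        assert out.on_bipolar_gain == 0.0
        assert out.off_bipolar_gain == gains.off_bipolar_gain
        assert out.op_gain == gains.op_gain

    def test_unknown_lesion_rejected(self, gains):
        with pytest.raises(ValueError):
            apply_lesion(gains, "laser")


class TestSynthesizeFlash:
    def test_decomposition_closure(self, gains, by_label):
        for label in ("DA 3", "LA 3", "X67-blue"):
            resp = synthesize_flash_response(by_label[label], gains)
            total = sum(c.volts for c in resp.components.values())
            assert np.allclose(resp.trace.volts, total, rtol=0, atol=1e-12)

    def test_crao_sum_is_pure_photoreceptor(self, gains, by_label):
        resp = synthesize_flash_response(by_label["DA 3"], gains, "crao")
        expected = resp.components["rod_pr"].volts + resp.components["cone_pr"].volts
        assert np.array_equal(resp.trace.volts, expected)

    def test_blue_background_silences_rod_components(self, gains, by_label):
        resp = synthesize_flash_response(by_label["X67-blue"], gains)
        assert np.all(resp.components["rod_pr"].volts == 0.0)
        assert np.all(resp.components["rod_on_bipolar"].volts == 0.0)

    def test_blue_equals_rod_gains_zeroed(self, gains, by_label):
        """Idealized blue background is bit-identical to synthesizing with
        the rod pathway gains set to zero."""
        blue = synthesize_flash_response(by_label["X67-blue"], gains)
        zeroed = gains.replace(rod_pr_max=0.0, rod_pii_weight=0.0)
        dark = StimulusSpec("X67-dark0", 67.0)
        ref = synthesize_flash_response(dark, zeroed)
        assert np.array_equal(blue.trace.volts, ref.trace.volts)

    def test_partial_rod_suppression(self, gains, by_label):
        resp = synthesize_flash_response(
            by_label["X67-blue"], gains, rod_suppression=0.8
        )
        rod = resp.components["rod_pr"].volts
        full = synthesize_flash_response(by_label["X67-dark"], gains)
        assert np.allclose(rod, 0.2 * full.components["rod_pr"].volts, atol=1e-9)

    def test_lesion_nesting(self, gains, by_label):
        """CRAO = cCSNB minus the OFF component, and setting the OFF gain
        to zero in a cCSNB synthesis reproduces the CRAO response exactly
        (oscillatory potentials are ON-gated, so both vanish with the ON
        pathway)."""
        stim = by_label["X67-blue"]
        crao = synthesize_flash_response(stim, gains, "crao")
        ccsnb = synthesize_flash_response(stim, gains, "ccsnb")
        assert np.all(ccsnb.components["oscillatory"].volts == 0.0)
        derived = (
            ccsnb.trace.volts
            - ccsnb.components["cone_off_bipolar"].volts
            - ccsnb.components["oscillatory"].volts
        )
        assert np.allclose(crao.trace.volts, derived, rtol=0, atol=1e-9)
        ccsnb_no_off = synthesize_flash_response(
            stim, gains.replace(off_bipolar_gain=0.0), "ccsnb"
        )
        assert np.array_equal(crao.trace.volts, ccsnb_no_off.trace.volts)

    def test_a_trough_monotone_in_flash_strength(self, gains):
        troughs = []
        for strength in (0.01, 0.67, 3.0, 4.0, 10.0, 13.0, 67.0):
            stim = StimulusSpec(f"S{strength}", strength)
            tr = synthesize_flash_response(stim, gains).trace
            mask = tr.window(3.0, 30.0)
            troughs.append(-tr.volts[mask].min())
        assert np.all(np.diff(troughs) >= -1e-9)

    def test_off_gain_creates_gradient_change(self, gains, by_label):
        """The light-adapted flash waveform shows a gradient change in the
        20-30 ms window with the default OFF gain that disappears when the
        OFF gain is substantially reduced."""
        la3 = by_label["LA 3"]
        full = synthesize_flash_response(la3, gains).trace
        reduced = synthesize_flash_response(
            la3, gains.replace(off_bipolar_gain=0.25 * gains.off_bipolar_gain)
        ).trace
        assert gradient_change_prominence(full) >= 1.0
        assert gradient_change_prominence(reduced) <= 0.5

    def test_flicker_stimulus_rejected(self, gains, by_label):
        with pytest.raises(ValueError):
            synthesize_flash_response(by_label["LA 30Hz"], gains)


class TestSynthesizeFlicker:
    def test_zero_cone_gains_flat(self, gains, by_label):
        dead = gains.replace(
            cone_pr_max=0.0, on_bipolar_gain=0.0, off_bipolar_gain=0.0, op_gain=0.0
        )
        tr = synthesize_flicker_response(by_label["LA 30Hz"], dead)
        assert np.all(tr.volts == 0.0)

    def test_periodicity(self, gains, by_label):
        period = 1000.0 / 30.0
        grid = make_time_grid()
        a = synthesize_flicker_response(by_label["LA 30Hz"], gains, grid=grid)
        b = synthesize_flicker_response(by_label["LA 30Hz"], gains, grid=grid + period)
        assert np.allclose(a.volts, b.volts, rtol=0, atol=1e-9)

    def test_ccsnb_reduced_but_nonzero(self, gains, by_label):
        amp = flicker_steady_state_amplitude(by_label["LA 30Hz"], gains)
        amp_ccsnb = flicker_steady_state_amplitude(by_label["LA 30Hz"], gains, "ccsnb")
        assert 0.0 < amp_ccsnb < amp

    def test_single_flash_rejected(self, gains, by_label):
        with pytest.raises(ValueError):
            synthesize_flicker_response(by_label["LA 3"], gains)


class TestAddNoise:
    def test_zero_noise_identity(self, gains, by_label):
        tr = synthesize_flash_response(by_label["DA 3"], gains).trace
        out = add_noise(tr, 0.0, 0.0, seed=1)
        assert np.array_equal(out.volts, tr.volts)

    def test_seed_determinism(self, gains, by_label):
        tr = synthesize_flash_response(by_label["DA 3"], gains).trace
        a = add_noise(tr, 5.0, 2.0, seed=42)
        b = add_noise(tr, 5.0, 2.0, seed=42)
        assert np.array_equal(a.volts, b.volts)
        c = add_noise(tr, 5.0, 2.0, seed=43)
        assert not np.array_equal(a.volts, c.volts)

    def test_noise_variance(self):
        """Sample variance of (noisy - clean) matches noise_sd^2 within 2%
        over 1e5 samples."""
        from ergtwin.forward_model import Trace

        n = 100_001
        tr = Trace(np.linspace(-20, 480, n), np.zeros(n))
        out = add_noise(tr, 3.0, 0.0, seed=7)
        assert np.var(out.volts) == pytest.approx(9.0, rel=0.02)

    def test_negative_sd_rejected(self, gains, by_label):
        tr = synthesize_flash_response(by_label["DA 3"], gains).trace
        with pytest.raises(ValueError):
            add_noise(tr, -1.0)


class TestStimulusSpec:
    def test_dark_background_luminance_invariant(self):
        with pytest.raises(ValueError):
            StimulusSpec("bad", 3.0, "dark", 30.0, 0.0)

    def test_blue_background_defaults(self):
        s = StimulusSpec.blue_background("X4-blue", 4.0)
        assert s.background_scotopic_luminance == 30.0
        assert s.background_photopic_luminance == 1.0

    def test_nonpositive_flash_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec("bad", 0.0)
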