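"""Unit tests for baseline, artifact rejection, averaging, feature
measurement and rod isolation."""

import numpy as np
import pytest

from ergtwin.forward_model import (
    Trace,
    add_noise,
    make_time_grid,
    synthesize_flash_response,
    synthesize_flicker_response,
    flicker_steady_state_amplitude,
)
from ergtwin.processing import (
    average_traces,
    estimate_baseline,
    extract_features,
    isolate_rod_response,
    measure_a_wave,
    measure_b_wave,
    measure_flicker_amplitude,
    reject_artifacts,
)


def _trace(volts, grid=None, **meta):
    grid = make_time_grid() if grid is None else grid
    v = np.broadcast_to(np.asarray(volts, float), grid.shape).copy()
    return Trace(grid, v, meta)


class TestEstimateBaseline:
    def test_constant(self):
        assert estimate_baseline(_trace(3.25)) == 3.25

    def test_post_stimulus_isolation(self):
        tr = _trace(1.0)
        tr.volts[tr.times >= 0] += np.sin(tr.times[tr.times >= 0])
        assert estimate_baseline(tr) == 1.0

    def test_linear_drift_closed_form(self):
        grid = make_time_grid()
        a, b = 2.0, 0.3
        tr = Trace(grid, a + b * grid)
        expected = a + b * grid[(grid >= -20) & (grid < 0)].mean()  # a - 10.25 b
        assert estimate_baseline(tr) == pytest.approx(expected, rel=1e-12)

    def test_insufficient_prestimulus_rejected(self):
        grid = -10.0 + 0.5 * np.arange(100)
        with pytest.raises(ValueError):
            estimate_baseline(Trace(grid, np.zeros(100)))


class TestRejectArtifacts:
    def test_clean_sweeps_all_kept(self, rng):
        sweeps = [_trace(0.0) for _ in range(5)]
        for s in sweeps:
            s.volts += rng.normal(0, 3, s.volts.shape)
        kept, log = reject_artifacts(sweeps)
        assert len(kept) == 5 and not log["rejected"]

    def test_injected_transient_removed(self, rng):
        sweeps = [_trace(0.0) for _ in range(6)]
        for s in sweeps:
            s.volts += rng.normal(0, 3, s.volts.shape)
        bad = sweeps[2]
        bad.volts[300] += 2000.0
        kept, log = reject_artifacts(sweeps)
        assert len(kept) == 5
        assert [r["index"] for r in log["rejected"]] == [2]

    def test_all_noise_keeps_single_best(self, rng):
        sweeps = [_trace(0.0) for _ in range(4)]
        for s in sweeps:
            s.volts += rng.normal(0, 2000, s.volts.shape)
        kept, log = reject_artifacts(sweeps)
        assert len(kept) == 1 and log["all_failed"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reject_artifacts([])


class TestAverageTraces:
    def test_single_trace_identity(self):
        tr = _trace(1.5)
        out = average_traces([tr])
        assert np.array_equal(out.volts, tr.volts)

    def test_negation_cancels(self):
        tr = _trace(0.0)
        tr.volts += np.sin(tr.times)
        neg = tr.copy(volts=-tr.volts)
        assert np.all(average_traces([tr, neg]).volts == 0.0)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        grid = make_time_grid()
        clean = np.zeros_like(grid)
        def resid_sd(n):
            sweeps = [Trace(grid, clean + rng.normal(0, 5, grid.shape)) for _ in range(n)]
            return average_traces(sweeps).volts.std()

        assert resid_sd(64) == pytest.approx(resid_sd(4) / 4.0, rel=0.3)

    def test_grid_mismatch_rejected(self):
        a = _trace(0.0)
        b = Trace(a.times + 0.1, a.volts)
        with pytest.raises(ValueError):
            average_traces([a, b])


class TestMeasureAWave:
    def test_flat_trace(self):
        amp, t = measure_a_wave(_trace(0.0))
        assert amp == 0.0 and t == 3.0  # earliest sample in the window

    def test_reporting_convention(self):
        tr = _trace(0.0)
        tr.volts[tr.window(10, 12)] = -150.0
        amp, t = measure_a_wave(tr, baseline=0.0)
        assert amp == 150.0 and t == 10.0  # earliest tie wins

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            measure_a_wave(_trace(0.0), window=(3.0, 500.0))


class TestMeasureBWave:
    def test_pure_positive_kernel(self):
        from ergtwin.forward_model import bipolar_kernel

        grid = make_time_grid()
        tr = Trace(grid, bipolar_kernel(grid, 80.0, 40.0, 3.0))
        amp, t = measure_b_wave(tr)
        assert amp == pytest.approx(80.0, rel=1e-9)
        assert t == 40.0

    def test_trough_to_peak_arithmetic(self):
        tr = _trace(0.0)
        tr.volts[tr.window(14, 15)] = -20.0
        tr.volts[tr.window(40, 41)] = 80.0
        amp, _ = measure_b_wave(tr, baseline=0.0)
        assert amp == 100.0

    def test_dim_flash_uses_baseline_reference(self):
        tr = _trace(0.0)
        tr.volts[tr.window(40, 41)] = 60.0
        amp, _ = measure_b_wave(tr, baseline=0.0, a_window=None)
        assert amp == 60.0


class TestMeasureFlicker:
    def test_pure_sinusoid(self):
        grid = make_time_grid()
        period = 1000.0 / 30.0
        tr = Trace(grid, 7.0 * np.sin(2 * np.pi * grid / period))
        assert measure_flicker_amplitude(tr) == pytest.approx(14.0, rel=0.01)

    def test_flat(self):
        assert measure_flicker_amplitude(_trace(0.0)) == 0.0

    def test_too_few_cycles_rejected(self):
        grid = -20.0 + 0.5 * np.arange(140)  # 50 ms post-stimulus
        with pytest.raises(ValueError):
            measure_flicker_amplitude(Trace(grid, np.zeros(140)))

    def test_round_trip_through_generator(self, gains, by_label):
        tr = synthesize_flicker_response(by_label["LA 30Hz"], gains)
        ref = flicker_steady_state_amplitude(by_label["LA 30Hz"], gains)
        assert measure_flicker_amplitude(tr) == pytest.approx(ref, rel=0.01)


class TestIsolateRod:
    def test_identical_traces_cancel(self):
        a = _trace(5.0, flash_strength=4.0)
        b = _trace(5.0, flash_strength=4.0)
        assert np.all(isolate_rod_response(a, b).volts == 0.0)

    def test_noiseless_closure(self, gains, by_label):
        dark = synthesize_flash_response(by_label["X4-dark"], gains)
        blue = synthesize_flash_response(by_label["X4-blue"], gains)
        dark.trace.meta["flash_strength"] = blue.trace.meta["flash_strength"] = 4.0
        rod = isolate_rod_response(dark.trace, blue.trace)
        truth = (
            dark.components["rod_pr"].volts + dark.components["rod_on_bipolar"].volts
        )
        assert np.allclose(rod.volts, truth, rtol=0, atol=1e-9)

    def test_variance_addition(self, gains, by_label, rng):
        """Residual against the true rod trace has per-sample variance
        ~2 sigma^2 when both inputs carry independent noise sd sigma."""
        dark = synthesize_flash_response(by_label["X4-dark"], gains)
        blue = synthesize_flash_response(by_label["X4-blue"], gains)
        truth = (
            dark.components["rod_pr"].volts + dark.components["rod_on_bipolar"].volts
        )
        sigma = 4.0
        resid = []
        for _ in range(40):
            d = add_noise(dark.trace, sigma, rng=rng)
            b = add_noise(blue.trace, sigma, rng=rng)
            d.meta["flash_strength"] = b.meta["flash_strength"] = 4.0
            resid.append(isolate_rod_response(d, b).volts - truth)
        assert np.var(np.concatenate(resid)) == pytest.approx(2 * sigma**2, rel=0.05)

    def test_flash_strength_mismatch_rejected(self):
        a = _trace(0.0, flash_strength=4.0)
        b = _trace(0.0, flash_strength=13.0)
        with pytest.raises(ValueError):
            isolate_rod_response(a, b)

    def test_commutes_with_averaging(self, gains, by_label, rng):
        darks, blues = [], []
        for _ in range(4):
            d = add_noise(synthesize_flash_response(by_label["X13-dark"], gains).trace, 5.0, rng=rng)
            b = add_noise(synthesize_flash_response(by_label["X13-blue"], gains).trace, 5.0, rng=rng)
            d.meta["flash_strength"] = b.meta["flash_strength"] = 13.0
            darks.append(d)
            blues.append(b)
        avg_then_sub = isolate_rod_response(
            average_traces(darks, flash_strength=13.0),
            average_traces(blues, flash_strength=13.0),
        )
        sub_then_avg = average_traces(
            [isolate_rod_response(d, b) for d, b in zip(darks, blues)]
        )
        assert np.allclose(avg_then_sub.volts, sub_then_avg.volts, rtol=0, atol=1e-10)


class TestExtractFeatures:
    @staticmethod
    def _noiseless_sweeps(gains, protocol, n_sweeps=1, eyes=("R", "L")):
        sweeps = []
        for stim in protocol:
            if stim.mode == "flicker_30hz":
                base = synthesize_flicker_response(stim, gains)
            else:
                base = synthesize_flash_response(stim, gains).trace
            for eye in eyes:
                for j in range(n_sweeps):
                    sw = base.copy()
                    sw.meta.update(
                        stimulus=stim.label, eye=eye, sweep=j,
                        flash_strength=stim.flash_strength,
                        background=stim.background_kind, mode=stim.mode,
                    )
                    sweeps.append(sw)
        return sweeps

    def test_eye_combination_equivalence(self, gains, by_label):
        """For identical noiseless eyes, parameter-level eye averaging
        equals the single-eye measurement."""
        protocol = [by_label["DA 3"], by_label["X67-dark"], by_label["X67-blue"]]
        both, _ = extract_features(self._noiseless_sweeps(gains, protocol))
        single, _ = extract_features(
            self._noiseless_sweeps(gains, protocol, eyes=("R",))
        )
        assert both == pytest.approx(single)

    def test_dim_flash_has_no_a_wave_parameter(self, gains, by_label):
        feats, _ = extract_features(
            self._noiseless_sweeps(gains, [by_label["DA 0.01"]])
        )
        assert "DA 0.01 b" in feats and "DA 0.01 a" not in feats

    def test_contaminated_sessions_converge_to_clean(self, gains, by_label, rng):
        """With artifact rejection, features from contaminated sessions
        approach the clean-session values as sweep count grows."""
        stim = by_label["DA 3"]
        clean = synthesize_flash_response(stim, gains).trace

        def feats_with(n_sweeps):
            sweeps = []
            for j in range(n_sweeps):
                sw = add_noise(clean, 8.0, rng=rng)
                if j % 5 == 0:
                    sw.volts[400] += 3000.0
                sw.meta.update(
                    stimulus=stim.label, eye="R", sweep=j,
                    flash_strength=stim.flash_strength,
                    background=stim.background_kind, mode=stim.mode,
                )
                sweeps.append(sw)
            out, _ = extract_features(sweeps)
            return out["DA 3 a"]

        truth = measure_a_wave(clean)[0]
        assert abs(feats_with(40) - truth) < 3.0
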