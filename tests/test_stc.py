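"""Transporter-current analysis: isolation, kinetic fits, deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gluclear import stc as ST
from gluclear import synth as S


def _trace(samples, rate=10.0, stim=50.0):
    return ST.CurrentTrace(np.asarray(samples, float), rate, stim)


class TestIsolation:
    def test_null_subtraction(self):
        spec = S.SynthSpec(seed=0, noise_sd_pa=0.0, facilitation=1.0)
        single, paired_same, _ = S.synth_fstc(spec)
        # facilitation 1.0: the second response equals the first; the fSTC
        # is that response itself, so isolating from (single, single) is zero
        fstc = ST.isolate_fstc(single, single)
        assert np.allclose(fstc.samples, 0.0)

    def test_facilitation_scales_fstc(self):
        spec = S.SynthSpec(seed=0, noise_sd_pa=0.0, facilitation=1.5)
        single, paired, _ = S.synth_fstc(spec)
        fstc = ST.isolate_fstc(single, paired)
        i0 = single.index_of(single.stim_ms)
        single_amp = np.abs(single.samples).max()
        assert np.abs(fstc.samples).max() == pytest.approx(1.5 * single_amp,
                                                           rel=1e-6)

    def test_alignment_to_own_stimulus(self):
        spec = S.SynthSpec(seed=0, noise_sd_pa=0.0)
        single, paired, _ = S.synth_fstc(spec)
        fstc = ST.isolate_fstc(single, paired)
        # response onset sits at the stimulus time, as in the single trace
        i_stim = fstc.index_of(fstc.stim_ms)
        assert np.allclose(fstc.samples[: i_stim - 5], 0.0, atol=1e-9)
        assert np.abs(fstc.samples[i_stim + 5:]).max() > 1.0

    def test_rate_mismatch_rejected(self):
        a = _trace(np.zeros(2000), rate=10.0)
        b = _trace(np.zeros(2000), rate=20.0)
        with pytest.raises(ST.TraceError, match="rate"):
            ST.isolate_fstc(a, b)


class TestMultiExponentialFit:
    def test_self_consistency_noise_free(self):
        # waveform generated from the fit model itself is recovered to 1%
        t = np.arange(0, 300, 0.1)
        true = dict(amp=30.0, t0=0.3, tau_rise=1.0, tau_fast=5.3,
                    tau_slow=18.3, frac_fast=0.6)
        y = ST._model_curve(t - 50.0, **true)
        fit = ST.fit_multiexponential(_trace(-y))
        assert fit.tau_rise_ms == pytest.approx(1.0, rel=0.01)
        assert fit.tau_fast_ms == pytest.approx(5.3, rel=0.01)
        assert fit.tau_slow_ms == pytest.approx(18.3, rel=0.01)
        assert fit.frac_fast == pytest.approx(0.6, rel=0.01)
        assert fit.sign == -1

    def test_noisy_recovery_median_error(self):
        t = np.arange(0, 300, 0.1)
        true = dict(amp=30.0, t0=0.3, tau_rise=1.0, tau_fast=5.3,
                    tau_slow=18.3, frac_fast=0.6)
        y = ST._model_curve(t - 50.0, **true)
        rng = np.random.default_rng(1)
        errs = []
        for _ in range(20):
            fit = ST.fit_multiexponential(
                _trace(-(y + rng.normal(0, 0.01 * np.abs(y).max(), len(y)))))
            errs.append(abs(fit.tau_slow_ms / 18.3 - 1))
        assert np.median(errs) < 0.05

    def test_single_exponential_degenerates(self):
        t = np.arange(0, 300, 0.1)
        y = ST._model_curve(t - 50.0, amp=10.0, t0=0.0, tau_rise=0.5,
                            tau_fast=10.0, tau_slow=10.0, frac_fast=1.0)
        fit = ST.fit_multiexponential(_trace(-y))
        mono = (fit.frac_fast > 0.95 or fit.frac_fast < 0.05
                or abs(fit.tau_fast_ms / fit.tau_slow_ms - 1) < 0.2)
        assert mono

    def test_flat_trace_raises(self):
        with pytest.raises(ST.FitError):
            ST.fit_multiexponential(_trace(np.zeros(2000)))


class TestRise2080:
    def test_saturating_exponential(self):
        t = np.arange(0, 100, 0.1)
        y = np.where(t >= 50.0, 1 - np.exp(-(t - 50.0) / 2.0), 0.0)
        assert ST.rise_20_80(_trace(y)) == pytest.approx(2 * np.log(4),
                                                         abs=0.05)

    def test_linear_ramp(self):
        t = np.arange(0, 100, 0.1)
        ramp = np.clip((t - 50.0) / 20.0, 0, 1)  # 20 ms ramp
        assert ST.rise_20_80(_trace(ramp)) == pytest.approx(0.6 * 20.0,
                                                            abs=0.05)

    def test_flat_trace_raises(self):
        with pytest.raises(ST.TraceError):
            ST.rise_20_80(_trace(np.zeros(1000)))


class TestCentroid:
    def test_rectangular_pulse(self):
        y = np.zeros(2000)
        i0 = 500
        y[i0:i0 + 100] = -3.0  # 10 ms wide pulse from the stimulus
        assert ST.centroid(_trace(y)) == pytest.approx(10.0 / 2, abs=0.06)

    def test_single_exponential_equals_tau(self):
        t = np.arange(0, 400, 0.1)
        y = np.where(t >= 50.0, np.exp(-(t - 50.0) / 7.0), 0.0)
        tr = ST.CurrentTrace(y, 10.0, 50.0)
        got = ST.centroid(tr, window_ms=(0.0, 350.0))
        assert got == pytest.approx(7.0, rel=0.01)

    def test_biexponential_closed_form(self):
        t = np.arange(0, 1000, 0.1)
        y = np.where(t >= 50.0,
                     0.5 * np.exp(-(t - 50.0) / 5.0)
                     + 0.5 * np.exp(-(t - 50.0) / 15.0), 0.0)
        tr = ST.CurrentTrace(y, 10.0, 50.0)
        # (f tf^2 + (1-f) ts^2) / (f tf + (1-f) ts) = 12.5 ms
        assert ST.centroid(tr, window_ms=(0.0, 900.0)) == pytest.approx(
            12.5, rel=0.01)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariant(self, scale):
        rng = np.random.default_rng(0)
        y = np.zeros(2000)
        y[500:900] = -np.abs(rng.standard_normal(400)) - 0.1
        tr = ST.CurrentTrace(y, 10.0, 50.0)
        tr2 = ST.CurrentTrace(y * scale, 10.0, 50.0)
        assert ST.centroid(tr2) == pytest.approx(ST.centroid(tr), rel=1e-9)

    def test_shift_equivariant(self):
        y = np.zeros(4000)
        y[600:1000] = -2.0
        a = ST.centroid(ST.CurrentTrace(y, 10.0, 50.0))
        shifted = np.roll(y, 300)
        b = ST.centroid(ST.CurrentTrace(shifted, 10.0, 80.0))
        assert b == pytest.approx(a, abs=0.02)

    def test_zero_integral_raises(self):
        with pytest.raises(ST.TraceError):
            ST.centroid(_trace(np.zeros(2000)))


class TestDeconvolution:
    def test_identity_filter_returns_input_shape(self):
        spec = S.SynthSpec(seed=2, noise_sd_pa=0.0)
        single, paired, truth = S.synth_fstc(spec)
        fstc = ST.isolate_fstc(single, paired)
        dt = fstc.dt_ms
        delta = np.zeros(500)
        delta[0] = 1.0 / dt
        ce = ST.estimate_clearance(fstc, delta, reg=1e-8)
        assert ce.centroid_ms == pytest.approx(
            ST.centroid(fstc), rel=0.02)

    def test_self_deconvolution_gives_delta(self):
        # a trace equal to its own decay kernel deconvolves to a spike at 0
        t = np.arange(0, 200, 0.1)
        decay = np.where(t >= 50.0, np.exp(-(t - 50.0) / 12.0), 0.0)
        tr = ST.CurrentTrace(-decay, 10.0, 50.0)
        filt = ST.derive_filter(tr, reg=1e-8)
        dt = 0.1
        assert filt[0] * dt > 0.5            # most mass in the first sample
        assert filt[int(5 / dt):].max() * dt < 0.01

    def test_round_trip_reconstruction(self):
        spec = S.SynthSpec(seed=3, noise_sd_pa=0.28)
        single, paired, truth = S.synth_fstc(spec)
        fstc = ST.isolate_fstc(single, paired)
        ce = ST.estimate_clearance(fstc, truth["filter"][:2000])
        assert ce.reconstruction_rms < 0.05

    def test_recovered_filter_matches_truth(self):
        spec = S.SynthSpec(seed=4, noise_sd_pa=0.0)
        ts, tp, truth = S.synth_fstc(spec, tboa=True)
        fstc_t = ST.isolate_fstc(ts, tp)
        filt = ST.derive_filter(fstc_t)
        true_f = truth["filter"][: len(filt)].copy()
        n = min(len(filt), 300)  # compare over the filter support
        rms = np.sqrt(np.mean((filt[:n] - true_f[:n]) ** 2))
        assert rms / true_f.max() < 0.05

    def test_regularized_filter_non_oscillatory(self):
        spec = S.SynthSpec(seed=5, noise_sd_pa=0.5)
        ts, tp, truth = S.synth_fstc(spec, tboa=True)
        filt = ST.derive_filter(ST.isolate_fstc(ts, tp))
        dt = 0.1
        tv = np.abs(np.diff(filt)).sum() * dt
        # total variation of the same order as the peak, not noise-dominated
        assert tv < 5.0 * filt.max() * dt * 10

    def test_clearance_faster_than_fstc(self):
        spec = S.SynthSpec(seed=6)
        single, paired, _ = S.synth_fstc(spec)
        fstc = ST.isolate_fstc(single, paired)
        ts, tp, _ = S.synth_fstc(spec, tboa=True)
        filt = ST.derive_filter(ST.isolate_fstc(ts, tp))
        ce = ST.estimate_clearance(fstc, filt)
        assert ce.centroid_ms < ST.centroid(fstc)

    def test_all_zero_filter_rejected(self):
        spec = S.SynthSpec(seed=0)
        single, paired, _ = S.synth_fstc(spec)
        fstc = ST.isolate_fstc(single, paired)
        with pytest.raises(ST.TraceError):
            ST.estimate_clearance(fstc, np.zeros(100))


class TestSustainedCurrent:
    def test_plateau_value(self):
        y = np.zeros(6001)
        y[500:] = 10.6  # plateau from the stimulus to the end (600 ms record)
        assert ST.measure_sustained_current(_trace(y)) == pytest.approx(10.6)

    def test_zero_trace(self):
        assert ST.measure_sustained_current(_trace(np.zeros(6001))) == 0.0

    def test_short_record_rejected(self):
        with pytest.raises(ST.TraceError, match="record ends"):
            ST.measure_sustained_current(_trace(np.zeros(2000)))

    def test_plateau_ending_before_window(self):
        y = np.zeros(6001)
        y[500:2000] = 8.0  # ends 150 ms after the stimulus
        assert ST.measure_sustained_current(_trace(y)) == pytest.approx(0.0)


class TestModelInterface:
    def test_fit_pipeline_and_summary(self):
        spec = S.SynthSpec(seed=7)
        single, paired, truth = S.synth_fstc(spec)
        ts, tp, _ = S.synth_fstc(spec, tboa=True)
        model = ST.TransporterCurrentModel(single, paired, ts, tp)
        res = model.fit()
        table = res.summary()
        assert "clearance centroid <t> (ms)" in table.index
        assert res.clearance.centroid_ms == pytest.approx(
            truth["clearance_centroid_ms"], rel=0.06)

    def test_tfllr_like_condition_orders_clearance(self):
        """Faster generated clearance (PAR1-activated condition) comes out
        faster through the full pipeline."""
        def run(tau_slow):
            spec = S.SynthSpec(seed=8, clearance_tau_slow_ms=tau_slow)
            single, paired, _ = S.synth_fstc(spec)
            ts, tp, _ = S.synth_fstc(spec, tboa=True)
            return ST.TransporterCurrentModel(single, paired, ts, tp).fit()

        ctrl = run(18.0)
        tfllr = run(11.0)
        assert (tfllr.clearance.centroid_ms < ctrl.clearance.centroid_ms)

    def test_csv_round_trip(self, tmp_path):
        spec = S.SynthSpec(seed=9)
        single, _, _ = S.synth_fstc(spec)
        path = tmp_path / "t.csv"
        single.to_csv(path)
        back = ST.CurrentTrace.from_csv(path)
        assert back.rate_khz == pytest.approx(10.0, rel=1e-6)
        assert np.allclose(back.samples, single.samples)
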