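import numpy as np
import pytest

from drgcal import (
    ImageStack,
    LabelMap,
    Trace,
    bandpass,
    detect_transients,
    extract_traces,
    normalize_dff,
    single_spike_resolvable,
    spectrum,
)
from drgcal.synthgen import solve_kernel_decay, transient_kernel
from oracles import roi_means_bruteforce

FR = 50.0


def _trace_from_dff(dff, fr=FR):
    dff = np.asarray(dff, dtype=float)
    return Trace(neuron_id=1, raw=100.0 * (1 + dff), frame_rate=fr, dff=dff)


class TestExtractTraces:
    def test_constant_stack_flat_trace(self):
        stack = ImageStack(np.full((6, 8, 8), 100, dtype=np.uint8))
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:5, 2:5] = 1
        (trace,) = extract_traces(stack, LabelMap(labels))
        np.testing.assert_allclose(trace.raw, 100.0)

    def test_single_pixel_roi_equals_pixel_series(self, rng):
        frames = rng.uniform(0, 255, size=(10, 6, 6))
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[3, 4] = 1
        (trace,) = extract_traces(ImageStack(frames), LabelMap(labels))
        np.testing.assert_allclose(trace.raw, frames[:, 3, 4])

    def test_matches_pixel_loop_oracle(self, rng):
        frames = rng.uniform(0, 255, size=(8, 12, 12))
        labels = np.zeros((12, 12), dtype=np.int32)
        for k in (1, 2, 3):
            rr = rng.integers(0, 12, size=6)
            cc = rng.integers(0, 12, size=6)
            labels[rr, cc] = k
        traces = extract_traces(ImageStack(frames), LabelMap(labels))
        for trace in traces:
            np.testing.assert_allclose(
                trace.raw, roi_means_bruteforce(frames, labels, trace.neuron_id), atol=1e-12
            )

    def test_linearity_in_stack_scale(self, rng):
        frames = rng.uniform(1, 100, size=(6, 8, 8))
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1:4, 1:4] = 1
        (t1,) = extract_traces(ImageStack(frames), LabelMap(labels))
        (t2,) = extract_traces(ImageStack(frames * 2.5), LabelMap(labels))
        np.testing.assert_allclose(t2.raw, 2.5 * t1.raw)

    def test_shape_mismatch_raises(self):
        stack = ImageStack(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            extract_traces(stack, LabelMap(np.zeros((5, 5), dtype=np.int32)))


class TestNormalizeDff:
    def test_flat_trace_zero_dff(self):
        t = normalize_dff(Trace(1, np.full(100, 80.0)), (0.0, 1.0))
        np.testing.assert_allclose(t.dff, 0.0)

    def test_step_closed_form(self):
        raw = np.concatenate([np.full(50, 100.0), np.full(50, 105.0)])
        t = normalize_dff(Trace(1, raw), (0.0, 1.0))
        assert t.dff[0] == pytest.approx(0.0)
        assert t.dff[-1] == pytest.approx(0.05)

    def test_round_trip_recovers_raw(self, rng):
        raw = rng.uniform(50, 150, size=200)
        t = normalize_dff(Trace(1, raw), (0.0, 2.0))
        f0 = raw[:100].mean()
        np.testing.assert_allclose((1 + t.dff) * f0, raw, atol=1e-10)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_dff(Trace(1, np.zeros(100)), (0.0, 1.0))
        with pytest.raises(ValueError, match="frames"):
            normalize_dff(Trace(1, np.full(100, 5.0)), (0.0, 0.02))


class TestSpectrum:
    def test_pure_tone_dominant_bin(self):
        t = np.arange(1000) / FR
        trace = _trace_from_dff(np.sin(2 * np.pi * 1.0 * t))
        freqs, mag = spectrum(trace)
        assert freqs[np.argmax(mag[1:]) + 1] == pytest.approx(1.0, abs=0.05)
        assert freqs[-1] == pytest.approx(FR / 2)

    def test_two_tones(self):
        t = np.arange(2000) / FR
        trace = _trace_from_dff(np.sin(2 * np.pi * 0.5 * t) + np.sin(2 * np.pi * 3.0 * t))
        freqs, mag = spectrum(trace)
        top2 = freqs[np.argsort(mag)[-2:]]
        assert sorted(np.round(top2, 2).tolist()) == [0.5, 3.0]

    def test_white_noise_spectrum_is_flat(self):
        # median magnitude across 100 seeds: no bin sticks out of the floor
        mags = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, mag = spectrum(_trace_from_dff(rng.normal(0, 0.01, 512)))
            mags.append(mag[1:])
        med = np.median(np.array(mags), axis=0)
        assert med.max() < 5 * np.median(med)

    def test_requires_dff_and_length(self):
        with pytest.raises(ValueError, match="ΔF/F|normalize"):
            spectrum(Trace(1, np.zeros(100)))
        with pytest.raises(ValueError, match="16"):
            spectrum(_trace_from_dff(np.zeros(8)))


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        t = np.arange(3000) / FR
        trace = _trace_from_dff(np.sin(2 * np.pi * 1.0 * t))
        out = bandpass(trace, 0.3, 5.0)
        mid = out.dff[500:-500]
        assert mid.max() == pytest.approx(1.0, rel=0.05)

    def test_lowpass_rejects_octave_above(self):
        t = np.arange(3000) / FR
        trace = _trace_from_dff(np.sin(2 * np.pi * 10.0 * t))
        out = bandpass(trace, 0.0, 5.0)
        assert np.abs(out.dff[500:-500]).max() < 0.1  # ≥ 90% attenuation

    def test_dc_removed_by_bandpass(self):
        trace = _trace_from_dff(np.full(2000, 0.5))
        out = bandpass(trace, 0.3, 5.0)
        assert abs(out.dff.mean()) < 1e-3

    def test_invalid_corners(self):
        trace = _trace_from_dff(np.zeros(100))
        with pytest.raises(ValueError):
            bandpass(trace, 5.0, 0.3)
        with pytest.raises(ValueError):
            bandpass(trace, 0.3, 30.0)  # beyond Nyquist


class TestDetectTransients:
    def test_flat_trace_no_events(self):
        assert detect_transients(_trace_from_dff(np.zeros(500))) == []

    def test_slow_ramp_rejected(self):
        # +3% spread over 1 s is 0.6% per 200 ms: below the rise criterion
        dff = np.concatenate([np.zeros(100), np.linspace(0, 0.03, 50), np.full(100, 0.03)])
        assert detect_transients(_trace_from_dff(dff)) == []

    def test_fast_rise_detected_with_kernel_width(self):
        # instantaneous rise to 5%, exponential decay with 25%-width 1.3 s
        tau = 1.3 / np.log(4.0)
        t = np.arange(500) / FR
        dff = np.where(t >= 1.0, 0.05 * np.exp(-(t - 1.0) / tau), 0.0)
        events = detect_transients(_trace_from_dff(dff))
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_dff == pytest.approx(0.05, abs=1e-3)
        assert ev.duration_25pct == pytest.approx(1.3, abs=0.02)

    def test_spike_train_sensitivity_and_no_false_positives(self):
        # 0.5 Hz spikes, 5% peaks, 0.3% baseline noise: all found, none invented
        spikes = np.arange(1.0, 19.0, 2.0)
        t = np.arange(int(20 * FR)) / FR
        clean = np.zeros_like(t)
        for s in spikes:
            clean += 0.05 * transient_kernel(t - s, 0.05, 1.3)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trace = _trace_from_dff(clean + rng.normal(0, 0.003, size=t.size))
            filtered = bandpass(trace, 0.0, 5.0)
            events = detect_transients(filtered)
            assert len(events) == len(spikes)
            for ev in events:
                assert np.min(np.abs(spikes - ev.peak_time)) < 0.5
            hits += 1
        assert hits == 20

    def test_event_count_invariant_to_raw_offset(self):
        t = np.arange(1000) / FR
        clean = 0.05 * transient_kernel(t - 5.0, 0.05, 1.3)
        raw = 100.0 * (1 + clean)
        for offset in (0.0, 40.0):
            trace = normalize_dff(Trace(1, raw + offset), (0.0, 2.0))
            events = detect_transients(trace)
            assert len(events) == 1

    def test_merging_of_overlapping_events(self):
        # two rises 0.4 s apart whose 25% regions overlap fuse into one event
        t = np.arange(500) / FR
        dff = 0.05 * transient_kernel(t - 2.0, 0.05, 1.3) + 0.05 * transient_kernel(
            t - 2.4, 0.05, 1.3
        )
        events = detect_transients(_trace_from_dff(dff))
        assert len(events) == 1


class TestSingleSpikeResolvable:
    def _event(self, peak_time=2.0, peak=0.05):
        from drgcal.traces import TransientEvent

        return TransientEvent(1, peak_time, peak, peak_time - 0.2, 1.3)

    def test_large_excursion_true(self):
        t = np.arange(500) / FR
        filtered = _trace_from_dff(0.05 * transient_kernel(t - 2.0, 0.05, 1.3))
        assert single_spike_resolvable([self._event()], filtered)

    def test_small_excursion_false(self):
        t = np.arange(500) / FR
        filtered = _trace_from_dff(0.02 * transient_kernel(t - 2.0, 0.05, 1.3))
        assert not single_spike_resolvable([self._event(peak=0.02)], filtered)

    def test_no_events_false(self):
        filtered = _trace_from_dff(np.zeros(100))
        assert not single_spike_resolvable([], filtered)
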