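"""Per-neuron intensity profiles, ΔF/F, filtering, and transient detection.

The raw profile of neuron *m* is the mean intensity over its ROI in each
frame.  It is normalized by the pre-stimulus baseline F0 to ΔF/F, optionally
band-pass filtered (the evoked signal content lives between roughly 0.3 and
5 Hz; distension responses keep their DC-shifted baseline and use a 0–5 Hz
low-pass instead), and scanned for calcium transients: an event opens
wherever ΔF/F rises by at least 3% within any 200 ms window, its peak is the
local maximum that follows, and its duration is the width of the trace at
25% of the peak.  GCaMP6f transients from single action potentials are about
1.3 s wide at that level; a filtered peak-to-peak excursion above 3.5%
ΔF/F marks a transient as resolvable at the single-spike level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps


@dataclass
class Trace:
    """Intensity profile of one neuron.

    ``raw`` is mean ROI intensity per frame on the acquisition (0–255)
    scale; ``dff`` is its ΔF/F form, present only after
    :func:`normalize_dff`.
    """

    neuron_id: int
    raw: np.ndarray
    frame_rate: float = 50.0
    dff: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.dff is not None:
            self.dff = np.asarray(self.dff, dtype=np.float64)
            if self.dff.shape != self.raw.shape:
                raise ValueError("raw and dff must share one length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.raw)) / self.frame_rate


@dataclass
class TransientEvent:
    """One detected calcium transient."""

    neuron_id: int
    peak_time: float  # s
    peak_dff: float
    onset_time: float  # s, 25%-level up-crossing
    duration_25pct: float  # s, width at 25% of peak

    def to_dict(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "peak_time_s": self.peak_time,
            "peak_dff": self.peak_dff,
            "onset_time_s": self.onset_time,
            "duration_25pct_s": self.duration_25pct,
        }


def extract_traces(stack, labels) -> list[Trace]:
    """Mean ROI intensity per frame for every label.

    Linear in the stack: scaling the pixel data scales every trace.  Labels
    with no pixels are skipped.
    """
    lab = labels.labels
    if lab.shape != stack.frames.shape[1:]:
        raise ValueError(
            f"label map shape {lab.shape} does not match frames {stack.frames.shape[1:]}"
        )
    flat = stack.as_float().reshape(stack.n_frames, -1)
    traces = []
    for k in range(1, int(lab.max()) + 1):
        idx = np.flatnonzero(lab.ravel() == k)
        if idx.size == 0:
            continue
        traces.append(
            Trace(neuron_id=k, raw=flat[:, idx].mean(axis=1), frame_rate=stack.frame_rate)
        )
    return traces


def normalize_dff(trace: Trace, baseline_window: tuple[float, float]) -> Trace:
    """ΔF/F normalization against the pre-stimulus window.

    F0 is the mean raw intensity over ``baseline_window`` (seconds); the
    window must span at least 5 frames and F0 must be positive.
    """
    start, end = baseline_window
    fr = trace.frame_rate
    i0, i1 = int(np.floor(start * fr)), int(np.ceil(end * fr))
    i0, i1 = max(i0, 0), min(i1, len(trace.raw))
    if i1 - i0 < 5:
        raise ValueError(f"baseline window [{start}, {end}] s spans {i1 - i0} frames; need ≥ 5")
    f0 = float(trace.raw[i0:i1].mean())
    if f0 <= 0:
        raise ValueError(f"degenerate baseline: F0 = {f0}")
    return replace(trace, dff=(trace.raw - f0) / f0, baseline_window=(start, end))


def spectrum(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum of the ΔF/F trace.

    Frequencies run from 0 to the Nyquist rate.  Requires ≥ 16 samples and a
    prior :func:`normalize_dff`.
    """
    if trace.dff is None:
        raise ValueError("normalize to ΔF/F before computing the spectrum")
    n = len(trace.dff)
    if n < 16:
        raise ValueError(f"spectrum needs ≥ 16 samples, got {n}")
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.frame_rate)
    mag = np.abs(np.fft.rfft(trace.dff)) / n
    return freqs, mag


def bandpass(trace: Trace, low: float, high: float) -> Trace:
    """Zero-phase Butterworth band-pass of the ΔF/F trace.

    ``low = 0`` selects a pure low-pass (used for distension responses,
    whose baseline shift carries information); otherwise a band-pass with
    corners ``(low, high)`` Hz.  Filtering is forward–backward so event
    timing is preserved; the order is chosen to give ≥ 20 dB attenuation one
    octave outside the band while keeping mid-band gain within 5% of unity.
    """
    if trace.dff is None:
        raise ValueError("normalize to ΔF/F before filtering")
    nyq = trace.frame_rate / 2.0
    if not (0 <= low < high < nyq):
        raise ValueError(f"need 0 ≤ low < high < Nyquist ({nyq} Hz); got ({low}, {high})")
    if low == 0:
        sos = sps.butter(4, high, btype="low", fs=trace.frame_rate, output="sos")
    else:
        sos = sps.butter(3, [low, high], btype="band", fs=trace.frame_rate, output="sos")
    return replace(trace, dff=sps.sosfiltfilt(sos, trace.dff))


def _crossing(x: np.ndarray, level: float, i: int, direction: int) -> float:
    """Fractional index where ``x`` crosses ``level`` next to sample ``i``.

    ``direction=-1`` looks at the rising edge before ``i``, ``+1`` at the
    falling edge after.  Linear interpolation between the two samples
    flanking the crossing.
    """
    j = i + direction
    if j < 0 or j >= len(x):
        return float(i)
    a, b = x[i], x[j]
    if a == b:
        return float(i)
    frac = (a - level) / (a - b)
    return i + direction * min(max(frac, 0.0), 1.0)


def detect_transients(
    trace: Trace,
    rise_threshold: float = 0.03,
    rise_window: float = 0.2,
    width_fraction: float = 0.25,
) -> list[TransientEvent]:
    """Detect calcium transients by the 3%-rise-within-200-ms criterion.

    A candidate opens at any sample from which ΔF/F gains at least
    ``rise_threshold`` within ``rise_window`` seconds.  From the candidate
    the trace is followed to its local maximum; the event region is the
    contiguous stretch where ΔF/F stays at or above ``width_fraction`` of
    that peak, and its width (with sub-frame interpolation of the two
    crossings) is the event duration.  Candidates falling inside an already
    open region merge into one event.  Slow drifts that gain 3% only over
    seconds never trigger.
    """
    if trace.dff is None:
        raise ValueError("normalize to ΔF/F before detecting transients")
    d = trace.dff
    fr = trace.frame_rate
    n = len(d)
    w = max(2, int(round(rise_window * fr)))
    dt = 1.0 / fr

    rising = np.zeros(n, dtype=bool)
    for k in range(1, w + 1):
        rising[: n - k] |= (d[k:] - d[:-k]) >= rise_threshold
    candidates = np.flatnonzero(rising)

    events: list[TransientEvent] = []
    blocked_until = -1
    for i in candidates:
        if i <= blocked_until:
            continue
        # walk forward to the local maximum, stopping once the trace has
        # fallen below width_fraction of the running peak
        peak_idx, peak = i, d[i]
        j = i
        while j + 1 < n:
            j += 1
            if d[j] > peak:
                peak, peak_idx = d[j], j
            elif d[j] < width_fraction * peak:
                break
        if peak < rise_threshold:
            continue
        level = width_fraction * peak
        a = peak_idx
        while a > 0 and d[a - 1] >= level:
            a -= 1
        b = peak_idx
        while b + 1 < n and d[b + 1] >= level:
            b += 1
        t_up = _crossing(d, level, a, -1)
        t_dn = _crossing(d, level, b, +1)
        duration = max((t_dn - t_up) * dt, dt)
        events.append(
            TransientEvent(
                neuron_id=trace.neuron_id,
                peak_time=peak_idx * dt,
                peak_dff=float(peak),
                onset_time=t_up * dt,
                duration_25pct=float(duration),
            )
        )
        blocked_until = b
    return events


def single_spike_resolvable(events: list[TransientEvent], filtered: Trace, threshold: float = 0.035, window: float = 1.0) -> bool:
    """Whether every detected transient is resolvable at single-spike level.

    True iff the filtered-trace peak-to-peak excursion within ``±window``
    seconds of each event peak exceeds ``threshold`` (3.5% ΔF/F).  An empty
    event list is not resolvable — the claim is about detected spikes.
    """
    if not events:
        return False
    if filtered.dff is None:
        raise ValueError("supply a filtered ΔF/F trace")
    d = filtered.dff
    fr = filtered.frame_rate
    half = int(round(window * fr))
    for ev in events:
        c = int(round(ev.peak_time * fr))
        seg = d[max(0, c - half) : c + half + 1]
        if seg.size == 0 or (seg.max() - seg.min()) <= threshold:
            return False
    return True
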