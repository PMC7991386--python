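"""Synthetic wide-field DRG recordings with complete ground truth.

The generator emulates the statistics of the real preparation: sparse
bright disk-like somata of 10–40 μm diameter on a dim background
(0.7 μm/px sampling, 50 Hz, 8-bit), spike-train-driven calcium transients
whose kernel width at 25% of peak is 1.3 s, additive sensor noise, and
smooth rigid motion up to tens of μm translation and ~2° rotation locked to
the mechanical-stimulation windows.  Every latent quantity — soma masks,
spike times, per-frame motion, per-neuron ΔF/F and functional class — is
returned as :class:`GroundTruth` so registration, detection, trace
extraction, transient metrology and classification can all be scored
against truth.

The transient kernel is a difference of exponentials
``k(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise)`` normalized to unit peak; the
decay constant is solved numerically so the kernel's width at 25% of peak
equals the configured value (1.3 s by default).  High spike rates drive the
summed ΔF/F into a soft saturation (``ceiling·tanh(x/ceiling)``), emulating
the baseline build-up seen when stimulus rates exceed ~0.5 Hz; a linear
mode exists for closed-form oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from drgcal.classify import (
    AfferentClass,
    DistensionStep,
    NOXIOUS_PRESSURES,
    DISTENSION_PRESSURES,
    ShearWindow,
    StimulusProtocol,
)
from drgcal.detection import LabelMap
from drgcal.io_stack import ImageStack
from drgcal.registration import RigidTransform, apply_rigid


def default_protocol() -> StimulusProtocol:
    """Graded distension steps then a shear window, 2 s pre-stimulus baseline.

    Steps are 5 s at 15/30/45/60 mmHg with 3 s between windows — long
    enough for the ~1.3 s-wide GCaMP6f transient to decay back near
    baseline, so responses stay attributable to individual pressure steps.
    """
    steps = [
        DistensionStep(pressure=p, onset=2.0 + i * 8.0, duration=5.0)
        for i, p in enumerate(DISTENSION_PRESSURES)
    ]
    shear = [ShearWindow(onset=34.0, duration=5.0)]
    return StimulusProtocol(distension_steps=steps, shear_windows=shear)


@dataclass
class SynthConfig:
    """Knobs of the synthetic recording; the seed fully determines output."""

    seed: int = 0
    field_size: tuple[int, int] = (512, 512)  # H×W px
    pixel_size: float = 0.7  # μm/px
    frame_rate: float = 50.0  # Hz
    duration: float | None = None  # s; None → protocol end + 2 s
    n_neurons: int = 30
    diameter_range: tuple[float, float] = (10.0, 40.0)  # μm
    baseline_intensity: float = 120.0  # 8-bit units, soma resting brightness
    background_intensity: float = 30.0  # 8-bit units
    transient_amplitude: float = 0.30  # peak ΔF/F per single spike
    kernel_rise: float = 0.05  # s
    kernel_width_25: float = 1.3  # s, width at 25% of peak
    noise_sigma: float = 2.0  # 8-bit units, additive Gaussian
    motion_amplitude: float = 0.0  # μm, peak translation
    motion_rotation: float = 0.0  # degrees, peak rotation
    psf_sigma: float = 1.0  # px, optical blur
    saturation_ceiling: float | None = 0.6  # ΔF/F soft ceiling; None → linear
    protocol: StimulusProtocol = field(default_factory=default_protocol)
    class_mix: dict = field(
        default_factory=lambda: {
            AfferentClass.LT_MUSCULAR: 0.25,
            AfferentClass.HT_MUSCULAR: 0.25,
            AfferentClass.MUCOSAL: 0.25,
            AfferentClass.MUSCULAR_MUCOSAL: 0.25,
        }
    )
    keep_clean: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        for name in ("pixel_size", "frame_rate", "baseline_intensity", "kernel_rise", "kernel_width_25"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_duration(self) -> float:
        return self.duration if self.duration is not None else self.protocol.end + 2.0

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Every latent of a rendered recording."""

    masks: LabelMap
    spike_trains: list  # per-neuron arrays of event times (s)
    class_labels: list  # per-neuron AfferentClass
    motion_trajectory: list  # per-frame RigidTransform
    dff_traces: np.ndarray  # n_neurons × T, saturated ΔF/F
    protocol: StimulusProtocol
    clean_stack: ImageStack | None = None


# ---------------------------------------------------------------------------
# transient kernel


def solve_kernel_decay(rise: float, width_25: float) -> float:
    """Decay constant of the difference-of-exponentials kernel.

    Solves for τ_decay so the normalized kernel's width at 25% of its peak
    equals ``width_25``.  The width is monotone in τ_decay, so bisection on
    the closed-form width function converges unconditionally.
    """
    if width_25 <= rise:
        raise ValueError("width must exceed the rise constant")
    return brentq(
        lambda td: kernel_width_25(rise, td) - width_25,
        rise * 1.0001,
        width_25 * 10.0,
        xtol=1e-10,
    )


def _kernel_raw(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    tc = np.maximum(t, 0.0)  # negative times clipped before exp to avoid overflow
    out = np.exp(-tc / decay) - np.exp(-tc / rise)
    return np.where(t >= 0, out, 0.0)


def _kernel_peak(rise: float, decay: float) -> tuple[float, float]:
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    return t_peak, float(_kernel_raw(np.array([t_peak]), rise, decay)[0])


def kernel_width_25(rise: float, decay: float) -> float:
    """Closed-form width of the unit-peak kernel at 25% of peak."""
    t_peak, peak = _kernel_peak(rise, decay)
    level = 0.25 * peak
    f = lambda t: float(_kernel_raw(np.array([t]), rise, decay)[0]) - level
    t_up = brentq(f, 1e-12, t_peak, xtol=1e-12)
    hi = t_peak
    while f(hi) > 0:
        hi *= 2
    t_dn = brentq(f, t_peak, hi, xtol=1e-12)
    return t_dn - t_up


def transient_kernel(times: np.ndarray, rise: float, width_25: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel sampled at ``times``."""
    decay = solve_kernel_decay(rise, width_25)
    _, peak = _kernel_peak(rise, decay)
    return _kernel_raw(times, rise, decay) / peak


# ---------------------------------------------------------------------------
# geometry


def sample_geometry(config: SynthConfig) -> LabelMap:
    """Place non-overlapping ellipse-like somata, away from the border.

    Equivalent diameters are sampled uniformly over the configured range
    (with a half-μm margin so pixel quantization cannot push them out);
    centers stay at least one diameter from the border, and painted somata
    keep a few pixels of clearance so touching is the exception, not the
    rule.  Raises if the requested density cannot be placed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    h, w = config.field_size
    labels = np.zeros((h, w), dtype=np.int32)
    if config.n_neurons == 0:
        return LabelMap(labels=labels, pixel_size=config.pixel_size)
    d_lo, d_hi = config.diameter_range
    mean_r_px = (d_lo + d_hi) / 4.0 / config.pixel_size
    if config.n_neurons * np.pi * mean_r_px**2 > 0.5 * h * w:
        raise ValueError("requested soma density exceeds 50% field coverage")
    occupied = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    placed = 0
    attempts = 0
    max_attempts = 500 * config.n_neurons
    clearance = 4  # px between painted somata
    while placed < config.n_neurons:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_neurons} somata after {max_attempts} attempts"
            )
        d_um = rng.uniform(d_lo + 0.5, d_hi - 0.5)
        r = d_um / 2.0 / config.pixel_size
        margin = int(np.ceil(2 * r)) + 1  # center ≥ 1 diameter from border
        if 2 * margin >= min(h, w):
            continue
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        q = rng.uniform(0.85, 1.0)  # axis ratio; area preserved
        phi = rng.uniform(0, np.pi)
        a, b = r / np.sqrt(q), r * np.sqrt(q)
        c, s = np.cos(phi), np.sin(phi)
        u = (xx - cx) * c + (yy - cy) * s
        v = -(xx - cx) * s + (yy - cy) * c
        ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        grown = ndimage.binary_dilation(ellipse, iterations=clearance)
        if np.logical_and(grown, occupied).any():
            continue
        placed += 1
        labels[ellipse] = placed
        occupied |= ellipse
    return LabelMap(labels=labels, pixel_size=config.pixel_size)


# ---------------------------------------------------------------------------
# spike trains


_CLASS_WINDOWS = {
    AfferentClass.LT_MUSCULAR: (set(DISTENSION_PRESSURES), False),
    AfferentClass.HT_MUSCULAR: (set(NOXIOUS_PRESSURES), False),
    AfferentClass.MUCOSAL: (set(), True),
    AfferentClass.MUSCULAR_MUCOSAL: (set(DISTENSION_PRESSURES), True),
    AfferentClass.UNCLASSIFIED: (set(), False),
}


def spikes_from_class(
    class_label: AfferentClass, protocol: StimulusProtocol, seed: int
) -> np.ndarray:
    """Poisson spike times confined to the windows the class responds to.

    Distension-evoked firing runs at 2–5 Hz, shear-evoked firing at
    0.5–2 Hz (shear responses stay resolvable at the single-spike level).
    Every responding window receives at least one spike so the class
    archetype is always expressed; spikes keep 0.2 s clearance from the
    window end so the transient peak stays within the response window.
    """
    rng = np.random.default_rng(seed)
    pressures, shear = _CLASS_WINDOWS[AfferentClass(class_label)]
    windows = []
    for step in protocol.distension_steps:
        if step.pressure in pressures:
            windows.append((step.onset, step.duration, rng.uniform(2.0, 5.0)))
    if shear:
        for win in protocol.shear_windows:
            windows.append((win.onset, win.duration, rng.uniform(0.5, 2.0)))
    times = []
    for onset, duration, rate in windows:
        span = max(duration - 0.2, 0.0)
        if span <= 0:
            continue
        n = max(1, rng.poisson(rate * span))
        times.append(onset + np.sort(rng.uniform(0.0, span, size=n)))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


# ---------------------------------------------------------------------------
# motion and rendering


def motion_trajectory(config: SynthConfig) -> list[RigidTransform]:
    """Smooth sinusoidal rigid drift gated to the stimulation windows.

    Translation and rotation follow slow sinusoids scaled by a raised-cosine
    envelope that is 1 inside stimulus windows (0.5 s ramps) and 0 outside —
    mechanical stimulation is what moves the ganglion.  If the protocol has
    no windows the envelope is 1 throughout.
    """
    t = np.arange(config.n_frames) / config.frame_rate
    windows = [(s.onset, s.onset + s.duration) for s in config.protocol.distension_steps] + [
        (s.onset, s.onset + s.duration) for s in config.protocol.shear_windows
    ]
    if windows:
        ramp = 0.5
        env = np.zeros_like(t)
        for a, b in windows:
            rise = np.clip((t - a) / ramp, 0.0, 1.0)
            fall = np.clip((b + ramp - t) / ramp, 0.0, 1.0)
            env = np.maximum(env, np.minimum(rise, fall))
        env = 0.5 - 0.5 * np.cos(np.pi * env)  # raised-cosine shoulders
    else:
        env = np.ones_like(t)
    amp_px = config.motion_amplitude / config.pixel_size
    dx = amp_px * env * np.sin(2 * np.pi * 0.25 * t)
    dy = amp_px * env * np.sin(2 * np.pi * 0.17 * t + 1.0)
    th = config.motion_rotation * env * np.sin(2 * np.pi * 0.21 * t + 0.5)
    traj = [RigidTransform(dx=float(a), dy=float(b), theta=float(c)) for a, b, c in zip(dx, dy, th)]
    if traj and not traj[0].is_identity:
        traj[0] = RigidTransform()
    return traj


def make_drifting_stack(
    base: np.ndarray,
    trajectory: list[RigidTransform],
    frame_rate: float = 50.0,
    pixel_size: float = 0.7,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ImageStack:
    """Resample one base image under a known rigid trajectory (plus noise).

    The workhorse for registration ground-truth tests: frame ``j`` is the
    base image as seen by a camera displaced by ``trajectory[j]``.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(base, dtype=np.float64)
    frames = np.empty((len(trajectory),) + base.shape, dtype=np.uint8)
    for j, tf in enumerate(trajectory):
        f = apply_rigid(base, tf)
        if noise_sigma > 0:
            f = f + rng.normal(0.0, noise_sigma, size=f.shape)
        frames[j] = np.clip(np.round(f), 0, 255).astype(np.uint8)
    return ImageStack(frames, frame_rate=frame_rate, pixel_size=pixel_size, origin_path="synthetic")


def render_recording(config: SynthConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a full synthetic recording and its ground truth.

    Per-neuron fluorescence is ``baseline·(1 + ΔF/F)`` where ΔF/F is the
    spike train convolved with the unit-peak transient kernel scaled by
    ``transient_amplitude`` (optionally soft-saturated).  A Gaussian blur
    models the optics, per-pixel Gaussian noise the sensor, and each frame
    is resampled under the motion trajectory before 8-bit quantization.
    """
    ss = np.random.SeedSequence([config.seed, 2])
    noise_seed, class_seed = ss.spawn(2)
    masks = sample_geometry(config)
    n = config.n_neurons
    n_frames = config.n_frames
    t = np.arange(n_frames) / config.frame_rate

    class_rng = np.random.default_rng(class_seed)
    names = list(config.class_mix.keys())
    probs = np.array([config.class_mix[k] for k in names])
    class_labels = [names[i] for i in class_rng.choice(len(names), size=n, p=probs)]

    decay = solve_kernel_decay(config.kernel_rise, config.kernel_width_25)
    _, kpeak = _kernel_peak(config.kernel_rise, decay)
    spike_trains = []
    dff = np.zeros((n, n_frames))
    for m in range(n):
        spikes = spikes_from_class(
            class_labels[m], config.protocol, seed=(config.seed * 100003 + 7 * m) % (2**31)
        )
        spike_trains.append(spikes)
        for s in spikes:
            dff[m] += (config.transient_amplitude / kpeak) * _kernel_raw(
                t - s, config.kernel_rise, decay
            )
    if config.saturation_ceiling is not None:
        c = config.saturation_ceiling
        dff = c * np.tanh(dff / c)

    h, w = config.field_size
    static = np.full((h, w), config.background_intensity, dtype=np.float64)
    soma_gain = []  # per-neuron blurred intensity footprint, bounding-boxed
    for m in range(1, n + 1):
        mask = masks.labels == m
        static[mask] = config.baseline_intensity
        blurred = ndimage.gaussian_filter(mask.astype(np.float64), config.psf_sigma)
        rr, cc = np.nonzero(blurred > 1e-6)
        sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
        soma_gain.append((sl, blurred[sl] * config.baseline_intensity))
    base = ndimage.gaussian_filter(static, config.psf_sigma)

    traj = (
        motion_trajectory(config)
        if (config.motion_amplitude > 0 or config.motion_rotation > 0)
        else [RigidTransform() for _ in range(n_frames)]
    )

    noise_rng = np.random.default_rng(noise_seed)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    clean = np.empty((n_frames, h, w), dtype=np.float32) if config.keep_clean else None
    for j in range(n_frames):
        f = base.copy()
        for m in range(n):
            if dff[m, j] != 0.0:
                sl, gain = soma_gain[m]
                f[sl] += gain * dff[m, j]
        if clean is not None:
            clean[j] = f
        if not traj[j].is_identity:
            f = apply_rigid(f, traj[j])
        if config.noise_sigma > 0:
            f = f + noise_rng.normal(0.0, config.noise_sigma, size=f.shape)
        frames[j] = np.clip(np.round(f), 0, 255).astype(np.uint8)

    stack = ImageStack(
        frames,
        frame_rate=config.frame_rate,
        pixel_size=config.pixel_size,
        origin_path="synthetic",
    )
    truth = GroundTruth(
        masks=masks,
        spike_trains=spike_trains,
        class_labels=class_labels,
        motion_trajectory=traj,
        dff_traces=dff,
        protocol=config.protocol,
        clean_stack=(
            ImageStack(clean, config.frame_rate, config.pixel_size, "synthetic-clean")
            if clean is not None
            else None
        ),
    )
    return stack, truth
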