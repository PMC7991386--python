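# Methods

`drgcal` post-processes wide-field calcium-imaging recordings of intact
dorsal root ganglia (DRG): 8-bit grayscale stacks acquired at 50 frames/s
with 0.7 μm/px sampling, in which GCaMP6f-expressing sensory somata
(Φ 10–40 μm) light up when the attached colorectum is mechanically
stimulated. This note documents the models, the parameters that matter,
the synthetic-data generator the tests score against, and the numerical
choices made where the design was genuinely open.

## Rigid motion correction

Mechanical stimulation drags the ganglion by tens of μm (and rotates it by
a degree or two), so every frame `I_j` is registered to the first frame
before any signal extraction. The similarity objective is mutual
information over the joint intensity histogram,

    MI(X, Y) = H(X) + H(Y) − H(X, Y)   [bits],

chosen over cross-correlation because the calcium signal itself changes
intensities between frames: MI requires statistical dependence, not
photometric identity. The estimated motion model is a translation
`(dx, dy)` plus an in-plane rotation `θ` about the image center.

Numerical choices:

- **Histogram**: 64 equal-width bins per image spanning [0, 255] for 8-bit
  range data (joint min/max otherwise); entropies use the 0·log 0 = 0
  convention, so constant images yield MI = 0, never NaN.
- **Optimizer**: coordinate-wise finite-difference ascent on
  `(dx, dy, θ)`. Initial steps are 1 px / 0.5°, halved whenever no
  parameter move improves MI; the budget is 50 sweeps, with early exit
  once all steps fall below 10⁻³. Step halving is what provides subpixel
  resolution. A translation-only mode exists
  (`RegistrationSettings(estimate_rotation=False)`) for recordings where
  rotation is negligible.
- **Warm start**: frame *j*'s search starts from frame *j−1*'s estimate.
  Physical motion is temporally smooth, and warm-starting keeps the ascent
  inside the right basin even at 57 px total excursion, where a cold start
  could lock onto a false histogram optimum.
- **Resampling**: bilinear interpolation; out-of-frame pixels are filled
  with the image mean. Zero-fill would concentrate probability mass in the
  lowest histogram bin and bias MI toward large shifts.
- **Convention**: `register_pair` returns the displacement of the moving
  frame relative to the reference (inject `(5, −3, 0)`, get `(5, −3, 0)`
  back); alignment resamples under the inverse.

On the synthetic benchmark (200 frames, 256×256, drift peaking at 57 px ≈
40 μm plus ±2° rotation, sensor noise σ = 2), recovery is ≈ 0.01 px RMSE
and ≈ 0.02° — the aligned fiducial centroid stays well inside the 2 μm
margin the instrument requires.

## Unsupervised soma detection

Active neurons are localized on the per-pixel temporal variance map `V` of
the aligned stack (computed once, two-pass, chunked in float64). Each
iteration of the detection loop then:

1. **Dual threshold** — keep pixels with `V > H_G` (global) and
   `V >` local mean + offset (adaptive). Ties fall to background. The
   local mean uses an integral image over a square window clipped at
   borders, so a constant map thresholds to all-false exactly.
2. **Morphology** — closing then opening with the fixed 3×3 cross
   structuring element `[0,1,0;1,1,1;0,1,0]` (dilation treats
   out-of-bounds as background, erosion as foreground).
3. **Cleanup** — remove 4-connected components under 40 px and components
   touching the image border.
4. **Watershed** — Euclidean distance transform of the mask, negated and
   flooded from its distance peaks (markers deduplicated within ~half the
   minimum soma diameter) to split touching somata along distance ridges.
5. **Size gate** — keep regions whose equivalent diameter
   `2·pixel_size·√(area/π)` lies in [10, 40] μm inclusive.

If fewer than the expected count `P` have been accepted, `H_G` decays
geometrically (`H_G ← 0.75·H_G`) and the chain repeats (default budget
8 iterations, reaching ~10% of the initial threshold), so dimmer somata
surface in later passes. Everything is deterministic.

Open-design decisions:

- **`H_G` initialization**: 90th percentile of the variance map —
  scale-free, so it survives changes in amplitude, noise or bit depth.
- **Adaptive window**: ~2× the maximum soma diameter (115 px at 0.7 μm/px).
  A window equal to the object size was tried first and hollows out large
  somata — the local mean inside a 40 μm soma approaches the soma's own
  variance level — which fragments them; twice the object size is the
  standard adaptive-thresholding rule.
- **Accumulation across iterations**: accepted ROIs persist; a new region
  overlapping accepted ROIs by ≤ 20% of its own area is appended after
  trimming (and must still pass both size gates). A region overlapping
  more is normally a re-detection and is discarded — except when it
  contains ≥ 60% of each accepted ROI it touches, in which case it
  *supersedes* them: that pattern arises when a threshold level slices
  through a soma's variance plateau and fragments it, and the next, lower
  level recovers the complete region.

On the synthetic benchmark (512×512, 1000 frames, 30 somata, standard
noise) detection achieves recall and precision of 1.0 with mean mask IoU
≈ 0.93.

## Traces, filtering, transients

The raw profile of neuron *m* is the mean intensity over its ROI per
frame; ΔF/F normalizes by `F0`, the mean over the pre-stimulus baseline
window (default: everything before the first stimulus onset, minimum 1 s,
≥ 5 frames, `F0 > 0` enforced).

Evoked GCaMP6f signal content lives between roughly 0.3 and 5 Hz, so
traces are filtered with zero-phase (forward–backward) Butterworth
filters: a 0.3–5 Hz band-pass (order 3) for shear/electrical responses, a
0–5 Hz low-pass (order 4) for distension responses whose sustained
baseline shift carries information. Forward–backward application squares
the magnitude response — mid-band gain stays within 5% of unity and one
octave outside the band attenuation exceeds 20 dB — and cancels phase, so
event timing is preserved. `spectrum` exposes the one-sided FFT magnitude
used to justify the corner choices.

**Transient detection**: an event opens wherever ΔF/F gains ≥ 3% within
any 200 ms sliding window (the single-spike criterion for GCaMP6f in
these neurons); the trace is followed to its local maximum, and the event
region is the contiguous stretch at ≥ 25% of that peak. Duration is the
width of that region with sub-frame linear interpolation of the two
crossings — at 50 Hz, simple sample counting would quantize a 1.3 s width
by up to 2 frames. Candidates inside an open region merge into one event:
at spike rates ≥ 2 Hz transients summate and separate peaks are not
resolvable, so merged events are the honest unit. A slow drift that gains
3% only over ~1 s never triggers (0.6% per 200 ms window).
`single_spike_resolvable` applies the 3.5% filtered peak-to-peak
criterion within ±1 s of each event peak, returning false for empty
event lists.

## Functional classification

Response profiles are boolean: a stimulus window is "responded" iff at
least one event peak falls in `[onset, offset + 1 s]`. The 1 s latency
allowance is about one transient width; the response criterion itself
(how many events, what amplitude floor) is not quantified in the
literature, so one peak is the minimal, least-assuming choice. The
decision table over (15, 30, 45, 60 mmHg, shear) flags:

| profile | class |
|---|---|
| all four pressures, no shear | LT muscular |
| no 15 mmHg, ≥ 1 noxious pressure (30/45/60), no shear | HT muscular |
| shear only | mucosal |
| all four pressures + shear | muscular-mucosal |
| anything else | unclassified |

"HT responds to noxious pressures only" is read as *any* of 30/45/60 with
15 silent; requiring all three would misfile borderline-threshold neurons
whose 30 mmHg response sits at the detection floor. Partial profiles are
left unclassified rather than coerced. `class_summary` groups somata into
thoracolumbar (T12–L2) and lumbosacral (L5–S1) pathways; other ganglia
are reported as "other". The χ² comparison of class proportions between
pathways is deliberately not re-implemented — counts are exported for any
standard statistics package.

## Synthetic-recording generator

`synthgen` is first-class, tested code: it renders recordings whose every
latent is known, so registration, detection, trace extraction, transient
metrology and classification can all be scored against truth.

What it emulates, with defaults:

- **Geometry**: non-overlapping ellipse-like somata, equivalent diameters
  uniform in 10–40 μm, centers ≥ 1 diameter from the border, a few px of
  clearance between somata; 0.7 μm/px, 512×512 default field.
- **Dynamics**: per-neuron ΔF/F is the spike train convolved with a
  unit-peak difference-of-exponentials kernel
  `exp(−t/τ_d) − exp(−t/τ_r)`, τ_r = 50 ms and τ_d solved numerically
  (bisection on the closed-form width function) so the width at 25% of
  peak is 1.3 s — the measured single-spike transient width in these
  neurons. Single-spike amplitude 0.30 ΔF/F; summed ΔF/F passes through a
  soft ceiling `c·tanh(x/c)` (c = 0.6) emulating the baseline build-up
  seen beyond ~0.5 Hz stimulus rates; a linear mode exists for
  closed-form oracle tests.
- **Spiking**: Poisson trains confined to the windows the neuron's class
  archetype responds to — 2–5 Hz during distension, 0.5–2 Hz during
  shear — with at least one spike per responding window so the archetype
  is always expressed.
- **Protocol**: 5 s distension steps at 15/30/45/60 mmHg with 3 s between
  windows, then a 5 s shear window, 2 s pre-stimulus baseline. The 3 s
  gap is deliberate: the 1.3 s-wide transient must decay below the 25%
  width level between steps, otherwise the event-merge rule correctly
  fuses responses across windows and per-pressure attribution becomes
  impossible — as it would in a real experiment run without inter-step
  recovery time.
- **Imaging**: soma resting brightness 120, background 30 (8-bit units),
  1 px Gaussian optical blur, additive Gaussian sensor noise σ = 2
  pre-quantization, 8-bit clipping/rounding.
- **Motion**: slow sinusoidal translation/rotation scaled by a
  raised-cosine envelope that is nonzero only during stimulus windows
  (mechanical stimulation is what moves the tissue); amplitudes up to
  40 μm / 2° reproduce the instrument's worst case. With no stimulus
  windows the envelope is 1 throughout (used for registration
  benchmarks).

What it does **not** model: photobleaching, vignetting, neuropil
contamination, shot-noise statistics (a Poisson mode is a config away but
read noise dominates at these levels), non-rigid tissue deformation, the
instrument's second focal plane, and realistic optical PSFs. Passing
tests therefore demonstrate algorithmic correctness under the stated
noise/motion model, not robustness to every artifact of real tissue.

## Problem sizes used in validation

The shipped validation uses desk-scale stacks chosen as representative
slices of the full-size recordings: registration on 200 frames at
256×256 with the full 57 px excursion; detection/trace fidelity on a
512×512, 1000-frame, 30-neuron recording (covering the first two pressure
steps, hence a muscular-only class mix); classification on 192–256 px
fields over 10 noisy seeds plus noiseless archetype runs; determinism on
a 128×128 motion-bearing run through the complete pipeline. Determinism
is size-independent — no stage contains a stochastic element.

## Known limitations

- Spike *rates* are deliberately out of scope beyond binary transient
  detection: above ~4 Hz the summated transient is not a reliable measure
  of activity.
- The watershed marker suppression radius (~half the minimum soma
  diameter) trades over-splitting of plateaued distance ridges against
  under-splitting of deeply overlapping somata; heavily confluent tissue
  would need marker tuning.
- Stacks are processed in memory; multi-GB recordings should be windowed
  or downsampled before loading (the variance map is already chunked).
- The MI ascent is single-resolution; pathological stacks whose first
  frame is atypical (e.g., saturated) would need a different reference
  frame, which is a one-line config change.
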