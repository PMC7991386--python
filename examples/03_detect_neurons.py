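"""Detect active somata with the iterative variance-map/watershed chain.

Renders a recording, runs detection, and prints the per-iteration log
(the global threshold decays by 0.75 each pass until the expected count
is reached) plus the recovered ROI geometry.
"""

import numpy as np
from scipy import ndimage

from drgcal import DetectionParams, detect_neurons
from drgcal.synthgen import SynthConfig, render_recording

cfg = SynthConfig(seed=5, field_size=(256, 256), n_neurons=10)
stack, truth = render_recording(cfg)

label_map, rois, log = detect_neurons(stack, DetectionParams(expected_neurons=10))

for entry in log:
    print(f"iteration {entry['iteration']}: H_G={entry['h_global']:8.1f}  "
          f"new={entry['new_rois']}  total={entry['total']}")
print(f"\ndetected {len(rois)} ROIs (ground truth: {truth.masks.n_labels})")
true_cent = ndimage.center_of_mass(truth.masks.labels > 0, truth.masks.labels,
                                   range(1, truth.masks.n_labels + 1))
for r in rois:
    d = min(np.hypot(c[0] - r.centroid[0], c[1] - r.centroid[1]) for c in true_cent)
    print(f"  ROI {r.id}: {r.area_px:4d} px, {r.equivalent_diameter_um:5.1f} um, "
          f"centroid error {d:.2f} px")
# Each ROI passes the 40-px floor and the 10-40 um diameter gate; centroid
# errors of a pixel or less mean masks coincide with the true somata.
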