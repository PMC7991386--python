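"""Unsupervised detection of active somata on the temporal-variance map.

Active neurons are the pixels whose intensity varies most over time, so
detection starts from the per-pixel temporal variance of the aligned stack
and runs an iterative chain per threshold level:

1. dual thresholding — a global variance threshold ``H_G`` combined
   pointwise with an adaptive (local-mean) threshold;
2. morphological closing then opening with a fixed 3×3 cross structuring
   element to clean speckle;
3. removal of components under 40 px and of components touching the border;
4. Euclidean distance transform + marker-based watershed to split touching
   somata;
5. a physical size gate keeping regions whose equivalent diameter lies in
   the 10–40 μm soma range.

If fewer than the expected number of neurons ``P`` have been found, the
global threshold decays geometrically (``H_G ← α·H_G``, α = 0.75) and the
chain repeats, so dimmer neurons surface in later iterations; regions that
re-detect an already-accepted soma are discarded by an overlap test.
Everything here is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

#: fixed 3×3 cross structuring element used by closing and opening
CROSS_SE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class DetectionParams:
    """Parameters of the iterative detection loop.

    ``h_global_init=None`` initializes the global threshold at the 90th
    percentile of the variance map (scale-free default).  The adaptive
    neighborhood defaults to a square window roughly one maximum soma
    diameter wide.  ``alpha`` is the geometric decay of the global threshold
    between iterations.
    """

    expected_neurons: int = 30
    h_global_init: float | None = None
    neuron_diameter_min: float = 10.0  # μm
    neuron_diameter_max: float = 40.0  # μm
    alpha: float = 0.75
    max_iterations: int = 8
    min_feature_px: int = 40
    adaptive_neighborhood: int | None = None  # px, odd; None → from max diameter
    adaptive_offset: float = 0.0
    overlap_discard_frac: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.neuron_diameter_min <= 0 or self.neuron_diameter_min >= self.neuron_diameter_max:
            raise ValueError("need 0 < neuron_diameter_min < neuron_diameter_max")
        if self.expected_neurons < 1:
            raise ValueError("expected_neurons must be ≥ 1")
        if self.min_feature_px < 1:
            raise ValueError("min_feature_px must be ≥ 1")
        if self.adaptive_neighborhood is not None and (
            self.adaptive_neighborhood < 3 or self.adaptive_neighborhood % 2 == 0
        ):
            raise ValueError("adaptive_neighborhood must be odd and ≥ 3")

    def neighborhood_px(self, pixel_size: float) -> int:
        # window must exceed the largest soma, else the local mean inside a
        # big soma approaches the soma's own level and hollows it out
        if self.adaptive_neighborhood is not None:
            return self.adaptive_neighborhood
        n = int(round(2.0 * self.neuron_diameter_max / pixel_size))
        return max(3, n + 1 if n % 2 == 0 else n)

    def area_bounds_px(self, pixel_size: float) -> tuple[float, float]:
        """Soma diameter gate converted to pixel-area bounds."""
        to_area = lambda d: np.pi * (d / (2.0 * pixel_size)) ** 2
        return to_area(self.neuron_diameter_min), to_area(self.neuron_diameter_max)


@dataclass
class VarianceMap:
    values: np.ndarray  # H×W, per-pixel temporal variance
    source_frames: int


@dataclass
class LabelMap:
    """Integer-labeled segmentation: 0 = background, k ≥ 1 = ROI k."""

    labels: np.ndarray
    pixel_size: float = 0.7

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class NeuronROI:
    id: int
    pixels: np.ndarray  # (n, 2) row/col coordinates
    centroid: tuple[float, float]
    area_px: int
    equivalent_diameter_um: float


def variance_map(stack, chunk: int = 200) -> VarianceMap:
    """Per-pixel population variance along time, computed in two passes.

    Frames are promoted to float64 chunk by chunk so arbitrarily long 8-bit
    stacks never materialize a full float copy.
    """
    frames = stack.frames
    n = frames.shape[0]
    if n < 2:
        raise ValueError(f"variance needs ≥ 2 frames, got {n}")
    mean = np.zeros(frames.shape[1:], dtype=np.float64)
    for j in range(0, n, chunk):
        mean += frames[j : j + chunk].astype(np.float64).sum(axis=0)
    mean /= n
    sq = np.zeros_like(mean)
    for j in range(0, n, chunk):
        d = frames[j : j + chunk].astype(np.float64) - mean
        sq += np.einsum("thw,thw->hw", d, d)
    return VarianceMap(values=sq / n, source_frames=n)


def local_mean(values: np.ndarray, neighborhood: int) -> np.ndarray:
    """Arithmetic mean over a square window, clipped at image borders.

    Computed from an integral image so a constant input returns exactly its
    own value everywhere — the strict-inequality tie rule in
    :func:`dual_threshold` depends on that.
    """
    values = np.asarray(values, dtype=np.float64)
    h, w = values.shape
    half = neighborhood // 2
    # sums run on an offset-subtracted field so a constant input is an exact
    # all-zero sum and the mean returns the constant itself, bit for bit
    offset = float(values.flat[0])
    shifted = values - offset
    integral = np.zeros((h + 1, w + 1))
    integral[1:, 1:] = shifted.cumsum(axis=0).cumsum(axis=1)
    r = np.arange(h)
    c = np.arange(w)
    r0 = np.clip(r - half, 0, h)[:, None]
    r1 = np.clip(r + half + 1, 0, h)[:, None]
    c0 = np.clip(c - half, 0, w)[None, :]
    c1 = np.clip(c + half + 1, 0, w)[None, :]
    sums = integral[r1, c1] - integral[r0, c1] - integral[r1, c0] + integral[r0, c0]
    counts = (r1 - r0) * (c1 - c0)
    return offset + sums / counts


def dual_threshold(
    v: VarianceMap | np.ndarray,
    h_global: float,
    neighborhood: int = 57,
    offset: float = 0.0,
) -> np.ndarray:
    """Combine the global and adaptive (local-mean) variance thresholds.

    A pixel passes only if its variance strictly exceeds both ``h_global``
    and the mean over its ``neighborhood``-sized square window plus
    ``offset``; ties fall to background.
    """
    values = v.values if isinstance(v, VarianceMap) else np.asarray(v, dtype=np.float64)
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd and ≥ 3")
    adaptive = values > (local_mean(values, neighborhood) + offset)
    return (values > h_global) & adaptive


def morph_close_open(mask: np.ndarray) -> np.ndarray:
    """Morphological closing then opening with the 3×3 cross.

    Closing (dilate ⊕ then erode ⊖) bridges small gaps; opening (erode then
    dilate) deletes speckle smaller than the cross.  Erosion treats pixels
    beyond the border as foreground and dilation as background, the usual
    binary-image convention.
    """
    mask = np.asarray(mask, dtype=bool)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(mask, CROSS_SE, border_value=0), CROSS_SE, border_value=1
    )
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(closed, CROSS_SE, border_value=1), CROSS_SE, border_value=0
    )
    return opened


def remove_small_and_border(mask: np.ndarray, min_feature_px: int = 40) -> np.ndarray:
    """Drop 4-connected components under ``min_feature_px`` or touching the border."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=CROSS_SE)
    if n == 0:
        return mask.copy()
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep[areas < min_feature_px] = False
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    keep[border] = False
    return keep[labels]


def watershed_labels(mask: np.ndarray, pixel_size: float = 0.7, min_marker_distance: int | None = None) -> LabelMap:
    """Split touching somata by watershed on the negated distance transform.

    The Euclidean distance of each foreground pixel to the nearest
    background pixel is negated and flooded from its deepest minima (the
    distance peaks), restricted to the mask; touching neurons separate along
    the distance ridge between their centers.  ``min_marker_distance``
    suppresses duplicate markers on near-flat distance plateaus; the default
    is half the minimum soma diameter in pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return LabelMap(labels=out, pixel_size=pixel_size)
    if min_marker_distance is None:
        min_marker_distance = max(3, int(round(5.0 / pixel_size)))  # ≈ half of Φ10 μm
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=min_marker_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers=markers, mask=mask, connectivity=1)
    # relabel contiguously in raster order for determinism
    ids = np.unique(labels)
    ids = ids[ids > 0]
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return LabelMap(labels=out, pixel_size=pixel_size)


def _equivalent_diameter_um(area_px: int, pixel_size: float) -> float:
    return 2.0 * pixel_size * np.sqrt(area_px / np.pi)


def select_by_size(labels: LabelMap, params: DetectionParams) -> LabelMap:
    """Keep regions whose equivalent diameter lies within the soma gate."""
    lab = labels.labels
    out = np.zeros_like(lab)
    areas = np.bincount(lab.ravel())
    new = 0
    for k in range(1, len(areas)):
        if areas[k] == 0:
            continue
        d = _equivalent_diameter_um(areas[k], labels.pixel_size)
        if params.neuron_diameter_min <= d <= params.neuron_diameter_max:
            new += 1
            out[lab == k] = new
    return LabelMap(labels=out, pixel_size=labels.pixel_size)


def rois_from_labels(labels: LabelMap) -> list[NeuronROI]:
    """Materialize per-region records (pixels, centroid, area, diameter)."""
    lab = labels.labels
    rois = []
    for k in range(1, labels.n_labels + 1):
        rr, cc = np.nonzero(lab == k)
        if rr.size == 0:
            continue
        rois.append(
            NeuronROI(
                id=k,
                pixels=np.column_stack([rr, cc]),
                centroid=(float(rr.mean()), float(cc.mean())),
                area_px=int(rr.size),
                equivalent_diameter_um=_equivalent_diameter_um(rr.size, labels.pixel_size),
            )
        )
    return rois


def detect_neurons(stack, params: DetectionParams | None = None):
    """Run the full iterative detection loop on an aligned stack.

    Returns ``(LabelMap, list[NeuronROI], iteration_log)``.  The variance
    map is computed once; each iteration thresholds it at the current
    ``H_G``, runs morphology, cleanup, watershed and the size gate, and
    appends newly found regions that overlap no accepted region by more
    than ``overlap_discard_frac`` of their own area.  ``H_G`` decays by
    ``alpha`` between iterations; the loop exits once the accepted count
    reaches ``expected_neurons`` or the iteration budget is spent.  The log
    records ``(iteration, h_global, new_rois, total)`` per pass.
    """
    params = params or DetectionParams()
    vmap = variance_map(stack)
    pixel_size = stack.pixel_size
    neighborhood = params.neighborhood_px(pixel_size)
    h = (
        params.h_global_init
        if params.h_global_init is not None
        else float(np.percentile(vmap.values, 90.0))
    )
    accepted: list[np.ndarray] = []  # one boolean region per ROI, in order
    log = []
    for it in range(params.max_iterations):
        mask = dual_threshold(vmap, h, neighborhood, params.adaptive_offset)
        mask = morph_close_open(mask)
        mask = remove_small_and_border(mask, params.min_feature_px)
        labs = watershed_labels(mask, pixel_size=pixel_size)
        labs = select_by_size(labs, params)
        new = 0
        for k in range(1, labs.n_labels + 1):
            region = labs.labels == k
            area = int(region.sum())
            if area < params.min_feature_px:
                continue
            hits = [i for i, a in enumerate(accepted) if np.logical_and(a, region).any()]
            overlap = sum(int(np.logical_and(accepted[i], region).sum()) for i in hits)
            if overlap <= params.overlap_discard_frac * area:
                # mostly-new region: trim away claimed pixels, re-check gates
                fresh = region.copy()
                for i in hits:
                    fresh &= ~accepted[i]
                fresh_area = int(fresh.sum())
                d = _equivalent_diameter_um(fresh_area, pixel_size)
                if fresh_area >= params.min_feature_px and (
                    params.neuron_diameter_min <= d <= params.neuron_diameter_max
                ):
                    accepted.append(fresh)
                    new += 1
            elif hits and all(
                np.logical_and(accepted[i], region).sum() >= 0.6 * accepted[i].sum()
                for i in hits
            ):
                # a more complete re-detection at the lower threshold
                # supersedes the partial regions it contains
                for i in sorted(hits, reverse=True):
                    del accepted[i]
                accepted.append(region)
            # else: re-detection of an established ROI — discard
        log.append(
            {"iteration": it + 1, "h_global": h, "new_rois": new, "total": len(accepted)}
        )
        h *= params.alpha
        if len(accepted) >= params.expected_neurons:
            break
    labels = np.zeros(vmap.values.shape, dtype=np.int32)
    for idx, region in enumerate(accepted, start=1):
        labels[region] = idx
    label_map = LabelMap(labels=labels, pixel_size=pixel_size)
    return label_map, rois_from_labels(label_map), log
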