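"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written definitionally — explicit loops over pixels and
structuring-element offsets — and deliberately shares no code with the
package internals it checks.
"""

from __future__ import annotations

import numpy as np

CROSS_OFFSETS = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]


def mi_bruteforce(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Mutual information in bits from an explicitly tabulated joint histogram.

    Bin edges are ``n_bins`` equal-width intervals over [0, 255]
    (left-inclusive, last bin closed).  Entropies are summed term by term
    with the 0·log 0 = 0 convention.
    """
    edges = np.linspace(0.0, 255.0, n_bins + 1)

    def idx(v: float) -> int:
        k = int(np.searchsorted(edges, v, side="right")) - 1
        return min(max(k, 0), n_bins - 1)

    joint = np.zeros((n_bins, n_bins))
    for xv, yv in zip(np.ravel(x), np.ravel(y)):
        joint[idx(float(xv)), idx(float(yv))] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        h = 0.0
        for v in np.ravel(p):
            if v > 0:
                h -= v * np.log2(v)
        return h

    return entropy(px) + entropy(py) - entropy(joint)


def dilate_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Minkowski dilation with the 3×3 cross; outside the image is background."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            for dr, dc in CROSS_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def erode_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Minkowski erosion with the 3×3 cross; outside the image is foreground."""
    h, w = mask.shape
    out = np.ones_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            for dr, dc in CROSS_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                    out[r, c] = False
                    break
    return out


def close_open_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Closing (⊕ then ⊖) followed by opening (⊖ then ⊕), definitionally."""
    closed = erode_bruteforce(dilate_bruteforce(mask))
    return dilate_bruteforce(erode_bruteforce(closed))


def local_mean_bruteforce(values: np.ndarray, neighborhood: int) -> np.ndarray:
    """Sliding-window arithmetic mean with the window clipped at borders."""
    h, w = values.shape
    half = neighborhood // 2
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            r0, r1 = max(0, r - half), min(h, r + half + 1)
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            total, count = 0.0, 0
            for rr in range(r0, r1):
                for cc in range(c0, c1):
                    total += values[rr, cc]
                    count += 1
            out[r, c] = total / count
    return out


def variance_bruteforce(frames: np.ndarray) -> np.ndarray:
    """Two-pass per-pixel population variance, one pixel at a time."""
    t, h, w = frames.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            series = [float(frames[j, r, c]) for j in range(t)]
            mean = sum(series) / t
            out[r, c] = sum((v - mean) ** 2 for v in series) / t
    return out


def roi_means_bruteforce(frames: np.ndarray, labels: np.ndarray, label: int) -> np.ndarray:
    """Per-frame mean over a label's pixels via explicit loops."""
    t = frames.shape[0]
    coords = [(r, c) for r, c in zip(*np.nonzero(labels == label))]
    out = np.zeros(t)
    for j in range(t):
        out[j] = sum(float(frames[j, r, c]) for r, c in coords) / len(coords)
    return out


def match_rois(true_centroids, found_centroids, true_radii_px):
    """Greedy centroid matching within one true-neuron radius.

    Returns (n_matched, matches) where matches maps true-index → found-index.
    """
    matches = {}
    used = set()
    for i, (tc, rad) in enumerate(zip(true_centroids, true_radii_px)):
        best, best_d = None, np.inf
        for k, fc in enumerate(found_centroids):
            if k in used:
                continue
            d = float(np.hypot(tc[0] - fc[0], tc[1] - fc[1]))
            if d < best_d:
                best, best_d = k, d
        if best is not None and best_d <= rad:
            matches[i] = best
            used.add(best)
    return len(matches), matches
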