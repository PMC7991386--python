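"""Rigid motion correction by mutual-information maximization.

Mechanical stimulation of the attached colorectum drags the ganglion under
the objective — translations of tens of μm and rotations of a degree or two
are typical — so every frame is registered to the first frame of the
recording before any signal extraction.  The similarity objective is the
mutual information of the joint intensity histogram,

    MI(X, Y) = H(X) + H(Y) − H(X, Y)   [bits],

which tolerates the intensity changes that the calcium signal itself
introduces between frames (the two images need not be photometrically
identical, only statistically dependent).  The per-frame transform is a
translation plus an in-plane rotation about the image center, found by a
finite-difference ascent with per-parameter step halving and a fixed
iteration budget (default 50), warm-started from the previous frame because
the motion is temporally smooth.

Conventions
-----------
A :class:`RigidTransform` ``(dx, dy, theta)`` describes the displacement of
the moving frame relative to the reference: the moving frame looks like the
reference shifted by ``dx`` columns / ``dy`` rows and rotated by ``theta``
degrees counter-clockwise about the image center.  Alignment therefore
resamples each frame under the *inverse* of its estimated transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: x/y translation in pixels, rotation in degrees."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx) and np.isfinite(self.dy) and np.isfinite(self.theta)):
            raise ValueError("transform parameters must be finite")

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and self.theta == 0.0

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one (compose(inverse) == identity)."""
        c, s = np.cos(np.radians(-self.theta)), np.sin(np.radians(-self.theta))
        # rotate the negated translation into the inverse frame
        dyi = -(c * self.dy - s * self.dx)
        dxi = -(s * self.dy + c * self.dx)
        return RigidTransform(dx=dxi, dy=dyi, theta=-self.theta)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        c, s = np.cos(np.radians(self.theta)), np.sin(np.radians(self.theta))
        dy = c * other.dy - s * other.dx + self.dy
        dx = s * other.dy + c * other.dx + self.dx
        return RigidTransform(dx=dx, dy=dy, theta=self.theta + other.theta)

    def to_dict(self) -> dict:
        return {"dx_px": self.dx, "dy_px": self.dy, "theta_deg": self.theta}


@dataclass
class RegistrationSettings:
    """Optimizer knobs for the MI ascent.

    ``n_bins`` is the per-image histogram bin count over the 8-bit range;
    64 bins is the usual bias/variance compromise for 8-bit data.  Initial
    step sizes are 1 px translation and 0.5° rotation, halved whenever no
    parameter move improves MI; the search stops after ``max_iterations``
    sweeps or once all steps fall below ``step_tolerance``.
    """

    n_bins: int = 64
    max_iterations: int = 50
    init_step_px: float = 1.0
    init_step_deg: float = 0.5
    step_tolerance: float = 1e-3
    estimate_rotation: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be ≥ 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be ≥ 1")


def _entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count table (0·log 0 = 0)."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _bin_indices(image: np.ndarray, n_bins: int, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.zeros(image.size, dtype=np.intp)
    idx = ((np.asarray(image, dtype=np.float64).ravel() - lo) * (n_bins / span)).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def _histogram_range(image_x: np.ndarray, image_y: np.ndarray) -> tuple[float, float]:
    # 8-bit data bins over the full [0, 255] range; anything else over the
    # joint min/max so the histogram stays meaningful for float stacks.
    lo = min(float(np.min(image_x)), float(np.min(image_y)))
    hi = max(float(np.max(image_x)), float(np.max(image_y)))
    if lo >= 0.0 and hi <= 255.0:
        return 0.0, 255.0
    return lo, hi


def mutual_information(image_x: np.ndarray, image_y: np.ndarray, n_bins: int = 64) -> float:
    """Mutual information between two equal-shape images, in bits.

    Computed as ``H(X) + H(Y) − H(X, Y)`` from the joint intensity histogram
    with ``n_bins`` equal-width bins per image (spanning [0, 255] for 8-bit
    range data).  Symmetric and non-negative up to floating tolerance;
    degenerate constant images give 0 via the 0·log 0 = 0 convention.
    """
    image_x = np.asarray(image_x)
    image_y = np.asarray(image_y)
    if image_x.shape != image_y.shape:
        raise ValueError(f"shape mismatch: {image_x.shape} vs {image_y.shape}")
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    lo, hi = _histogram_range(image_x, image_y)
    ix = _bin_indices(image_x, n_bins, lo, hi)
    iy = _bin_indices(image_y, n_bins, lo, hi)
    joint = np.bincount(ix * n_bins + iy, minlength=n_bins * n_bins)
    hx = _entropy_bits(np.bincount(ix, minlength=n_bins))
    hy = _entropy_bits(np.bincount(iy, minlength=n_bins))
    hxy = _entropy_bits(joint)
    return hx + hy - hxy


def apply_rigid(image: np.ndarray, transform: RigidTransform, fill: float | None = None) -> np.ndarray:
    """Resample an image under a rigid transform (bilinear interpolation).

    The output at pixel ``p`` samples the input at the pre-image of ``p``
    under the transform's forward map (rotate about center, then shift), so
    ``apply_rigid(ref, T)`` produces the frame a camera displaced by ``T``
    would have recorded.  Out-of-frame pixels are filled with the image mean
    by default — constant-zero fill would put a spurious spike in the
    intensity histogram and bias MI.
    """
    image = np.asarray(image, dtype=np.float64)
    if transform.is_identity:
        return image.copy()
    if fill is None:
        fill = float(image.mean())
    center = (np.asarray(image.shape) - 1) / 2.0
    t = np.array([transform.dy, transform.dx])
    ang = np.radians(-transform.theta)
    c, s = np.cos(ang), np.sin(ang)
    matrix = np.array([[c, -s], [s, c]])
    offset = center - matrix @ (center + t)
    return ndimage.affine_transform(
        image, matrix, offset=offset, order=1, mode="constant", cval=fill
    )


@dataclass
class AlignmentResult:
    """Per-frame rigid estimates plus the resampled stack."""

    transforms: list
    aligned: "ImageStack"
    mi_trace: np.ndarray


def _check_finite(image: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(image)):
        raise ValueError(f"{what} contains non-finite pixels")


def register_pair(
    reference: np.ndarray,
    moving: np.ndarray,
    settings: RegistrationSettings | None = None,
    initial: RigidTransform | None = None,
) -> RigidTransform:
    """Estimate the rigid displacement of ``moving`` relative to ``reference``.

    Maximizes MI over (dx, dy, theta) by coordinate-wise finite-difference
    ascent with step halving; subpixel accuracy comes from the shrinking
    steps.  Resampling ``moving`` under the returned transform's inverse
    aligns it onto ``reference``.
    """
    settings = settings or RegistrationSettings()
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {moving.shape}")
    _check_finite(reference, "reference")
    _check_finite(moving, "moving")

    n_bins = settings.n_bins
    lo, hi = _histogram_range(reference, moving)
    ref_idx = _bin_indices(reference, n_bins, lo, hi)
    ref_counts = np.bincount(ref_idx, minlength=n_bins)
    h_ref = _entropy_bits(ref_counts)
    fill = float(moving.mean())

    def mi_at(params: np.ndarray) -> float:
        t = RigidTransform(dx=params[0], dy=params[1], theta=params[2])
        warped = apply_rigid(moving, t.inverse(), fill=fill)
        wi = _bin_indices(np.clip(warped, lo, hi), n_bins, lo, hi)
        joint = np.bincount(ref_idx * n_bins + wi, minlength=n_bins * n_bins)
        hy = _entropy_bits(np.bincount(wi, minlength=n_bins))
        return h_ref + hy - _entropy_bits(joint)

    params = np.array(
        [initial.dx, initial.dy, initial.theta] if initial is not None else [0.0, 0.0, 0.0]
    )
    steps = np.array([settings.init_step_px, settings.init_step_px, settings.init_step_deg])
    active = [0, 1, 2] if settings.estimate_rotation else [0, 1]
    best = mi_at(params)
    for _ in range(settings.max_iterations):
        improved = False
        for k in active:
            for sign in (1.0, -1.0):
                cand = params.copy()
                cand[k] += sign * steps[k]
                val = mi_at(cand)
                if val > best:
                    best, params = val, cand
                    improved = True
                    break
        if not improved:
            steps *= 0.5
            if steps.max() < settings.step_tolerance:
                break
    return RigidTransform(dx=params[0], dy=params[1], theta=params[2])


def align_stack(stack, settings: RegistrationSettings | None = None) -> AlignmentResult:
    """Register every frame to the first frame and resample the stack.

    Frame 0 is the reference and passes through untouched; each later frame
    is resampled under the inverse of its estimated transform.  Each frame's
    search is warm-started from the previous frame's estimate, which keeps
    the ascent near the right optimum when the motion is smooth.
    """
    settings = settings or RegistrationSettings()
    frames = stack.as_float()
    n = frames.shape[0]
    reference = frames[0]
    transforms: list[RigidTransform] = [RigidTransform()]
    aligned = np.empty_like(frames)
    aligned[0] = reference
    mi_trace = np.empty(n)
    mi_trace[0] = mutual_information(reference, reference, settings.n_bins)
    prev = RigidTransform()
    for j in range(1, n):
        try:
            t = register_pair(reference, frames[j], settings, initial=prev)
        except ValueError as exc:
            raise ValueError(f"registration failed at frame {j}: {exc}") from exc
        transforms.append(t)
        prev = t
        aligned[j] = apply_rigid(frames[j], t.inverse())
        mi_trace[j] = mutual_information(reference, aligned[j], settings.n_bins)
    out = stack.with_frames(aligned)
    return AlignmentResult(transforms=transforms, aligned=out, mi_trace=mi_trace)
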