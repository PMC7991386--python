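"""Reading and writing image stacks and pipeline artifacts.

An :class:`ImageStack` is the in-memory unit the whole chain operates on: a
time-ordered ``T×H×W`` array plus the two acquisition numbers everything
downstream needs — frame rate (Hz) and pixel size (μm/px).  Stacks load from
multi-page TIFFs, directories of numbered still images, or common video
containers; color input is collapsed to grayscale by unweighted channel mean
because the instrument records monochrome.  All science modules promote pixel
data to float64 before computing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

_STILL_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_VIDEO_EXTS = {".mp4", ".avi", ".mov"}


class StackFormatError(ValueError):
    """Unreadable, inconsistent, or unsupported image input."""


@dataclass
class ImageStack:
    """A time-ordered fluorescence recording with acquisition metadata.

    Parameters
    ----------
    frames
        ``T×H×W`` array. 8-bit integer as recorded, or floating point after
        alignment/processing.
    frame_rate
        Acquisition rate in Hz (default instrument setting: 50).
    pixel_size
        Lateral sampling in μm per pixel (default instrument setting: 0.7).
    origin_path
        Provenance string; empty for synthetic stacks.
    """

    frames: np.ndarray
    frame_rate: float = 50.0
    pixel_size: float = 0.7
    origin_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise StackFormatError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise StackFormatError(f"need at least 2 frames, got {self.frames.shape[0]}")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate

    def as_float(self) -> np.ndarray:
        """Pixel data promoted to float64 (copy only if needed)."""
        return np.asarray(self.frames, dtype=np.float64)

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        """New stack with replaced pixel data, metadata carried over."""
        return replace(self, frames=frames)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing color axis by unweighted channel mean."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        out = arr[..., :3].mean(axis=-1)
        if np.issubdtype(arr.dtype, np.integer):
            out = np.round(out).astype(arr.dtype)
        return out
    raise StackFormatError(f"cannot interpret image of shape {arr.shape} as grayscale")


def _numeric_key(name: str):
    # frame2 sorts before frame10
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def _load_tiff(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # pages with color channels
        arr = np.stack([_to_gray(page) for page in arr])
    return arr


def _load_directory(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _STILL_EXTS),
        key=lambda p: _numeric_key(p.name),
    )
    if not files:
        raise StackFormatError(f"no still images found in {path}")
    frames = [_to_gray(np.asarray(iio.imread(f))) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise StackFormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
    return np.stack(frames)


def _load_video(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    frames = [_to_gray(np.asarray(f)) for f in iio.imiter(path)]
    if not frames:
        raise StackFormatError(f"no frames decoded from {path}")
    return np.stack(frames)


def load_stack(path, frame_rate: float = 50.0, pixel_size: float = 0.7) -> ImageStack:
    """Load a recording from TIFF stack, image-sequence directory, or video.

    Color inputs are converted to grayscale by channel averaging.  Frames are
    ordered by page index (TIFF), numeric-aware filename sort (directories),
    or decode order (video).

    Raises
    ------
    StackFormatError
        If the path is unreadable, frames have mixed shapes, or fewer than
        two frames are present.
    """
    path = Path(path)
    if not path.exists():
        raise StackFormatError(f"no such file or directory: {path}")
    try:
        if path.is_dir():
            frames = _load_directory(path)
        elif path.suffix.lower() in (".tif", ".tiff"):
            frames = _load_tiff(path)
        elif path.suffix.lower() in _VIDEO_EXTS:
            frames = _load_video(path)
        elif path.suffix.lower() in _STILL_EXTS:
            raise StackFormatError(
                f"{path} is a single still image; pass a TIFF stack, directory, or video"
            )
        else:
            raise StackFormatError(f"unsupported input format: {path.suffix!r}")
    except StackFormatError:
        raise
    except Exception as exc:  # decoder errors surface as format errors
        raise StackFormatError(f"could not read {path}: {exc}") from exc
    if frames.shape[0] < 2:
        raise StackFormatError(f"{path} holds {frames.shape[0]} frame(s); need ≥ 2")
    return ImageStack(frames, frame_rate=frame_rate, pixel_size=pixel_size, origin_path=str(path))


def save_stack(stack: ImageStack, path) -> Path:
    """Write a stack as a multi-page TIFF (float data stored as float32).

    Round-trips losslessly for integer stacks.
    """
    path = Path(path)
    frames = stack.frames
    if np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float32)
    try:
        tifffile.imwrite(path, frames, photometric="minisblack")
    except OSError as exc:
        raise OSError(f"cannot write stack to {path}: {exc}") from exc
    return path


def export_traces(traces, path) -> Path:
    """Write traces as a tab-delimited table: time column + one column per id.

    ΔF/F values are written when present, otherwise the raw intensity
    profile.  All traces must share one time base.
    """
    path = Path(path)
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to export")
    n = len(traces[0].raw)
    fr = traces[0].frame_rate
    for t in traces:
        if len(t.raw) != n or t.frame_rate != fr:
            raise ValueError("traces do not share one time base")
    header = "time_s\t" + "\t".join(f"neuron_{t.neuron_id}" for t in traces)
    cols = [np.arange(n) / fr] + [
        (t.dff if t.dff is not None else np.asarray(t.raw, dtype=float)) for t in traces
    ]
    table = np.column_stack(cols)
    np.savetxt(path, table, delimiter="\t", header=header, comments="", fmt="%.6f")
    return path
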