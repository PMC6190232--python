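"""Frame-sequence I/O: reading videos or image directories, writing results.

Coordinate convention used throughout the package: ``(u, v) = (row, column)``,
0-based, origin at the top-left pixel.  Frame indices in the public API are
1-based, i.e. the first frame of a video is frame 1.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .speed import CorrelationTrace, SpeedProfile

__all__ = [
    "FrameSequence",
    "load_frames",
    "to_grayscale",
    "write_results",
]

#: ITU-R BT.601 luma weights used for the RGB -> grayscale conversion.
_BT601 = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


class FrameSequenceError(ValueError):
    """Raised for unreadable, inconsistent or too-short frame sources."""


def _round_half_up(x):
    """Round half away from zero toward +inf (0.5 -> 1), elementwise."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert a single frame to 8-bit-range grayscale floats.

    RGB(A) input is collapsed with BT.601 weights (0.299, 0.587, 0.114) and
    rounded half-up; grayscale input passes through unchanged (idempotent).
    Inputs with more than 8 bits per channel are rescaled linearly to 0-255.
    """
    arr = np.asarray(frame)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise FrameSequenceError(
                f"expected an RGB(A) frame, got shape {arr.shape}"
            )
        arr = arr[:, :, :3]
        gray = _round_half_up(arr.astype(float) @ _BT601)
    elif arr.ndim == 2:
        gray = arr.astype(float)
    else:
        raise FrameSequenceError(f"frame must be 2-D or 3-D, got shape {arr.shape}")
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        info = np.iinfo(np.asarray(frame).dtype)
        if info.max > 255:  # >8-bit camera: linear rescale to the 8-bit range
            gray = _round_half_up(gray * (255.0 / info.max))
    return gray


@dataclass(frozen=True)
class FrameSequence:
    """An ordered stack of equally-sized grayscale frames with a frame rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Grayscale intensities in the 8-bit range 0-255, stored as floats so
        that downstream arithmetic (background averaging, correlation) is
        exact.
    f_fps : float
        Frame rate in frames per second; must be positive.

    Notes
    -----
    Frames are addressed 1-based through :meth:`frame`; ``seq.frame(1)`` is
    the first frame.
    """

    frames: np.ndarray
    f_fps: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3:
            raise FrameSequenceError(
                f"frames must be a (n, height, width) stack, got shape {arr.shape}"
            )
        if arr.shape[0] < 2:
            raise FrameSequenceError("a frame sequence needs at least 2 frames")
        if not (self.f_fps > 0 and math.isfinite(self.f_fps)):
            raise FrameSequenceError(f"f_fps must be positive, got {self.f_fps}")
        object.__setattr__(self, "frames", arr)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def frame(self, i: int) -> np.ndarray:
        """Return frame ``i`` (1-based)."""
        if not 1 <= i <= len(self):
            raise IndexError(f"frame index {i} outside [1, {len(self)}]")
        return self.frames[i - 1]

    @classmethod
    def from_arrays(cls, frames: Sequence[np.ndarray], f_fps: float) -> "FrameSequence":
        """Build a sequence from individual frames (color allowed)."""
        grays = [to_grayscale(f) for f in frames]
        shapes = {g.shape for g in grays}
        if len(shapes) > 1:
            raise FrameSequenceError(f"frames have mismatched sizes: {sorted(shapes)}")
        return cls(np.stack(grays), f_fps)


def _numeric_key(path: Path):
    """Sort key putting frame_2 before frame_10 (numeric filename order)."""
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def load_frames(source_path, f_fps: float) -> FrameSequence:
    """Load a video container or a directory of numbered images.

    Supported sources: a directory of PNG/TIFF/BMP frames (sorted by the
    numeric components of their filenames), a multi-page TIFF, or any
    single-file container imageio can open.  Color frames are converted to
    grayscale (BT.601).

    Raises
    ------
    FrameSequenceError
        If the source is unreadable, has mismatched frame sizes, or holds
        fewer than two frames.
    """
    path = Path(source_path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=_numeric_key,
        )
        if len(files) < 2:
            raise FrameSequenceError(f"need at least 2 image frames in {path}")
        import imageio.v3 as iio

        return FrameSequence.from_arrays([iio.imread(f) for f in files], f_fps)
    if not path.exists():
        raise FrameSequenceError(f"no such file or directory: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 2:
            raise FrameSequenceError(f"{path} holds a single frame")
        return FrameSequence.from_arrays(list(stack), f_fps)
    try:
        import imageio.v3 as iio

        frames = list(iio.imiter(path))
    except Exception as exc:  # pragma: no cover - depends on installed plugins
        raise FrameSequenceError(f"could not read video {path}: {exc}") from exc
    if len(frames) < 2:
        raise FrameSequenceError(f"{path} holds fewer than 2 frames")
    return FrameSequence.from_arrays(frames, f_fps)


def write_results(
    profile: "SpeedProfile",
    trace: "CorrelationTrace",
    out_path,
    parameters: dict | None = None,
) -> None:
    """Write the measurement to ``out_path`` as ``results.csv`` + ``summary.json``.

    The CSV holds one row per rotation cycle (``record=cycle``: cycle index,
    interval in frames, rpm) and one row per trajectory point
    (``record=trajectory``: peak frame index, u, v).  The JSON summary holds
    the mean rpm (null when no complete cycle was observed), the cycle count,
    the reference frame index and the parameters used.
    """
    out_dir = Path(out_path)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "results.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record", "index", "interval_frames", "rpm", "frame", "u", "v"])
        for k, (dt, rpm) in enumerate(
            zip(profile.intervals, profile.speeds_rpm), start=1
        ):
            writer.writerow(["cycle", k, repr(float(dt)), repr(float(rpm)), "", "", ""])
        for idx, (u, v) in zip(profile.peak_indices, profile.trajectory):
            writer.writerow(["trajectory", "", "", "", idx, u, v])

    summary = {
        "mean_rpm": None if profile.mean_rpm is None else float(profile.mean_rpm),
        "n_cycles": len(profile.speeds_rpm),
        "reference_frame": int(trace.reference_index),
        "lbound": float(profile.lbound),
        "parameters": parameters or {},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
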