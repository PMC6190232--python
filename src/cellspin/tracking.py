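"""Background subtraction, moving-region segmentation and cell tracking.

The cell of interest is marked once, with a rectangle in the first frame.
Every frame is then compared against a static background image (the pixelwise
mean of the first ``N`` frames); the absolute difference is binarized with
Otsu's threshold, cleaned with morphological opening and closing, and its
connected components are labeled.  The component nearest the previous frame's
position is taken as the cell's moving region, and a search window slightly
larger than the moving region is recorded for the template matching stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .io import FrameSequence, _round_half_up

__all__ = [
    "RegionRect",
    "ConnectedComponent",
    "TrackState",
    "TrackingError",
    "compute_background",
    "otsu_threshold",
    "segment_moving_regions",
    "track",
]

logger = logging.getLogger(__name__)


class TrackingError(RuntimeError):
    """Raised when tracking cannot start (no moving region in frame 1)."""


@dataclass(frozen=True)
class RegionRect:
    """Odd-sized rectangle: center ``(u, v)``, half extents ``(W, H)``.

    Spans ``2*half_width + 1`` columns and ``2*half_height + 1`` rows, i.e.
    rows ``u - half_height .. u + half_height`` and columns
    ``v - half_width .. v + half_width`` inclusive.
    """

    u: int
    v: int
    half_width: int
    half_height: int

    def __post_init__(self) -> None:
        if self.half_width < 1 or self.half_height < 1:
            raise ValueError("half extents must be >= 1")

    @property
    def center(self) -> tuple[int, int]:
        return (self.u, self.v)

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1

    @property
    def height(self) -> int:
        return 2 * self.half_height + 1

    def fits_in(self, shape: tuple[int, int]) -> bool:
        """True when the rectangle lies fully inside a (height, width) frame."""
        return (
            self.u - self.half_height >= 0
            and self.v - self.half_width >= 0
            and self.u + self.half_height < shape[0]
            and self.v + self.half_width < shape[1]
        )


@dataclass(frozen=True)
class ConnectedComponent:
    """A labeled moving blob: its pixels, rounded centroid and max radius.

    ``centroid`` is the rounded (half-up) mean of the pixel coordinates;
    ``radius`` is the rounded maximum distance of any pixel from the exact
    (unrounded) centroid.
    """

    pixels: np.ndarray  # (M, 2) array of (u, v) coordinates
    label: int

    @property
    def count(self) -> int:
        return self.pixels.shape[0]

    @property
    def exact_centroid(self) -> tuple[float, float]:
        cu, cv = self.pixels.mean(axis=0)
        return (float(cu), float(cv))

    @property
    def centroid(self) -> tuple[int, int]:
        cu, cv = self.exact_centroid
        return (int(_round_half_up(cu)), int(_round_half_up(cv)))

    @property
    def radius(self) -> int:
        cu, cv = self.exact_centroid
        d = np.hypot(self.pixels[:, 0] - cu, self.pixels[:, 1] - cv)
        return int(_round_half_up(d.max()))


@dataclass
class TrackState:
    """Per-frame tracking record for the cell of interest.

    ``centers[i-1]`` and ``radii[i-1]`` are the moving-region center and
    radius in frame ``i`` (1-based).  ``moving_regions[i-1]`` is the square
    ``Rect[(u_i, v_i), 2 r_i + 1, 2 r_i + 1]`` over which the matching stage
    places candidate template centers; ``search_windows[i-1]`` is that
    square dilated by the template half extents,
    ``Rect[(u_i, v_i), 2 r_i + 2W + 1, 2 r_i + 2H + 1]`` — the pixel support
    touched by any candidate placement.  ``half_width``/``half_height`` are
    the template half extents ``W``/``H`` from the initial rectangle.
    """

    centers: list[tuple[int, int]]
    radii: list[int]
    moving_regions: list[RegionRect]
    search_windows: list[RegionRect]
    background: np.ndarray
    otsu_levels: list[int]
    struct_radius: int
    half_width: int
    half_height: int

    def center(self, i: int) -> tuple[int, int]:
        return self.centers[i - 1]

    def moving_region(self, i: int) -> RegionRect:
        return self.moving_regions[i - 1]

    def search_window(self, i: int) -> RegionRect:
        return self.search_windows[i - 1]


def compute_background(seq: FrameSequence, n: int) -> np.ndarray:
    """Pixelwise arithmetic mean of frames ``1..n`` at float precision.

    ``n`` must satisfy ``2 <= n <= len(seq)`` and, for a reliable background,
    should exceed the number of frames in one self-rotation cycle (the
    caller's responsibility: a shorter window leaves a rotating texture
    imprinted on the mean).
    """
    if not 2 <= n <= len(seq):
        raise ValueError(f"n must be in [2, {len(seq)}], got {n}")
    return seq.frames[:n].mean(axis=0)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's level on a 256-bin histogram, smallest maximizer tie-break.

    Returns the smallest integer ``t`` in ``[0, 255]`` maximizing the
    between-class variance of the split ``{<= t, > t}``; intensities are
    binned by their integer part (bin ``k`` covers ``[k, k+1)``).  A
    single-valued image returns that value, so the strict-greater
    binarization yields an empty foreground.
    """
    arr = np.asarray(img, dtype=float)
    if arr.size == 0:
        raise ValueError("image has no pixels")
    binned = np.clip(np.floor(arr), 0, 255).astype(int)
    hist = np.bincount(binned.ravel(), minlength=256).astype(float)
    total = hist.sum()
    w0 = np.cumsum(hist)  # class {<= t}
    w1 = total - w0
    cum_mean = np.cumsum(hist * np.arange(256))
    grand = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand - cum_mean) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, 0.0)
    if var_between.max() == 0.0:  # constant image: degenerate split
        return int(np.flatnonzero(hist)[0])
    return int(np.argmax(var_between))


def _disk(radius: int) -> np.ndarray:
    # flat structuring element: pixel centers no farther than `radius` from origin
    return morphology.disk(radius)


def _segment(frame: np.ndarray, background: np.ndarray, struct_radius: int):
    """Segment moving regions; returns (components, otsu_level, mask)."""
    if frame.shape != background.shape:
        raise ValueError("frame and background must share dimensions")
    if struct_radius < 1:
        raise ValueError("struct_radius must be >= 1")
    diff = np.abs(np.asarray(frame, dtype=float) - background)
    level = otsu_threshold(diff)
    mask = diff > level
    selem = _disk(struct_radius)
    mask = morphology.opening(mask, selem)
    mask = morphology.closing(mask, selem)
    labels = measure.label(mask, connectivity=2)
    components = []
    for q in range(1, labels.max() + 1):
        pixels = np.argwhere(labels == q)
        components.append(ConnectedComponent(pixels=pixels, label=q))
    return components, level, mask


def segment_moving_regions(
    frame: np.ndarray, background: np.ndarray, struct_radius: int
) -> list[ConnectedComponent]:
    """Moving blobs of one frame: |frame - background| -> Otsu -> open/close -> label.

    Opening (flat disk of radius ``struct_radius``) removes small noise
    speckles, closing reconnects fragments of one cell, and 8-connected
    labeling yields one :class:`ConnectedComponent` per moving object.  An
    empty list is a valid result (nothing moved).
    """
    components, _, _ = _segment(frame, background, struct_radius)
    return components


def _nearest_component(
    components: list[ConnectedComponent], point: tuple[int, int]
) -> ConnectedComponent:
    centroids = np.array([c.centroid for c in components], dtype=float)
    d2 = ((centroids - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    return components[int(np.argmin(d2))]  # ties: smallest label (raster order)


def track(
    seq: FrameSequence,
    init_rect: RegionRect,
    n_background: int = 40,
    struct_radius: int = 3,
) -> TrackState:
    """Track the cell marked by ``init_rect`` through the whole video.

    In frame 1 the moving region is the connected component whose centroid is
    nearest (Euclidean) to the rectangle's center; in frame ``i > 1`` it is
    the component nearest the previous frame's center ``(u_{i-1}, v_{i-1})``.
    Each frame's search window is ``Rect[(u_i, v_i), 2 r_i + 2W + 1,
    2 r_i + 2H + 1]`` with ``W``/``H`` from ``init_rect``.

    A frame with no moving regions carries the previous center and radius
    forward (one washed-out frame must not abort a multi-cycle measurement);
    no components in frame 1 is a hard :class:`TrackingError`.
    """
    if not init_rect.fits_in((seq.height, seq.width)):
        raise ValueError("init_rect does not lie inside the frame")
    background = compute_background(seq, n_background)

    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    regions: list[RegionRect] = []
    windows: list[RegionRect] = []
    levels: list[int] = []
    prev: tuple[int, int] = init_rect.center
    prev_r = 0

    for i in range(1, len(seq) + 1):
        components, level, _ = _segment(seq.frame(i), background, struct_radius)
        levels.append(level)
        if components:
            comp = _nearest_component(components, prev)
            center, radius = comp.centroid, comp.radius
        elif i == 1:
            raise TrackingError(
                "no moving regions in frame 1; tracking cannot start"
            )
        else:
            logger.warning(
                "frame %d: no moving regions; carrying forward (%d, %d), r=%d",
                i, prev[0], prev[1], prev_r,
            )
            center, radius = prev, prev_r
        centers.append(center)
        radii.append(radius)
        regions.append(
            RegionRect(
                u=center[0], v=center[1],
                half_width=max(radius, 1), half_height=max(radius, 1),
            )
        )
        windows.append(
            RegionRect(
                u=center[0],
                v=center[1],
                half_width=radius + init_rect.half_width,
                half_height=radius + init_rect.half_height,
            )
        )
        prev, prev_r = center, radius

    return TrackState(
        centers=centers,
        radii=radii,
        moving_regions=regions,
        search_windows=windows,
        background=background,
        otsu_levels=levels,
        struct_radius=struct_radius,
        half_width=init_rect.half_width,
        half_height=init_rect.half_height,
    )
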