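"""Model/Results interface tying the whole measurement pipeline together.

:class:`SelfRotationModel` is constructed from a frame sequence and the
rectangle marking the cell of interest in the first frame; :meth:`fit` runs
background estimation, tracking, reference-frame selection, correlation
tracing, peak detection with parabolic sub-frame refinement, and speed/
trajectory extraction, returning a :class:`SelfRotationResults` carrying the
per-cycle estimates, their dispersion, diagnostics and a ``summary()``
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import io as _io
from .io import FrameSequence, load_frames
from .matching import RefSelection, select_reference
from .speed import (
    CorrelationTrace,
    SpeedProfile,
    choose_lbound,
    correlation_trace,
    cycle_speeds,
    find_peaks,
    parabola_vertex,
    trajectory,
)
from .tracking import RegionRect, TrackState, track

__all__ = ["SelfRotationModel", "SelfRotationResults"]

logger = logging.getLogger(__name__)


class SelfRotationModel:
    """Self-rotation speed measurement for one cell in a multi-cell video.

    Parameters
    ----------
    frames : FrameSequence
        Grayscale video with a known frame rate.
    roi : RegionRect or (u, v, W, H)
        Rectangle covering the cell of interest in frame 1; center (u, v) =
        (row, col), half extents W (columns) and H (rows).  Keep it as tight
        around the cell as possible — excess background dilutes the
        correlation signal.
    n_background : int
        Number of leading frames averaged into the background image and
        searched for the reference frame; must exceed the number of frames
        per rotation cycle.
    struct_radius : int
        Radius (px) of the flat disk structuring element used to clean the
        binarized difference image.
    lbound : float or "auto"
        Correlation threshold above which local maxima of the trace count as
        once-per-revolution peaks.  The measurement protocol adjusts this
        threshold slightly per video; ``"auto"`` applies
        :func:`cellspin.speed.choose_lbound`, which selects the threshold
        yielding the most regular once-per-cycle peak train.

    Examples
    --------
    >>> model = SelfRotationModel(seq, roi=(64, 64, 16, 16))   # doctest: +SKIP
    >>> res = model.fit()                                      # doctest: +SKIP
    >>> res.mean_speed_rpm                                     # doctest: +SKIP
    """

    def __init__(
        self,
        frames: FrameSequence,
        roi,
        *,
        n_background: int = 40,
        struct_radius: int = 3,
        lbound: float = 0.5,
    ) -> None:
        if not isinstance(frames, FrameSequence):
            raise TypeError("frames must be a FrameSequence (see load_frames)")
        if not isinstance(roi, RegionRect):
            u, v, w, h = roi
            roi = RegionRect(int(u), int(v), int(w), int(h))
        if not roi.fits_in((frames.height, frames.width)):
            raise ValueError(
                f"roi {roi} does not fit inside a "
                f"{frames.height}x{frames.width} frame"
            )
        if not 2 <= n_background <= len(frames):
            raise ValueError(
                f"n_background must be in [2, {len(frames)}] "
                f"(video has {len(frames)} frames), got {n_background}"
            )
        if n_background < 3:
            raise ValueError("n_background must be >= 3 for reference selection")
        if lbound != "auto" and not 0 <= lbound < 1:
            raise ValueError(f"lbound must be in [0, 1) or 'auto', got {lbound}")
        self.frames = frames
        self.roi = roi
        self.n_background = int(n_background)
        self.struct_radius = int(struct_radius)
        self.lbound = lbound if lbound == "auto" else float(lbound)

    @classmethod
    def from_path(cls, path, f_fps: float, roi, **kwargs) -> "SelfRotationModel":
        """Build the model straight from a video file or frame directory."""
        return cls(load_frames(path, f_fps), roi, **kwargs)

    def fit(self) -> "SelfRotationResults":
        """Run the full pipeline and return the fitted results."""
        logger.info("tracking cell through %d frames", len(self.frames))
        track_state = track(
            self.frames, self.roi, self.n_background, self.struct_radius
        )
        ref = select_reference(self.frames, track_state, self.roi, self.n_background)
        logger.info("reference frame: %d", ref.reference_index)
        trace = correlation_trace(self.frames, track_state, ref)
        lbound = self.lbound
        if lbound == "auto":
            lbound = choose_lbound(trace)
            logger.info("auto-selected lbound=%.3f", lbound)
        peaks = find_peaks(trace, lbound)
        logger.info("found %d peaks above lbound=%.3f", len(peaks), lbound)
        v = trace.values
        vertices = [
            parabola_vertex(v[p - 2], v[p - 1], v[p], p) for p in peaks
        ]
        profile = cycle_speeds(
            vertices,
            self.frames.f_fps,
            peak_indices=peaks,
            traj=trajectory(trace, peaks),
            lbound=lbound,
        )
        return SelfRotationResults(self, profile, trace, track_state, ref)


@dataclass
class SelfRotationResults:
    """Fitted self-rotation measurement: estimates, dispersion, diagnostics."""

    model: SelfRotationModel
    profile: SpeedProfile
    trace: CorrelationTrace
    track_state: TrackState
    reference: RefSelection

    # -- primary estimates -------------------------------------------------
    @property
    def mean_speed_rpm(self) -> float | None:
        """Arithmetic mean of the per-cycle speeds (None if < 1 cycle)."""
        return self.profile.mean_rpm

    @property
    def cycle_speeds_rpm(self) -> tuple[float, ...]:
        return self.profile.speeds_rpm

    @property
    def n_cycles(self) -> int:
        return self.profile.n_cycles

    @property
    def speed_std_rpm(self) -> float:
        """Sample standard deviation of the per-cycle speeds (nan if < 2)."""
        s = self.profile.speeds_rpm
        return float(np.std(s, ddof=1)) if len(s) >= 2 else float("nan")

    @property
    def trajectory_points(self) -> tuple[tuple[int, int], ...]:
        return self.profile.trajectory

    # -- diagnostics -------------------------------------------------------
    @property
    def interval_std_integer(self) -> float:
        """Sample std of cycle lengths measured from integer peak frames."""
        d = np.diff(self.profile.peak_indices)
        return float(np.std(d, ddof=1)) if len(d) >= 2 else float("nan")

    @property
    def interval_std_parabola(self) -> float:
        """Sample std of cycle lengths measured from parabola vertices."""
        d = np.diff(self.profile.vertices)
        return float(np.std(d, ddof=1)) if len(d) >= 2 else float("nan")

    def summary(self) -> str:
        """Plain-text summary table of the fitted measurement."""
        m = self.model
        lines = [
            "Self-rotation speed measurement",
            "=" * 46,
            f"{'frames':<28}{len(m.frames):>18}",
            f"{'frame rate (fps)':<28}{m.frames.f_fps:>18.3f}",
            f"{'reference frame':<28}{self.trace.reference_index:>18}",
            f"{'peaks found':<28}{len(self.profile.peak_indices):>18}",
            f"{'complete cycles':<28}{self.n_cycles:>18}",
        ]
        if self.profile.complete:
            lines += [
                f"{'mean speed (rpm)':<28}{self.mean_speed_rpm:>18.2f}",
                f"{'cycle speed std (rpm)':<28}{self.speed_std_rpm:>18.2f}",
                f"{'speed range (rpm)':<28}"
                f"{min(self.cycle_speeds_rpm):>8.1f} -{max(self.cycle_speeds_rpm):>8.1f}",
                f"{'interval std, integer (fr)':<28}{self.interval_std_integer:>18.2f}",
                f"{'interval std, parabola (fr)':<28}{self.interval_std_parabola:>18.2f}",
            ]
        else:
            lines.append(f"{'mean speed (rpm)':<28}{'no complete cycle':>18}")
        lines += [
            f"{'lbound':<28}{self.profile.lbound:>18.2f}",
            f"{'n_background':<28}{m.n_background:>18}",
            f"{'struct radius (px)':<28}{m.struct_radius:>18}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write ``results.csv`` and ``summary.json`` into ``out_dir``."""
        params = {
            "f_fps": self.model.frames.f_fps,
            "roi": [self.model.roi.u, self.model.roi.v,
                    self.model.roi.half_width, self.model.roi.half_height],
            "n_background": self.model.n_background,
            "struct_radius": self.model.struct_radius,
            "lbound": self.profile.lbound,
        }
        _io.write_results(self.profile, self.trace, out_dir, parameters=params)

    # -- plotting ----------------------------------------------------------
    def plot_trace(self, ax=None):
        """Correlation trace with peak markers and parabola vertices."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, len(self.trace) + 1)
        ax.plot(x, self.trace.values, "-", color="0.4", lw=1)
        p = list(self.profile.peak_indices)
        if p:
            ax.plot(p, self.trace.values[np.array(p) - 1], "b+", ms=10,
                    label="peak frames")
            ax.plot(self.profile.vertices,
                    self.trace.values[np.array(p) - 1], "ro", mfc="none",
                    label="parabola vertices")
            ax.legend(loc="lower right", fontsize=8)
        ax.axhline(self.model.lbound, color="r", ls=":", lw=0.8)
        ax.set_xlabel("frame")
        ax.set_ylabel("max correlation with reference")
        ax.set_ylim(-1.05, 1.05)
        return ax

    def plot_trajectory(self, ax=None):
        """Motion trajectory (matched ROI centers at the peak frames)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = np.asarray(self.profile.trajectory, dtype=float)
        if len(pts):
            ax.plot(pts[:, 1], pts[:, 0], "o-", ms=4)
        ax.set_xlabel("v (column, px)")
        ax.set_ylabel("u (row, px)")
        ax.invert_yaxis()
        ax.set_aspect("equal")
        return ax
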