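"""Normalized correlation matching and automatic reference-frame selection.

The similarity between two equally-sized patches is the normalized
correlation coefficient

    R = sum[(a - mean(a)) (b - mean(b))] /
        sqrt(sum[(a - mean(a))^2] * sum[(b - mean(b))^2])

which lies in [-1, 1] and is invariant to adding a constant to, or scaling
by a positive factor, either patch.  A patch with zero variance carries no
rotational information, so any zero-variance operand defines R = 0 (this
also keeps blank regions from ever outscoring textured matches).

The reference frame is the frame whose cell appearance differs most from
both temporal neighbors: chain the region of interest forward through the
first ``N`` frames, collect the adjacent-frame maximum correlations
``C_{i,i-1}``, sort the forward and backward sub-sequences ascending, and
pick the frame with the smallest sum of ordinal ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import FrameSequence
from .tracking import RegionRect, TrackState

__all__ = [
    "MatchError",
    "RefSelection",
    "patch_mean",
    "ncc",
    "best_match",
    "reference_from_correlations",
    "select_reference",
]


class MatchError(RuntimeError):
    """Raised when a search window admits no valid candidate centers."""


def _extract(frame: np.ndarray, center, half_width: int, half_height: int) -> np.ndarray:
    u, v = center
    rect = RegionRect(int(u), int(v), half_width, half_height)
    if not rect.fits_in(frame.shape):
        raise IndexError(
            f"rectangle at ({u}, {v}) with half extents "
            f"({half_width}, {half_height}) exceeds frame {frame.shape}"
        )
    return frame[
        u - half_height : u + half_height + 1, v - half_width : v + half_width + 1
    ]


def patch_mean(frame: np.ndarray, center, half_width: int, half_height: int) -> float:
    """Mean gray value of the rectangle around ``center`` (bounds-checked)."""
    return float(_extract(np.asarray(frame, float), center, half_width, half_height).mean())


def ncc(
    frame_i: np.ndarray,
    center_p,
    frame_j: np.ndarray,
    center_j,
    half_width: int,
    half_height: int,
) -> float:
    """Normalized correlation coefficient of two equally-sized rectangles.

    Returns a value in [-1, 1]; 0 if either rectangle has zero variance.
    """
    a = _extract(np.asarray(frame_i, float), center_p, half_width, half_height)
    b = _extract(np.asarray(frame_j, float), center_j, half_width, half_height)
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom2 = (a0**2).sum() * (b0**2).sum()
    if denom2 == 0.0:
        return 0.0
    return float(np.clip((a0 * b0).sum() / np.sqrt(denom2), -1.0, 1.0))


def best_match(
    frame: np.ndarray,
    search_window: RegionRect,
    template_frame: np.ndarray,
    template_center,
    half_width: int,
    half_height: int,
) -> tuple[tuple[int, int], float]:
    """Maximize the correlation over all candidate centers in a rectangle.

    Every center inside ``search_window`` whose template-sized rectangle
    fits inside ``frame`` is evaluated; the first maximizer in raster-scan
    order (rows, then columns) is returned together with its coefficient.
    In the pipeline the candidate rectangle is the tracked *moving region*
    of the cell; the template placed at any of its centers stays inside the
    per-frame search window (the moving region dilated by the template half
    extents).

    Raises
    ------
    MatchError
        If the window, clipped to centers where the template fits, is empty.
    """
    frame = np.asarray(frame, dtype=float)
    template = _extract(
        np.asarray(template_frame, dtype=float), template_center, half_width, half_height
    )
    nrows, ncols = frame.shape
    u_lo = max(search_window.u - search_window.half_height, half_height)
    u_hi = min(search_window.u + search_window.half_height, nrows - 1 - half_height)
    v_lo = max(search_window.v - search_window.half_width, half_width)
    v_hi = min(search_window.v + search_window.half_width, ncols - 1 - half_width)
    if u_lo > u_hi or v_lo > v_hi:
        raise MatchError("search window admits no valid template placement")

    region = frame[
        u_lo - half_height : u_hi + half_height + 1,
        v_lo - half_width : v_hi + half_width + 1,
    ]
    # FFT correlation with the zero-mean template gives the numerator of the
    # coefficient at every placement; integral images give the patch sums
    # needed for the per-patch variance in the denominator.
    t0 = template - template.mean()
    t_ss = (t0**2).sum()
    n_px = template.size
    num = fftconvolve(region, t0[::-1, ::-1], mode="valid")
    ones = np.ones(template.shape)
    p_sum = fftconvolve(region, ones, mode="valid")
    p_sum2 = fftconvolve(region**2, ones, mode="valid")
    p_ss = np.maximum(p_sum2 - p_sum**2 / n_px, 0.0)
    denom2 = p_ss * t_ss
    scores = np.zeros_like(num)
    ok = denom2 > 1e-9
    scores[ok] = np.clip(num[ok] / np.sqrt(denom2[ok]), -1.0, 1.0)
    nu, nv = scores.shape
    # FFT round-off could scramble exact ties; re-evaluate the near-maximal
    # placements exactly and keep the first maximizer in raster-scan order.
    best = scores.max()
    cand = np.argwhere(scores >= best - 1e-6)
    exact_best, exact_pos = -2.0, None
    for du, dv in cand[np.lexsort((cand[:, 1], cand[:, 0]))]:
        c = ncc(
            frame, (u_lo + du, v_lo + dv), template_frame, template_center,
            half_width, half_height,
        )
        if c > exact_best + 1e-15:
            exact_best, exact_pos = c, (u_lo + int(du), v_lo + int(dv))
    return exact_pos, float(exact_best)


def _ordinal_ranks(values: np.ndarray) -> np.ndarray:
    """Position of each element in the ascending stable sort (ties kept in
    original order, each getting a distinct ordinal)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(len(values))
    return ranks


def reference_from_correlations(adjacent: np.ndarray) -> int:
    """Rank-sum reference choice from the adjacent-correlation sequence.

    ``adjacent[k]`` is ``C_{k+2, k+1}``, i.e. the sequence
    ``[C_21, C_32, ..., C_{N,N-1}]`` for an ``N``-frame prefix.  The forward
    sub-sequence ``[C_21 .. C_{N-1,N-2}]`` and backward sub-sequence
    ``[C_32 .. C_{N,N-1}]`` are sorted ascending; the returned frame index
    ``T`` (1-based, in ``[2, N-1]``) minimizes
    ``rank_FS(C_{T,T-1}) + rank_BS(C_{T+1,T})``, smallest index on ties.
    """
    adjacent = np.asarray(adjacent, dtype=float)
    if len(adjacent) < 2:
        raise ValueError("need correlations for at least 3 frames")
    rank_fs = _ordinal_ranks(adjacent[:-1])
    rank_bs = _ordinal_ranks(adjacent[1:])
    return 2 + int(np.argmin(rank_fs + rank_bs))


@dataclass(frozen=True)
class RefSelection:
    """Outcome of reference-frame selection over the first ``N`` frames.

    ``roi_centers[i-1]`` is the chained region-of-interest center
    ``(u_Ri, v_Ri)`` in frame ``i``; ``adjacent_correlations[k]`` is
    ``C_{k+2,k+1}``.  ``reference_index`` is 1-based and lies in
    ``[2, N-1]``.
    """

    reference_index: int
    reference_center: tuple[int, int]
    adjacent_correlations: np.ndarray
    roi_centers: list[tuple[int, int]]


def select_reference(
    seq: FrameSequence, track_state: TrackState, init_rect: RegionRect, n: int
) -> RefSelection:
    """Chain the ROI through frames ``1..n`` and pick the reference frame.

    The ROI in frame 1 is ``init_rect``; in frame ``i`` it is the best match
    of frame ``i-1``'s ROI patch inside frame ``i``'s search window.  The
    collected adjacent correlations feed :func:`reference_from_correlations`.
    """
    if n < 3:
        raise ValueError(f"reference selection needs n >= 3, got {n}")
    if n > len(seq):
        raise ValueError(f"n={n} exceeds video length {len(seq)}")
    w, h = init_rect.half_width, init_rect.half_height
    roi_centers: list[tuple[int, int]] = [init_rect.center]
    correlations: list[float] = []
    for i in range(2, n + 1):
        center, c = best_match(
            seq.frame(i),
            track_state.moving_region(i),
            seq.frame(i - 1),
            roi_centers[-1],
            w,
            h,
        )
        roi_centers.append(center)
        correlations.append(c)
    adjacent = np.asarray(correlations)
    t = reference_from_correlations(adjacent)
    return RefSelection(
        reference_index=t,
        reference_center=roi_centers[t - 1],
        adjacent_correlations=adjacent,
        roi_centers=roi_centers,
    )
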