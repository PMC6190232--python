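"""Synthetic microscopy videos of self-rotating cells with ground truth.

Renders one or more textured, roughly circular cells (default radius 15 px,
emulating a ~12 um lymphoblast imaged at typical magnification) rotating in
the image plane at a prescribed rpm over a static textured background, at a
default 15 fps with additive Gaussian camera noise (default sigma = 3 gray
levels).  Each cell's intensity pattern is an asymmetric arrangement of
uniform angular sectors overlaid with speckle (see :class:`CellSpec`), so
that distinct rotation angles produce distinct images — the regime the
matching algorithm requires (a rotationally symmetric cell has no
appearance periodicity to measure).

Rendering is fully deterministic given the scene seed, and an integer-frame
rotation period reproduces bit-identical frames in the noise-free case
(angles are accumulated modulo 360 before any trigonometry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import FrameSequence

__all__ = ["CellSpec", "SceneSpec", "render", "single_cell_scene", "write_scene"]


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell: circular, textured, rotating, optionally drifting.

    ``center`` is the (u, v) position in frame 1; ``velocity`` the per-frame
    (du, dv) drift in pixels.  ``rpm`` may be a constant or a per-frame
    schedule of length ``n_frames``.

    The intensity pattern is a two-zone "dartboard" of uniform-intensity
    angular sectors (an outer annulus of four wide sectors and an inner disk
    of eight narrow ones, with independently placed boundaries), modulated
    and overlaid by fine speckle.  The design reproduces the appearance
    properties the matching algorithm relies on in real cells: the image
    differs at every rotation angle, the correlation-vs-angle curve has a
    single wide peak per revolution, and the intensity deviates strongly
    from the background everywhere inside the cell, so the difference image
    stays one solid blob at every angle.
    """

    center: tuple[float, float]
    radius: float = 15.0
    rpm: float | tuple[float, ...] = 54.76
    velocity: tuple[float, float] = (0.0, 0.0)
    texture_seed: int = 0
    contrast: float = 45.0
    granule_mod: float = 0.2
    granule_add: float = 8.0


@dataclass(frozen=True)
class SceneSpec:
    """Full scene description; every random choice derives from the seeds."""

    shape: tuple[int, int] = (128, 128)
    f_fps: float = 15.0
    n_frames: int = 158
    cells: tuple[CellSpec, ...] = ()
    background_level: float = 120.0
    background_seed: int = 1
    background_contrast: float = 6.0
    noise_sigma: float = 3.0
    seed: int = 0


def _angles_deg(cell: CellSpec, n_frames: int, f_fps: float) -> np.ndarray:
    """Cumulative rotation angle per frame, reduced modulo 360."""
    if np.isscalar(cell.rpm):
        inc = 360.0 * float(cell.rpm) / (60.0 * f_fps)
        return (inc * np.arange(n_frames)) % 360.0
    rpms = np.asarray(cell.rpm, dtype=float)
    if len(rpms) != n_frames:
        raise ValueError("per-frame rpm schedule must have n_frames entries")
    incs = 360.0 * rpms / (60.0 * f_fps)
    angles = np.concatenate([[0.0], np.cumsum(incs[:-1])])
    return angles % 360.0


def _sector_wheel(rng: np.random.Generator, levels: np.ndarray):
    """Angular sector edges (irregular widths) and their intensity levels."""
    n = len(levels)
    w = rng.uniform(0.85, 1.15, n)
    w = w / w.sum() * 2.0 * np.pi
    edges = np.concatenate([[0.0], np.cumsum(w)]) + rng.uniform(0.0, 2.0 * np.pi)
    return edges, levels


def _paint_sectors(ang: np.ndarray, edges: np.ndarray, levels: np.ndarray):
    out = np.zeros_like(ang)
    a2 = ang % (2.0 * np.pi)
    for k in range(len(levels)):
        lo, hi = edges[k] % (2.0 * np.pi), edges[k + 1] % (2.0 * np.pi)
        m = (a2 >= lo) & (a2 < hi) if lo < hi else (a2 >= lo) | (a2 < hi)
        out[m] = levels[k]
    return out


def _boundary_ridges(
    ang: np.ndarray, rr: np.ndarray, edges: np.ndarray, half_width_px: float
) -> np.ndarray:
    """Mask of thin radial lines along the sector boundaries.

    A bright membrane-like ridge drawn on these lines keeps the cell's
    intensity away from the background level where a positive and a
    negative sector meet, so the thresholded difference image cannot split
    along a boundary.
    """
    mask = np.zeros_like(ang, dtype=bool)
    for e in edges[:-1]:
        d = np.abs((ang - e + np.pi) % (2.0 * np.pi) - np.pi)
        mask |= d * np.maximum(rr, 1.0) < half_width_px
    return mask


#: Sector level patterns, as multiples of ``contrast``.  Chosen so that the
#: circular autocorrelation of each wheel is non-positive at every whole-
#: sector shift (no rotation angle re-aligns the pattern with itself).
_OUTER_LEVELS = np.array([1.0, 0.85, -0.85, -1.0])
_INNER_LEVELS = np.array([1.0, -1.0, 0.85, -0.85, 0.9, -0.9, 0.95, -0.95])


def _texture(cell: CellSpec) -> np.ndarray:
    """Cell-local intensity pattern: two-zone sector dartboard + speckle."""
    r = cell.radius
    half = int(np.ceil(r)) + 3
    size = 2 * half + 1
    rng = np.random.default_rng(cell.texture_seed)
    uu, vv = np.mgrid[0:size, 0:size] - half
    rr = np.hypot(uu, vv)
    ang = np.arctan2(vv, uu)
    e_in, l_in = _sector_wheel(rng, _INNER_LEVELS * cell.contrast)
    e_out, l_out = _sector_wheel(rng, _OUTER_LEVELS * cell.contrast)
    tex = np.where(
        rr < 0.45 * r,
        _paint_sectors(ang, e_in, l_in),
        _paint_sectors(ang, e_out, l_out),
    )
    outer_ridge = _boundary_ridges(ang, rr, e_out, 1.3) & (rr >= 0.45 * r)
    inner_ridge = _boundary_ridges(ang, rr, e_in, 1.3) & (rr < 0.45 * r)
    tex[outer_ridge | inner_ridge] = 1.3 * cell.contrast
    tex = gaussian_filter(tex, 1.0)
    g = gaussian_filter(rng.normal(size=(size, size)), sigma=1.2)
    g = g / (g.std() or 1.0)
    return tex * (1.0 + cell.granule_mod * np.tanh(g)) + g * cell.granule_add


def _paths(spec: SceneSpec) -> list[np.ndarray]:
    steps = np.arange(spec.n_frames)[:, None]
    return [
        np.asarray(c.center, dtype=float) + steps * np.asarray(c.velocity, dtype=float)
        for c in spec.cells
    ]


def _validate(spec: SceneSpec, paths: list[np.ndarray]) -> None:
    h, w = spec.shape
    if spec.n_frames < 2:
        raise ValueError("a scene needs at least 2 frames")
    if not spec.cells:
        raise ValueError("a scene needs at least one cell")
    for cell, path in zip(spec.cells, paths):
        r = cell.radius
        if (
            (path[:, 0] - r < 1).any()
            or (path[:, 1] - r < 1).any()
            or (path[:, 0] + r > h - 2).any()
            or (path[:, 1] + r > w - 2).any()
        ):
            raise ValueError("cell leaves the frame along its path")


def render(spec: SceneSpec) -> tuple[FrameSequence, dict]:
    """Render the scene; returns the frame stack and a ground-truth manifest.

    The manifest records, per cell and per frame, the true center and the
    rotation angle, plus the rpm schedule — everything a test needs to score
    the pipeline's output against the construction.
    """
    paths = _paths(spec)
    _validate(spec, paths)
    h, w = spec.shape
    # fine-grained static texture: debris-like speckle, no broad ramps that
    # could mimic the shaded cell and attract the template matcher
    rng_bg = np.random.default_rng(spec.background_seed)
    speckle = gaussian_filter(rng_bg.normal(size=(h, w)), sigma=2.0)
    background = (
        spec.background_level
        + speckle / (speckle.std() or 1.0) * spec.background_contrast
    )
    textures = [_texture(c) for c in spec.cells]
    angle_table = [_angles_deg(c, spec.n_frames, spec.f_fps) for c in spec.cells]
    noise_rng = np.random.default_rng(spec.seed)

    frames = np.empty((spec.n_frames, h, w))
    for i in range(spec.n_frames):
        frame = background.copy()
        for cell, tex, angles, path in zip(spec.cells, textures, angle_table, paths):
            cu, cv = path[i]
            theta = np.deg2rad(angles[i])
            half = (tex.shape[0] - 1) // 2
            u0, u1 = int(np.floor(cu - cell.radius)), int(np.ceil(cu + cell.radius))
            v0, v1 = int(np.floor(cv - cell.radius)), int(np.ceil(cv + cell.radius))
            uu, vv = np.mgrid[u0 : u1 + 1, v0 : v1 + 1]
            du, dv = uu - cu, vv - cv
            inside = du**2 + dv**2 <= cell.radius**2
            c, s = np.cos(theta), np.sin(theta)
            lu = c * du + s * dv + half  # rotate offsets back into texture frame
            lv = -s * du + c * dv + half
            vals = map_coordinates(tex, [lu[inside], lv[inside]], order=1, mode="nearest")
            patch = frame[u0 : u1 + 1, v0 : v1 + 1]
            patch[inside] = spec.background_level + vals
        if spec.noise_sigma > 0:
            frame = frame + noise_rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[i] = np.clip(np.floor(frame + 0.5), 0.0, 255.0)  # 8-bit camera

    manifest = {
        "f_fps": spec.f_fps,
        "n_frames": spec.n_frames,
        "shape": list(spec.shape),
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "cells": [
            {
                "radius": c.radius,
                "rpm": list(np.atleast_1d(c.rpm).astype(float)),
                "centers": paths[k].tolist(),
                "angles_deg": angle_table[k].tolist(),
            }
            for k, c in enumerate(spec.cells)
        ],
    }
    return FrameSequence(frames, spec.f_fps), manifest


def single_cell_scene(
    rpm: float = 54.76,
    n_frames: int = 158,
    f_fps: float = 15.0,
    *,
    noise_sigma: float = 3.0,
    radius: float = 15.0,
    shape: tuple[int, int] = (128, 128),
    velocity: tuple[float, float] = (0.0, 0.0),
    center: tuple[float, float] | None = None,
    seed: int = 0,
) -> SceneSpec:
    """Convenience spec for the common one-cell study conditions."""
    if center is None:
        center = (shape[0] / 2.0, shape[1] / 2.0)
    cell = CellSpec(
        center=center,
        radius=radius,
        rpm=rpm,
        velocity=velocity,
        texture_seed=seed + 101,
    )
    return SceneSpec(
        shape=shape,
        f_fps=f_fps,
        n_frames=n_frames,
        cells=(cell,),
        background_seed=seed + 7,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def write_scene(spec: SceneSpec, out_dir) -> Path:
    """Render and write PNG frames plus ``manifest.json``; returns the dir."""
    import imageio.v3 as iio

    seq, manifest = render(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ndigits = len(str(len(seq)))
    for i in range(1, len(seq) + 1):
        iio.imwrite(
            out / f"frame_{i:0{ndigits}d}.png", seq.frame(i).astype(np.uint8)
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
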