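"""Background model, Otsu threshold, segmentation and tracking."""

import numpy as np
import pytest
from skimage import morphology

from cellspin import (
    FrameSequence,
    RegionRect,
    TrackingError,
    compute_background,
    otsu_threshold,
    render,
    segment_moving_regions,
    single_cell_scene,
    track,
)
from cellspin.synthetic import CellSpec, SceneSpec
from cellspin.tracking import ConnectedComponent


def brute_force_otsu(img):
    """Reference: exhaustive between-class variance over all 256 levels."""
    binned = np.clip(np.floor(np.asarray(img, float)), 0, 255).astype(int).ravel()
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo, hi = binned[binned <= t], binned[binned > t]
        if len(lo) == 0 or len(hi) == 0:
            var = 0.0
        else:
            w0, w1 = len(lo) / len(binned), len(hi) / len(binned)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_t, best_var = t, var
    if best_var == 0.0:
        return int(binned[0])
    return best_t


class TestBackground:
    def test_constant_frames(self):
        seq = FrameSequence(np.full((5, 8, 8), 7.0), 15.0)
        assert np.array_equal(compute_background(seq, 5), np.full((8, 8), 7.0))

    def test_two_frame_mean(self):
        seq = FrameSequence(np.stack([np.zeros((4, 4)), np.full((4, 4), 255.0)]), 15.0)
        assert np.array_equal(compute_background(seq, 2), np.full((4, 4), 127.5))

    def test_mean_residual_is_zero(self):
        rng = np.random.default_rng(3)
        seq = FrameSequence(rng.integers(0, 256, (6, 10, 10)).astype(float), 15.0)
        bg = compute_background(seq, 6)
        assert np.allclose((seq.frames[:6] - bg).sum(axis=0), 0.0, atol=1e-9)

    def test_static_pixels_recovered_exactly(self):
        # a moving cell never visits the far corner; there the 40-frame mean
        # must equal the static background exactly
        spec = single_cell_scene(rpm=60, n_frames=40, noise_sigma=0.0, seed=4,
                                 center=(40.0, 40.0))
        seq, _ = render(spec)
        bg = compute_background(seq, 40)
        assert np.array_equal(bg[100:, 100:], seq.frame(1)[100:, 100:])

    @pytest.mark.parametrize("n", [1, 7])
    def test_invalid_n(self, n):
        seq = FrameSequence(np.zeros((6, 4, 4)), 15.0)
        with pytest.raises(ValueError):
            compute_background(seq, n)


class TestOtsu:
    def test_constant_image_degenerate(self):
        img = np.full((10, 10), 40.0)
        level = otsu_threshold(img)
        assert level == 40
        assert not (img > level).any()  # strict-greater rule: empty mask

    def test_two_level_tie_break(self):
        img = np.array([[50.0] * 8, [200.0] * 8])
        assert otsu_threshold(img) == 50  # smallest maximizing threshold

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(24, 24))
        assert otsu_threshold(img) == brute_force_otsu(img)


class TestConnectedComponent:
    def test_three_pixel_row(self):
        c = ConnectedComponent(pixels=np.array([[0, 0], [0, 1], [0, 2]]), label=1)
        assert c.count == 3
        assert c.centroid == (0, 1)
        assert c.radius == 1

    def test_rounding_is_half_up(self):
        c = ConnectedComponent(pixels=np.array([[0, 0], [1, 0], [2, 0], [3, 0]]),
                               label=1)
        assert c.centroid == (2, 0)  # mean 1.5 rounds up


class TestSegmentation:
    def test_frame_equals_background(self):
        bg = np.full((32, 32), 100.0)
        assert segment_moving_regions(bg.copy(), bg, 3) == []

    def test_two_rendered_disks(self):
        bg = np.full((96, 128), 100.0)
        frame = bg.copy()
        uu, vv = np.mgrid[0:96, 0:128]
        truth = [(40, 30), (40, 90)]
        for cu, cv in truth:
            frame[(uu - cu) ** 2 + (vv - cv) ** 2 <= 8**2] = 220.0
        comps = segment_moving_regions(frame, bg, 3)
        assert len(comps) == 2
        for comp, (cu, cv) in zip(sorted(comps, key=lambda c: c.centroid[1]), truth):
            assert abs(comp.centroid[0] - cu) <= 1
            assert abs(comp.centroid[1] - cv) <= 1
            assert abs(comp.radius - 8) <= 2

    def test_opening_closing_idempotent(self, rng):
        mask = rng.random((64, 64)) > 0.6
        selem = morphology.disk(3)
        once = morphology.closing(morphology.opening(mask, selem), selem)
        twice = morphology.closing(morphology.opening(once, selem), selem)
        assert np.array_equal(once, twice)


class TestTrack:
    def test_stationary_cell_region_covers_cell(self):
        # for a stationary cell the difference image holds angle-dependent
        # texture lobes, so the component centroid orbits the true center a
        # few px; the moving region must nevertheless keep covering the cell
        seq, man = render(single_cell_scene(rpm=54.76, n_frames=60, seed=2))
        state = track(seq, RegionRect(64, 64, 16, 16), 40, 3)
        centers = np.array(state.centers, float)
        true = np.array(man["cells"][0]["centers"])
        err = np.hypot(*(centers - true).T)
        assert err.max() <= 8.0   # always well inside the 15 px cell radius
        for reg, (cu, cv) in zip(state.moving_regions, true):
            assert abs(reg.u - cu) <= reg.half_height
            assert abs(reg.v - cv) <= reg.half_width

    def test_translating_cell_follows_path(self):
        cell = CellSpec(center=(40.0, 30.0), radius=15, rpm=60.0,
                        velocity=(0.0, 1.0), texture_seed=205)
        spec = SceneSpec(shape=(96, 200), f_fps=15.0, n_frames=100,
                         cells=(cell,), background_seed=11, noise_sigma=3.0, seed=4)
        seq, man = render(spec)
        state = track(seq, RegionRect(40, 30, 16, 16), 40, 3)
        err = np.hypot(*(np.array(state.centers, float)
                         - np.array(man["cells"][0]["centers"])).T)
        # the cell's own temporal smear biases the difference centroid, so
        # individual frames can be several px off; the track as a whole hugs
        # the path
        assert np.median(err) <= 2.0
        assert err.max() <= 12.0

    def test_two_cells_selects_marked_one(self):
        a = CellSpec(center=(40.0, 40.0), radius=15, rpm=60.0, texture_seed=7)
        b = CellSpec(center=(90.0, 100.0), radius=15, rpm=40.0, texture_seed=8)
        spec = SceneSpec(shape=(128, 144), f_fps=15.0, n_frames=60,
                         cells=(a, b), background_seed=5, noise_sigma=3.0, seed=5)
        seq, man = render(spec)
        state = track(seq, RegionRect(40, 40, 16, 16), 40, 3)
        centers = np.array(state.centers, float)
        d_a = np.hypot(*(centers - np.array(man["cells"][0]["centers"])).T)
        d_b = np.hypot(*(centers - np.array(man["cells"][1]["centers"])).T)
        assert (d_a < d_b).all()

    def test_search_window_geometry(self):
        seq, _ = render(single_cell_scene(rpm=54.76, n_frames=45, seed=2))
        w, h = 16, 12
        state = track(seq, RegionRect(64, 64, w, h), 40, 3)
        for r, win, reg in zip(state.radii, state.search_windows,
                               state.moving_regions):
            assert win.width * win.height == (2 * r + 2 * w + 1) * (2 * r + 2 * h + 1)
            # the search window is the moving region dilated by the template
            assert win.half_width == reg.half_width + w or r == 0
            assert win.u == reg.u and win.v == reg.v

    def test_washed_out_frame_carries_forward(self):
        seq0, _ = render(single_cell_scene(rpm=54.76, n_frames=50, seed=2))
        frames = seq0.frames.copy()
        bg = compute_background(seq0, 40)
        frames[44] = bg  # one washed-out frame must not abort the run
        seq = FrameSequence(frames, seq0.f_fps)
        state = track(seq, RegionRect(64, 64, 16, 16), 40, 3)
        assert state.centers[44] == state.centers[43]
        assert state.radii[44] == state.radii[43]

    def test_empty_first_frame_is_fatal(self):
        seq = FrameSequence(np.full((10, 64, 64), 50.0), 15.0)
        with pytest.raises(TrackingError):
            track(seq, RegionRect(32, 32, 8, 8), 5, 3)

    def test_roi_outside_frame(self):
        seq = FrameSequence(np.zeros((5, 32, 32)), 15.0)
        with pytest.raises(ValueError):
            track(seq, RegionRect(2, 2, 8, 8), 5, 3)
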