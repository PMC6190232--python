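"""Normalized correlation, best-match search and reference-frame choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellspin import (
    MatchError,
    RegionRect,
    best_match,
    ncc,
    patch_mean,
    reference_from_correlations,
)


def literal_ncc(a, b):
    """Reference: the correlation coefficient as an explicit double sum."""
    ma = sum(sum(row) for row in a) / a.size
    mb = sum(sum(row) for row in b) / b.size
    num = den_a = den_b = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            num += (a[i, j] - ma) * (b[i, j] - mb)
            den_a += (a[i, j] - ma) ** 2
            den_b += (b[i, j] - mb) ** 2
    if den_a == 0.0 or den_b == 0.0:
        return 0.0
    return num / np.sqrt(den_a * den_b)


def brute_force_reference(adjacent):
    """Reference: evaluate the rank-sum rule for every eligible frame."""
    adjacent = list(adjacent)
    forward, backward = adjacent[:-1], adjacent[1:]
    fs = sorted(range(len(forward)), key=lambda k: (forward[k], k))
    bs = sorted(range(len(backward)), key=lambda k: (backward[k], k))
    rank_f = {orig: pos for pos, orig in enumerate(fs)}
    rank_b = {orig: pos for pos, orig in enumerate(bs)}
    best_i, best_sum = None, None
    for i in range(2, len(adjacent) + 1):  # frame i in [2, N-1]
        s = rank_f[i - 2] + rank_b[i - 2]
        if best_sum is None or s < best_sum:
            best_i, best_sum = i, s
    return best_i


class TestPatchMean:
    def test_constant(self):
        frame = np.full((9, 9), 13.0)
        assert patch_mean(frame, (4, 4), 2, 2) == 13.0

    def test_one_to_nine(self):
        frame = np.arange(1, 10, dtype=float).reshape(3, 3)
        assert patch_mean(frame, (1, 1), 1, 1) == 5.0

    def test_matches_direct_sum(self, rng):
        frame = rng.random((21, 21)) * 255
        got = patch_mean(frame, (10, 9), 4, 5)
        want = frame[10 - 5 : 10 + 6, 9 - 4 : 9 + 5].sum() / (9 * 11)
        assert got == pytest.approx(want, abs=1e-12)

    def test_out_of_bounds(self):
        with pytest.raises(IndexError):
            patch_mean(np.zeros((8, 8)), (1, 1), 3, 3)


class TestNcc:
    def test_identical_patches(self, rng):
        f = rng.random((11, 11)) * 255
        assert ncc(f, (5, 5), f, (5, 5), 3, 3) == pytest.approx(1.0)

    def test_affine_invariance_sign(self, rng):
        f = rng.random((11, 11)) * 100 + 50
        g = 2.0 * f + 11.0
        h = -0.5 * f + 200.0
        assert ncc(f, (5, 5), g, (5, 5), 4, 4) == pytest.approx(1.0)
        assert ncc(f, (5, 5), h, (5, 5), 4, 4) == pytest.approx(-1.0)

    def test_zero_variance_patch(self, rng):
        flat = np.full((9, 9), 120.0)
        textured = rng.random((9, 9)) * 255
        assert ncc(flat, (4, 4), textured, (4, 4), 2, 2) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        fa = rng.integers(0, 256, (15, 15)).astype(float)
        fb = rng.integers(0, 256, (15, 15)).astype(float)
        got = ncc(fa, (7, 7), fb, (7, 7), 5, 5)
        want = literal_ncc(fa[2:13, 2:13], fb[2:13, 2:13])
        assert got == pytest.approx(want, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), gain=st.floats(0.1, 5.0),
           offset=st.floats(-50.0, 50.0))
    def test_symmetry_and_affine_invariance(self, seed, gain, offset):
        rng = np.random.default_rng(seed)
        a = rng.random((9, 9)) * 255
        b = rng.random((9, 9)) * 255
        c_ab = ncc(a, (4, 4), b, (4, 4), 3, 3)
        c_ba = ncc(b, (4, 4), a, (4, 4), 3, 3)
        c_scaled = ncc(gain * a + offset, (4, 4), b, (4, 4), 3, 3)
        assert c_ab == pytest.approx(c_ba, abs=1e-10)
        assert c_scaled == pytest.approx(c_ab, abs=1e-7)


class TestBestMatch:
    def test_finds_pasted_template(self, rng):
        frame = rng.integers(0, 256, (64, 64)).astype(float)
        template_frame = rng.integers(0, 256, (31, 31)).astype(float)
        frame[20 - 5 : 20 + 6, 37 - 5 : 37 + 6] = template_frame[
            15 - 5 : 15 + 6, 15 - 5 : 15 + 6
        ]
        window = RegionRect(24, 32, 12, 12)
        (u, v), c = best_match(frame, window, template_frame, (15, 15), 5, 5)
        assert (u, v) == (20, 37)
        assert c == pytest.approx(1.0)

    def test_tie_goes_to_first_raster_position(self):
        frame = np.zeros((40, 40))
        patch = np.arange(25, dtype=float).reshape(5, 5)
        frame[10:15, 8:13] = patch   # copy 1 at center (12, 10)
        frame[20:25, 24:29] = patch  # copy 2 at center (22, 26)
        template_frame = np.zeros((9, 9))
        template_frame[2:7, 2:7] = patch
        window = RegionRect(17, 18, 14, 14)
        (u, v), c = best_match(frame, window, template_frame, (4, 4), 2, 2)
        assert (u, v) == (12, 10)
        assert c == pytest.approx(1.0)

    def test_constant_window_returns_first_candidate(self):
        frame = np.full((30, 30), 90.0)
        template_frame = np.full((9, 9), 90.0)
        window = RegionRect(15, 15, 4, 4)
        (u, v), c = best_match(frame, window, template_frame, (4, 4), 3, 3)
        assert c == 0.0
        assert (u, v) == (11, 11)  # first valid center in raster order

    def test_fully_clipped_window(self):
        frame = np.zeros((20, 20))
        window = RegionRect(1, 1, 1, 1)  # no center admits a 13x13 template
        with pytest.raises(MatchError):
            best_match(frame, window, frame, (10, 10), 6, 6)

    def test_self_match_is_perfect(self, rng):
        frame = rng.integers(0, 256, (48, 48)).astype(float)
        window = RegionRect(24, 24, 6, 6)
        (u, v), c = best_match(frame, window, frame, (24, 24), 8, 8)
        assert (u, v) == (24, 24)
        assert c == pytest.approx(1.0)


class TestReferenceSelection:
    def test_all_equal_correlations_pick_frame_two(self):
        assert reference_from_correlations([0.9] * 10) == 2

    def test_single_anomalous_frame(self):
        # frame k looks unlike both neighbors: C_{k,k-1} and C_{k+1,k} are
        # jointly minimal only at i = k
        c = [0.9, 0.91, 0.2, 0.25, 0.92, 0.9]  # C_21 .. C_76; anomaly at k=4
        assert reference_from_correlations(c) == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(-1, 1, size=rng.integers(3, 40))
        assert reference_from_correlations(c) == brute_force_reference(c)

    def test_too_short(self):
        with pytest.raises(ValueError):
            reference_from_correlations([0.5])
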