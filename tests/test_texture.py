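"""Run-length matrices, the 11 GLRLM statistics, and Tamura coarseness."""

import numpy as np
import pytest

from dermcadx.imaging import quantize_gray
from dermcadx.texture import (
    DIRECTIONS,
    GLRLM_STATISTICS,
    QUANTIZATION_LEVELS,
    glrlm_statistics,
    run_length_matrix,
    tamura_coarseness,
)

# ---------------------------------------------------------------- oracles


def brute_force_runs(img, direction):
    """Independent run scanner: walk each scan line pixel by pixel."""
    H, W = img.shape
    if direction == 0:
        lines = [[img[r, c] for c in range(W)] for r in range(H)]
    elif direction == 90:
        lines = [[img[r, c] for r in range(H)] for c in range(W)]
    elif direction == 45:
        # anti-diagonals r + c = k, traversed upward (descending r)
        lines = [
            [img[r, k - r] for r in range(H - 1, -1, -1) if 0 <= k - r < W]
            for k in range(H + W - 1)
        ]
    else:  # 135
        lines = [
            [img[r, c] for r in range(H) for c in range(W) if c - r == k]
            for k in range(-(H - 1), W)
        ]
    runs = []
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs.append((int(line[i]), j - i))
            i = j
    return runs


def brute_force_statistics(runs, n_pixels, levels):
    """Second, independent coding of the 11 statistics (explicit sums)."""
    N = len(runs)
    import math

    def s(f):
        return math.fsum(f(g, r) for g, r in runs)

    gl = {}
    rl = {}
    for g, r in runs:
        gl[g] = gl.get(g, 0) + 1
        rl[r] = rl.get(r, 0) + 1
    return {
        "sre": s(lambda g, r: 1 / r**2) / N,
        "lre": s(lambda g, r: r**2) / N,
        "gln": sum(v**2 for v in gl.values()) / N,
        "rln": sum(v**2 for v in rl.values()) / N,
        "rp": N / n_pixels,
        "lgre": s(lambda g, r: 1 / (g + 1) ** 2) / N,
        "hgre": s(lambda g, r: (g + 1) ** 2) / N,
        "srlge": s(lambda g, r: 1 / ((g + 1) ** 2 * r**2)) / N,
        "srhge": s(lambda g, r: (g + 1) ** 2 / r**2) / N,
        "lrlge": s(lambda g, r: r**2 / (g + 1) ** 2) / N,
        "lrhge": s(lambda g, r: (g + 1) ** 2 * r**2) / N,
    }


# ---------------------------------------------------------------- run-length matrix


class TestRunLengthMatrix:
    def test_hand_enumerated_4x4(self):
        img = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 2, 2], [3, 3, 3, 3]])
        m = run_length_matrix(img, 0)
        assert m.counts[0, 1] == 2  # two runs of value 0, length 2
        assert m.counts[1, 1] == 2
        assert m.counts[2, 3] == 1
        assert m.counts[3, 3] == 1
        assert m.counts.sum() == 6

    def test_constant_image_single_run_per_row(self):
        m = run_length_matrix(np.full((8, 8), 3), 0, levels=4)
        assert m.counts[3, 7] == 8 and m.counts.sum() == 8

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_conservation_on_random_images(self, direction, rng):
        for _ in range(50):
            img = rng.integers(0, 4, size=rng.integers(2, 12, size=2))
            m = run_length_matrix(img, direction)
            r = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts * r).sum() == img.size

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_brute_force_scanner(self, direction, rng):
        for _ in range(20):
            img = rng.integers(0, 4, size=(7, 9))
            m = run_length_matrix(img, direction, levels=4)
            expected = np.zeros_like(m.counts)
            for g, r in brute_force_runs(img, direction):
                expected[g, r - 1] += 1
            assert np.array_equal(m.counts, expected)


class TestGlrlmStatistics:
    def test_checkerboard_unit_runs(self):
        board = (np.add.outer(np.arange(8), np.arange(8)) % 2)
        m = run_length_matrix(board, 0, levels=2)
        stats = glrlm_statistics([m])
        assert stats["sre"] == pytest.approx(1.0)
        assert stats["lre"] == pytest.approx(1.0)
        assert stats["rp"] == pytest.approx(1.0)

    def test_constant_image_run_percentage(self):
        m = run_length_matrix(np.full((8, 8), 1), 0, levels=2)
        stats = glrlm_statistics([m])
        assert stats["rp"] == pytest.approx(8 / 64)  # one run per scan line

    def test_matches_independent_formula_coding(self, rng):
        for _ in range(200):
            img = rng.integers(0, 4, size=(8, 8))
            mats = [run_length_matrix(img, d, levels=4) for d in DIRECTIONS]
            stats = glrlm_statistics(mats)
            per_dir = [
                brute_force_statistics(brute_force_runs(img, d), img.size, 4)
                for d in DIRECTIONS
            ]
            for k in GLRLM_STATISTICS:
                expected = np.mean([d[k] for d in per_dir])
                assert stats[k] == pytest.approx(expected, abs=1e-9), k

    def test_transposition_invariance_of_direction_average(self, rng):
        img = rng.integers(0, 8, size=(10, 14))
        stats = glrlm_statistics([run_length_matrix(img, d, levels=8) for d in DIRECTIONS])
        stats_t = glrlm_statistics(
            [run_length_matrix(img.T.copy(), d, levels=8) for d in DIRECTIONS]
        )
        for k in GLRLM_STATISTICS:
            assert stats[k] == pytest.approx(stats_t[k], rel=1e-12)

    def test_inconsistent_matrices_rejected(self, rng):
        a = run_length_matrix(rng.integers(0, 4, (8, 8)), 0, levels=4)
        b = run_length_matrix(rng.integers(0, 8, (8, 8)), 90, levels=8)
        with pytest.raises(ValueError):
            glrlm_statistics([a, b])


def checkerboard(size, block):
    tiles = np.add.outer(np.arange(size) // block, np.arange(size) // block) % 2
    return (tiles * 255).astype(float)


def brute_force_coarseness(gray, kmax):
    """Independent direct implementation: per-pixel loops, explicit window sums."""
    H, W = gray.shape
    sizes = []
    for r in range(H):
        for c in range(W):
            best_e, best_s = 0.0, 2.0
            valid = True
            for k in range(1, kmax + 1):
                h = 2 ** (k - 1)
                # horizontal / vertical neighbor windows of size 2^k
                boxes = [
                    ((r - h, r + h), (c, c + 2 * h)),      # right
                    ((r - h, r + h), (c - 2 * h, c)),      # left
                    ((r, r + 2 * h), (c - h, c + h)),      # down
                    ((r - 2 * h, r), (c - h, c + h)),      # up
                ]
                if any(b[0][0] < 0 or b[0][1] > H or b[1][0] < 0 or b[1][1] > W
                       for b in boxes):
                    valid = False
                    break
                means = [gray[b[0][0]:b[0][1], b[1][0]:b[1][1]].mean() for b in boxes]
                e = max(abs(means[0] - means[1]), abs(means[2] - means[3]))
                if e > 1e-9 * 255 and e >= best_e - 1e-9 * 255:
                    best_e, best_s = max(best_e, e), 2.0 ** k
            if valid:
                sizes.append(best_s)
    return float(np.mean(sizes))


class TestTamuraCoarseness:
    def test_constant_image_ties_give_smallest_window(self):
        assert tamura_coarseness(np.full((80, 80), 55.0)) == pytest.approx(2.0)

    def test_matches_direct_loop_oracle(self, rng):
        blocks = checkerboard(40, 4)
        noise = rng.uniform(0, 255, size=(40, 40))
        for img in (blocks, noise):
            with pytest.warns(UserWarning, match="truncated"):
                value = tamura_coarseness(img)
            assert value == pytest.approx(brute_force_coarseness(img, kmax=4), abs=1e-9)

    def test_blocky_texture_coarser_than_fine(self):
        c4 = tamura_coarseness(checkerboard(128, 4))
        c1 = tamura_coarseness(checkerboard(128, 1))
        assert c4 > c1

    def test_monotone_in_block_size(self):
        values = [tamura_coarseness(checkerboard(128, b)) for b in (1, 2, 4, 8, 16)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] > values[1]  # strict between block 2 and 16

    def test_small_image_truncates_scale_range(self):
        with pytest.warns(UserWarning, match="truncated"):
            tamura_coarseness(np.arange(40.0 * 40).reshape(40, 40))

    def test_masked_mean_restricted_to_lesion(self):
        img = checkerboard(128, 8)
        lesion = np.zeros((128, 128), dtype=bool)
        lesion[40:80, 40:80] = True
        whole = tamura_coarseness(img)
        masked = tamura_coarseness(img, mask=lesion)
        assert masked > 0 and abs(masked - whole) < whole  # same texture, same scale
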