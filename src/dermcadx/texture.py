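"""Gray-level run-length matrix (GLRLM) and Tamura coarseness texture features.

The texture block of the feature vector has 46 entries:

* 44 GLRLM statistics — the 11 canonical run-length statistics (five
  Galloway: SRE, LRE, GLN, RLN, RP; two Chu: LGRE, HGRE; four
  Dasarathy-Holder joint statistics: SRLGE, SRHGE, LRLGE, LRHGE) computed on
  the rectangular sub-image grayscale after quantization to 16, 8, 4 and 2
  gray levels.  Each statistic is averaged over the four scan directions
  0, 45, 90 and 135 degrees.
* 2 Tamura coarseness values — one over the whole sub-image, one averaged
  over lesion pixels only (windows may straddle the lesion border).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import LesionMask, quantize_gray, to_grayscale

__all__ = [
    "RunLengthMatrix",
    "GLRLM_STATISTICS",
    "QUANTIZATION_LEVELS",
    "DIRECTIONS",
    "run_length_matrix",
    "glrlm_statistics",
    "tamura_coarseness",
    "extract_texture_features",
]

GLRLM_STATISTICS = (
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
    "srlge", "srhge", "lrlge", "lrhge",
)
QUANTIZATION_LEVELS = (16, 8, 4, 2)
DIRECTIONS = (0, 45, 90, 135)

_TAMURA_KMAX = 5


@dataclass(frozen=True)
class RunLengthMatrix:
    """Counts of maximal same-level pixel runs by (gray level, run length)."""

    counts: np.ndarray  # L x Rmax, counts[g, r-1] = number of runs of length r
    direction: int
    levels: int
    n_pixels: int

    def total_runs(self) -> int:
        return int(self.counts.sum())


def _scan_lines(img: np.ndarray, direction: int) -> list[np.ndarray]:
    """The 1-D scan lines of an image along one of the four GLRLM directions."""
    H, W = img.shape
    if direction == 0:
        return [img[r, :] for r in range(H)]
    if direction == 90:
        return [img[:, c] for c in range(W)]
    if direction == 45:
        # anti-diagonals, lower-left to upper-right
        flipped = np.flipud(img)
        return [np.diagonal(flipped, offset=k) for k in range(-(H - 1), W)]
    if direction == 135:
        return [np.diagonal(img, offset=k) for k in range(-(H - 1), W)]
    raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction}")


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """(value, run length) pairs of the maximal runs in a 1-D sequence."""
    if line.size == 0:
        return []
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [line.size]])
    return [(int(line[s]), int(e - s)) for s, e in zip(starts, ends)]


def run_length_matrix(quantized: np.ndarray, direction: int, levels: int | None = None) -> RunLengthMatrix:
    """Build the run-length matrix of a quantized image for one direction."""
    q = np.asarray(quantized)
    if q.size == 0:
        raise ValueError("empty image")
    if levels is None:
        levels = int(q.max()) + 1
    rmax = max(q.shape)
    counts = np.zeros((levels, rmax), dtype=np.int64)
    for line in _scan_lines(q, direction):
        for value, length in _run_lengths(np.asarray(line)):
            counts[value, length - 1] += 1
    return RunLengthMatrix(counts=counts, direction=direction,
                           levels=levels, n_pixels=q.size)


def _statistics_one(m: RunLengthMatrix) -> dict[str, float]:
    counts = m.counts.astype(np.float64)
    L, R = counts.shape
    g = np.arange(1, L + 1, dtype=np.float64)[:, None]   # 1-based gray level
    r = np.arange(1, R + 1, dtype=np.float64)[None, :]
    n_runs = counts.sum()
    if n_runs == 0:
        raise ValueError("run-length matrix is empty")
    p_g = counts.sum(axis=1)
    p_r = counts.sum(axis=0)
    return {
        "sre": float((counts / r**2).sum() / n_runs),
        "lre": float((counts * r**2).sum() / n_runs),
        "gln": float((p_g**2).sum() / n_runs),
        "rln": float((p_r**2).sum() / n_runs),
        "rp": float(n_runs / m.n_pixels),
        "lgre": float((counts / g**2).sum() / n_runs),
        "hgre": float((counts * g**2).sum() / n_runs),
        "srlge": float((counts / (g**2 * r**2)).sum() / n_runs),
        "srhge": float((counts * g**2 / r**2).sum() / n_runs),
        "lrlge": float((counts * r**2 / g**2).sum() / n_runs),
        "lrhge": float((counts * g**2 * r**2).sum() / n_runs),
    }


def glrlm_statistics(matrices: list[RunLengthMatrix]) -> dict[str, float]:
    """The 11 run-length statistics averaged over the supplied directions."""
    if not matrices:
        raise ValueError("at least one run-length matrix required")
    shapes = {(m.levels, m.n_pixels) for m in matrices}
    if len(shapes) > 1:
        raise ValueError("matrices come from differently sized/quantized images")
    per_dir = [_statistics_one(m) for m in matrices]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_STATISTICS}


def _window_means(gray: np.ndarray, k: int) -> np.ndarray:
    """Mean over the 2^k x 2^k window whose top-left corner offset is
    (-2^(k-1), -2^(k-1)); entries whose window leaves the image are NaN."""
    H, W = gray.shape
    size = 2 ** k
    half = size // 2
    integral = np.zeros((H + 1, W + 1))
    integral[1:, 1:] = gray.cumsum(0).cumsum(1)
    out = np.full((H, W), np.nan)
    # window rows [r-half, r+half-1], cols [c-half, c+half-1]
    r0 = np.arange(H) - half
    valid_r = (r0 >= 0) & (r0 + size <= H)
    c0 = np.arange(W) - half
    valid_c = (c0 >= 0) & (c0 + size <= W)
    rr = r0[valid_r][:, None]
    cc = c0[valid_c][None, :]
    sums = (integral[rr + size, cc + size] - integral[rr, cc + size]
            - integral[rr + size, cc] + integral[rr, cc])
    out[np.ix_(valid_r, valid_c)] = sums / (size * size)
    return out


def tamura_coarseness(gray: np.ndarray, mask: LesionMask | np.ndarray | None = None,
                      kmax: int = _TAMURA_KMAX) -> float:
    """Tamura's coarseness: mean best window size 2^k per pixel.

    For each scale k (window 2^k) the difference between the mean gray value
    of opposite non-overlapping windows is taken horizontally and vertically;
    each pixel's best size is the window maximizing that contrast (ties go to
    the smallest window).  The result is the mean best size over all pixels
    whose largest windows lie fully inside the image, optionally restricted
    to lesion pixels.
    """
    gray = np.asarray(gray, dtype=np.float64)
    H, W = gray.shape
    # truncate the scale range when the shifted largest windows cannot fit
    while kmax > 1 and 2 ** (kmax + 1) >= min(H, W):
        kmax -= 1
        if kmax == _TAMURA_KMAX - 1:
            warnings.warn(
                f"image {H}x{W} too small for 2^{_TAMURA_KMAX} Tamura windows; "
                f"scale range truncated", stacklevel=2)
    tol = 1e-9 * 255  # contrast tie tolerance
    best_e = np.zeros((H, W))
    best_s = np.full((H, W), 2.0)  # zero-contrast pixels keep the smallest window
    valid = np.ones((H, W), dtype=bool)
    for k in range(1, kmax + 1):
        A = _window_means(gray, k)
        half = 2 ** (k - 1)
        eh = np.abs(np.roll(A, -half, axis=1) - np.roll(A, half, axis=1))
        ev = np.abs(np.roll(A, -half, axis=0) - np.roll(A, half, axis=0))
        # roll wraps around; mark wrapped/NaN entries invalid explicitly
        eh[:, :half] = np.nan
        eh[:, W - half:] = np.nan
        ev[:half, :] = np.nan
        ev[H - half:, :] = np.nan
        e = np.maximum(eh, ev)  # NaN propagates: both directions must fit
        valid &= np.isfinite(e)
        # sharp edges saturate every window size at once, so positive ties go
        # to the largest window; only zero contrast falls back to the smallest
        better = np.isfinite(e) & (e >= best_e - tol) & (e > tol)
        best_e[better] = np.maximum(best_e[better], e[better])
        best_s[better] = 2.0 ** k
    if mask is not None:
        m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
        valid &= m
    if not valid.any():
        raise ValueError("no pixels with all Tamura windows inside the image")
    return float(best_s[valid].mean())


def extract_texture_features(sub_image, mask: LesionMask) -> dict[str, float]:
    """All 46 texture features of a region pair's sub-image."""
    gray = to_grayscale(sub_image)
    out: dict[str, float] = {}
    for levels in QUANTIZATION_LEVELS:
        q = quantize_gray(gray, levels)
        mats = [run_length_matrix(q, d, levels=levels) for d in DIRECTIONS]
        stats = glrlm_statistics(mats)
        for name in GLRLM_STATISTICS:
            out[f"texture.glrlm.L{levels}.{name}"] = stats[name]
    out["texture.tamura.sub"] = tamura_coarseness(gray)
    out["texture.tamura.lesion"] = tamura_coarseness(gray, mask=mask)
    return out
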