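"""Single-channel color statistics and multidimensional (correlation / PCA) color features.

The color block of the feature vector has 42 entries, each computed twice:
once over the whole sub-image ("sub" region, lesion plus equal-area skin)
and once over the lesion pixels alone ("lesion" region):

* 24 conventional statistics — variance, Shannon entropy (bits, 256-bin
  histogram) and skewness of the gray, red, green and blue channel values.
* 12 inter-channel Pearson correlations — the six pairs red-green,
  green-blue, blue-red, red-gray, green-gray, blue-gray.
* 6 PCA color variances — the eigenvalues of the 3x3 covariance matrix of
  the raw RGB triples, sorted descending (PC1 >= PC2 >= PC3): the variances
  of the pixel cloud along its three principal color axes.

All moments are population moments (the pixel set is the full population of
its region), and PCA is performed on raw 0-255 values without
standardization.
"""

from __future__ import annotations

import numpy as np

from .imaging import GRAY_WEIGHTS, RegionPair

__all__ = [
    "CHANNELS",
    "CHANNEL_PAIRS",
    "REGIONS",
    "channel_statistics",
    "pearson_correlation",
    "pca_color_variances",
    "extract_color_features",
]

CHANNELS = ("gray", "r", "g", "b")
CHANNEL_PAIRS = (("r", "g"), ("g", "b"), ("b", "r"),
                 ("r", "gray"), ("g", "gray"), ("b", "gray"))
REGIONS = ("sub", "lesion")


def channel_statistics(values: np.ndarray) -> tuple[float, float, float]:
    """(variance, entropy, skewness) of one channel's pixel values.

    Variance and skewness use population moments; a constant sample has
    skewness 0 by convention.  Entropy is Shannon entropy in bits of the
    256-bin integer histogram (values floored into [0, 255]).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("channel statistics need at least 2 values")
    mean = v.mean()
    m2 = ((v - mean) ** 2).mean()
    m3 = ((v - mean) ** 3).mean()
    skew = 0.0 if m2 == 0 else float(m3 / m2**1.5)
    hist = np.bincount(np.clip(np.floor(v), 0, 255).astype(np.int64), minlength=256)
    p = hist[hist > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    return float(m2), entropy, skew


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson r with a degeneracy flag.

    A constant input has no defined correlation; such pairs return
    ``(0.0, True)`` so the feature table stays rectangular.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("correlation needs at least 2 values")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0, True
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return float(np.clip(r, -1.0, 1.0)), False


def pca_color_variances(rgb_pixels: np.ndarray) -> tuple[float, float, float]:
    """Eigenvalues of the population covariance of RGB triples, descending.

    Equivalently the variances of the pixel color cloud projected onto its
    three orthogonal principal axes: PC1 >= PC2 >= PC3 >= 0.
    """
    px = np.asarray(rgb_pixels, dtype=np.float64).reshape(-1, 3)
    if px.shape[0] < 3:
        raise ValueError("PCA needs at least 3 pixels")
    centered = px - px.mean(axis=0)
    cov = centered.T @ centered / px.shape[0]
    evals = np.linalg.eigvalsh(cov)[::-1]
    evals = np.clip(evals, 0.0, None)
    return float(evals[0]), float(evals[1]), float(evals[2])


def _region_channels(rgb: np.ndarray) -> dict[str, np.ndarray]:
    wr, wg, wb = GRAY_WEIGHTS
    return {
        "r": rgb[:, 0],
        "g": rgb[:, 1],
        "b": rgb[:, 2],
        "gray": wr * rgb[:, 0] + wg * rgb[:, 1] + wb * rgb[:, 2],
    }


def extract_color_features(pair: RegionPair) -> dict[str, float]:
    """All 42 color features of a region pair.

    Returns a flat name -> value mapping with the canonical CSV names
    ``color.var.{ch}.{region}``, ``color.entropy.{ch}.{region}``,
    ``color.skew.{ch}.{region}``, ``color.corr.{a}{b}.{region}`` and
    ``color.pca.pc{i}.{region}``.
    """
    out: dict[str, float] = {}
    region_pixels = {"sub": pair.all_pixels, "lesion": pair.lesion_pixels}
    for region, rgb in region_pixels.items():
        ch = _region_channels(rgb)
        for name in CHANNELS:
            var, ent, skew = channel_statistics(ch[name])
            out[f"color.var.{name}.{region}"] = var
            out[f"color.entropy.{name}.{region}"] = ent
            out[f"color.skew.{name}.{region}"] = skew
        for a, b in CHANNEL_PAIRS:
            r, _degenerate = pearson_correlation(ch[a], ch[b])
            out[f"color.corr.{a}{b}.{region}"] = r
        pc1, pc2, pc3 = pca_color_variances(rgb)
        out[f"color.pca.pc1.{region}"] = pc1
        out[f"color.pca.pc2.{region}"] = pc2
        out[f"color.pca.pc3.{region}"] = pc3
    return out
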