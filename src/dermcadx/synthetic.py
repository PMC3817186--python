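"""Seeded synthetic macrophotographs, masks and feature tables.

No public image set exists for this problem, so the package ships a
generator that emulates the imaging conventions the classifier assumes: one
centered lesion occupying at most half the frame on a skin-colored
background, with class-dependent structure —

* **benign** lesions draw their pixels from a single unimodal color palette
  and have a nearly smooth star-convex border;
* **malignant** lesions mix at least three palette colors in spatially
  clustered patches (a more dispersed RGB cloud, hence larger principal-
  component color variances) and carry a more irregular border (larger
  radial perturbation amplitude).

Lesion supports are star-convex, ``r(theta) = r0 (1 + sum_k a_k
sin(k theta + phi_k))``, so the continuous boundary is available in closed
form for shape-feature oracles.  Everything is a pure function of the
configuration and seed.

A second, image-free tier (``generate_feature_table(mode="direct")``)
samples 91-column feature vectors from two multivariate Gaussians with a
configurable set of informative columns; it makes selection/evaluation tests
fast and their ground truth exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import ALL_FEATURES, extract_features
from .imaging import LesionMask, MacroImage, make_region_pair
from .selection import LabeledFeatureTable

__all__ = [
    "GeneratorConfig",
    "benign_config",
    "malignant_config",
    "generate_lesion_image",
    "generate_feature_table",
    "analytic_fixtures",
    "disk_mask",
    "star_mask",
]

#: default palettes; fixed, documented as non-clinical
SKIN_COLOR = (200.0, 170.0, 150.0)
BENIGN_PALETTE = ((120.0, 80.0, 60.0),)
MALIGNANT_PALETTE = ((90.0, 60.0, 50.0), (60.0, 70.0, 80.0), (150.0, 60.0, 60.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic macrograph generator."""

    image_size: int = 128
    lesion_radius_range: tuple[float, float] = (18.0, 28.0)
    lesion_class: str = "benign"
    palette: tuple[tuple[float, float, float], ...] = BENIGN_PALETTE
    palette_weights: tuple[float, ...] | None = None
    palette_spread: float = 8.0
    border_amplitude: float = 0.04
    border_harmonics: tuple[int, ...] = (2, 3, 4, 5)
    skin_color: tuple[float, float, float] = SKIN_COLOR
    skin_spread: float = 3.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_class not in ("benign", "malignant"):
            raise ValueError("lesion_class must be 'benign' or 'malignant'")
        r_max = self.lesion_radius_range[1] * (1 + len(self.border_harmonics) * self.border_amplitude)
        half = self.image_size / 2
        if r_max >= half - 0.5 * self.lesion_radius_range[1]:
            raise ValueError(
                "lesion cannot fit with the required skin margin; enlarge image_size"
            )
        if np.pi * r_max**2 > 0.5 * self.image_size**2:
            raise ValueError("lesion area may exceed 50% of the frame")


def benign_config(**overrides) -> GeneratorConfig:
    """Default benign conditions: single color, low border irregularity."""
    return replace(GeneratorConfig(), **overrides)


def malignant_config(**overrides) -> GeneratorConfig:
    """Default malignant conditions: 3-color clustered mixture, irregular border."""
    cfg = GeneratorConfig(
        lesion_class="malignant",
        palette=MALIGNANT_PALETTE,
        border_amplitude=0.12,
    )
    return replace(cfg, **overrides)


def _star_convex_mask(size, center, r0, amplitudes, phases, harmonics) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    radius = np.full_like(dist, float(r0))
    for a, ph, k in zip(amplitudes, phases, harmonics):
        radius += r0 * a * np.sin(k * theta + ph)
    return dist <= radius


def generate_lesion_image(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[MacroImage, LesionMask, int]:
    """Render one macrograph; returns (image, mask, label) with label 1 = malignant.

    Bit-identical for identical (config, seed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    size = config.image_size
    center = (size / 2 + rng.uniform(-2, 2), size / 2 + rng.uniform(-2, 2))
    r0 = rng.uniform(*config.lesion_radius_range)
    K = len(config.border_harmonics)
    amplitudes = config.border_amplitude * rng.uniform(0.5, 1.0, size=K)
    phases = rng.uniform(0, 2 * np.pi, size=K)
    mask = _star_convex_mask(size, center, r0, amplitudes, phases, config.border_harmonics)

    img = np.empty((size, size, 3))
    img[:] = np.asarray(config.skin_color)
    img += rng.normal(0, config.skin_spread, size=img.shape)

    palette = np.asarray(config.palette, dtype=float)
    n_colors = len(palette)
    lesion_idx = np.argwhere(mask)
    if n_colors == 1:
        assign = np.zeros(len(lesion_idx), dtype=int)
    else:
        # spatially clustered patches: nearest of one seed point per color
        weights = (np.asarray(config.palette_weights, dtype=float)
                   if config.palette_weights is not None
                   else np.ones(n_colors))
        weights = weights / weights.sum()
        seeds = lesion_idx[rng.choice(len(lesion_idx), size=n_colors, replace=False)]
        d = np.linalg.norm(lesion_idx[:, None, :] - seeds[None, :, :], axis=2)
        d = d / weights[None, :]  # heavier colors claim larger patches
        assign = d.argmin(axis=1)
    lesion_colors = palette[assign] + rng.normal(
        0, config.palette_spread, size=(len(lesion_idx), 3)
    )
    img[lesion_idx[:, 0], lesion_idx[:, 1]] = lesion_colors
    img += rng.normal(0, config.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    label = 1 if config.lesion_class == "malignant" else 0
    return MacroImage(pixels), LesionMask(mask), label


def _direct_table(n_benign, n_malignant, rng, informative, effect_size) -> LabeledFeatureTable:
    p = len(ALL_FEATURES)
    info_idx = [ALL_FEATURES.index(f) for f in informative]
    shift = np.zeros(p)
    shift[info_idx] = effect_size
    Xb = rng.standard_normal((n_benign, p))
    Xm = rng.standard_normal((n_malignant, p)) + shift
    X = np.vstack([Xb, Xm])
    y = np.concatenate([np.zeros(n_benign, int), np.ones(n_malignant, int)])
    ids = tuple(f"b{i:03d}" for i in range(n_benign)) + tuple(
        f"m{i:03d}" for i in range(n_malignant)
    )
    return LabeledFeatureTable(pd.DataFrame(X, columns=list(ALL_FEATURES)), y, ids)


def generate_feature_table(
    n_benign: int,
    n_malignant: int,
    seed: int = 0,
    mode: str = "rendered",
    informative_features=None,
    effect_size: float = 2.0,
    benign: GeneratorConfig | None = None,
    malignant: GeneratorConfig | None = None,
) -> LabeledFeatureTable:
    """A labeled 91-column feature table of synthetic lesions.

    ``mode="rendered"`` draws images with the two class configurations and
    runs the full feature extraction; ``mode="direct"`` samples the named
    informative columns from shifted standard normals (effect size = mean
    shift in SD units) and everything else from noise.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one record per class")
    rng = np.random.default_rng(seed)
    if mode == "direct":
        informative = tuple(informative_features or ALL_FEATURES[:5])
        unknown = set(informative) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        return _direct_table(n_benign, n_malignant, rng, informative, effect_size)
    if mode != "rendered":
        raise ValueError("mode must be 'rendered' or 'direct'")
    benign = benign or benign_config()
    malignant = malignant or malignant_config()
    rows, labels, ids = [], [], []
    for i in range(n_benign + n_malignant):
        cfg = benign if i < n_benign else malignant
        sub_seed = int(rng.integers(0, 2**31 - 1))
        image, mask, label = generate_lesion_image(cfg, seed=sub_seed)
        pair = make_region_pair(image, mask)
        rows.append(extract_features(pair))
        labels.append(label)
        ids.append(f"{'b' if label == 0 else 'm'}{i:03d}")
    return LabeledFeatureTable(
        pd.DataFrame(rows, columns=list(ALL_FEATURES)),
        np.array(labels),
        tuple(ids),
    )


def disk_mask(size: int = 64, radius: float = 20.0, center=None) -> np.ndarray:
    c = (size / 2, size / 2) if center is None else center
    rr, cc = np.mgrid[0:size, 0:size]
    return np.hypot(rr - c[0], cc - c[1]) <= radius


def star_mask(size: int = 96, r_inner: float = 15.0, r_outer: float = 30.0,
              points: int = 5) -> np.ndarray:
    """A regular star whose polar boundary interpolates r_inner..r_outer."""
    c = size / 2
    rr, cc = np.mgrid[0:size, 0:size]
    theta = np.arctan2(rr - c, cc - c)
    radius = star_radius(theta, r_inner, r_outer, points)
    return np.hypot(rr - c, cc - c) <= radius


def star_radius(theta, r_inner: float, r_outer: float, points: int = 5):
    """Continuous polar boundary of the star (triangle wave between radii)."""
    frac = np.abs(((np.asarray(theta) * points / (2 * np.pi)) % 1.0) - 0.5) * 2
    return r_inner + (r_outer - r_inner) * frac


def analytic_fixtures() -> dict[str, dict]:
    """Deterministic fixtures with machine-readable expected properties.

    Each entry holds an ``image`` (H x W x 3 uint8) and/or ``mask`` (bool)
    plus an ``expect`` mapping naming the property the fixture pins down.
    """
    fx: dict[str, dict] = {}

    const = np.full((64, 64, 3), 97, dtype=np.uint8)
    fx["constant_image"] = {
        "image": const,
        "expect": {"all_channel_variances": 0.0, "all_entropies": 0.0},
    }

    ramp = np.repeat(np.arange(64, dtype=np.uint8) * 4, 64).reshape(64, 64)
    gray_ramp = np.stack([ramp] * 3, axis=-1)
    fx["gray_ramp"] = {
        "image": gray_ramp,
        "expect": {"channel_pair_correlations": 1.0, "pc2": 0.0, "pc3": 0.0},
    }

    r = np.tile(np.arange(64, dtype=np.float64), (64, 1))
    g = np.clip(2 * r + 5, 0, 255)
    linear = np.stack([r, g, np.full_like(r, 40.0)], axis=-1).astype(np.uint8)
    fx["linear_channels"] = {
        "image": linear,
        "expect": {"corr_rg": 1.0},
    }

    for block in (4, 16):
        tiles = (np.add.outer(np.arange(64) // block, np.arange(64) // block) % 2)
        board = (tiles * 255).astype(np.uint8)
        fx[f"checkerboard{block}"] = {
            "image": np.stack([board] * 3, axis=-1),
            "expect": {"coarser_than_block_1": True, "block": block},
        }

    fx["disk_mask"] = {
        "mask": disk_mask(80, radius=30),
        "expect": {"compactness_near": 1.0, "asymmetry_below": 0.02,
                   "radial_variance_below": 0.005},
    }
    sq = np.zeros((60, 60), dtype=bool)
    sq[10:50, 10:50] = True
    fx["square_mask"] = {
        "mask": sq,
        "expect": {"compactness_near": (4 * 40) ** 2 / (4 * np.pi * 1600)},
    }
    bar = np.zeros((20, 110), dtype=bool)
    bar[9:10, 5:105] = True
    fx["bar_mask"] = {"mask": bar, "expect": {"compactness_above": 5.0}}
    fx["star_mask"] = {
        "mask": star_mask(96, 15, 30, 5),
        "expect": {"r_inner": 15.0, "r_outer": 30.0, "points": 5},
    }
    return fx
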