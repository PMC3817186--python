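"""Image and mask I/O, region-of-interest construction, grayscale and quantization.

Every downstream feature module works on a :class:`RegionPair`: the cropped
rectangular sub-image that contains the whole lesion centered, plus an amount
of surrounding normal skin whose pixel count equals the lesion's pixel count
(within 2%).  This equal-area convention standardizes how much skin context
enters the color and texture statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from imageio import v3 as iio
from scipy import ndimage

__all__ = [
    "MacroImage",
    "LesionMask",
    "RegionPair",
    "FormatError",
    "MaskValidationError",
    "ContextError",
    "load_image",
    "load_mask",
    "make_region_pair",
    "to_grayscale",
    "quantize_gray",
]

#: BT.601 luma weights used for the grayscale channel.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

MIN_SIDE = 8

# 8-connectivity structuring element for component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


class FormatError(ValueError):
    """Input file has an unsupported pixel format or bit depth."""


class MaskValidationError(ValueError):
    """Lesion mask violates a structural invariant."""


class ContextError(ValueError):
    """Not enough surrounding skin exists to build the equal-area region."""


@dataclass(frozen=True)
class MacroImage:
    """One 8-bit RGB macrophotograph, shape ``(H, W, 3)``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected H x W x 3 RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise FormatError(f"pixel values must be integers, got dtype {px.dtype}")
            if px.min() < 0 or px.max() > 255:
                raise FormatError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask paired with a :class:`MacroImage`.

    The lesion must be a single 8-connected component that does not touch the
    image border (skin context is required on all sides).
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise MaskValidationError(f"mask must be 2-D, got shape {m.shape}")
        n = int(m.sum())
        if n == 0:
            raise MaskValidationError("mask contains no lesion pixels")
        _, ncomp = ndimage.label(m, structure=_STRUCT8)
        if ncomp != 1:
            raise MaskValidationError(
                f"lesion must be one 8-connected component, found {ncomp}"
            )
        border = np.concatenate([m[0, :], m[-1, :], m[:, 0], m[:, -1]])
        if border.any():
            raise MaskValidationError("lesion touches the image border")

    @property
    def lesion_pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass(frozen=True)
class RegionPair:
    """The two analysis regions cut from one photograph.

    ``sub_image``/``sub_mask`` is the rectangle holding the centered lesion
    plus (approximately) an equal pixel-area of normal skin.  ``clipped`` is
    set when the rectangle had to be cut at the original image border;
    ``tolerance_met`` records whether the 2% skin/lesion balance was achieved.
    """

    sub_image: MacroImage
    sub_mask: LesionMask
    clipped: bool = False
    tolerance_met: bool = True
    origin: tuple[int, int] = (0, 0)

    @property
    def lesion_pixels(self) -> np.ndarray:
        """RGB triples under the mask, shape (A, 3) float64."""
        return self.sub_image.pixels[self.sub_mask.mask].astype(np.float64)

    @property
    def skin_pixels(self) -> np.ndarray:
        """RGB triples of the rectangle outside the mask, shape (S, 3) float64."""
        return self.sub_image.pixels[~self.sub_mask.mask].astype(np.float64)

    @property
    def all_pixels(self) -> np.ndarray:
        return self.sub_image.pixels.reshape(-1, 3).astype(np.float64)


def load_image(path) -> MacroImage:
    """Read an 8-bit RGB PNG or JPEG into a :class:`MacroImage`.

    Grayscale sources are replicated across the three channels with a warning;
    an alpha channel, if present, is dropped.
    """
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit samples, got dtype {arr.dtype}")
    if arr.ndim == 2:
        warnings.warn(f"{path}: grayscale source replicated to RGB", stacklevel=2)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: unsupported channel layout {arr.shape}")
    return MacroImage(arr)


def _polygon_mask(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon of (row, col) vertices.

    A pixel belongs to the lesion when its center lies inside the polygon or
    exactly on its boundary.
    """
    import shapely

    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise MaskValidationError("polygon needs at least 3 (row, col) vertices")
    poly = shapely.Polygon(verts)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = shapely.points(np.column_stack([rr.ravel(), cc.ravel()]))
    return shapely.covers(poly, pts).reshape(shape)


def load_mask(path_or_polygon, image: MacroImage) -> LesionMask:
    """Load the manually drawn lesion border as a binary mask.

    Accepts a single-channel image file with exactly two distinct values
    (nonzero = lesion), a JSON file holding a ``[[row, col], ...]`` polygon,
    or an in-memory polygon vertex list.  The polygon interior is filled and
    boundary pixels are included.
    """
    shape = (image.height, image.width)
    if isinstance(path_or_polygon, (list, tuple, np.ndarray)):
        mask = _polygon_mask(path_or_polygon, shape)
    else:
        p = str(path_or_polygon)
        if p.endswith(".json"):
            with open(p) as fh:
                mask = _polygon_mask(json.load(fh), shape)
        else:
            arr = iio.imread(p)
            if arr.ndim == 3:
                if not np.all(arr[..., 0:1] == arr):
                    raise MaskValidationError(f"{p}: mask must be single-channel")
                arr = arr[..., 0]
            values = np.unique(arr)
            if len(values) > 2:
                raise MaskValidationError(
                    f"{p}: mask has {len(values)} distinct values, expected 2"
                )
            mask = arr != 0
    if mask.shape != shape:
        raise MaskValidationError(
            f"mask shape {mask.shape} does not match image shape {shape}"
        )
    return LesionMask(mask)


def _rect_bounds(center: tuple[float, float], h: int, w: int, shape: tuple[int, int]):
    """Integer rectangle of size h x w centered at `center`, clipped to `shape`."""
    r0 = int(round(center[0] - h / 2))
    c0 = int(round(center[1] - w / 2))
    r1, c1 = r0 + h, c0 + w
    cr0, cc0 = max(r0, 0), max(c0, 0)
    cr1, cc1 = min(r1, shape[0]), min(c1, shape[1])
    clipped = (cr0, cc0, cr1, cc1) != (r0, c0, r1, c1)
    return (cr0, cc0, cr1, cc1), clipped


def make_region_pair(
    image: MacroImage, mask: LesionMask, tolerance: float = 0.02
) -> RegionPair:
    """Crop the equal-area lesion + skin rectangle.

    The rectangle is centered on the lesion centroid, takes the aspect ratio
    of the lesion bounding box, and targets an area of twice the lesion pixel
    count so that skin and lesion contribute equal pixel counts.  Integer
    side lengths are refined by +/-1-pixel steps until ``|skin - lesion| <=
    tolerance * lesion`` or the search window is exhausted; rectangles cut by
    the image border carry ``clipped=True``.
    """
    if mask.shape != (image.height, image.width):
        raise MaskValidationError("image and mask dimensions differ")
    if image.height < MIN_SIDE or image.width < MIN_SIDE:
        raise FormatError(
            f"feature extraction needs at least {MIN_SIDE}x{MIN_SIDE} images, "
            f"got {image.height}x{image.width}"
        )
    A = mask.lesion_pixel_count
    if image.height * image.width - A < 0.5 * A:
        raise ContextError(
            "lesion occupies too much of the frame for an equal-area skin region"
        )
    rr, cc = np.nonzero(mask.mask)
    centroid = (float(rr.mean()), float(cc.mean()))
    bbox_h = int(rr.max() - rr.min() + 1)
    bbox_w = int(cc.max() - cc.min() + 1)
    aspect = bbox_h / bbox_w

    # minimum sides so the centered rectangle covers the lesion extent with a
    # 1-pixel skin margin (the sub-mask must not touch the rectangle border)
    need_h = int(np.ceil(2 * max(centroid[0] - (rr.min() - 1), (rr.max() + 1) - centroid[0]) + 1))
    need_w = int(np.ceil(2 * max(centroid[1] - (cc.min() - 1), (cc.max() + 1) - centroid[1]) + 1))

    ideal_h = max(need_h, int(round(np.sqrt(2 * A * aspect))))
    ideal_w = max(need_w, int(round(np.sqrt(2 * A / aspect))))

    best = None  # (meets_tol, -aspect_dev, -area_dev, -h) maximized
    span = 6
    for h in range(max(need_h, ideal_h - span), ideal_h + span + 1):
        for w in range(max(need_w, ideal_w - span), ideal_w + span + 1):
            (r0, c0, r1, c1), clipped = _rect_bounds(
                centroid, h, w, (image.height, image.width)
            )
            sub = mask.mask[r0:r1, c0:c1]
            lesion_in = int(sub.sum())
            if lesion_in < A:  # rectangle must contain the whole lesion
                continue
            if sub[[0, -1], :].any() or sub[:, [0, -1]].any():
                continue  # keep a skin margin around the lesion
            skin = (r1 - r0) * (c1 - c0) - lesion_in
            dev = abs(skin - A)
            meets = dev <= tolerance * A
            aspect_dev = abs(h / w - aspect)
            key = (meets, -aspect_dev, -dev, -h)
            if best is None or key > best[0]:
                best = (key, (r0, c0, r1, c1), clipped, meets)
    if best is None:
        raise ContextError("no rectangle containing the lesion fits in the frame")
    (_, (r0, c0, r1, c1), clipped, meets) = best
    sub_img = MacroImage(image.pixels[r0:r1, c0:c1])
    sub_mask = LesionMask(mask.mask[r0:r1, c0:c1])
    return RegionPair(
        sub_image=sub_img,
        sub_mask=sub_mask,
        clipped=clipped,
        tolerance_met=meets,
        origin=(r0, c0),
    )


def to_grayscale(image: MacroImage | np.ndarray) -> np.ndarray:
    """BT.601 luma: ``0.299 R + 0.587 G + 0.114 B``, real-valued in [0, 255]."""
    px = image.pixels if isinstance(image, MacroImage) else np.asarray(image)
    px = px.astype(np.float64)
    wr, wg, wb = GRAY_WEIGHTS
    return wr * px[..., 0] + wg * px[..., 1] + wb * px[..., 2]


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform-width quantization of [0, 256) gray values to ``levels`` bins."""
    if levels not in (2, 4, 8, 16):
        raise ValueError(f"unsupported gray-level count {levels}; use 2, 4, 8 or 16")
    gray = np.asarray(gray, dtype=np.float64)
    if gray.size and (gray.min() < 0 or gray.max() > 255):
        raise ValueError("gray values must lie in [0, 255]")
    q = np.floor(gray * levels / 256.0).astype(np.int64)
    return np.clip(q, 0, levels - 1)
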