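"""Canonical feature registry and the full 91-feature extraction.

The feature vector concatenates:

==================  =====  ==========================================
block               count  names
==================  =====  ==========================================
shape                   3  ``shape.{asymmetry,compactness,radial_variance}``
texture                46  ``texture.glrlm.L{16,8,4,2}.{11 stats}``,
                           ``texture.tamura.{sub,lesion}``
color (1-channel)      24  ``color.{var,entropy,skew}.{gray,r,g,b}.{sub,lesion}``
color correlation      12  ``color.corr.{rg,gb,br,rgray,ggray,bgray}.{sub,lesion}``
color PCA               6  ``color.pca.pc{1,2,3}.{sub,lesion}``
==================  =====  ==========================================

The first three blocks (73 features) form the *conventional* set used by the
baseline classifier; the last two (18 features) are the *new*
multidimensional color set.  ``ALL_FEATURES`` fixes the canonical column
order of every feature table the package writes.
"""

from __future__ import annotations

import numpy as np

from . import color as _color
from . import shape as _shape
from . import texture as _texture
from .imaging import LesionMask, MacroImage, RegionPair, make_region_pair

__all__ = [
    "SHAPE_FEATURES",
    "TEXTURE_FEATURES",
    "COLOR_CONVENTIONAL_FEATURES",
    "COLOR_CORRELATION_FEATURES",
    "COLOR_PCA_FEATURES",
    "CONVENTIONAL_FEATURES",
    "NEW_FEATURES",
    "ALL_FEATURES",
    "extract_features",
]

SHAPE_FEATURES = (
    "shape.asymmetry",
    "shape.compactness",
    "shape.radial_variance",
)

TEXTURE_FEATURES = tuple(
    f"texture.glrlm.L{levels}.{stat}"
    for levels in _texture.QUANTIZATION_LEVELS
    for stat in _texture.GLRLM_STATISTICS
) + ("texture.tamura.sub", "texture.tamura.lesion")

COLOR_CONVENTIONAL_FEATURES = tuple(
    f"color.{stat}.{ch}.{region}"
    for region in _color.REGIONS
    for stat in ("var", "entropy", "skew")
    for ch in _color.CHANNELS
)

COLOR_CORRELATION_FEATURES = tuple(
    f"color.corr.{a}{b}.{region}"
    for region in _color.REGIONS
    for a, b in _color.CHANNEL_PAIRS
)

COLOR_PCA_FEATURES = tuple(
    f"color.pca.pc{i}.{region}" for region in _color.REGIONS for i in (1, 2, 3)
)

#: the 73 conventional features of the baseline classifier
CONVENTIONAL_FEATURES = SHAPE_FEATURES + TEXTURE_FEATURES + COLOR_CONVENTIONAL_FEATURES
#: the 18 new multidimensional color features
NEW_FEATURES = COLOR_CORRELATION_FEATURES + COLOR_PCA_FEATURES
#: all 91 features in canonical column order
ALL_FEATURES = CONVENTIONAL_FEATURES + NEW_FEATURES

assert len(CONVENTIONAL_FEATURES) == 73
assert len(NEW_FEATURES) == 18
assert len(ALL_FEATURES) == 91


def extract_features(
    image: MacroImage | RegionPair, mask: LesionMask | None = None
) -> dict[str, float]:
    """Extract the full 91-feature vector for one lesion.

    Accepts either a raw photograph plus its lesion mask (the equal-area
    region pair is built internally) or a ready-made :class:`RegionPair`.
    Returns an ordered name -> value mapping following ``ALL_FEATURES``.
    """
    if isinstance(image, RegionPair):
        pair = image
    else:
        if mask is None:
            raise ValueError("a lesion mask is required with a raw image")
        pair = make_region_pair(image, mask)
    values: dict[str, float] = {}
    values.update(_shape.extract_shape_features(pair.sub_mask).as_dict())
    values.update(_texture.extract_texture_features(pair.sub_image, pair.sub_mask))
    values.update(_color.extract_color_features(pair))
    ordered = {name: float(values[name]) for name in ALL_FEATURES}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return ordered
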