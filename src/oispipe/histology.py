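"""Histology burden quantification: amyloid (% area) and aortic plaque (% area).

Amyloid burden in DAB-stained brain sections counts detected amyloid pixels
plus cerebral-amyloid-angiopathy (CAA) pixels — both those reclassified from
the automatic detection and those added manually — against tissue plus
detected amyloid:

    burden % = 100 * (A + CAA_reclassified + CAA_added)
                  / (T + A + CAA_reclassified)

(the manually *added* CAA pixels enter the numerator only).  Pixel classes
come from a color-deconvolution threshold on the DAB optical-density channel,
with every class replaceable by externally supplied masks so that manual
reclassification workflows can be reproduced.

Atherosclerotic plaque burden in Oil-Red-O-stained aortic arches is the
fraction of pixels inside a hand-drawn arch polygon that fall below gray
level 150 after 8-bit grayscale conversion (the lipid stain is dark on the
luminance channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from skimage.color import rgb2gray, rgb2hed
from skimage.draw import polygon2mask

from .errors import InputError

__all__ = [
    "LabelMasks",
    "ArchImage",
    "amyloid_burden",
    "dab_classify",
    "plaque_burden",
]

CLASS_NAMES = ("amyloid", "caa_reclassified", "caa_added", "tissue", "ignore")


@dataclass
class LabelMasks:
    """Mutually disjoint boolean pixel-class masks on one section grid."""

    amyloid: np.ndarray
    caa_reclassified: np.ndarray
    caa_added: np.ndarray
    tissue: np.ndarray
    ignore: np.ndarray

    def __post_init__(self) -> None:
        arrays = [getattr(self, n) for n in CLASS_NAMES]
        for n, a in zip(CLASS_NAMES, arrays):
            setattr(self, n, np.asarray(a, dtype=bool))
        arrays = [getattr(self, n) for n in CLASS_NAMES]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise InputError("all class masks must share one grid")
        total = np.zeros(arrays[0].shape, dtype=int)
        for a in arrays:
            total += a
        if total.max() > 1:
            raise InputError("class masks must be mutually disjoint")

    @classmethod
    def empty(cls, shape) -> "LabelMasks":
        z = np.zeros(shape, dtype=bool)
        return cls(*(z.copy() for _ in CLASS_NAMES))


@dataclass
class ArchImage:
    """Aortic-arch photograph plus the hand-drawn arch polygon.

    ``polygon`` is an (N, 2) array of (row, col) vertices; ``threshold`` is
    the 8-bit gray level below which a pixel counts as Oil-Red-O positive.
    """

    image: np.ndarray  # RGB (H, W, 3) in [0, 1] or uint8, or 8-bit grayscale
    polygon: np.ndarray
    threshold: float = 150.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise InputError("polygon must be an (N, 2) vertex array")
        if len(self.polygon) < 3:
            raise InputError("polygon needs at least 3 vertices")


def amyloid_burden(masks: LabelMasks) -> float:
    """Amyloid % area from pixel-class counts (see module docstring)."""
    a = int(masks.amyloid.sum())
    c_re = int(masks.caa_reclassified.sum())
    c_add = int(masks.caa_added.sum())
    t = int(masks.tissue.sum())
    denom = t + a + c_re
    if denom == 0:
        raise InputError("zero denominator: no tissue or amyloid pixels detected")
    return 100.0 * (a + c_re + c_add) / denom


def dab_classify(
    image: np.ndarray,
    dab_threshold: float = 0.15,
    tissue_threshold: float = 0.05,
    overrides: Optional[Dict[str, np.ndarray]] = None,
) -> LabelMasks:
    """Threshold classifier on color-deconvolved DAB/hematoxylin channels.

    The RGB section is separated into hematoxylin / eosin / DAB optical
    densities with the standard stain-deconvolution matrix; pixels with DAB
    OD above ``dab_threshold`` are amyloid, remaining pixels with hematoxylin
    OD above ``tissue_threshold`` are tissue, and everything else is ignored.
    CAA classes start empty — they exist to receive manual reclassification
    via ``overrides``, which replace any class mask exactly (pixels claimed
    by an override are removed from the automatic classes to keep the masks
    disjoint).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError("dab_classify expects an RGB image (H, W, 3)")
    if image.dtype == np.uint8:
        image = image.astype(float) / 255.0
    hed = rgb2hed(image)
    hema, dab = hed[..., 0], hed[..., 2]
    amyloid = dab > dab_threshold
    tissue = (hema > tissue_threshold) & ~amyloid
    shape = image.shape[:2]
    masks = {
        "amyloid": amyloid,
        "caa_reclassified": np.zeros(shape, dtype=bool),
        "caa_added": np.zeros(shape, dtype=bool),
        "tissue": tissue,
        "ignore": ~(amyloid | tissue),
    }
    if overrides:
        for name, m in overrides.items():
            if name not in CLASS_NAMES:
                raise InputError(f"unknown class {name!r}; known: {CLASS_NAMES}")
            masks[name] = np.asarray(m, dtype=bool)
        claimed = np.zeros(shape, dtype=bool)
        for name in overrides:
            claimed |= masks[name]
        for name in CLASS_NAMES:
            if name not in overrides:
                masks[name] = masks[name] & ~claimed
    return LabelMasks(**masks)


def to_8bit_gray(image: np.ndarray) -> np.ndarray:
    """Standard luminance conversion to 8-bit gray (passthrough for 2-D input)."""
    image = np.asarray(image)
    if image.ndim == 2:
        if image.dtype == np.uint8:
            return image.astype(float)
        arr = image.astype(float)
        return arr * 255.0 if arr.max() <= 1.0 else arr
    if image.ndim == 3 and image.shape[2] == 3:
        arr = image.astype(float)
        if image.dtype == np.uint8 or arr.max() > 1.0:
            arr = arr / 255.0
        return rgb2gray(arr) * 255.0
    raise InputError("image must be grayscale (H, W) or RGB (H, W, 3)")


def plaque_burden(arch: ArchImage) -> float:
    """Oil-Red-O plaque % area inside the arch polygon (gray < threshold).

    The polygon is rasterized by the pixel-center even-odd rule; image
    content outside it never affects the result.
    """
    gray = to_8bit_gray(arch.image)
    mask = polygon2mask(gray.shape, arch.polygon)
    n_arch = int(mask.sum())
    if n_arch == 0:
        raise InputError("degenerate polygon: encloses no pixel centers")
    positive = int((gray[mask] < arch.threshold).sum())
    return 100.0 * positive / n_arch
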