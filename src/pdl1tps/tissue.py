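"""Tissue/background separation on stained slides.

Background on a bright-field scan is pale and unsaturated; any stained
tissue is darker and/or more saturated.  Detection thresholds a per-pixel
"whiteness" channel (1 − saturation) · value with Otsu's method, then
cleans the binary mask with morphological closing and small-object removal.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color, filters, morphology


def whiteness_channel(image: np.ndarray) -> np.ndarray:
    """(1 − S) · V in [0, 1]: high for pale unsaturated background."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    hsv = color.rgb2hsv(image)
    return (1.0 - hsv[..., 1]) * hsv[..., 2]


def detect_tissue(
    image: np.ndarray,
    min_object_px: int = 1000,
    closing_radius: int = 5,
) -> np.ndarray:
    """Binary tissue mask for an RGB slide image.

    Otsu's threshold is computed on the whiteness channel; pixels below it
    (stained, non-white) are tissue.  The raw mask is closed with a disk of
    ``closing_radius`` pixels and connected components smaller than
    ``min_object_px`` are dropped.

    A constant-intensity image has no Otsu threshold; an empty mask is
    returned with a warning.
    """
    if image.size == 0:
        raise ValueError("empty image")
    w = whiteness_channel(image)
    if np.ptp(w) < 1e-6:
        warnings.warn("constant-intensity image: Otsu threshold undefined, empty tissue mask")
        return np.zeros(w.shape, dtype=bool)
    mask = w < filters.threshold_otsu(w)
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    if min_object_px > 0:
        # drop components strictly smaller than min_object_px
        mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    return mask


def write_tissue_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.astype(np.uint8)) * 255)


def read_tissue_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(str(path)) > 0
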