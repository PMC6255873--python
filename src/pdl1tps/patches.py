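"""Patch dataset construction from slides, annotations and tissue masks.

Labeled patches come from the regions where two annotators agree
(discordant pixels are discarded); they are sampled on a dense regular grid
(default stride 20 px) anchored at the bounding box of each connected
annotated region, and a grid position becomes a training patch only when
one single label dominates the window.  Unlabeled patches are sampled on a
coarser grid (default stride 60 px) over the detected tissue.  Coordinates
are 0-based ``(x, y)`` = (column, row) with top-left origin and half-open
patch extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .classes import IGNORE_ID


@dataclass
class LabeledPatch:
    image: np.ndarray  # (patch, patch, 3) uint8
    label: int
    origin: tuple[str, int, int]  # (slide_id, x, y) of the top-left pixel


@dataclass
class UnlabeledPatch:
    image: np.ndarray
    origin: tuple[str, int, int]


def grid_count(length: int, patch: int, stride: int) -> int:
    """Number of grid positions along one axis: floor((L − patch)/stride) + 1."""
    if length < patch:
        return 0
    return (length - patch) // stride + 1


def concordant_mask(annot_a: np.ndarray, annot_b: np.ndarray) -> np.ndarray:
    """Pixels where both annotators assigned the same non-ignore label.

    Everything else — unannotated by either, or annotated with different
    classes — becomes ignore (0) and is discarded from training.
    """
    annot_a = np.asarray(annot_a)
    annot_b = np.asarray(annot_b)
    if annot_a.shape != annot_b.shape:
        raise ValueError(f"annotation shapes differ: {annot_a.shape} vs {annot_b.shape}")
    agree = (annot_a == annot_b) & (annot_a != IGNORE_ID)
    return np.where(agree, annot_a, IGNORE_ID).astype(annot_a.dtype)


def sample_labeled(
    image: np.ndarray,
    label_mask: np.ndarray,
    patch_size: int = 128,
    stride: int = 20,
    purity_threshold: float = 0.9,
    slide_id: str = "slide",
) -> list[LabeledPatch]:
    """Extract labeled patches on a regular grid over annotated regions.

    For every connected region of each label, a grid of ``stride`` px is
    anchored at the region's bounding-box top-left corner.  A grid window
    is kept when one single label covers at least ``purity_threshold`` of
    the *window* (all pixels, so windows dominated by discarded/ignore
    area are skipped too); that label is assigned.  This keeps training
    labels clean near region borders and discordant annotations.  Windows
    never extend beyond the region bounding box (hence never beyond the
    image).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if patch_size > min(image.shape[0], image.shape[1]):
        raise ValueError("patch_size exceeds image dimensions")
    if image.shape[:2] != label_mask.shape:
        raise ValueError("image and label mask shapes differ")

    patches: list[LabeledPatch] = []
    seen: set[tuple[int, int]] = set()
    for label in np.unique(label_mask):
        if label == IGNORE_ID:
            continue
        regions = measure.label(label_mask == label, connectivity=2)
        for region in measure.regionprops(regions):
            r0, c0, r1, c1 = region.bbox
            for y in range(r0, r1 - patch_size + 1, stride):
                for x in range(c0, c1 - patch_size + 1, stride):
                    if (x, y) in seen:
                        continue
                    window = label_mask[y : y + patch_size, x : x + patch_size]
                    annotated = window[window != IGNORE_ID]
                    if annotated.size == 0:
                        continue
                    values, counts = np.unique(annotated, return_counts=True)
                    best = int(np.argmax(counts))
                    if counts[best] / window.size < purity_threshold:
                        continue
                    seen.add((x, y))
                    patches.append(
                        LabeledPatch(
                            image=image[y : y + patch_size, x : x + patch_size].copy(),
                            label=int(values[best]),
                            origin=(slide_id, x, y),
                        )
                    )
    return patches


def sample_unlabeled(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    patch_size: int = 128,
    stride: int = 60,
    slide_id: str = "slide",
) -> list[UnlabeledPatch]:
    """One unlabeled patch per grid node whose center pixel lies in tissue."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if image.shape[:2] != tissue_mask.shape:
        raise ValueError("image and tissue mask shapes differ")
    h, w = tissue_mask.shape
    half = patch_size // 2
    patches: list[UnlabeledPatch] = []
    for iy in range(grid_count(h, patch_size, stride)):
        y = iy * stride
        for ix in range(grid_count(w, patch_size, stride)):
            x = ix * stride
            if tissue_mask[y + half, x + half]:
                patches.append(
                    UnlabeledPatch(
                        image=image[y : y + patch_size, x : x + patch_size].copy(),
                        origin=(slide_id, x, y),
                    )
                )
    return patches


def augment_rotations(patches: list[LabeledPatch]) -> list[LabeledPatch]:
    """Emit each patch in all four 90-degree orientations, labels preserved."""
    out: list[LabeledPatch] = []
    for p in patches:
        for k in range(4):
            out.append(
                LabeledPatch(
                    image=np.ascontiguousarray(np.rot90(p.image, k)),
                    label=p.label,
                    origin=p.origin,
                )
            )
    return out


def save_patch_dataset(patches, directory, manifest_name: str = "manifest.csv") -> None:
    """Persist patches as PNG tiles plus a CSV manifest.

    Manifest columns: filename, slide_id, x, y, label (``"unlabeled"`` for
    unlabeled patches).
    """
    import imageio.v3 as iio
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        label = getattr(p, "label", None)
        fname = f"patch_{i:06d}.png"
        iio.imwrite(directory / fname, p.image)
        slide_id, x, y = p.origin
        rows.append(
            {
                "filename": fname,
                "slide_id": slide_id,
                "x": x,
                "y": y,
                "label": "unlabeled" if label is None else label,
            }
        )
    pd.DataFrame(rows).to_csv(directory / manifest_name, index=False)


def load_patch_dataset(directory, manifest_name: str = "manifest.csv"):
    """Inverse of :func:`save_patch_dataset`; returns (labeled, unlabeled)."""
    import imageio.v3 as iio
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    manifest = pd.read_csv(directory / manifest_name)
    labeled, unlabeled = [], []
    for row in manifest.itertuples():
        img = iio.imread(directory / row.filename)
        origin = (row.slide_id, int(row.x), int(row.y))
        if str(row.label) == "unlabeled":
            unlabeled.append(UnlabeledPatch(image=img, origin=origin))
        else:
            labeled.append(LabeledPatch(image=img, label=int(row.label), origin=origin))
    return labeled, unlabeled
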