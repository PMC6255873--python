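"""Slide-level prediction and tumor proportion scoring.

Prediction runs a patch classifier over the detected tissue in a sliding
window (default stride 32 px); posteriors of overlapping windows are
averaged per pixel, every pixel is assigned its maximum-probability class,
and the TPS follows as the pixel-count ratio

    TPS = #TC(+) / (#TC(+) + #TC(−)) · 100,

with every non-tumor class excluded from both numerator and denominator.
The PD-L1 status is called at the SP263 25% cut-off with the clinical
"TC >= 25%" boundary convention (TPS exactly 25 is positive).  A slide
with no detected tumor pixels has an *undefined* TPS and status — never a
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classes import IGNORE_ID, ClassScheme, default_scheme
from .synthetic import DEFAULT_PALETTE, ClassTexture, generate_class_texture
from .training import patches_to_float

POSITIVE, NEGATIVE, UNDEFINED = "positive", "negative", "undefined"


@dataclass
class ClassProbabilityMap:
    """Per-pixel class posterior restricted to tissue.

    ``probs`` has shape (H, W, K); rows outside tissue are NaN.  Column
    order matches the class scheme used by the classifier.
    """

    probs: np.ndarray
    tissue: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.tissue & np.isfinite(self.probs[..., 0])


@dataclass
class TpsResult:
    tps: float | None
    n_pos_pixels: int
    n_neg_pixels: int
    status: str
    cutoff: float = 25.0


def pdl1_status(tps: float | None, cutoff: float = 25.0) -> str:
    """PD-L1 status call: positive iff TPS >= cutoff; undefined TPS propagates."""
    if tps is None or (isinstance(tps, float) and np.isnan(tps)):
        return UNDEFINED
    return POSITIVE if tps >= cutoff else NEGATIVE


def compute_tps(label_mask: np.ndarray, scheme: ClassScheme | None = None,
                cutoff: float = 25.0) -> TpsResult:
    """Pixel-ratio TPS from a class-ID mask (0 = ignore allowed)."""
    scheme = scheme or default_scheme()
    label_mask = np.asarray(label_mask)
    present = np.unique(label_mask)
    unknown = [int(v) for v in present if v != IGNORE_ID and v not in scheme]
    if unknown:
        raise ValueError(f"mask contains unknown class IDs: {unknown}")
    n_pos = int(np.count_nonzero(label_mask == scheme.tc_pos))
    n_neg = int(np.count_nonzero(label_mask == scheme.tc_neg))
    if n_pos + n_neg == 0:
        return TpsResult(None, 0, 0, UNDEFINED, cutoff)
    tps = 100.0 * n_pos / (n_pos + n_neg)
    return TpsResult(tps, n_pos, n_neg, pdl1_status(tps, cutoff), cutoff)


def predict_map(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    model,
    window: int = 32,
    stride: int = 32,
    batch_size: int = 256,
) -> ClassProbabilityMap:
    """Sliding-window class posteriors, averaged per pixel over overlaps.

    The grid starts at the top-left corner; a final row/column of windows
    is added flush with the image edge so every pixel is covered.  Windows
    are scored with ``model.predict_proba`` (floats in [-1, 1], NCHW) and
    each window's posterior is accredited to all its pixels; overlapping
    contributions are averaged.  Pixels outside the tissue mask are NaN.
    """
    if stride > window:
        raise ValueError("stride must not exceed window")
    if image.shape[:2] != tissue_mask.shape:
        raise ValueError("image and tissue mask shapes differ")
    h, w = image.shape[:2]
    pad_h, pad_w = max(0, window - h), max(0, window - w)
    if pad_h or pad_w:
        warnings.warn(
            f"image {h}x{w} smaller than window {window}; using reflective padding"
        )
        image = np.pad(image, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
        hp, wp = image.shape[:2]
    else:
        hp, wp = h, w

    if not tissue_mask.any():
        probe = model.predict_proba(patches_to_float(image[:window, :window][None]))
        k = probe.shape[1]
        return ClassProbabilityMap(
            probs=np.full((h, w, k), np.nan), tissue=tissue_mask.astype(bool)
        )

    ys = list(range(0, hp - window + 1, stride))
    if ys[-1] != hp - window:
        ys.append(hp - window)
    xs = list(range(0, wp - window + 1, stride))
    if xs[-1] != wp - window:
        xs.append(wp - window)
    positions = [(y, x) for y in ys for x in xs]

    prob_sum = None
    counts = np.zeros((hp, wp), dtype=np.int32)
    for start in range(0, len(positions), batch_size):
        chunk = positions[start : start + batch_size]
        tiles = np.stack([image[y : y + window, x : x + window] for y, x in chunk])
        probs = model.predict_proba(patches_to_float(tiles))
        if prob_sum is None:
            prob_sum = np.zeros((hp, wp, probs.shape[1]))
        for (y, x), p in zip(chunk, probs):
            prob_sum[y : y + window, x : x + window] += p
            counts[y : y + window, x : x + window] += 1

    prob_map = prob_sum / counts[..., None]
    prob_map = prob_map[:h, :w]
    prob_map[~tissue_mask.astype(bool)] = np.nan
    return ClassProbabilityMap(probs=prob_map, tissue=tissue_mask.astype(bool))


def classify_pixels(cmap: ClassProbabilityMap, scheme: ClassScheme | None = None) -> np.ndarray:
    """Per-pixel argmax class mask; exact ties go to the lowest class ID.

    Undefined (non-tissue) pixels get ignore (0).
    """
    scheme = scheme or default_scheme()
    probs = cmap.probs
    if probs.shape[-1] != scheme.n_classes:
        raise ValueError(
            f"probability map has {probs.shape[-1]} classes, scheme has {scheme.n_classes}"
        )
    ids = np.asarray(scheme.class_ids)
    order = np.argsort(ids, kind="stable")  # so first-max == lowest ID
    reordered = probs[..., order]
    defined = cmap.defined
    out = np.zeros(probs.shape[:2], dtype=np.int32)
    if defined.any():
        arg = np.argmax(reordered[defined], axis=-1)
        out[defined] = ids[order][arg]
    return out


def score_slide(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    model,
    scheme: ClassScheme | None = None,
    window: int = 32,
    stride: int = 32,
    cutoff: float = 25.0,
) -> tuple[TpsResult, np.ndarray]:
    """Predict, classify and score one slide; returns (TpsResult, label mask)."""
    scheme = scheme or default_scheme()
    cmap = predict_map(image, tissue_mask, model, window=window, stride=stride)
    mask = classify_pixels(cmap, scheme)
    return compute_tps(mask, scheme, cutoff), mask


def _masked_local_std(gray: np.ndarray, mask: np.ndarray, size: int):
    """Standard deviation of ``gray`` in a ``size``-px neighborhood,
    restricted to pixels where ``mask`` is true (excludes cross-boundary
    contamination).  Returns (std, coverage fraction)."""
    from scipy import ndimage

    m = mask.astype(np.float64)
    cnt = ndimage.uniform_filter(m, size)
    s1 = ndimage.uniform_filter(gray * m, size)
    s2 = ndimage.uniform_filter(gray * gray * m, size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = s1 / cnt
        var = s2 / cnt - mu * mu
    return np.sqrt(np.maximum(var, 0.0)), cnt


class OracleClassifier:
    """Window classifier with privileged knowledge of the synthetic palette,
    used as the known-good region detector in end-to-end recovery tests.

    Each window pixel votes for its nearest palette mean color, with the
    two brown classes (positive tumor and macrophage, identical mean and
    noise amplitude by design) pooled; brown pixels are then split by the
    local standard deviation of the luminance at two scales (9 px and
    3 px) — high for granular tumor stain, low for smooth macrophage
    blotches — computed over brown-voted pixels only so region boundaries
    do not contaminate the texture estimate.  The split is a diagonal
    Gaussian likelihood whose per-class moments are fitted on reference
    tiles rendered from the palette.  The window posterior is the
    per-class fraction of pixel votes, i.e. the window's estimated
    composition.  No training involved.
    """

    TEXTURE_SIZES = (9, 3)

    def __init__(
        self,
        window: int = 16,
        scheme: ClassScheme | None = None,
        palette: dict[str, ClassTexture] | None = None,
        n_reference: int = 8,
        seed: int = 909090,
    ):
        self.scheme = scheme or default_scheme()
        self.palette = palette or DEFAULT_PALETTE
        self.window = window
        self.centers = np.array([self.palette[n].mean for n in self.scheme.names])
        self._i_pos = self.scheme.names.index("tc_pos")
        self._i_mac = self.scheme.names.index("macrophage")
        mus, sds = [], []
        for idx in (self._i_pos, self._i_mac):
            feats = []
            for r in range(n_reference):
                tile = generate_class_texture(
                    self.scheme.class_ids[idx], 64, seed + r, self.scheme, self.palette
                ).astype(np.float64)
                gray = tile.mean(axis=2)
                full = np.ones(gray.shape, bool)
                per_scale = [
                    _masked_local_std(gray, full, s)[0][8:-8, 8:-8].ravel()
                    for s in self.TEXTURE_SIZES
                ]
                feats.append(np.stack(per_scale, axis=1))
            f = np.concatenate(feats)
            mus.append(f.mean(axis=0))
            sds.append(np.maximum(f.std(axis=0), 1e-3))
        self._tex_mu = np.array(mus)  # (2 classes, 2 scales)
        self._tex_sd = np.array(sds)

    def pixel_votes(self, tiles: np.ndarray) -> np.ndarray:
        """Per-pixel class-index votes for (n, h, w, 3) uint8-scale tiles."""
        d2 = ((tiles[..., None, :] - self.centers[None, None, None]) ** 2).sum(axis=-1)
        d2[..., self._i_mac] = d2[..., self._i_pos]  # pool the brown pair
        votes = d2.argmin(axis=-1)
        brown = (votes == self._i_pos) | (votes == self._i_mac)
        gray = tiles.mean(axis=3)
        for i in range(len(tiles)):
            if not brown[i].any():
                continue
            feats = np.stack(
                [_masked_local_std(gray[i], brown[i], s)[0] for s in self.TEXTURE_SIZES],
                axis=-1,
            )
            z = (
                ((feats[..., None, :] - self._tex_mu) / self._tex_sd) ** 2
                + 2 * np.log(self._tex_sd)
            ).sum(axis=-1)
            pick = np.where(z[..., 0] <= z[..., 1], self._i_pos, self._i_mac)
            votes[i][brown[i]] = pick[brown[i]]
        return votes

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Vote-fraction posterior for NCHW float input in [-1, 1]."""
        tiles = (np.asarray(x, dtype=np.float64).transpose(0, 2, 3, 1) + 1.0) * 127.5
        votes = self.pixel_votes(tiles)
        k = len(self.centers)
        out = np.zeros((len(tiles), k))
        for j in range(k):
            out[:, j] = (votes == j).mean(axis=(1, 2))
        return out


# ---------------------------------------------------------------------------
# I/O

def write_probability_map(path, cmap: ClassProbabilityMap) -> None:
    """Store the posterior stack as a multi-channel float32 TIFF."""
    import tifffile

    tifffile.imwrite(str(path), cmap.probs.astype(np.float32))


def read_probability_map(path, tissue_mask: np.ndarray | None = None) -> ClassProbabilityMap:
    import tifffile

    probs = tifffile.imread(str(path)).astype(np.float64)
    tissue = np.isfinite(probs[..., 0]) if tissue_mask is None else tissue_mask
    return ClassProbabilityMap(probs=probs, tissue=tissue)
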