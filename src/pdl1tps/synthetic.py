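"""Synthetic stained-tissue slides with known ground truth.

No public PD-L1 NSCLC slide cohort exists, so the package ships a generator
that emulates the *statistical* structure the scoring pipeline relies on:

* eight region classes whose colors mimic IHC appearance — DAB-brown for
  PD-L1 positive classes, hematoxylin-blue for negative classes, pale pink
  for stroma/necrosis and near-white background;
* macrophages deliberately share the brown mean color of positive tumor
  cells and differ only in texture scale, preserving the hardest confusion
  pair of the real task;
* spatially intermixed class regions drawn as smoothed random blobs;
* a per-slide ground-truth label mask from which the true pixel-ratio TPS
  is computed exactly;
* simulated pathologist visual scores (truth plus clipped Gaussian noise)
  and simulated second-rater annotation masks with a controlled
  disagreement rate.

Everything is bit-reproducible under a fixed seed.  The generator makes no
attempt at photorealism: no nuclei, no scanner artifacts, no stain
variability beyond per-class Gaussian texture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classes import IGNORE_ID, ClassScheme, default_scheme

#: Mean luminance (0-255) above which a class texture is considered
#: background-like; the non_tissue palette is designed to exceed it.
BACKGROUND_LUMINANCE_THRESHOLD = 220.0


@dataclass(frozen=True)
class ClassTexture:
    """Per-class texture parameters: mean RGB, noise SD and correlation scale."""

    mean: tuple[float, float, float]
    sd: float
    sigma: float  # Gaussian correlation length of the noise, px


# DAB-brown for positive stain, hematoxylin-blue for negative, pale
# eosin-like tones for stroma/necrosis.  Macrophage shares the tc_pos mean
# color *and* noise amplitude and differs only in texture correlation
# length (smooth diffuse blotches vs fine stain granularity), so color
# statistics alone cannot separate the pair — a classifier must use
# texture, which preserves the hardest confusion of the real task.
DEFAULT_PALETTE: dict[str, ClassTexture] = {
    "tc_pos": ClassTexture((165.0, 110.0, 70.0), 12.0, 1.0),
    "tc_neg": ClassTexture((95.0, 105.0, 170.0), 12.0, 1.0),
    "lymph_pos": ClassTexture((130.0, 85.0, 55.0), 10.0, 1.0),
    "lymph_neg": ClassTexture((60.0, 70.0, 135.0), 10.0, 1.0),
    "macrophage": ClassTexture((165.0, 110.0, 70.0), 12.0, 6.0),
    "necrosis": ClassTexture((185.0, 160.0, 145.0), 14.0, 2.0),
    "stroma": ClassTexture((185.0, 150.0, 175.0), 10.0, 1.5),
    "non_tissue": ClassTexture((246.0, 245.0, 243.0), 3.0, 1.0),
}


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide.

    ``class_fractions`` maps class *names* to target areal fractions; they
    must sum to at most 1, the remainder being filled with ``non_tissue``.
    ``target_tps`` (fraction in [0, 1], optional) must be consistent with
    the tumor fractions: tc_pos / (tc_pos + tc_neg).
    """

    width: int
    height: int
    class_fractions: dict[str, float]
    seed: int
    target_tps: float | None = None
    blob_sigma: float = 24.0
    palette: dict[str, ClassTexture] = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    scheme: ClassScheme = field(default_factory=default_scheme)

    def validate(self) -> None:
        total = float(sum(self.class_fractions.values()))
        if total > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {total:.4f} > 1")
        for name, frac in self.class_fractions.items():
            if name not in self.scheme.names:
                raise ValueError(f"unknown class name in fractions: {name!r}")
            if frac < 0:
                raise ValueError(f"negative fraction for {name!r}")
        if self.target_tps is not None:
            if not 0.0 <= self.target_tps <= 1.0:
                raise ValueError("target_tps must be a fraction in [0, 1]")
            f_pos = self.class_fractions.get("tc_pos", 0.0)
            f_neg = self.class_fractions.get("tc_neg", 0.0)
            if f_pos + f_neg > 0:
                implied = f_pos / (f_pos + f_neg)
                if abs(implied - self.target_tps) > 0.02:
                    raise ValueError(
                        f"target_tps {self.target_tps:.3f} inconsistent with tumor "
                        f"fractions (implied {implied:.3f})"
                    )


@dataclass
class SlideGroundTruth:
    """Ground truth of a synthetic slide: label mask and exact pixel-ratio TPS.

    ``true_tps`` is a percentage in [0, 100], or ``None`` when the mask
    contains no tumor pixels at all (the no-tumor flag).
    """

    label_mask: np.ndarray
    true_tps: float | None

    @property
    def no_tumor(self) -> bool:
        return self.true_tps is None


def _correlated_noise(shape, sd, sigma, rng):
    """Zero-mean Gaussian field with correlation length sigma and exact SD."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    s = noise.std()
    if s > 0:
        noise *= sd / s
    return noise


def _render_texture(texture: ClassTexture, shape, rng) -> np.ndarray:
    img = np.empty(shape + (3,), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = texture.mean[ch] + _correlated_noise(shape, texture.sd, texture.sigma, rng)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_class_texture(
    class_id: int,
    size: int,
    seed: int,
    scheme: ClassScheme | None = None,
    palette: dict[str, ClassTexture] | None = None,
) -> np.ndarray:
    """Render a ``size`` × ``size`` RGB texture tile for one class.

    Deterministic for a fixed ``(class_id, size, seed)`` triple.
    """
    scheme = scheme or default_scheme()
    palette = palette or DEFAULT_PALETTE
    if class_id not in scheme:
        raise ValueError(f"unknown class ID: {class_id}")
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    rng = np.random.default_rng([seed, class_id, size])
    return _render_texture(palette[scheme.name_of(class_id)], (size, size), rng)


def generate_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, SlideGroundTruth]:
    """Generate a synthetic RGB slide and its ground truth.

    Class regions are carved sequentially from smoothed random fields: for
    each class, the target number of still-unassigned pixels with the
    highest field value is claimed, which yields blob-shaped, spatially
    intermixed regions whose realized areal fractions match the spec to
    rounding error.  Whatever remains becomes ``non_tissue``.  The returned
    ``true_tps`` is computed from the *realized* mask, never from the
    target.
    """
    spec.validate()
    h, w = spec.height, spec.width
    scheme = spec.scheme
    rng = np.random.default_rng(spec.seed)
    n_total = h * w

    mask = np.full((h, w), scheme.non_tissue, dtype=np.int32)
    unassigned = np.ones((h, w), dtype=bool)
    # Iterate in scheme order for reproducibility independent of dict order.
    for name in scheme.names:
        frac = spec.class_fractions.get(name, 0.0)
        if frac <= 0 or name == "non_tissue":
            continue
        n_want = int(round(frac * n_total))
        field_k = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.blob_sigma)
        flat_idx = np.flatnonzero(unassigned.ravel())
        n_take = min(n_want, flat_idx.size)
        if n_take == 0:
            continue
        order = np.argpartition(-field_k.ravel()[flat_idx], n_take - 1)[:n_take]
        chosen = flat_idx[order]
        mask.ravel()[chosen] = scheme.id_of(name)
        unassigned.ravel()[chosen] = False

    img = np.empty((h, w, 3), dtype=np.uint8)
    for class_id in np.unique(mask):
        tex = _render_texture(palette_for(spec, class_id), (h, w), rng)
        sel = mask == class_id
        img[sel] = tex[sel]

    truth = SlideGroundTruth(label_mask=mask, true_tps=_true_tps(mask, scheme))
    return img, truth


def palette_for(spec: SyntheticSlideSpec, class_id: int) -> ClassTexture:
    return spec.palette[spec.scheme.name_of(class_id)]


def _true_tps(mask: np.ndarray, scheme: ClassScheme) -> float | None:
    n_pos = int(np.count_nonzero(mask == scheme.tc_pos))
    n_neg = int(np.count_nonzero(mask == scheme.tc_neg))
    if n_pos + n_neg == 0:
        return None
    return 100.0 * n_pos / (n_pos + n_neg)


def simulate_visual_scores(
    true_tps: float, n_raters: int, noise_sd: float, seed: int
) -> list[float]:
    """Simulate pathologist visual TPS scores for one slide.

    Each score is the true TPS plus independent Gaussian rater noise on the
    percentage scale, clipped to [0, 100].
    """
    if true_tps is None:
        raise ValueError("cannot simulate visual scores for a no-tumor slide")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scores = true_tps + rng.normal(0.0, noise_sd, size=n_raters) if noise_sd > 0 else np.full(
        n_raters, float(true_tps)
    )
    return [float(s) for s in np.clip(scores, 0.0, 100.0)]


def generate_rater_annotations(
    truth: SlideGroundTruth,
    disagreement_rate: float,
    seed: int,
    scheme: ClassScheme | None = None,
) -> np.ndarray:
    """Emulate a second pathologist's annotation of a slide.

    A fraction ``disagreement_rate`` of the annotated (non-ignore) pixels is
    relabeled to a uniformly random *different* class of the scheme; the
    realized disagreement fraction matches the request to rounding error.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must be in [0, 1]")
    scheme = scheme or default_scheme()
    mask = truth.label_mask.copy()
    annotated = np.flatnonzero(mask.ravel() != IGNORE_ID)
    n_flip = int(round(disagreement_rate * annotated.size))
    if n_flip == 0:
        return mask
    rng = np.random.default_rng(seed)
    flip = rng.choice(annotated, size=n_flip, replace=False)
    current = mask.ravel()[flip]
    ids = np.asarray(scheme.class_ids)
    # Draw a uniform different class: offset by 1..K-1 positions in ID order.
    pos = np.searchsorted(ids, current)
    offset = rng.integers(1, len(ids), size=n_flip)
    mask.ravel()[flip] = ids[(pos + offset) % len(ids)]
    return mask


def slide_spec_for_tps(
    target_tps_percent: float,
    tumor_fraction: float = 0.4,
    other_fractions: dict[str, float] | None = None,
    *,
    width: int = 256,
    height: int = 256,
    seed: int = 0,
    blob_sigma: float = 24.0,
) -> SyntheticSlideSpec:
    """Convenience constructor: split ``tumor_fraction`` to hit a target TPS.

    ``other_fractions`` assigns areal fractions to non-tumor classes
    (default: modest lymphocyte/stroma/macrophage content); the remainder is
    background.
    """
    if not 0.0 <= target_tps_percent <= 100.0:
        raise ValueError("target_tps_percent must be in [0, 100]")
    f = target_tps_percent / 100.0
    fractions = {
        "tc_pos": tumor_fraction * f,
        "tc_neg": tumor_fraction * (1.0 - f),
    }
    if other_fractions is None:
        other_fractions = {"lymph_neg": 0.1, "stroma": 0.15, "macrophage": 0.05}
    fractions.update(other_fractions)
    return SyntheticSlideSpec(
        width=width,
        height=height,
        class_fractions=fractions,
        target_tps=f,
        seed=seed,
        blob_sigma=blob_sigma,
    )


# ---------------------------------------------------------------------------
# Disk I/O (PNG/TIFF slides and masks, CSV score tables)

def write_slide(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), image)


def read_slide(path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(str(path))
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    return img


def write_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    if mask.max(initial=0) > 255:
        raise ValueError("mask IDs exceed uint8 range")
    iio.imwrite(str(path), mask.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    mask = iio.imread(str(path))
    if mask.ndim != 2:
        raise ValueError(f"label mask must be single-channel, got shape {mask.shape}")
    return mask.astype(np.int32)


def write_truth_table(records: list[dict], path) -> None:
    """Write per-slide ground truth and simulated rater scores as CSV.

    Each record needs ``slide_id`` and ``true_tps`` (None for no-tumor
    slides) plus any number of ``rater_*`` columns.
    """
    import pandas as pd

    pd.DataFrame.from_records(records).to_csv(path, index=False)


def make_study(
    n_slides: int,
    seed: int,
    *,
    width: int = 256,
    height: int = 256,
    n_raters: int = 3,
    rater_noise_sd: float = 5.0,
    tps_values: list[float] | None = None,
    blob_sigma: float = 24.0,
):
    """Generate a small synthetic scoring study.

    Returns a list of ``(slide_id, image, truth, visual_scores)`` tuples
    with slide-level TPS values spread over [0, 100] (evenly spaced by
    default, mirroring a cohort selected across the score range).
    """
    if tps_values is None:
        tps_values = list(np.linspace(2.0, 98.0, n_slides))
    if len(tps_values) != n_slides:
        raise ValueError("tps_values length must equal n_slides")
    rng = np.random.default_rng(seed)
    out = []
    for i, tps in enumerate(tps_values):
        spec = slide_spec_for_tps(
            float(tps),
            width=width,
            height=height,
            seed=int(rng.integers(2**31 - 1)),
            blob_sigma=blob_sigma,
        )
        img, truth = generate_slide(spec)
        if truth.no_tumor:  # pragma: no cover - tumor_fraction > 0 above
            warnings.warn(f"slide {i}: no tumor realized")
            scores = None
        else:
            scores = simulate_visual_scores(
                truth.true_tps, n_raters, rater_noise_sd, seed=int(rng.integers(2**31 - 1))
            )
        out.append((f"slide_{i:03d}", img, truth, scores))
    return out
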