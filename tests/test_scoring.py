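"""Sliding-window prediction, pixel classification and TPS computation."""

import numpy as np
import pytest

from pdl1tps.classes import default_scheme
from pdl1tps.scoring import (ClassProbabilityMap, OracleClassifier,
                             classify_pixels, compute_tps, pdl1_status,
                             predict_map, score_slide)
from pdl1tps.synthetic import SyntheticSlideSpec, generate_slide
from pdl1tps.tissue import detect_tissue

SCHEME = default_scheme()


class TestComputeTps:
    def test_non_tumor_pixels_excluded(self):
        mask = np.concatenate(
            [
                np.full(30, SCHEME.tc_pos),
                np.full(70, SCHEME.tc_neg),
                np.full(500, SCHEME.id_of("stroma")),
            ]
        ).reshape(20, 30)
        result = compute_tps(mask, SCHEME)
        assert result.tps == pytest.approx(30.0)
        assert (result.n_pos_pixels, result.n_neg_pixels) == (30, 70)

    def test_all_positive_mask_is_100(self):
        mask = np.full((10, 10), SCHEME.tc_pos)
        assert compute_tps(mask, SCHEME).tps == 100.0

    def test_no_tumor_is_undefined_not_zero(self):
        mask = np.full((10, 10), SCHEME.id_of("stroma"))
        result = compute_tps(mask, SCHEME)
        assert result.tps is None
        assert result.status == "undefined"

    def test_unknown_class_ids_rejected(self):
        mask = np.full((5, 5), 42)
        with pytest.raises(ValueError, match="42"):
            compute_tps(mask, SCHEME)

    def test_invariant_to_non_tumor_dilution(self, rng):
        base = rng.choice([SCHEME.tc_pos, SCHEME.tc_neg], size=400)
        tps0 = compute_tps(base.reshape(20, 20), SCHEME).tps
        for filler in (SCHEME.id_of("stroma"), SCHEME.id_of("necrosis"), 0):
            diluted = np.concatenate([base, np.full(1000, filler)])
            assert compute_tps(diluted.reshape(-1, 20), SCHEME).tps == tps0

    def test_truth_mask_roundtrip_exact(self, small_slide):
        """Scoring the generator's own label mask reproduces the stored
        ground-truth TPS exactly (integer pixel arithmetic)."""
        _, truth = small_slide
        assert compute_tps(truth.label_mask, SCHEME).tps == truth.true_tps


class TestPdl1Status:
    @pytest.mark.parametrize(
        "tps, expected",
        [(24.9, "negative"), (25.0, "positive"), (100.0, "positive"),
         (0.0, "negative"), (None, "undefined")],
    )
    def test_cutoff_convention(self, tps, expected):
        assert pdl1_status(tps, cutoff=25.0) == expected


class TestClassifyPixels:
    def test_certain_map_gives_uniform_mask(self):
        probs = np.zeros((6, 6, 8))
        probs[..., 0] = 1.0  # column 0 = tc_pos
        cmap = ClassProbabilityMap(probs=probs, tissue=np.ones((6, 6), bool))
        assert (classify_pixels(cmap, SCHEME) == SCHEME.tc_pos).all()

    def test_tie_goes_to_lowest_class_id(self):
        probs = np.zeros((2, 2, 8))
        probs[..., 2] = 0.5
        probs[..., 5] = 0.5
        cmap = ClassProbabilityMap(probs=probs, tissue=np.ones((2, 2), bool))
        assert (classify_pixels(cmap, SCHEME) == SCHEME.class_ids[2]).all()

    def test_matches_bruteforce_argmax(self, rng):
        probs = rng.dirichlet(np.ones(8), size=(10, 10))
        cmap = ClassProbabilityMap(probs=probs, tissue=np.ones((10, 10), bool))
        got = classify_pixels(cmap, SCHEME)
        for i in range(10):
            for j in range(10):
                best = max(range(8), key=lambda k: (probs[i, j, k], -k))
                assert got[i, j] == SCHEME.class_ids[best]

    def test_non_tissue_pixels_are_ignore(self):
        probs = np.full((4, 4, 8), np.nan)
        tissue = np.zeros((4, 4), bool)
        cmap = ClassProbabilityMap(probs=probs, tissue=tissue)
        assert (classify_pixels(cmap, SCHEME) == 0).all()


class TestPredictMap:
    def test_all_background_slide_entirely_undefined(self):
        image = np.full((64, 64, 3), 250, dtype=np.uint8)
        tissue = np.zeros((64, 64), bool)
        oracle = OracleClassifier(window=16)
        cmap = predict_map(image, tissue, oracle, window=16, stride=16)
        assert np.isnan(cmap.probs).all()

    def test_probabilities_sum_to_one_on_tissue(self, small_slide):
        image, truth = small_slide
        tissue = truth.label_mask != SCHEME.non_tissue
        oracle = OracleClassifier(window=16)
        cmap = predict_map(image, tissue, oracle, window=16, stride=8)
        sums = cmap.probs[tissue].sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-5)
        assert np.isnan(cmap.probs[~tissue]).all()

    def test_constant_positive_slide_recovered(self):
        """A slide consisting entirely of positive tumor texture is
        classified tc_pos on >= 99% of its pixels."""
        spec = SyntheticSlideSpec(128, 128, {"tc_pos": 1.0}, seed=23)
        image, truth = generate_slide(spec)
        tissue = np.ones(truth.label_mask.shape, bool)
        oracle = OracleClassifier(window=16)
        cmap = predict_map(image, tissue, oracle, window=16, stride=8)
        mask = classify_pixels(cmap, SCHEME)
        assert (mask == SCHEME.tc_pos).mean() >= 0.99

    def test_small_image_padded_with_warning(self):
        image = np.full((20, 20, 3), 120, dtype=np.uint8)
        tissue = np.ones((20, 20), bool)
        oracle = OracleClassifier(window=32)
        with pytest.warns(UserWarning, match="padding"):
            cmap = predict_map(image, tissue, oracle, window=32, stride=32)
        assert cmap.probs.shape == (20, 20, 8)

    def test_stride_larger_than_window_rejected(self, small_slide):
        image, truth = small_slide
        with pytest.raises(ValueError):
            predict_map(image, truth.label_mask != 8, OracleClassifier(), window=16, stride=32)

    def test_rotation_equivariant_for_disjoint_tiling(self):
        """With stride == window (non-overlapping tiling) on a size-aligned
        slide, rotate-then-predict equals predict-then-rotate."""
        spec = SyntheticSlideSpec(
            128, 128, {"tc_pos": 0.3, "tc_neg": 0.3, "stroma": 0.2}, seed=17
        )
        image, truth = generate_slide(spec)
        tissue = truth.label_mask != SCHEME.non_tissue
        oracle = OracleClassifier(window=32)
        direct = predict_map(
            np.ascontiguousarray(np.rot90(image)), np.rot90(tissue), oracle,
            window=32, stride=32,
        )
        rotated = predict_map(image, tissue, oracle, window=32, stride=32)
        assert np.allclose(
            direct.probs, np.rot90(rotated.probs), atol=1e-6, equal_nan=True
        )


class TestEndToEndOracle:
    def test_oracle_pipeline_recovers_true_tps(self):
        """Tissue detection + oracle sliding-window scoring recovers the
        ground-truth TPS within 2 percentage points."""
        from pdl1tps.synthetic import slide_spec_for_tps

        oracle = OracleClassifier(window=16)
        for i, tps in enumerate([10.0, 45.0, 85.0]):
            spec = slide_spec_for_tps(tps, width=384, height=384, seed=100 + i,
                                      blob_sigma=36.0)
            image, truth = generate_slide(spec)
            tissue = detect_tissue(image)
            result, _ = score_slide(image, tissue, oracle, SCHEME, window=16, stride=8)
            assert result.tps == pytest.approx(truth.true_tps, abs=2.0)
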