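"""Object-based overlap ratios: hand-computed cases, bounds, monotonicity,
and recovery of designed coincidence on synthetic fields."""

import numpy as np
import pytest

from golgikin.colocalization import (
    bootstrap_median_ci,
    colocalization_profile,
    overlap_ratio,
)
from golgikin.exceptions import DegenerateObjectError, InvalidParameterError
from golgikin.preprocess import subtract_background
from golgikin.segmentation import PunctumObject


def _punctum(pixels, intensities, img_shape=(8, 8)):
    img = np.zeros(img_shape)
    pix = np.array(pixels)
    img[pix[:, 0], pix[:, 1]] = intensities
    obj = PunctumObject(
        id=0,
        pixels=pix,
        centroid=tuple(pix.mean(axis=0)),
        area=len(pix),
        integrated_intensity=float(np.sum(intensities)),
    )
    return obj, img


class TestOverlapRatio:
    def test_fully_inside_is_one(self):
        obj, img = _punctum([(2, 2), (2, 3)], [10.0, 20.0])
        mask = np.ones((8, 8), dtype=bool)
        assert overlap_ratio(obj, mask, img) == 1.0

    def test_disjoint_is_zero(self):
        obj, img = _punctum([(2, 2), (2, 3)], [10.0, 20.0])
        mask = np.zeros((8, 8), dtype=bool)
        assert overlap_ratio(obj, mask, img) == 0.0

    def test_hand_computed_intensity_vs_pixel_mode(self):
        # punctum pixels (30, 10); only the bright one inside the mask
        obj, img = _punctum([(3, 3), (3, 4)], [30.0, 10.0])
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 3] = True
        assert overlap_ratio(obj, mask, img, mode="intensity") == pytest.approx(0.75)
        assert overlap_ratio(obj, mask, img, mode="pixel") == pytest.approx(0.5)

    def test_zero_intensity_punctum_raises(self):
        obj, img = _punctum([(2, 2)], [0.0])
        with pytest.raises(DegenerateObjectError):
            overlap_ratio(obj, np.ones((8, 8), dtype=bool), img)

    def test_unknown_mode_rejected(self):
        obj, img = _punctum([(2, 2)], [5.0])
        with pytest.raises(InvalidParameterError):
            overlap_ratio(obj, np.ones((8, 8), dtype=bool), img, mode="banana")

    def test_enlarging_mask_never_decreases_ratio(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pix = [(int(r), int(c)) for r, c in rng.integers(0, 8, size=(4, 2))]
            pix = list(dict.fromkeys(pix))
            obj, img = _punctum(pix, rng.uniform(1, 100, len(pix)))
            mask = rng.random((8, 8)) < 0.3
            bigger = mask | (rng.random((8, 8)) < 0.3)
            assert overlap_ratio(obj, bigger, img) >= overlap_ratio(obj, mask, img)


class TestColocalizationProfile:
    def _preprocessed(self, image):
        return np.stack([subtract_background(ch) for ch in image])

    def test_fully_coincident_median_is_one(self, clean_snapshot):
        image, _ = clean_snapshot
        result = colocalization_profile([self._preprocessed(image)], seed=0)
        assert result.median == 1.0
        assert result.n_puncta == 10

    def test_channel_swap_keeps_coincident_median(self, clean_snapshot):
        image, _ = clean_snapshot
        swapped = self._preprocessed(image)[::-1]
        result = colocalization_profile([swapped], seed=0)
        assert result.median == 1.0

    def test_no_coincidence_median_zero(self):
        from golgikin.synthetic import SimConfig, noise_free, simulate_coloc_snapshot

        cfg = noise_free(SimConfig(image_shape=(160, 160), seed=8))
        image, _ = simulate_coloc_snapshot(cfg, 0, 12, 12)
        result = colocalization_profile([self._preprocessed(image)], seed=0)
        assert result.median == 0.0
        assert result.n_puncta == 12

    def test_ratios_bounded_and_ci_brackets_median(self, clean_snapshot):
        image, _ = clean_snapshot
        result = colocalization_profile([self._preprocessed(image)], seed=1)
        assert result.per_punctum["overlap_ratio"].between(0, 1).all()
        lo, hi = result.ci95
        assert lo <= result.median <= hi

    def test_bootstrap_deterministic_under_seed(self):
        vals = np.random.default_rng(0).random(100)
        assert bootstrap_median_ci(vals, seed=5) == bootstrap_median_ci(vals, seed=5)
        assert bootstrap_median_ci(vals, seed=5) != bootstrap_median_ci(vals, seed=6)

    def test_empty_input_warns_not_fails(self):
        blank = np.zeros((2, 32, 32))
        with pytest.warns(UserWarning, match="no puncta"):
            result = colocalization_profile([blank], seed=0)
        assert result.n_puncta == 0
        assert np.isnan(result.median)
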