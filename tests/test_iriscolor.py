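"""CIELAB conversion, robust normalization and the composite iris index."""

import numpy as np
import pytest

from iridens.errors import (
    CohortTooSmall,
    DegenerateRegion,
    NotColorImage,
    ZeroIQR,
)
from iridens.iriscolor import (
    IrisLabSummary,
    classify_pigmentation,
    fit_cohort_normalization,
    iris_color_index,
    normalize_component,
    polygon_roi_mask,
    rgb_to_cielab,
    score_cohort,
    summarize_iris_roi,
)
from iridens.synthetic import make_iris_image


def _solid(rgb, size=8):
    img = np.zeros((size, size, 3), dtype=np.uint8)
    img[...] = rgb
    return img


def _srgb_gray_lab_oracle(v8: int) -> float:
    """Independent closed-form L* of an sRGB gray level: linearize the
    transfer function, then apply the Lab lightness function (for grays
    X/Xn = Y/Yn = Z/Zn, so a* = b* = 0)."""
    s = v8 / 255.0
    lin = s / 12.92 if s <= 0.04045 else ((s + 0.055) / 1.055) ** 2.4
    eps = (6.0 / 29.0) ** 3
    f = lin ** (1.0 / 3.0) if lin > eps else lin / (3 * (6 / 29) ** 2) + 4.0 / 29.0
    return 116.0 * f - 16.0


class TestRgbToCielab:
    def test_white_maps_to_achromatic_100(self):
        lab = rgb_to_cielab(_solid((255, 255, 255)))
        assert np.allclose(lab[0, 0], [100.0, 0.0, 0.0], atol=1e-6)

    def test_black_maps_to_origin(self):
        lab = rgb_to_cielab(_solid((0, 0, 0)))
        assert np.allclose(lab[0, 0], [0.0, 0.0, 0.0], atol=1e-6)

    @pytest.mark.parametrize("gray", [119, 30, 200])
    def test_gray_matches_closed_form(self, gray):
        lab = rgb_to_cielab(_solid((gray, gray, gray)))
        assert lab[0, 0, 0] == pytest.approx(_srgb_gray_lab_oracle(gray), abs=1e-6)
        assert abs(lab[0, 0, 1]) < 1e-6
        assert abs(lab[0, 0, 2]) < 1e-6

    def test_agrees_with_skimage_on_random_colors(self):
        """Independent library route agrees to within the small white-point
        rounding difference (<0.02 Lab units)."""
        from skimage import color as skcolor

        rng = np.random.default_rng(6)
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        assert np.allclose(rgb_to_cielab(img), skcolor.rgb2lab(img), atol=0.02)

    def test_grayscale_input_rejected(self):
        with pytest.raises(NotColorImage):
            rgb_to_cielab(np.zeros((8, 8), dtype=np.uint8))


class TestRoiSummary:
    def test_uniform_patch(self):
        lab = rgb_to_cielab(_solid((120, 80, 60)))
        roi = np.ones((8, 8), dtype=bool)
        s = summarize_iris_roi(lab, roi, "e1")
        assert np.allclose([s.L, s.a, s.b], lab[0, 0])

    def test_two_pixel_mean(self):
        lab = np.zeros((1, 2, 3))
        lab[0, 0, 0], lab[0, 1, 0] = 40.0, 60.0
        s = summarize_iris_roi(lab, np.ones((1, 2), bool), "e1")
        assert s.L == pytest.approx(50.0)

    def test_median_statistic_option(self):
        lab = np.zeros((1, 3, 3))
        lab[0, :, 0] = [10.0, 20.0, 90.0]
        s = summarize_iris_roi(lab, np.ones((1, 3), bool), "e1", statistic="median")
        assert s.L == pytest.approx(20.0)

    def test_synthetic_iris_matches_recorded_truth(self):
        rgb, roi, truth = make_iris_image(0.4, seed=3)
        s = summarize_iris_roi(rgb_to_cielab(rgb), roi, "e1")
        assert s.L == pytest.approx(truth.lab_mean[0], abs=0.5)
        assert s.a == pytest.approx(truth.lab_mean[1], abs=0.5)
        assert s.b == pytest.approx(truth.lab_mean[2], abs=0.5)

    def test_empty_roi_raises(self):
        lab = rgb_to_cielab(_solid((10, 10, 10)))
        with pytest.raises(DegenerateRegion):
            summarize_iris_roi(lab, np.zeros((8, 8), bool), "e1")


def _summaries(values):
    """Cohort whose three components all take the given values."""
    return [
        IrisLabSummary(eye_id=f"e{i}", L=v, a=v, b=v) for i, v in enumerate(values)
    ]


class TestNormalization:
    def test_median_and_iqr_of_small_set(self):
        norm = fit_cohort_normalization(_summaries([1, 2, 3, 4, 5]))
        assert norm.median_L == 3.0
        assert norm.iqr_L == pytest.approx(2.0)  # linear-interpolation quantiles

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(50, 8, size=25)
        norm = fit_cohort_normalization(_summaries(vals))
        s = np.sort(vals)

        def quantile(q):  # linear interpolation between order statistics
            pos = q * (len(s) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert norm.median_L == pytest.approx(quantile(0.5), abs=1e-12)
        assert norm.iqr_L == pytest.approx(quantile(0.75) - quantile(0.25), abs=1e-12)

    def test_identical_cohort_raises_zero_iqr(self):
        with pytest.raises(ZeroIQR):
            fit_cohort_normalization(_summaries([5, 5, 5, 5]))

    def test_small_cohort_rejected(self):
        with pytest.raises(CohortTooSmall):
            fit_cohort_normalization(_summaries([1, 2, 3]))

    @pytest.mark.parametrize(
        "x,median,iqr,expected", [(3, 3, 2, 0.0), (5, 3, 2, 1.0), (1, 3, 2, -1.0)]
    )
    def test_normalize_component(self, x, median, iqr, expected):
        assert normalize_component(x, median, iqr) == pytest.approx(expected)

    def test_zero_iqr_component(self):
        with pytest.raises(ZeroIQR):
            normalize_component(1.0, 0.0, 0.0)


class TestIndexAndClass:
    @pytest.mark.parametrize(
        "Ln,an,bn,expected",
        [(0, 0, 0, 0.0), (1, 0, 0, -1.0), (-1, 1, 1, 3.0), (0.5, 0.25, 0.25, 0.0)],
    )
    def test_composite_index(self, Ln, an, bn, expected):
        assert iris_color_index(Ln, an, bn) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "value,expected",
        [(-0.5, "light"), (2.0, "dark"), (0.0, "indeterminate"), (-1e-9, "light")],
    )
    def test_sign_rule(self, value, expected):
        assert classify_pigmentation(value) == expected


class TestCohortScoring:
    def _gradient_cohort(self, n=11, noise=0.0, seed=0):
        summaries = []
        for i, level in enumerate(np.linspace(0, 1, n)):
            rgb, roi, _ = make_iris_image(level, seed=seed + i, noise_sd=noise)
            summaries.append(
                summarize_iris_roi(rgb_to_cielab(rgb), roi, f"e{i:02d}")
            )
        return summaries

    def test_self_centering_after_normalization(self):
        records, _ = score_cohort(self._gradient_cohort(noise=1.0))
        for comp in ("Ln", "an", "bn"):
            vals = np.array([getattr(r, comp) for r in records])
            assert np.median(vals) == pytest.approx(0.0, abs=1e-9)
            q1, q3 = np.percentile(vals, [25, 75])
            assert q3 - q1 == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_gradient_preserves_rank_order(self):
        records, _ = score_cohort(self._gradient_cohort(noise=0.0))
        scores = [r.iris_color for r in records]
        assert scores == sorted(scores)

    def test_directional_coherence_under_fixed_norm(self):
        summaries = self._gradient_cohort(noise=1.0)
        _, norm = score_cohort(summaries)
        s = summaries[5]
        base = score_cohort([s], norm=norm)[0][0].iris_color
        brighter = IrisLabSummary(s.eye_id, s.L + 5.0, s.a, s.b)
        redder = IrisLabSummary(s.eye_id, s.L, s.a + 5.0, s.b)
        yellower = IrisLabSummary(s.eye_id, s.L, s.a, s.b + 5.0)
        assert score_cohort([brighter], norm=norm)[0][0].iris_color < base
        assert score_cohort([redder], norm=norm)[0][0].iris_color > base
        assert score_cohort([yellower], norm=norm)[0][0].iris_color > base

    def test_cohort_edit_changes_all_scores(self):
        """The index is cohort-relative: appending one extreme eye must
        change the recomputed normalized values of existing eyes."""
        summaries = self._gradient_cohort(noise=1.0)
        before, _ = score_cohort(summaries)
        extreme = IrisLabSummary("extreme", L=95.0, a=-20.0, b=-40.0)
        after, _ = score_cohort(summaries + [extreme])
        assert before[0].iris_color != after[0].iris_color


def test_polygon_roi_mask_square():
    mask = polygon_roi_mask((20, 20), [(2, 2), (2, 10), (10, 10), (10, 2)])
    assert mask[5, 5]
    assert not mask[15, 15]
    assert mask.sum() > 40
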