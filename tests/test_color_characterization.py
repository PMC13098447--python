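"""Color characterization tests, including brute-force oracles for the
Otsu threshold and median-cut quantization conventions."""

import numpy as np
import pytest

from fibrouq.imaging_io import BinaryMask, GrayImage, RasterImage
from fibrouq.color_characterization import (
    SIRIUS_RED_DEFAULT_STAINS,
    StainMatrix,
    cohort_color_table,
    deconvolve_stains,
    median_cut,
    otsu_threshold,
    primary_color,
    rgb_to_cielab,
    tissue_mask,
    to_grayscale,
    whiten_background,
)

# ---------------------------------------------------------------- oracles


def otsu_brute_force(gray: np.ndarray) -> int:
    """Exhaustive 256-way search maximizing between-class variance of {<=t},{>t}."""
    vals = gray.ravel().astype(np.float64)
    best_t, best_v = None, -1.0
    for t in range(256):
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def median_cut_brute_force(pixels: np.ndarray, k: int):
    """Independent list-of-lists re-implementation of the stated split/tie rules."""
    boxes = [[tuple(p) for p in pixels]]
    n_distinct = len({tuple(p) for p in pixels})
    while len(boxes) < min(k, n_distinct):
        scores = []
        for box in boxes:
            rngs = [max(p[c] for p in box) - min(p[c] for p in box) for c in range(3)]
            scores.append(max(rngs))
        if max(scores) == 0:
            break
        bi = scores.index(max(scores))
        box = boxes[bi]
        rngs = [max(p[c] for p in box) - min(p[c] for p in box) for c in range(3)]
        ch = rngs.index(max(rngs))
        med = float(np.median([p[ch] for p in box]))
        lower = [p for p in box if p[ch] <= med]
        upper = [p for p in box if p[ch] > med]
        if not upper:
            lower = [p for p in box if p[ch] < med]
            upper = [p for p in box if p[ch] >= med]
        boxes[bi : bi + 1] = [lower, upper]
    entries = [
        (tuple(int(round(np.mean([p[c] for p in box]))) for c in range(3)), len(box))
        for box in boxes
    ]
    entries.sort(key=lambda e: -e[1])
    return entries


def cielab_closed_form(rgb):
    """Direct CIE formulas: sRGB -> linear -> XYZ (D65) -> L*a*b*."""
    c = np.asarray(rgb, dtype=np.float64) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    f = xyz / white
    eps, kappa = 216 / 24389, 24389 / 27
    fx = np.where(f > eps, np.cbrt(f), (kappa * f + 16) / 116)
    L = 116 * fx[1] - 16
    return (L, 500 * (fx[0] - fx[1]), 200 * (fx[1] - fx[2]))


# ----------------------------------------------------------------- tests


class TestGrayscale:
    @pytest.mark.parametrize("rgb,expected", [((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 100, 100), 100)])
    def test_fixed_points(self, rgb, expected):
        img = RasterImage(np.full((2, 2, 3), rgb, dtype=np.uint8))
        assert np.all(to_grayscale(img).pixels == expected)

    def test_bt601_weights(self):
        img = RasterImage(np.array([[[200, 50, 10]]], dtype=np.uint8))
        expected = round(0.299 * 200 + 0.587 * 50 + 0.114 * 10)
        assert to_grayscale(img).pixels[0, 0] == expected


class TestOtsu:
    def test_bimodal_smallest_maximizer(self):
        # 100 px at 50 and 100 px at 200: all t in [50, 199] tie; smallest wins
        gray = GrayImage(np.repeat([50, 200], 100).reshape(10, 20).astype(np.uint8))
        assert otsu_threshold(gray) == 50

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(GrayImage(np.full((8, 8), 42, dtype=np.uint8)))

    def test_matches_exhaustive_search_on_random_images(self, rng):
        for _ in range(100):
            arr = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            if len(np.unique(arr)) < 2:
                continue
            assert otsu_threshold(GrayImage(arr)) == otsu_brute_force(arr)

    def test_agrees_with_skimage_class_separation(self, rng):
        # skimage's threshold is also inclusive-below (foreground = image > t);
        # both must induce the same partition of the sample
        from skimage.filters import threshold_otsu

        arr = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        t = otsu_threshold(GrayImage(arr))
        t_sk = threshold_otsu(arr)
        assert np.array_equal(arr <= t, arr <= t_sk)


class TestTissueMaskAndWhitening:
    def test_threshold_boundary_is_tissue(self):
        gray = GrayImage(np.array([[100, 101]], dtype=np.uint8))
        m = tissue_mask(gray, 100)
        assert m.pixels[0, 0] and not m.pixels[0, 1]

    def test_whiten_replaces_exactly_background(self, rng):
        img = RasterImage(rng.integers(0, 200, size=(4, 4, 3), dtype=np.uint8))
        mask = BinaryMask(np.indices((4, 4)).sum(axis=0) % 2 == 0)
        out = whiten_background(img, mask)
        assert np.all(out.pixels[~mask.pixels] == 255)
        assert np.array_equal(out.pixels[mask.pixels], img.pixels[mask.pixels])

    def test_shape_mismatch_raises(self, rng):
        img = RasterImage(rng.integers(0, 255, size=(4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            whiten_background(img, BinaryMask(np.zeros((3, 3), dtype=bool)))


class TestMedianCut:
    def test_identical_pixels_single_bucket(self):
        entries = median_cut([(10, 20, 30)] * 10, k=3)
        assert len(entries) == 1
        assert entries[0].rgb == (10, 20, 30) and entries[0].count == 10

    def test_two_separable_clusters(self):
        px = [(0, 0, 0)] * 5 + [(255, 255, 255)] * 5
        entries = median_cut(px, k=2)
        assert sorted(e.rgb for e in entries) == [(0, 0, 0), (255, 255, 255)]
        assert all(e.count == 5 for e in entries)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            median_cut([], k=2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 65))
            px = rng.integers(0, 256, size=(n, 3))
            k = int(rng.integers(1, 6))
            got = [(e.rgb, e.count) for e in median_cut(px, k)]
            expected = median_cut_brute_force(px, k)
            assert sorted(got) == sorted(expected)
            # counts partition the input
            assert sum(c for _, c in got) == n

    def test_representative_within_bucket_bounds(self, rng):
        px = rng.integers(0, 256, size=(200, 3))
        for e in median_cut(px, k=4):
            assert all(0 <= v <= 255 for v in e.rgb)


class TestCielab:
    def test_white_point(self):
        L, a, b = rgb_to_cielab((255, 255, 255))
        assert abs(L - 100.0) < 0.01 and abs(a) < 0.01 and abs(b) < 0.01

    def test_black(self):
        assert np.allclose(rgb_to_cielab((0, 0, 0)), (0, 0, 0), atol=1e-6)

    @pytest.mark.parametrize("rgb", [(255, 0, 0), (12, 200, 98), (180, 60, 60)])
    def test_matches_closed_form(self, rgb):
        assert np.allclose(rgb_to_cielab(rgb), cielab_closed_form(rgb), atol=0.1)

    def test_monotone_lightness_along_gray_axis(self):
        Ls = [rgb_to_cielab((g, g, g))[0] for g in range(0, 256, 15)]
        assert all(a < b for a, b in zip(Ls, Ls[1:]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rgb_to_cielab((300, 0, 0))


class TestPrimaryColor:
    @staticmethod
    def _image(colors_and_counts, shape):
        px = np.concatenate([np.tile(np.array(c, np.uint8), (n, 1)) for c, n in colors_and_counts])
        return RasterImage(px.reshape(*shape, 3))

    def test_dominant_tissue_cluster(self):
        # 70% dark red tissue, 30% pale tissue, white background
        img = self._image(
            [((180, 60, 60), 70), ((230, 230, 180), 30), ((255, 255, 255), 100)], (10, 20)
        )
        res = primary_color(img)
        assert res.rgb == (180, 60, 60)

    def test_uniform_tissue_color(self):
        img = self._image([((120, 40, 40), 50), ((255, 255, 255), 50)], (10, 10))
        assert primary_color(img).rgb == (120, 40, 40)

    def test_background_never_dominates(self, rng):
        # after whitening, the primary color must not be near-white when tissue exists
        tissue = rng.integers(20, 160, size=(40, 3))
        img = RasterImage(
            np.concatenate([tissue, np.full((216, 3), 255)]).reshape(16, 16, 3).astype(np.uint8)
        )
        res = primary_color(img)
        assert not all(c >= 250 for c in res.rgb)

    def test_constant_slide_raises(self):
        # a constant image has no tissue/background separation at all
        img = self._image([((255, 255, 255), 100)], (10, 10))
        with pytest.raises(ValueError):
            primary_color(img)

    def test_tissue_class_never_empty(self):
        # the inclusive-below threshold always keeps the darkest pixels as tissue
        img = self._image([((255, 255, 255), 99), ((254, 254, 254), 1)], (10, 10))
        assert primary_color(img).rgb == (254, 254, 254)


class TestStainDeconvolution:
    def test_white_pixel_zero_concentration(self):
        img = RasterImage(np.full((2, 2, 3), 255, dtype=np.uint8))
        conc = deconvolve_stains(img)
        assert np.allclose(conc, 0.0, atol=1e-6)

    def test_forward_model_inversion(self):
        v = SIRIUS_RED_DEFAULT_STAINS.matrix[:, 0]
        I = np.clip(np.rint(255.0 * 10 ** (-0.5 * v)), 0, 255).astype(np.uint8)
        img = RasterImage(np.tile(I, (2, 2, 1)))
        conc = deconvolve_stains(img)
        # quantization to 8 bits limits the recovery accuracy
        assert abs(conc[0, 0, 0] - 0.5) < 5e-3
        assert np.all(conc[1:, :, :] < 5e-3)

    def test_random_round_trip(self, rng):
        for _ in range(20):
            m = rng.random((3, 3)) + 0.1
            m /= np.linalg.norm(m, axis=0)
            if np.linalg.cond(m) > 1e3:
                continue
            stains = StainMatrix(m)
            c_true = rng.random(3) * 0.8
            od = m @ c_true
            I = 255.0 * 10**-od  # exact forward model, no quantization
            conc = np.linalg.inv(m) @ (-np.log10(np.maximum(I, 1.0) / 255.0))
            assert np.allclose(conc, c_true, atol=1e-3)

    def test_singular_matrix_rejected(self):
        col = _ = np.array([0.5, 0.5, 0.70710678])
        col = col / np.linalg.norm(col)
        with pytest.raises(ValueError):
            StainMatrix(np.column_stack([col, col, col]))


class TestCohortTable:
    def test_uniform_slides_records(self):
        def mk(c):
            px = np.full((8, 8, 3), 255, dtype=np.uint8)
            px[:4] = c
            return RasterImage(px)

        slides = [(f"s{i}", "A", mk((100 + 10 * i, 50, 50))) for i in range(3)]
        records = cohort_color_table(slides)
        assert [r.slide_id for r in records] == ["s0", "s1", "s2"]
        for i, r in enumerate(records):
            assert r.rgb == (100 + 10 * i, 50, 50)
            assert r.error is None

    def test_failure_becomes_error_row(self):
        bad = RasterImage(np.full((4, 4, 3), 200, dtype=np.uint8))  # constant -> otsu fails
        records = cohort_color_table([("bad", "A", bad)])
        assert records[0].error is not None and records[0].rgb is None
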