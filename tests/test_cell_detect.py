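import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import measure as sk_measure

from nanosense import cell_detect, scene_sim
from nanosense.cell_detect import (
    DegenerateHistogramError,
    DetectionParams,
    detect_cells,
    extract_contours,
    gaussian_blur,
    histogram_peak,
    hybrid_binarize,
    morph_close,
    nocc,
    otsu_threshold,
    penetration_sites,
    triangle_threshold,
)


def brute_force_otsu(img: np.ndarray) -> int:
    """Independent oracle: exhaustive between-class-variance search."""
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:  # strict: keeps the smallest level on ties
            best_v, best_t = v, t
    return best_t


def image_from_histogram(hist: dict[int, int]) -> np.ndarray:
    vals = np.concatenate([np.full(n, g, dtype=np.uint8) for g, n in hist.items()])
    return vals.reshape(1, -1)


class TestGaussianBlur:
    def test_sigma_zero_identity(self):
        img = np.random.default_rng(0).integers(0, 256, (20, 20), dtype=np.uint8)
        assert np.array_equal(gaussian_blur(img, 0.0), img)

    def test_constant_preserved(self):
        img = np.full((15, 15), 77, np.uint8)
        assert np.array_equal(gaussian_blur(img, 3.0), img)

    def test_impulse_reproduces_kernel(self):
        # oracle: sampled Gaussian kernel, normalized over the truncated support
        sigma = 2.0
        img = np.zeros((33, 33), np.uint8)
        img[16, 16] = 255
        out = gaussian_blur(img, sigma).astype(float)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        expected = 255.0 * np.outer(k1, k1)
        window = out[16 - radius : 16 + radius + 1, 16 - radius : 16 + radius + 1]
        assert np.max(np.abs(window - expected)) <= 0.5 + 1e-9

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((5, 5), np.uint8), -1.0)


class TestOtsu:
    def test_two_level_matches_brute_force(self):
        img = image_from_histogram({10: 50, 200: 50})
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_random_images_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        t = otsu_threshold(img)
        t_c = otsu_threshold(255 - img)
        assert abs(t_c - (255 - t)) <= 1

    def test_constant_image_errors(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((10, 10), 42, np.uint8))


class TestHistogramPeak:
    def test_constant(self):
        assert histogram_peak(np.full((5, 5), 77, np.uint8)) == 77

    def test_unique_mode(self):
        img = image_from_histogram({10: 30, 200: 70})
        assert histogram_peak(img) == 200

    def test_tie_takes_smallest(self):
        img = image_from_histogram({10: 50, 200: 50})
        # brute-force mode check
        hist = np.bincount(img.ravel(), minlength=256)
        assert hist[10] == hist[200] == hist.max()
        assert histogram_peak(img) == 10


def brute_force_triangle(hist: np.ndarray, toward: str) -> int:
    """Geometric oracle: distance from every bin to the peak-end chord."""
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    end = int(nz[-1]) if toward == "brighter_end" else int(nz[0])
    x1, y1 = peak, hist[peak]
    x2, y2 = end, hist[end]
    best, best_d = None, -1.0
    lo, hi = sorted((peak, end))
    for b in range(lo + 1, hi):
        d = abs((y2 - y1) * (b - x1) - (x2 - x1) * (hist[b] - y1)) / np.hypot(
            x2 - x1, y2 - y1
        )
        if d > best_d:
            best_d, best = d, b
    return best


class TestTriangleThreshold:
    def test_ramp_tail_matches_oracle(self):
        hist = {200: 500}
        for g in range(50, 200):
            hist[g] = (g - 49) // 3 + 1  # rising ramp toward the peak
        img = image_from_histogram(hist)
        h = np.bincount(img.ravel(), minlength=256).astype(float)
        assert triangle_threshold(img, "darker_end") == brute_force_triangle(h, "darker_end")

    def test_peak_at_end_errors(self):
        img = image_from_histogram({200: 100, 100: 10})
        with pytest.raises(DegenerateHistogramError):
            triangle_threshold(img, "brighter_end")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_output_strictly_between_peak_and_end(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        hist = np.bincount(img.ravel(), minlength=256)
        peak = int(np.argmax(hist))
        nz = np.flatnonzero(hist)
        for toward, end in (("brighter_end", nz[-1]), ("darker_end", nz[0])):
            if abs(int(end) - peak) < 2:
                continue  # no interior bin exists
            t = triangle_threshold(img, toward)
            lo, hi = sorted((peak, int(end)))
            assert lo < t < hi

    def test_matches_oracle_on_random_histograms(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            img = rng.integers(0, 200, (16, 16), dtype=np.uint8)
            hist = np.bincount(img.ravel(), minlength=256).astype(float)
            peak = int(np.argmax(hist))
            nz = np.flatnonzero(hist)
            if nz[-1] != peak:
                assert triangle_threshold(img, "brighter_end") == brute_force_triangle(
                    hist, "brighter_end"
                )


class TestHybridBinarize:
    def test_negative_defocus_takes_triangle_branch(self, clean_scene):
        img = gaussian_blur(scene_sim.render_cell_image(clean_scene, -30.0), 2.0)
        _, record = hybrid_binarize(img)
        assert record["branch"] == "triangle"
        assert record["t_otsu"] >= record["t_peak"]

    def test_positive_defocus_takes_otsu_branch(self, clean_scene):
        img = gaussian_blur(scene_sim.render_cell_image(clean_scene, 30.0), 2.0)
        _, record = hybrid_binarize(img)
        assert record["branch"] == "otsu"
        assert record["t_otsu"] < record["t_peak"]
        assert record["threshold"] == record["t_otsu"]

    def test_branch_is_pure_function_of_thresholds(self, clean_scene):
        for df in (-40.0, -10.0, 10.0, 40.0):
            img = gaussian_blur(scene_sim.render_cell_image(clean_scene, df), 2.0)
            _, record = hybrid_binarize(img)
            expected = "triangle" if record["t_otsu"] >= record["t_peak"] else "otsu"
            assert record["branch"] == expected


class TestMorphClose:
    def test_all_true_unchanged(self):
        img = np.ones((20, 20), bool)
        assert np.array_equal(morph_close(img, 2), img)

    def test_gap_bridged(self):
        # two blobs separated by a 1-px gap merge into one component
        img = np.zeros((11, 21), bool)
        img[3:8, 2:10] = True
        img[3:8, 11:19] = True
        closed = morph_close(img, 1)
        n = sk_measure.label(closed, connectivity=2).max()
        assert n == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        img = rng.random((30, 30)) > 0.6
        once = morph_close(img, 2)
        assert np.array_equal(morph_close(once, 2), once)


class TestExtractContours:
    def test_empty_foreground(self):
        assert extract_contours(np.zeros((10, 10), bool)) == []

    def test_three_disks(self):
        img = np.zeros((60, 160), bool)
        yy, xx = np.mgrid[0:60, 0:160]
        for cx in (30, 80, 130):
            img |= (yy - 30) ** 2 + (xx - cx) ** 2 <= 100
        contours = extract_contours(img, min_area=30)
        # oracle: connected-component count
        assert sk_measure.label(img, connectivity=2).max() == 3
        assert len(contours) == 3

    def test_disk_with_hole_outer_only(self):
        yy, xx = np.mgrid[0:50, 0:50]
        r2 = (yy - 25) ** 2 + (xx - 25) ** 2
        img = (r2 <= 400) & (r2 >= 25)
        contours = extract_contours(img, min_area=10)
        assert len(contours) == 1

    def test_min_area_filter(self):
        img = np.zeros((30, 30), bool)
        img[2:4, 2:4] = True  # 4 px
        img[10:20, 10:20] = True  # 100 px
        assert len(extract_contours(img, min_area=10)) == 1

    def test_ordered_by_descending_area(self):
        img = np.zeros((40, 80), bool)
        img[5:10, 5:10] = True
        img[15:35, 40:75] = True
        contours = extract_contours(img)
        assert contours[0].pixel_area >= contours[1].pixel_area


class TestNocc:
    def test_uniform_image_zero(self):
        assert nocc(np.full((64, 64), 120, np.uint8)) == 0

    def test_positive_defocus_counts_phantoms(self, clean_scene):
        img = scene_sim.render_cell_image(clean_scene, 30.0)
        assert nocc(img) == len(clean_scene.phantoms)

    def test_negative_defocus_zero(self, clean_scene):
        img = scene_sim.render_cell_image(clean_scene, -30.0)
        assert nocc(img) == 0

    def test_matches_component_count_oracle(self, noisy_scene):
        img = scene_sim.render_cell_image(noisy_scene, 30.0)
        params = DetectionParams()
        gray = cell_detect.to_gray(gaussian_blur(img, params.blur_sigma))
        binary, _ = hybrid_binarize(gray)
        inverted = ~morph_close(binary, params.close_radius)
        labels = sk_measure.label(inverted, connectivity=2)
        areas = np.bincount(labels.ravel())[1:]
        max_area = int(params.max_area_frac * inverted.size)
        expected = int(np.sum((areas >= params.min_area) & (areas <= max_area)))
        assert nocc(img, params) == expected


class TestPenetrationSites:
    def test_square_centroid(self):
        verts = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        contour = cell_detect.Contour(vertices=verts, pixel_area=121)
        assert contour.centroid() == pytest.approx((5.0, 5.0))

    def test_disk_centroid_matches_mask_oracle(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = (yy - 31.0) ** 2 + (xx - 33.0) ** 2 <= 144
        contour = extract_contours(img)[0]
        r, c = contour.centroid()
        # pixel-mask centroid oracle
        rr, cc = np.argwhere(img).mean(axis=0)
        assert abs(r - rr) <= 0.5 and abs(c - cc) <= 0.5

    def test_empty_list(self):
        assert penetration_sites([]) == []

    def test_sites_inside_convex_contours(self, clean_scene):
        img = scene_sim.render_cell_image(clean_scene, 30.0)
        result = detect_cells(img)
        for (r, c), contour in zip(result.sites, result.contours):
            vmin = contour.vertices.min(axis=0)
            vmax = contour.vertices.max(axis=0)
            assert vmin[0] <= r <= vmax[0]
            assert vmin[1] <= c <= vmax[1]


class TestDetectCells:
    def test_shoelace_area_positive(self, clean_scene):
        img = scene_sim.render_cell_image(clean_scene, 30.0)
        for c in detect_cells(img).contours:
            assert c.area > 0
            assert c.perimeter > 0

    def test_rgb_input_accepted(self, clean_scene):
        img = scene_sim.render_cell_image(clean_scene, 30.0)
        rgb = np.stack([img] * 3, axis=-1)
        assert detect_cells(rgb).nocc == detect_cells(img).nocc
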