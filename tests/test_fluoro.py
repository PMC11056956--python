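"""PGR quantification workflow: IO, Otsu thresholding, ROI decomposition,
area ratios, and group comparison."""

import math

import numpy as np
import pytest

from adenoquant import fluoro, synthetic
from adenoquant.fluoro import (
    CompartmentROIs,
    DegenerateHistogramError,
    TrichromeImage,
    decompose_compartments,
    otsu_threshold,
    quantify_pgr,
    rasterize_polygons,
)


# --- independent oracles ---------------------------------------------------


def otsu_brute_force(hist: np.ndarray) -> int:
    """Lowest t in 0..254 minimising within-class variance (equivalently
    maximising between-class variance), by direct evaluation."""
    levels = np.arange(256, dtype=float)
    best_t, best = None, np.inf
    total = hist.sum()
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1:] * levels[t + 1:]).sum() / w1
        var0 = (hist[: t + 1] * (levels[: t + 1] - mu0) ** 2).sum() / w0
        var1 = (hist[t + 1:] * (levels[t + 1:] - mu1) ** 2).sum() / w1
        within = (w0 * var0 + w1 * var1) / total
        if within < best - 1e-12:
            best, best_t = within, t
    return best_t


def point_in_polygon(x: float, y: float, poly) -> bool:
    """Even-odd crossing-number test, independent of shapely."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xt = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xt:
                inside = not inside
    return inside


# --- IO --------------------------------------------------------------------


class TestImageIO:
    @pytest.mark.parametrize("ext", ["tiff", "png"])
    def test_round_trip_bit_exact(self, tmp_path, ext):
        img, _, _, _ = synthetic.simulate_trichrome_image(
            synthetic.ImageSimParams(seed=1, size=96, nucleus_radius=3,
                                     noise=0.02,
                                     nuclei_per_compartment={"stroma": 10})
        )
        path = tmp_path / f"img.{ext}"
        fluoro.write_trichrome(img, path)
        back = fluoro.read_trichrome(path)
        assert np.array_equal(back.to_array(), img.to_array())

    def test_grayscale_file_rejected(self, tmp_path):
        from PIL import Image

        path = tmp_path / "gray.png"
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(path)
        with pytest.raises(ValueError, match="3-channel"):
            fluoro.read_trichrome(path)

    def test_channel_order_swaps_planes(self, tmp_path):
        img, _, _, _ = synthetic.simulate_trichrome_image(
            synthetic.ImageSimParams(seed=2, size=96, nucleus_radius=3,
                                     nuclei_per_compartment={"stroma": 10})
        )
        path = tmp_path / "img.tiff"
        fluoro.write_trichrome(img, path)
        rgb = fluoro.read_trichrome(path, "RGB")
        bgr = fluoro.read_trichrome(path, "BGR")
        assert np.array_equal(bgr.red, rgb.blue)
        assert np.array_equal(bgr.blue, rgb.red)
        assert np.array_equal(bgr.green, rgb.green)


# --- Otsu ------------------------------------------------------------------


class TestOtsu:
    def test_two_level_image_lowest_tie(self):
        channel = np.array([[0] * 8, [255] * 8], dtype=np.uint8)
        t = otsu_threshold(channel)
        assert t == 0
        assert np.count_nonzero(channel > t) == 8

    def test_constant_region_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((4, 4), 7, dtype=np.uint8))

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
            if len(np.unique(img)) < 2:
                continue
            hist = np.bincount(img.ravel(), minlength=256).astype(float)
            assert otsu_threshold(img) == otsu_brute_force(hist)

    def test_agrees_with_skimage_on_bimodal_data(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        img = np.concatenate(
            [rng.normal(60, 8, 500), rng.normal(190, 8, 500)]
        ).clip(0, 255).astype(np.uint8).reshape(20, 50)
        t = otsu_threshold(img)
        # skimage thresholds on bin centers; conventions differ by <= 1 level
        assert abs(t - threshold_otsu(img, nbins=256)) <= 1

    def test_masked_scope(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:5] = 200
        mask = np.zeros_like(img, dtype=bool)
        mask[4:6] = True  # one bright and one dark row
        t = otsu_threshold(img, within=mask)
        assert 0 <= t < 200


# --- decomposition ---------------------------------------------------------


def _square(x0, y0, x1, y1):
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


class TestDecomposition:
    def test_no_sub_rois_all_stroma(self):
        img = TrichromeImage(*(np.zeros((32, 32), dtype=np.uint8) for _ in range(3)))
        rois = CompartmentROIs(total_region=_square(1.5, 1.5, 30.5, 30.5))
        masks = decompose_compartments(img, rois)
        assert not masks.epithelium.any() and not masks.glands.any()
        assert np.array_equal(masks.stroma, masks.studied_region)

    def test_rasterization_matches_point_in_polygon_oracle(self):
        poly = [(2.3, 1.2), (27.8, 4.4), (22.1, 28.6), (5.7, 19.9)]
        mask = rasterize_polygons([poly], (32, 32))
        expected = np.zeros((32, 32), dtype=bool)
        for r in range(32):
            for c in range(32):
                expected[r, c] = point_in_polygon(c, r, poly)
        assert np.array_equal(mask, expected)

    def test_overlapping_gland_polygons_counted_once(self):
        img = TrichromeImage(*(np.zeros((32, 32), dtype=np.uint8) for _ in range(3)))
        g1 = _square(5.5, 5.5, 15.5, 15.5)
        g2 = _square(10.5, 10.5, 20.5, 20.5)
        rois = CompartmentROIs(
            total_region=_square(0.5, 0.5, 30.5, 30.5), glands=[g1, g2]
        )
        masks = decompose_compartments(img, rois)
        m1 = rasterize_polygons([g1], (32, 32))
        m2 = rasterize_polygons([g2], (32, 32))
        assert np.array_equal(masks.glands, m1 | m2)

    def test_masks_disjoint_and_tile_studied_region(self):
        _, rois, masks, _ = synthetic.simulate_trichrome_image(
            synthetic.ImageSimParams(seed=9)
        )
        assert not (masks.epithelium & masks.glands).any()
        assert not (masks.epithelium & masks.stroma).any()
        assert not (masks.glands & masks.stroma).any()
        union = masks.epithelium | masks.glands | masks.stroma
        assert np.array_equal(union, masks.studied_region)

    def test_sub_roi_outside_total_region_rejected(self):
        with pytest.raises(ValueError, match="outside total_region"):
            CompartmentROIs(
                total_region=_square(5, 5, 20, 20),
                glands=[_square(18, 18, 30, 30)],
            )

    def test_roi_json_round_trip(self, tmp_path):
        rois = CompartmentROIs(
            total_region=_square(1.5, 1.5, 30.5, 30.5),
            luminal_epithelium=[_square(2.5, 2.5, 10.5, 10.5)],
            glands=[_square(12.5, 12.5, 18.5, 18.5)],
        )
        path = tmp_path / "rois.json"
        rois.to_json(path)
        back = CompartmentROIs.from_json(path)
        assert back.total_region == rois.total_region
        assert back.glands == rois.glands


# --- quantification --------------------------------------------------------


class TestQuantification:
    def test_full_fraction_phantom_ratio_one(self):
        p = synthetic.ImageSimParams(
            seed=3, pgr_positive_fraction={c: 1.0 for c in ("epithelium", "glands", "stroma")}
        )
        img, _, masks, _ = synthetic.simulate_trichrome_image(p)
        q = quantify_pgr(img, masks)
        for comp in ("epithelium", "glands", "stroma"):
            assert q.compartments[comp].ratio == pytest.approx(1.0)

    def test_programmed_fraction_recovered_exactly(self):
        p = synthetic.ImageSimParams(
            seed=3,
            pgr_positive_fraction={"epithelium": 0.6, "glands": 0.5, "stroma": 0.30},
        )
        img, _, masks, truth = synthetic.simulate_trichrome_image(p)
        q = quantify_pgr(img, masks)
        assert q.compartments["stroma"].ratio == pytest.approx(
            truth.true_fraction["stroma"]
        )
        assert q.compartments["stroma"].ratio == pytest.approx(0.30)

    def test_empty_compartment_flagged_undefined(self):
        p = synthetic.ImageSimParams(
            seed=3, nuclei_per_compartment={"epithelium": 0, "glands": 0, "stroma": 40}
        )
        img, _, masks, _ = synthetic.simulate_trichrome_image(p)
        q = quantify_pgr(img, masks)
        assert not q.compartments["glands"].ratio_defined
        assert math.isnan(q.compartments["glands"].ratio)
        assert q.compartments["glands"].area_red == 0

    def test_area_conservation_across_compartments(self):
        img, _, masks, _ = synthetic.simulate_trichrome_image(
            synthetic.ImageSimParams(seed=6, noise=0.04)
        )
        q = quantify_pgr(img, masks)
        for attr in ("area_red", "area_blue"):
            total = sum(getattr(q.compartments[c], attr)
                        for c in ("epithelium", "glands", "stroma"))
            assert total == getattr(q.compartments["studied_region"], attr)

    def test_rotation_invariance(self):
        p = synthetic.ImageSimParams(seed=8)
        img, rois, masks, _ = synthetic.simulate_trichrome_image(p)
        q = quantify_pgr(img, masks)
        # rotate image and masks 90 deg counterclockwise together
        rot = TrichromeImage(
            red=np.rot90(img.red).copy(), green=np.rot90(img.green).copy(),
            blue=np.rot90(img.blue).copy(),
        )
        from adenoquant.fluoro import CompartmentMasks

        rmasks = CompartmentMasks(
            epithelium=np.rot90(masks.epithelium).copy(),
            glands=np.rot90(masks.glands).copy(),
            stroma=np.rot90(masks.stroma).copy(),
            studied_region=np.rot90(masks.studied_region).copy(),
        )
        q2 = quantify_pgr(rot, rmasks)
        for comp in ("epithelium", "glands", "stroma"):
            assert q2.compartments[comp].area_red == q.compartments[comp].area_red
            assert q2.compartments[comp].area_blue == q.compartments[comp].area_blue
        assert q2.threshold_red == q.threshold_red

    def test_monotone_contrast_invariance(self):
        """Halving all intensities (threshold ordering preserved) leaves the
        ratio unchanged on a clean phantom."""
        p = synthetic.ImageSimParams(seed=10)
        img, _, masks, _ = synthetic.simulate_trichrome_image(p)
        dim = TrichromeImage(
            red=(img.red // 2), green=(img.green // 2), blue=(img.blue // 2)
        )
        q1 = quantify_pgr(img, masks)
        q2 = quantify_pgr(dim, masks)
        for comp in ("epithelium", "glands", "stroma"):
            r1, r2 = q1.compartments[comp].ratio, q2.compartments[comp].ratio
            assert r1 == pytest.approx(r2)


class TestGroupComparison:
    def _quant_with_ratios(self, ratios):
        comps = {
            c: fluoro.CompartmentQuant(area_red=int(r * 1000), area_blue=1000)
            for c, r in zip(("epithelium", "glands", "stroma"), ratios)
        }
        return fluoro.PGRQuant(compartments=comps, threshold_red=0, threshold_blue=0)

    def test_separated_groups_exact_p(self):
        quants = [self._quant_with_ratios([v] * 3) for v in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)]
        groups = ["a"] * 3 + ["b"] * 3
        res = fluoro.compare_groups_pgr(quants, groups)
        for comp in ("epithelium", "glands", "stroma"):
            assert res[comp].p_value == pytest.approx(0.1)

    def test_group_label_symmetry(self):
        quants = [self._quant_with_ratios([v] * 3) for v in (0.1, 0.5, 0.3, 0.2, 0.6, 0.4)]
        groups = ["a", "a", "a", "b", "b", "b"]
        swapped = ["b", "b", "b", "a", "a", "a"]
        r1 = fluoro.compare_groups_pgr(quants, groups)
        r2 = fluoro.compare_groups_pgr(quants, swapped)
        assert r1["stroma"].p_value == r2["stroma"].p_value

    def test_single_group_rejected(self):
        quants = [self._quant_with_ratios([0.1] * 3)] * 2
        with pytest.raises(ValueError):
            fluoro.compare_groups_pgr(quants, ["a", "a"])
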