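"""Image-trait extraction: CLAHE, HSV masking, cover/height/greenness."""

import numpy as np
import pytest
from skimage import color

from phenoyield.simulate import render_plot_tile, write_tile_dataset
from phenoyield.traits import (
    SegmentationConfig,
    canopy_cover,
    canopy_height,
    equalize_contrast,
    excess_green,
    extract_trait_table,
    mask_canopy,
    normalize_exg,
)

CFG = SegmentationConfig()


def _rgb_from_hsv8(h, s, v, shape=(10, 10)):
    """Build a uint8 RGB tile from OpenCV-scale HSV (H in 0..180)."""
    hsv = np.zeros(shape + (3,), float)
    hsv[..., 0] = h / 180.0
    hsv[..., 1] = s / 255.0
    hsv[..., 2] = v / 255.0
    return np.clip(np.round(color.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)


class TestEqualizeContrast:
    def test_flat_tile_unchanged_within_one_level(self):
        flat = np.full((100, 100, 3), 128, np.uint8)
        eq = equalize_contrast(flat, CFG)
        assert eq.dtype == np.uint8
        assert np.max(np.abs(eq.astype(int) - 128)) <= 1

    def test_dtype_and_range_contract(self, rng):
        tile = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        eq = equalize_contrast(tile, CFG)
        assert eq.dtype == np.uint8 and eq.shape == tile.shape

    def test_non_uint8_rejected(self):
        with pytest.raises(ValueError, match="8-bit"):
            equalize_contrast(np.zeros((10, 10, 3), np.float32), CFG)

    def test_two_halves_spread_increases_order_preserved(self, rng):
        tile = np.zeros((80, 80, 3), np.uint8)
        left = rng.integers(35, 46, (80, 40))
        right = rng.integers(195, 206, (80, 40))
        for c in range(3):
            tile[:, :40, c] = left
            tile[:, 40:, c] = right
        eq = equalize_contrast(tile, CFG)
        v_orig = tile.mean(axis=2)
        v_eq = eq.mean(axis=2)
        assert v_eq[:, :40].std() > v_orig[:, :40].std()
        assert v_eq[:, 40:].std() > v_orig[:, 40:].std()
        assert v_eq[:, :40].mean() < v_eq[:, 40:].mean()


class TestMaskCanopy:
    def test_hue_inside_band_is_canopy(self):
        assert np.all(mask_canopy(_rgb_from_hsv8(90, 128, 128), CFG) == 255)

    def test_hue_below_lower_bound_is_soil(self):
        assert np.all(mask_canopy(_rgb_from_hsv8(10, 200, 200), CFG) == 0)

    def test_all_soil_tile_gives_empty_mask(self):
        assert mask_canopy(_rgb_from_hsv8(12, 150, 150), CFG).sum() == 0

    def test_masking_is_idempotent(self):
        rgb, _ = render_plot_tile(0.3, 0.4, (50, 50), seed=1)
        mask = mask_canopy(rgb, CFG)
        masked_tile = rgb * (mask[..., None] > 0)
        assert np.array_equal(mask_canopy(masked_tile, CFG), mask)

    def test_raising_lower_hue_bound_shrinks_canopy(self, rng):
        tile = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        base = mask_canopy(tile, CFG)
        tighter = mask_canopy(
            tile, SegmentationConfig(hsv_lower=(60, 0, 0), hsv_upper=CFG.hsv_upper)
        )
        assert np.all(base[tighter == 255] == 255)
        assert tighter.sum() <= base.sum()

    def test_permutation_invariance_of_summary_traits(self, rng):
        rgb, dem = render_plot_tile(0.4, 0.3, (30, 30), seed=2)
        mask = mask_canopy(rgb, CFG)
        perm = rng.permutation(30 * 30)
        shuf = lambda a: a.reshape(-1, *a.shape[2:])[perm].reshape(a.shape)
        assert canopy_cover(mask) == canopy_cover(shuf(mask))
        ch, ch90, _ = canopy_height(dem, mask)
        ch_s, ch90_s, _ = canopy_height(shuf(dem), shuf(mask))
        assert (ch, ch90) == pytest.approx((ch_s, ch90_s))
        assert excess_green(rgb, mask) == pytest.approx(excess_green(shuf(rgb), shuf(mask)))


class TestCanopyCover:
    def test_fraction_of_plot_area(self):
        mask = np.zeros(10000, np.uint8)
        mask[:2000] = 255
        assert canopy_cover(mask.reshape(100, 100)) == 0.2

    def test_full_canopy(self):
        assert canopy_cover(np.full((10, 10), 255, np.uint8)) == 1.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            canopy_cover(np.zeros((5, 5), np.uint8), aom_pixel_count=0)

    def test_rendered_tile_round_trip(self):
        rgb, _ = render_plot_tile(0.37, 0.4, (100, 100), seed=5)
        cc = canopy_cover(mask_canopy(equalize_contrast(rgb, CFG), CFG))
        assert cc == pytest.approx(0.37, abs=1 / 10000)


class TestCanopyHeight:
    def test_constant_canopy_over_soil(self):
        rgb, dem = render_plot_tile(0.3, 0.45, (60, 60), seed=0, ground_elevation=0.10)
        mask = mask_canopy(rgb, CFG)
        ch, ch90, deciles = canopy_height(dem, mask)
        assert ch == pytest.approx(0.45, abs=1e-6)
        assert ch90 == pytest.approx(0.45, abs=1e-6)
        assert deciles == pytest.approx(np.full(10, 0.45), abs=1e-6)

    def test_empty_mask_gives_zeros(self):
        ch, ch90, deciles = canopy_height(np.ones((5, 5)), np.zeros((5, 5), np.uint8))
        assert (ch, ch90) == (0.0, 0.0)
        assert np.all(deciles == 0)

    def test_percentile_rule_matches_numpy_on_ten_heights(self):
        heights = np.arange(0.1, 1.01, 0.1)
        dem = np.zeros((1, 11))
        dem[0, :10] = heights  # soil pixel at col 10 has elevation 0 -> ground 0
        mask = np.zeros((1, 11), np.uint8)
        mask[0, :10] = 255
        ch, ch90, deciles = canopy_height(dem, mask)
        assert ch == pytest.approx(0.55)
        assert ch90 == pytest.approx(np.percentile(heights, 90))
        assert deciles == pytest.approx(np.percentile(heights, np.arange(10, 101, 10)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            canopy_height(np.zeros((4, 4)), np.zeros((5, 5), np.uint8))


class TestExcessGreen:
    def test_gray_pixels_give_zero(self):
        tile = np.full((5, 5, 3), 77, np.uint8)
        assert excess_green(tile, np.full((5, 5), 255, np.uint8)) == pytest.approx(0.0)

    def test_pure_green_gives_two(self):
        tile = np.zeros((5, 5, 3), np.uint8)
        tile[..., 1] = 255
        assert excess_green(tile, np.full((5, 5), 255, np.uint8)) == pytest.approx(2.0)

    def test_mixed_tile_matches_pixel_loop(self, rng):
        tile = rng.integers(1, 256, (8, 8, 3), dtype=np.uint8)
        mask = (rng.random((8, 8)) < 0.6).astype(np.uint8) * 255
        acc = []
        for i in range(8):
            for j in range(8):
                if mask[i, j]:
                    r, g, b = tile[i, j].astype(float)
                    s = r + g + b
                    acc.append(2 * g / s - r / s - b / s)
        assert excess_green(tile, mask) == pytest.approx(np.mean(acc), abs=1e-12)

    def test_empty_mask_is_missing(self):
        assert np.isnan(excess_green(np.zeros((3, 3, 3), np.uint8), np.zeros((3, 3))))


class TestNormalizeExg:
    def test_linear_map(self):
        assert normalize_exg([-0.1, 0.4, 0.9]) == pytest.approx([0.0, 0.5, 1.0])

    def test_identity_when_already_unit_range(self):
        vals = [0.0, 0.3, 1.0]
        assert normalize_exg(vals) == pytest.approx(vals)

    def test_ordering_preserved(self, rng):
        vals = rng.normal(size=50)
        out = normalize_exg(vals)
        assert np.all(np.argsort(out) == np.argsort(vals))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_all_equal_returns_half_with_warning(self):
        with pytest.warns(UserWarning, match="equal"):
            out = normalize_exg([0.2, 0.2, 0.2])
        assert out == pytest.approx([0.5, 0.5, 0.5])


@pytest.fixture(scope="module")
def manifest(tmp_path_factory):
    import pandas as pd

    records = pd.DataFrame(
        {
            "plot_id": ["p1", "p2", "p3"],
            "genotype": ["G1", "G2", "G3"],
            "year": ["2021"] * 3,
            "dap": [30, 60, 90],
            "CC": [0.10, 0.40, 0.80],
            "CH": [0.05, 0.25, 0.45],
        }
    )
    return write_tile_dataset(records, tmp_path_factory.mktemp("tiles"), seed=9)


class TestExtractTraitTable:
    def test_one_record_per_manifest_row(self, manifest):
        table = extract_trait_table(manifest, CFG)
        assert len(table) == 3
        assert not table["missing"].any()

    def test_recovers_rendered_targets(self, manifest):
        table = extract_trait_table(manifest, CFG).set_index("plot_id")
        assert table.loc["p2", "CC"] == pytest.approx(0.40, abs=1 / 10000)
        assert table.loc["p2", "CH"] == pytest.approx(0.25, abs=1e-5)
        assert table.loc["p3", "CH90"] == pytest.approx(0.45, abs=1e-5)

    def test_volume_is_cover_times_height(self, manifest):
        table = extract_trait_table(manifest, CFG)
        assert np.allclose(table["CV"], table["CC"] * table["CH"], atol=1e-12)
        assert np.allclose(table["CV90"], table["CC"] * table["CH90"], atol=1e-12)

    def test_missing_file_flagged_not_fatal(self, manifest):
        broken = manifest.copy()
        broken.loc[0, "rgb_path"] = "/nonexistent/tile.png"
        table = extract_trait_table(broken, CFG)
        assert len(table) == 3
        assert bool(table.loc[0, "missing"])
        assert np.isnan(table.loc[0, "CC"])

    def test_exg_normalized_within_year(self, manifest):
        table = extract_trait_table(manifest, CFG)
        assert table["ExG"].min() == 0.0 and table["ExG"].max() == 1.0
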