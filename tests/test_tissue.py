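import numpy as np
import pytest

from ki67quant import (
    SlideImage,
    StainModel,
    compute_custom_threshold,
    filter_components,
    generate_slide,
    segment_preliminary,
    segment_refined,
)
from ki67quant.fixtures import FixtureSpec
from ki67quant.tissue import WORKING_MPP

from conftest import h_vec_with_red


def _uniform_slide(red, size_px=256, mpp=WORKING_MPP):
    img = np.zeros((size_px, size_px, 3), np.uint8)
    img[..., 0] = red
    img[..., 1] = red
    img[..., 2] = red
    return SlideImage(img, mpp=mpp)


class TestFilterComponents:
    MPP = WORKING_MPP  # 16.0128 μm² per pixel

    def test_component_exactly_min_area_is_kept(self):
        # a 25×25 block at 4.0016 μm/px is 10008 μm²; ask for exactly that
        mask = np.zeros((60, 60), bool)
        mask[10:35, 10:35] = True
        area = 25 * 25 * self.MPP**2
        out = filter_components(mask, self.MPP, min_area_um2=area,
                                min_hole_area_um2=0.0)
        assert out.sum() == 25 * 25

    def test_component_below_min_area_removed(self):
        mask = np.zeros((60, 60), bool)
        mask[10:35, 10:35] = True
        area = 25 * 25 * self.MPP**2
        out = filter_components(mask, self.MPP, min_area_um2=area + 1.0,
                                min_hole_area_um2=0.0)
        assert not out.any()

    def test_checkerboard_of_single_pixels_removed(self):
        mask = np.zeros((40, 40), bool)
        mask[::3, ::3] = True          # isolated 16 μm² specks
        out = filter_components(mask, self.MPP, 10_000.0, 8_000.0)
        assert not out.any()

    def test_small_hole_filled_large_hole_kept(self):
        mask = np.ones((100, 100), bool)
        mask[10:25, 10:25] = False     # 15×15 = 3603 μm² hole -> filled
        mask[40:75, 40:75] = False     # 35×35 = 19616 μm² hole -> kept
        out = filter_components(mask, self.MPP, 0.0, 8_000.0)
        assert out[15, 15]
        assert not out[50, 50]

    def test_border_touching_background_is_not_a_hole(self):
        mask = np.ones((50, 50), bool)
        mask[:5, :5] = False           # touches the border: background
        out = filter_components(mask, self.MPP, 0.0, 1e9)
        assert not out[0, 0]

    def test_idempotent(self, rng):
        mask = rng.random((80, 80)) > 0.4
        once = filter_components(mask, self.MPP, 5_000.0, 3_000.0)
        twice = filter_components(once, self.MPP, 5_000.0, 3_000.0)
        np.testing.assert_array_equal(once, twice)

    def test_eight_connectivity(self):
        # two diagonal pixels are one 8-connected component of 32 μm²
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = mask[5, 5] = True
        out = filter_components(mask, self.MPP, 2 * self.MPP**2, 0.0)
        assert out.sum() == 2


class TestSegmentPreliminary:
    def test_uniform_bright_keeps_everything(self):
        mask = segment_preliminary(_uniform_slide(200)).mask
        assert mask.all()

    def test_uniform_dark_removed(self):
        mask = segment_preliminary(_uniform_slide(50)).mask
        assert not mask.any()

    def test_threshold_is_strictly_above_80(self):
        assert not segment_preliminary(_uniform_slide(80)).mask.any()
        assert segment_preliminary(_uniform_slide(81)).mask.all()

    def test_small_bright_patch_removed(self):
        # bright patch of ~10,000 μm² in a dark frame: below minArea 20,000
        img = np.full((128, 128, 3), 50, np.uint8)
        side = int(round(np.sqrt(10_000) / WORKING_MPP))   # 25 px
        img[50 : 50 + side, 50 : 50 + side] = 220
        slide = SlideImage(img, mpp=WORKING_MPP)
        assert not segment_preliminary(slide).mask.any()


class TestCustomThreshold:
    def test_strong_stain_lower_threshold(self, default_model):
        assert compute_custom_threshold(default_model, 240) == 200.0

    def test_weak_stain_higher_threshold(self):
        weak = StainModel(h_vec=h_vec_with_red(0.75),
                          dab_vec=StainModel.default().dab_vec)
        assert compute_custom_threshold(weak, 240) == 225.0

    def test_clamped_low(self, default_model):
        assert compute_custom_threshold(default_model, 20) == 10.0

    def test_uses_model_background_when_not_given(self):
        m = StainModel.default(background_rgb=(240, 250, 250))
        assert compute_custom_threshold(m) == 200.0


class TestSegmentRefined:
    def test_disk_fixture_segmented(self):
        spec = FixtureSpec(n_positive=20, n_negative=60, width_um=600,
                           height_um=500, seed=4)
        slide, truth = generate_slide(spec)
        prelim = segment_preliminary(slide)
        refined = segment_refined(slide, 203.0, preliminary=prelim)
        # the 32 μm Gaussian at the classifier resolution biases the mask
        # boundary inward, so small fixtures under-cover by a thin rim
        true_area = truth.tissue_polygon.area / 1e6
        assert refined.total_area_mm2 == pytest.approx(true_area, rel=0.25)
        assert refined.total_area_mm2 < true_area

    def test_uniform_background_empty(self):
        slide = _uniform_slide(243)
        refined = segment_refined(slide, 200.0)
        assert not refined.mask.any()

    def test_refined_subset_of_preliminary(self):
        spec = FixtureSpec(n_positive=10, n_negative=30, width_um=500,
                           height_um=400, seed=6, artifacts=["pen_mark"])
        slide, _ = generate_slide(spec)
        prelim = segment_preliminary(slide)
        refined = segment_refined(slide, 210.0, preliminary=prelim)
        assert not (refined.mask & ~prelim.mask).any()

    def test_monotone_in_threshold(self):
        spec = FixtureSpec(n_positive=10, n_negative=30, width_um=500,
                           height_um=400, seed=6)
        slide, _ = generate_slide(spec)
        prelim = segment_preliminary(slide)
        lo = segment_refined(slide, 180.0, preliminary=prelim)
        hi = segment_refined(slide, 220.0, preliminary=prelim)
        assert not (lo.mask & ~hi.mask).any()   # raising never shrinks

    def test_bright_hole_below_min_area_filled(self):
        spec = FixtureSpec(
            n_positive=10, n_negative=30, width_um=500, height_um=400, seed=6,
            artifacts=[{"type": "bright_hole", "area_um2": 5000.0}],
        )
        slide, truth = generate_slide(spec)
        prelim = segment_preliminary(slide)
        refined = segment_refined(slide, 203.0, preliminary=prelim)
        _, poly = truth.artifact_polygons[0]
        cx, cy = poly.centroid.x, poly.centroid.y
        assert refined.contains_um(np.array([cx]), np.array([cy]))[0]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            segment_refined(_uniform_slide(200), 5.0)


def test_total_area_consistent_with_components(small_fixture):
    slide, _ = small_fixture
    prelim = segment_preliminary(slide)
    total = sum(prelim.component_areas_um2) / 1e6
    assert prelim.total_area_mm2 == pytest.approx(total, rel=1e-3)


def test_padding_invariance():
    spec = FixtureSpec(n_positive=10, n_negative=30, width_um=500,
                       height_um=400, seed=6)
    slide, _ = generate_slide(spec)
    refined = segment_refined(slide, 203.0)
    pad_px = 80   # 40 μm of background on every side
    padded = np.pad(
        slide.pixel_data, ((pad_px, pad_px), (pad_px, pad_px), (0, 0)),
        constant_values=243,
    )
    refined_pad = segment_refined(SlideImage(padded, mpp=slide.mpp), 203.0)
    off = int(round(pad_px * slide.mpp / refined.mpp))
    h, w = refined.mask.shape
    inner = refined_pad.mask[off : off + h, off : off + w]
    agree = (inner == refined.mask).mean()
    assert agree > 0.99


def test_mask_exports(tmp_path, small_fixture):
    import json

    import imageio.v3 as iio

    from ki67quant.tissue import export_mask_geojson, export_mask_png

    slide, _ = small_fixture
    mask = segment_preliminary(slide)
    export_mask_geojson(mask, tmp_path / "m.geojson")
    payload = json.loads((tmp_path / "m.geojson").read_text())
    assert payload["features"]
    assert payload["features"][0]["properties"]["classification"]["name"] == "Tumor"
    ring = payload["features"][0]["geometry"]["coordinates"][0]
    assert ring[0] == ring[-1]
    export_mask_png(mask, tmp_path / "m.png")
    img = iio.imread(tmp_path / "m.png")
    assert img.shape == mask.mask.shape
    assert set(np.unique(img)) <= {0, 255}
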