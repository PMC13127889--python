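import json

import numpy as np
import pytest

from ki67quant import SlideImage, crop_control_tissue, iter_tiles, read_slide
from ki67quant.nuclei import Nucleus
from ki67quant.stats import SlideSummary
from ki67quant.wsi_io import (
    CalibrationError,
    nearest_at_or_finer,
    read_detections,
    read_manifest,
    read_slide_summary,
    resample_to_mpp,
    write_detections,
    write_slide_summary,
)


def _checker(h, w):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[::2, ::2] = 200
    return img


class TestReadSlide:
    def test_png_with_sidecar_mpp(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "s.png"
        iio.imwrite(path, _checker(64, 48))
        path.with_name("s.png.mpp.json").write_text(json.dumps({"mpp": 0.5}))
        slide = read_slide(path)
        assert slide.mpp == 0.5
        assert (slide.width, slide.height) == (48, 64)

    def test_missing_calibration_raises(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "s.png"
        iio.imwrite(path, _checker(8, 8))
        with pytest.raises(CalibrationError):
            read_slide(path)

    def test_tiff_resolution_tags(self, tmp_path):
        import tifffile

        path = tmp_path / "s.tif"
        mpp = 0.25
        ppcm = 1e4 / mpp
        tifffile.imwrite(path, _checker(32, 32), resolution=(ppcm, ppcm),
                         resolutionunit="CENTIMETER")
        slide = read_slide(path)
        assert slide.mpp == pytest.approx(mpp)

    def test_pyramid_level_selection(self, tmp_path):
        import tifffile

        base = _checker(256, 256)
        path = tmp_path / "p.tif"
        ppcm = 1e4 / 0.5
        with tifffile.TiffWriter(path) as tw:
            tw.write(base, subifds=2, resolution=(ppcm, ppcm),
                     resolutionunit="CENTIMETER")
            tw.write(base[::2, ::2], subfiletype=1)
            tw.write(base[::4, ::4], subfiletype=1)
        # levels at mpp {0.5, 1.0, 2.0}; 2.0016 requested -> 2.0 selected
        slide = read_slide(path, target_mpp=2.0016)
        assert slide.mpp == pytest.approx(2.0)
        assert slide.width == 64

    def test_nearest_at_or_finer_rule(self):
        assert nearest_at_or_finer([0.5, 2.0, 4.0], 4.0016) == 2
        assert nearest_at_or_finer([0.5, 2.0, 4.0], 1.9) == 0
        # all levels coarser than the request -> finest available
        assert nearest_at_or_finer([2.0, 4.0], 1.0) == 0


class TestCropControlTissue:
    def test_half_crop(self):
        slide = SlideImage(np.zeros((100, 1000, 3), np.uint8), mpp=1.0)
        view = crop_control_tissue(slide, 0.5)
        assert view.width == 500
        assert view.origin_um == (500.0, 0.0)
        assert view.height == 100

    def test_quarter_crop(self):
        slide = SlideImage(np.zeros((10, 400, 3), np.uint8), mpp=2.0)
        view = crop_control_tissue(slide, 0.25)
        assert view.width == 300
        assert view.origin_um == (200.0, 0.0)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_bad_fraction(self, fraction):
        slide = SlideImage(np.zeros((4, 4, 3), np.uint8), mpp=1.0)
        with pytest.raises(ValueError):
            crop_control_tissue(slide, fraction)

    def test_physical_extent_preserved(self):
        slide = SlideImage(np.zeros((50, 999, 3), np.uint8), mpp=0.7)
        view = crop_control_tissue(slide, 0.5)
        expected = (1 - 0.5) * slide.width * slide.mpp
        assert abs(view.width * view.mpp - expected) <= slide.mpp


class TestTiling:
    def test_exact_partition_no_overlap(self):
        data = np.random.default_rng(0).integers(0, 255, (1000, 1000, 3)).astype(np.uint8)
        slide = SlideImage(data, mpp=1.0)
        tiles = list(iter_tiles(slide, 1.0, 512, 0))
        assert len(tiles) == 4
        recon = np.zeros_like(data)
        for t in tiles:
            x0, y0, x1, y1 = t.core
            assert t.origin == (x0, y0)
            recon[y0:y1, x0:x1] = t.pixel_data
        np.testing.assert_array_equal(recon, data)

    def test_cores_partition_with_overlap(self):
        data = np.random.default_rng(1).integers(0, 255, (1000, 1000, 3)).astype(np.uint8)
        slide = SlideImage(data, mpp=1.0)
        tiles = list(iter_tiles(slide, 1.0, 512, 64))
        cover = np.zeros((1000, 1000), dtype=int)
        recon = np.zeros_like(data)
        for t in tiles:
            x0, y0, x1, y1 = t.core
            cover[y0:y1, x0:x1] += 1
            ox, oy = t.origin
            recon[y0:y1, x0:x1] = t.pixel_data[y0 - oy : y1 - oy, x0 - ox : x1 - ox]
        assert (cover == 1).all()          # every pixel in exactly one core
        np.testing.assert_array_equal(recon, data)
        # tile rasters extend beyond cores by the overlap where possible
        interior = [t for t in tiles if t.origin[0] > 0 and t.origin[1] > 0]
        assert all(t.core[0] - t.origin[0] == 64 for t in interior)

    def test_small_slide_single_tile(self):
        slide = SlideImage(np.zeros((100, 80, 3), np.uint8), mpp=1.0)
        tiles = list(iter_tiles(slide, 1.0, 512, 64))
        assert len(tiles) == 1
        assert tiles[0].pixel_data.shape[:2] == (100, 80)

    def test_invalid_overlap(self):
        slide = SlideImage(np.zeros((10, 10, 3), np.uint8), mpp=1.0)
        with pytest.raises(ValueError):
            list(iter_tiles(slide, 1.0, 64, 32))


class TestResample:
    def test_downsample_extent(self):
        slide = SlideImage(np.full((200, 300, 3), 100, np.uint8), mpp=0.5)
        out = resample_to_mpp(slide, 2.0)
        assert out.pixel_data.shape[:2] == (50, 75)
        assert abs(out.width * out.mpp - slide.width * slide.mpp) <= out.mpp

    def test_identity(self):
        slide = SlideImage(np.full((10, 10, 3), 7, np.uint8), mpp=1.0)
        assert resample_to_mpp(slide, 1.0) is slide


class TestDetectionsGeoJSON:
    def _nuclei(self):
        sq = [(0.0, 0.0), (4.0, 0.0), (4.0, 4.0), (0.0, 4.0)]
        return [
            Nucleus(centroid=(2.0, 2.0), polygon=sq, area_um2=16.0,
                    mean_dab=0.7, label="positive", detection_prob=0.9),
            Nucleus(centroid=(12.0, 2.0), polygon=[(p[0] + 10, p[1]) for p in sq],
                    area_um2=16.0, mean_dab=0.02, label="negative",
                    detection_prob=0.5),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "d.geojson"
        nuclei = self._nuclei()
        write_detections(nuclei, path)
        loaded = read_detections(path)
        assert [n.label for n in loaded] == ["positive", "negative"]
        for a, b in zip(nuclei, loaded):
            np.testing.assert_allclose(a.polygon, b.polygon, atol=1e-6)
            np.testing.assert_allclose(a.centroid, b.centroid, atol=1e-6)
            assert a.mean_dab == pytest.approx(b.mean_dab)

    def test_class_counts_and_closed_rings(self, tmp_path):
        path = tmp_path / "d.geojson"
        write_detections(self._nuclei(), path)
        payload = json.loads(path.read_text())
        names = [f["properties"]["classification"]["name"] for f in payload["features"]]
        assert sorted(names) == ["Negative", "Positive"]
        for f in payload["features"]:
            ring = f["geometry"]["coordinates"][0]
            assert ring[0] == ring[-1]

    def test_empty_collection(self, tmp_path):
        path = tmp_path / "d.geojson"
        write_detections([], path)
        payload = json.loads(path.read_text())
        assert payload["type"] == "FeatureCollection"
        assert payload["features"] == []


class TestSlideSummaryIO:
    def test_format_and_round_trip(self, tmp_path):
        s = SlideSummary(slide_id="s1", group="hgg", n_pos=10, n_neg=30,
                         area_mm2=2.5)
        path = tmp_path / "summary.txt"
        write_slide_summary(s, path)
        text = path.read_text()
        assert "total_detections: 40" in text
        assert "li_percent: 25.00" in text
        assert "annotation_area_mm2: 2.5000" in text
        back = read_slide_summary(path)
        assert (back.slide_id, back.n_pos, back.n_neg) == ("s1", 10, 30)
        assert back.area_mm2 == pytest.approx(2.5)
        assert back.li_percent == pytest.approx(25.0)

    def test_zero_detections_na(self, tmp_path):
        s = SlideSummary(slide_id="empty", n_pos=0, n_neg=0, area_mm2=0.0)
        path = tmp_path / "summary.txt"
        write_slide_summary(s, path)
        assert "li_percent: NA" in path.read_text()


def test_read_manifest(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(
        "slide_id,path,group,descriptor,has_control_tissue\n"
        "a,a.tif,hgg,initial,1\nb,b.tif,lgg,,0\n"
    )
    df = read_manifest(path)
    assert list(df.has_control_tissue) == [True, False]
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.csv"
        bad.write_text("slide_id,group\na,b\n")
        read_manifest(bad)
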