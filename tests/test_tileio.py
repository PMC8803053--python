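"""Calibrated I/O, tile planning, tiled analysis and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import adipoquant as aq
from adipoquant.cli import main as cli_main
from adipoquant.image import CalibratedImage


@pytest.fixture(scope="module")
def rgb():
    rng = np.random.default_rng(0)
    return rng.integers(0, 255, (120, 200, 3)).astype(np.uint8)


class TestCalibratedIO:
    def test_tiff_round_trip_preserves_calibration(self, tmp_path, rgb):
        path = tmp_path / "img.tif"
        aq.write_image(CalibratedImage(rgb, 0.5), path)
        back = aq.read_image(path)
        assert back.pixel_size_um == pytest.approx(0.5, rel=1e-9)
        assert np.array_equal(back.pixels, rgb)

    def test_png_sidecar_round_trip(self, tmp_path, rgb):
        path = tmp_path / "img.png"
        aq.write_image(CalibratedImage(rgb, 0.25), path)
        back = aq.read_image(path)
        assert back.pixel_size_um == pytest.approx(0.25)
        assert np.array_equal(back.pixels, rgb)

    def test_missing_calibration_errors_without_override(self, tmp_path, rgb):
        import imageio.v3 as iio

        path = tmp_path / "raw.png"
        iio.imwrite(path, rgb)
        with pytest.raises(aq.CalibrationError):
            aq.read_image(path)
        assert aq.read_image(path, mpp=1.5).pixel_size_um == 1.5

    def test_full_bbox_equals_full_image(self, tmp_path, rgb):
        path = tmp_path / "img.tif"
        aq.write_image(CalibratedImage(rgb, 1.0), path)
        region = aq.read_region(path, bbox_um=(0, 0, 200, 120))
        assert np.array_equal(region.pixels, rgb)
        assert region.origin_um == (0.0, 0.0)

    def test_adjacent_bboxes_partition_pixels(self, tmp_path, rgb):
        path = tmp_path / "img.tif"
        aq.write_image(CalibratedImage(rgb, 1.0), path)
        left = aq.read_region(path, bbox_um=(0, 0, 100, 120))
        right = aq.read_region(path, bbox_um=(100, 0, 200, 120))
        assert np.array_equal(np.concatenate([left.pixels, right.pixels], axis=1), rgb)
        assert right.origin_um == (100.0, 0.0)

    def test_bbox_outside_image_errors(self, tmp_path, rgb):
        path = tmp_path / "img.tif"
        aq.write_image(CalibratedImage(rgb, 1.0), path)
        with pytest.raises(ValueError):
            aq.read_region(path, bbox_um=(0, 0, 500, 120))


class TestTilePlan:
    def test_cores_partition_roi_bbox(self):
        plan = aq.plan_tiles((0, 0, 5000, 3000), (5000, 3000), tile_size_um=2000, halo_um=200)
        total = sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in plan.cores)
        assert total == pytest.approx(5000 * 3000)
        # No pairwise core overlap.
        for i, a in enumerate(plan.cores):
            for b in plan.cores[i + 1 :]:
                ox = min(a[2], b[2]) - max(a[0], b[0])
                oy = min(a[3], b[3]) - max(a[1], b[1])
                assert ox <= 0 or oy <= 0

    def test_windows_extend_by_halo_within_image(self):
        plan = aq.plan_tiles((0, 0, 4000, 2000), (4000, 2000), tile_size_um=2000, halo_um=150)
        for core, win in zip(plan.cores, plan.windows):
            assert win[0] == max(0, core[0] - 150)
            assert win[2] == min(4000, core[2] + 150)

    def test_small_halo_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="adipoquant"):
            aq.plan_tiles((0, 0, 1000, 1000), (1000, 1000), halo_um=10)
        assert any("halo" in rec.message for rec in caplog.records)


class TestTiledAnalysis:
    def test_single_tile_equals_untiled(self, small_region, small_model):
        _, image, truth = small_region
        mask = aq.classify_pixels(small_model, image)
        objs_u = aq.mask_to_objects(mask)
        objs_t, summary = aq.tiled_analysis(
            image, small_model, tile_size_um=5000.0, halo_um=100.0
        )
        assert len(objs_t) == len(objs_u)
        assert sorted(o.pixel_count for o in objs_t) == sorted(o.pixel_count for o in objs_u)
        assert summary.roi_area_um2 == pytest.approx(truth.roi_area_um2)

    def test_four_tiles_match_untiled_exactly(self, small_region, small_model):
        _, image, _ = small_region
        mask = aq.classify_pixels(small_model, image)
        objs_u = aq.mask_to_objects(mask)
        objs_t, _ = aq.tiled_analysis(
            image, small_model, tile_size_um=400.0, halo_um=150.0
        )
        assert len(objs_t) == len(objs_u)
        assert sum(o.pixel_count for o in objs_t) == sum(o.pixel_count for o in objs_u)

    def test_roi_restricts_detection(self, small_region, small_model):
        from shapely.geometry import box

        _, image, _ = small_region
        roi = box(0, 0, 400, 600)
        objs, summary = aq.tiled_analysis(image, small_model, roi_polygon=roi)
        assert summary.roi_area_um2 == pytest.approx(roi.area)
        for o in objs:
            assert o.centroid_um[0] <= 410  # inside ROI up to a boundary pixel

    def test_disk_backed_run_matches_in_memory(self, tmp_path, small_region, small_model):
        _, image, _ = small_region
        path = tmp_path / "region.tif"
        aq.write_image(image, path)
        objs_mem, s_mem = aq.tiled_analysis(image, small_model, tile_size_um=400.0)
        objs_disk, s_disk = aq.tiled_analysis(path, small_model, tile_size_um=400.0)
        assert s_mem.count == s_disk.count
        assert s_mem.mean_area_um2 == pytest.approx(s_disk.mean_area_um2)


class TestGeoJSON:
    def test_objects_geojson_round_trip_roi(self, tmp_path, small_region, small_model):
        _, image, _ = small_region
        mask = aq.classify_pixels(small_model, image)
        objs = aq.mask_to_objects(mask)
        path = tmp_path / "objects.geojson"
        aq.objects_to_geojson(objs, path)
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == len(objs)
        props = doc["features"][0]["properties"]
        assert {"object_id", "area_um2", "diameter_um", "classification"} <= set(props)

    def test_read_roi_geojson(self, tmp_path):
        doc = {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[0, 0], [100, 0], [100, 50], [0, 50], [0, 0]]],
            },
            "properties": {},
        }
        path = tmp_path / "roi.geojson"
        path.write_text(json.dumps(doc))
        roi = aq.read_roi_geojson(path)
        assert roi.area == pytest.approx(5000.0)


class TestCLI:
    def test_simulate_is_byte_reproducible(self, tmp_path):
        runner = CliRunner()
        args = ["simulate", "--width-um", "400", "--height-um", "300", "--seed", "5"]
        r1 = runner.invoke(cli_main, args + ["--out-dir", str(tmp_path / "a")])
        r2 = runner.invoke(cli_main, args + ["--out-dir", str(tmp_path / "b")])
        assert r1.exit_code == 0 and r2.exit_code == 0, r1.output + r2.output
        m1 = json.loads((tmp_path / "a" / "manifest.json").read_text())
        m2 = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert m1["outputs"] == m2["outputs"]

    def test_full_cli_pipeline(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        r = runner.invoke(
            cli_main,
            ["simulate", "--width-um", "500", "--height-um", "400", "--seed", "3",
             "--out-dir", str(sim)],
        )
        assert r.exit_code == 0, r.output
        model_path = tmp_path / "model.joblib"
        r = runner.invoke(
            cli_main,
            ["train", "--image", str(sim / "image.tif"), "--from-truth",
             str(sim / "truth.geojson"), "--seed", "0", "--out", str(model_path)],
        )
        assert r.exit_code == 0, r.output
        out = tmp_path / "ana"
        r = runner.invoke(
            cli_main,
            ["analyze", "--image", str(sim / "image.tif"), "--model", str(model_path),
             "--min-object", "20", "--min-hole", "30", "--area-range", "500:100000",
             "--out-dir", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert (out / "objects.geojson").exists()
        assert (out / "summary.csv").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["parameters"]["min_object_um2"] == 20.0

    def test_compare_identity_csv(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "id.csv"
        csv.write_text("subject_id,a_value,b_value\n1,1,1\n2,2,2\n3,3,3\n")
        out = tmp_path / "cmp"
        r = runner.invoke(cli_main, ["compare", "--input", str(csv), "--out-dir", str(out)])
        assert r.exit_code == 0, r.output
        import pandas as pd

        table = pd.read_csv(out / "agreement.csv")
        assert table.loc[0, "icc"] == pytest.approx(1.0)

    def test_unknown_flag_exits_nonzero(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["analyze", "--does-not-exist", "x"])
        assert r.exit_code != 0
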