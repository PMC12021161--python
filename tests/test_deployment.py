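"""Region scan, detection merging, reduction reporting, and export."""

import json

import numpy as np
import pandas as pd
import pytest

import herdscan as hs
from herdscan.deployment import Detection


def scan_frame(grid, flagged, scores=None):
    """Build a scan result DataFrame with the given (col, row) tiles flagged."""
    n = grid.n_tiles
    rows, cols = np.divmod(np.arange(n), grid.n_cols)
    flag = np.zeros(n, dtype=bool)
    score = np.zeros(n)
    for c, r in flagged:
        flag[r * grid.n_cols + c] = True
        score[r * grid.n_cols + c] = (scores or {}).get((c, r), 0.9)
    return pd.DataFrame({"col": cols, "row": rows, "score": score, "flag": flag})


GRID = hs.build_tile_grid((0, 0, 1280, 1280), 128, 2.0)  # 10 x 10


class TestMerge:
    def test_isolated_tile_detected_at_its_center(self):
        ds = hs.merge_detections(scan_frame(GRID, [(3, 4)]), GRID)
        assert len(ds) == 1
        assert ds.detections[0].centroid_xy == GRID.tile_center(3, 4)

    def test_2x2_block_centroid_at_shared_corner(self):
        ds = hs.merge_detections(
            scan_frame(GRID, [(2, 2), (3, 2), (2, 3), (3, 3)]), GRID)
        assert len(ds) == 1
        # union is a 256 m square spanning x,y in [256, 512)
        assert ds.detections[0].centroid_xy == (384.0, 384.0)

    def test_corner_touching_tiles_merge_under_8_connectivity(self):
        ds = hs.merge_detections(scan_frame(GRID, [(1, 1), (2, 2)]), GRID)
        assert len(ds) == 1
        assert len(ds.detections[0].member_tiles) == 2

    def test_separated_tiles_stay_distinct(self):
        ds = hs.merge_detections(scan_frame(GRID, [(0, 0), (5, 5)]), GRID)
        assert len(ds) == 2

    def test_flag_conservation(self):
        flagged = [(0, 0), (1, 0), (4, 4), (5, 5), (9, 9)]
        ds = hs.merge_detections(scan_frame(GRID, flagged), GRID)
        assert ds.n_flagged_tiles == len(flagged)
        assert sum(len(d.member_tiles) for d in ds.detections) == len(flagged)

    def test_merging_is_idempotent(self):
        flagged = [(2, 2), (3, 2), (7, 8), (8, 8), (8, 7)]
        ds1 = hs.merge_detections(scan_frame(GRID, flagged), GRID)
        members = [t for d in ds1.detections for t in d.member_tiles]
        ds2 = hs.merge_detections(scan_frame(GRID, members), GRID)
        assert len(ds2) == len(ds1)
        assert sorted((d.centroid_xy for d in ds2.detections)) == \
            sorted((d.centroid_xy for d in ds1.detections))

    def test_centroid_inside_member_bounding_box(self):
        flagged = [(1, 1), (2, 1), (2, 2)]  # L-shaped component
        ds = hs.merge_detections(scan_frame(GRID, flagged), GRID)
        (d,) = ds.detections
        xs = [GRID.tile_bounds(c, r) for c, r in d.member_tiles]
        assert min(b[0] for b in xs) <= d.centroid_xy[0] <= max(b[2] for b in xs)
        assert min(b[1] for b in xs) <= d.centroid_xy[1] <= max(b[3] for b in xs)

    def test_empty_scan_empty_set(self):
        ds = hs.merge_detections(scan_frame(GRID, []), GRID)
        assert len(ds) == 0


class TestReduction:
    def test_regional_deployment_fold_reduction(self):
        dets = hs.DetectionSet([Detection((0, 0), [(0, 0)], 1.0)] * 1100,
                               total_tiles_scanned=300_000,
                               n_flagged_tiles=1100, threshold=0.5)
        report = hs.reduction_report(300_000, dets)
        assert report.fold_reduction == pytest.approx(272.7, abs=0.05)
        assert report.fold_reduction >= 270

    def test_no_reduction_when_all_flagged(self):
        dets = hs.DetectionSet([Detection((0, 0), [(0, 0)], 1.0)] * 100,
                               100, 100, 0.5)
        assert hs.reduction_report(100, dets).fold_reduction == 1.0

    def test_single_candidate(self):
        dets = hs.DetectionSet([Detection((0, 0), [(0, 0)], 1.0)], 100, 1, 0.5)
        assert hs.reduction_report(100, dets).fold_reduction == 100.0

    def test_zero_detections_undefined(self):
        report = hs.reduction_report(100, hs.DetectionSet([], 100, 0, 0.5))
        assert report.fold_reduction is None
        assert report.n_for_review == 0


class TestExport:
    def _detections(self):
        return hs.DetectionSet(
            [Detection((100.0, 200.0), [(0, 1)], 0.7),
             Detection((300.0, 400.0), [(2, 3), (3, 3)], 0.95),
             Detection((500.0, 600.0), [(4, 4)], 0.8)], 100, 4, 0.5)

    def test_geojson_and_worklist(self, tmp_path):
        geo, csv = hs.export_detections(self._detections(), tmp_path)
        fc = json.loads(geo.read_text())
        assert len(fc["features"]) == 3
        wl = pd.read_csv(csv)
        assert len(wl) == 3
        assert wl["score"].is_monotonic_decreasing

    def test_geojson_round_trip_preserves_centroids(self, tmp_path):
        ds = self._detections()
        geo, _ = hs.export_detections(ds, tmp_path)
        fc = json.loads(geo.read_text())
        coords = sorted(tuple(f["geometry"]["coordinates"])
                        for f in fc["features"])
        assert coords == sorted(d.centroid_xy for d in ds.detections)

    def test_empty_set_valid_feature_collection(self, tmp_path):
        geo, _ = hs.export_detections(hs.DetectionSet([], 10, 0, 0.9), tmp_path)
        fc = json.loads(geo.read_text())
        assert fc == {"type": "FeatureCollection", "features": []}


@pytest.fixture(scope="module")
def scan_setup(small_scene):
    cfg = small_scene.config
    grid = hs.build_tile_grid((0, 0, cfg.region_width_m, cfg.region_height_m),
                              cfg.tile_size_m, cfg.resolution_m_per_px)
    model = hs.build_model(seed=0)
    return small_scene, grid, model


class TestScan:
    def test_every_tile_scored_once(self, scan_setup):
        scene, grid, model = scan_setup
        result = hs.scan_region(model, scene.raster, grid, alpha=0.5)
        assert len(result) == grid.n_tiles == 400
        assert result["score"].notna().all()

    def test_alpha_one_flags_nothing(self, scan_setup):
        scene, grid, model = scan_setup
        result = hs.scan_region(model, scene.raster, grid, alpha=1.0)
        assert not result["flag"].any()

    def test_checkpoint_resume_matches_single_pass(self, scan_setup, tmp_path):
        scene, grid, model = scan_setup
        full = hs.scan_region(model, scene.raster, grid, alpha=0.5)
        ckpt = tmp_path / "scan.npz"
        # simulate an interrupted scan: first 150 tiles only
        partial = hs.scan_region(model, scene.raster[:, :], grid, alpha=0.5,
                                 batch_size=50, checkpoint_path=ckpt)
        np.savez(ckpt, scores=partial["score"].to_numpy(), done=150)
        resumed = hs.scan_region(model, scene.raster, grid, alpha=0.5,
                                 batch_size=50, checkpoint_path=ckpt)
        np.testing.assert_allclose(resumed["score"], full["score"])
        np.testing.assert_array_equal(resumed["flag"], full["flag"])

    def test_fused_model_mismatch_detected_before_scan(self, scan_setup):
        scene, grid, _ = scan_setup
        fused = hs.build_model(fusion_strategy="aux2", aux_dim=3, seed=0)
        with pytest.raises(ValueError):
            hs.scan_region(fused, scene.raster, grid, alpha=0.5)


class TestPipelineContracts:
    def test_low_data_subsampling_paired_across_strategies(self, small_scene):
        cfg = hs.TrainingConfig(max_epochs=1, seed=0)
        table = hs.run_low_data_ablation(
            small_scene, small_scene.manifest, [6],
            [("none", "none"), ("water", "aux2")], cfg)
        ids = table["positive_ids"]
        assert ids[0] == ids[1]
        assert table["split_checksum"].nunique() == 1

    def test_low_data_count_exceeding_positives_rejected(self, small_scene):
        cfg = hs.TrainingConfig(max_epochs=1, seed=0)
        with pytest.raises(ValueError):
            hs.run_low_data_ablation(small_scene, small_scene.manifest,
                                     [1000], [("none", "none")], cfg)

    def test_resolution_ablation_single_row_matches_plain_run(self, small_scene):
        cfg = hs.TrainingConfig(max_epochs=2, seed=0)
        table = hs.run_resolution_ablation(small_scene, small_scene.manifest,
                                           [2.0], cfg)
        plain = hs.train_pipeline(small_scene, small_scene.manifest, cfg)
        assert table["auprc"][0] == pytest.approx(plain.val_report.auprc)
        assert table["split_checksum"][0] == plain.split_checksum

    def test_augmented_training_is_seeded_and_distinct(self, small_scene):
        cfg = hs.TrainingConfig(max_epochs=1, seed=0)
        plain = hs.train_pipeline(small_scene, small_scene.manifest, cfg)
        aug1 = hs.train_pipeline(small_scene, small_scene.manifest, cfg,
                                 augment=True)
        aug2 = hs.train_pipeline(small_scene, small_scene.manifest, cfg,
                                 augment=True)
        assert aug1.history.train_loss == aug2.history.train_loss
        assert aug1.history.train_loss != plain.history.train_loss

    def test_finer_than_source_resolution_rejected(self, small_scene):
        cfg = hs.TrainingConfig(max_epochs=1, seed=0)
        with pytest.raises(ValueError):
            hs.run_resolution_ablation(small_scene, small_scene.manifest,
                                       [0.5], cfg)
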