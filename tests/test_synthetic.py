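"""Scene generator: determinism, settlement appearance, distance structure,
stratified splitting, and IO round trips."""

import numpy as np
import pandas as pd
import pytest

import herdscan as hs
from conftest import small_scene_config


class TestDeterminism:
    def test_same_config_same_seed_byte_identical(self):
        b1 = hs.generate_scene(small_scene_config(seed=7))
        b2 = hs.generate_scene(small_scene_config(seed=7))
        assert b1.checksum() == b2.checksum()

    def test_different_seed_different_scene(self):
        b1 = hs.generate_scene(small_scene_config(seed=7))
        b2 = hs.generate_scene(small_scene_config(seed=8))
        assert b1.checksum() != b2.checksum()


class TestSceneStructure:
    def test_manifest_counts_match_config(self, small_scene):
        counts = small_scene.manifest.groupby("stratum").size()
        assert counts["active"] == 10
        assert counts["inactive"] == 5
        assert counts["near_settlement"] == 5
        assert small_scene.manifest["label"].sum() == 10

    def test_settlements_inside_region(self, small_scene):
        cfg = small_scene.config
        for x, y, _ in small_scene.settlements:
            assert 0 <= x <= cfg.region_width_m
            assert 0 <= y <= cfg.region_height_m

    def test_no_two_tiles_overlap(self, small_scene):
        man = small_scene.manifest
        xy = man[["x_m", "y_m"]].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        # centers >= tile size apart => half-open 128 m windows are disjoint
        assert d.min() >= small_scene.config.tile_size_m

    def test_near_settlement_negatives_near_an_active(self, small_scene):
        man = small_scene.manifest
        act = man[man["stratum"] == "active"][["x_m", "y_m"]].to_numpy()
        near = man[man["stratum"] == "near_settlement"][["x_m", "y_m"]].to_numpy()
        for p in near:
            assert np.min(np.hypot(*(act - p).T)) <= \
                small_scene.config.near_settlement_max_m

    def test_region_too_small_raises_placement_error(self):
        cfg = small_scene_config()
        cfg.n_active = 400  # cannot fit 400 separated settlements in 2.56 km
        with pytest.raises(hs.PlacementError):
            hs.generate_scene(cfg)


class TestDistanceStructure:
    def test_active_road_distance_mean_matches_truncated_normal(self):
        """500 actives; sample mean within +/- 15 m of the truncated-normal
        mean computed by numerical integration (the independent oracle)."""
        cfg = hs.SceneConfig(seed=3, n_active=500, n_inactive=0,
                             negative_strata=[], min_separation_m=60.0)
        bundle = hs.generate_scene(cfg)
        rec = hs.compute_distance_features(bundle.manifest, bundle.roads,
                                           bundle.waters)
        target = hs.truncated_normal_mean(200.0, 100.0)
        assert abs(rec["d_road_m"].mean() - target) < 15.0

    def test_gda_recovers_active_distance_parameters(self):
        """Fitting the generative model on realized distances recovers the
        class-1 parameters within 3 standard errors."""
        cfg = hs.SceneConfig(seed=11, n_active=500, n_inactive=0,
                             negative_strata=[("random_national", 250)],
                             min_separation_m=60.0)
        bundle = hs.generate_scene(cfg)
        rec = hs.compute_distance_features(bundle.manifest, bundle.roads,
                                           bundle.waters)
        labels = bundle.manifest["label"].to_numpy()
        model = hs.fit_gda(rec["d_road_m"], labels, "road")
        from scipy.stats import truncnorm
        mu_t = truncnorm.mean(-2.0, np.inf, 200.0, 100.0)
        sd_t = truncnorm.std(-2.0, np.inf, 200.0, 100.0)
        n1 = 500
        assert abs(model.mu1 - mu_t) < 3 * sd_t / np.sqrt(n1)
        assert abs(np.sqrt(model.var1) - sd_t) < 3 * sd_t / np.sqrt(2 * n1)

    def test_negatives_far_from_infrastructure(self, small_scene):
        rec = hs.compute_distance_features(small_scene.manifest,
                                           small_scene.roads,
                                           small_scene.waters)
        md = small_scene.manifest.merge(rec, on="tile_id")
        act = md[md["stratum"] == "active"]["d_road_m"].mean()
        neg = md[md["stratum"] == "random_national"]["d_road_m"].mean()
        assert act < neg


class TestRenderSettlement:
    def test_active_patch_has_dark_enclosure(self):
        rng = np.random.default_rng(0)
        patch = hs.render_settlement(True, 64, rng)
        assert hs.annulus_contrast(patch) < 0.8

    def test_patch_shape_contract(self):
        rng = np.random.default_rng(0)
        assert hs.render_settlement(True, 32, rng).shape == (32, 32, 3)
        with pytest.raises(ValueError):
            hs.render_settlement(True, 16, rng)

    def test_inactive_lacks_annulus_signature(self):
        """Ring statistic separates active from inactive across seeded pairs."""
        worse = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            active = hs.annulus_contrast(hs.render_settlement(True, 64, rng))
            inactive = hs.annulus_contrast(hs.render_settlement(False, 64, rng))
            worse += active < inactive
        assert worse >= 18  # active ring is darker nearly always


class TestSplits:
    def _manifest(self, n, stratum="active", label=1):
        return pd.DataFrame({"tile_id": [f"{stratum}{i}" for i in range(n)],
                             "x_m": np.arange(n, dtype=float),
                             "y_m": np.zeros(n),
                             "label": label, "stratum": stratum})

    def test_largest_remainder_exact_split(self):
        man = hs.make_labeled_dataset(self._manifest(100), (0.7, 0.15, 0.15))
        sizes = man.groupby("split").size()
        assert (sizes["train"], sizes["val"], sizes["test"]) == (70, 15, 15)

    def test_every_tile_in_exactly_one_split(self, small_scene):
        assert small_scene.manifest["split"].notna().all()
        assert set(small_scene.manifest["split"]) <= {"train", "val", "test"}

    def test_positive_split_counts_at_study_proportions(self):
        """695 positives at the study's split proportions land at 480/114/101."""
        man = hs.make_labeled_dataset(self._manifest(695),
                                      (480 / 695, 114 / 695, 101 / 695))
        pos = man[man["label"] == 1].groupby("split").size()
        assert (pos["train"], pos["val"], pos["test"]) == (480, 114, 101)

    def test_stratum_proportions_preserved(self, small_scene):
        for stratum, grp in small_scene.manifest.groupby("stratum"):
            n = len(grp)
            sizes = grp.groupby("split").size()
            for frac, split in zip((0.7, 0.15, 0.15), ("train", "val", "test")):
                assert abs(sizes.get(split, 0) - frac * n) <= 1

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            hs.make_labeled_dataset(self._manifest(10), (0.5, 0.5, 0.5))

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            hs.make_labeled_dataset(self._manifest(0))


class TestSceneIO:
    def test_scene_round_trip(self, small_scene, tmp_path):
        hs.write_scene(small_scene, tmp_path / "scene")
        back = hs.read_scene(tmp_path / "scene")
        np.testing.assert_array_equal(back.raster, small_scene.raster)
        assert back.config == small_scene.config
        assert len(back.manifest) == len(small_scene.manifest)
        assert len(back.roads) == len(small_scene.roads)

    def test_tile_png_export(self, small_scene, tmp_path):
        sub = small_scene.manifest.head(3)
        man = hs.write_tiles(small_scene, sub, tmp_path / "tiles")
        import imageio.v3 as iio
        for path in man["path"]:
            img = iio.imread(path)
            assert img.shape == (64, 64, 3)
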