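"""Shared fixtures: synthetic scenes and trained models are expensive, so they
are session-scoped and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import herdscan as hs


def small_scene_config(seed: int = 7) -> hs.SceneConfig:
    """A compact scene for fast structural tests (placement, IO, scanning)."""
    return hs.SceneConfig(
        region_width_m=2560.0, region_height_m=2560.0, resolution_m_per_px=2.0,
        n_active=10, n_inactive=5,
        negative_strata=[("near_settlement", 5), ("random_national", 5),
                         ("random_continental", 5)],
        road_distance_params=(500.0, 200.0, 80.0, 40.0),
        water_distance_params=(500.0, 200.0, 80.0, 40.0),
        near_settlement_max_m=400.0, seed=seed)


def main_scene_config(seed: int = 0) -> hs.SceneConfig:
    """The packaged synthetic study set: 200 active settlements, stratified
    negatives, class distance separation 200 m vs 2000 m."""
    return hs.SceneConfig(seed=seed)


def ablation_scene_config(seed: int = 5) -> hs.SceneConfig:
    """0.5 m/px scene for the resolution-degradation protocol (compact region,
    proportionally scaled distance structure)."""
    return hs.SceneConfig(
        region_width_m=3072.0, region_height_m=3072.0, resolution_m_per_px=0.5,
        n_active=60, n_inactive=20,
        negative_strata=[("near_settlement", 30), ("random_national", 30),
                         ("random_continental", 40)],
        road_distance_params=(600.0, 250.0, 80.0, 40.0),
        water_distance_params=(600.0, 250.0, 80.0, 40.0),
        near_settlement_max_m=400.0, seed=seed)


def second_region_config(seed: int = 9) -> hs.SceneConfig:
    """A second region with different geography (no continental stratum,
    inactive settlements as hard negatives) for the transfer experiment."""
    return hs.SceneConfig(
        region_width_m=6144.0, region_height_m=6144.0, resolution_m_per_px=2.0,
        n_active=60, n_inactive=40,
        negative_strata=[("near_settlement", 30), ("random_national", 60)],
        road_distance_params=(1200.0, 400.0, 150.0, 80.0),
        water_distance_params=(1200.0, 400.0, 150.0, 80.0),
        seed=seed)


@pytest.fixture(scope="session")
def small_scene():
    bundle = hs.generate_scene(small_scene_config())
    bundle.manifest = hs.make_labeled_dataset(bundle, seed=7)
    return bundle


@pytest.fixture(scope="session")
def main_scene():
    bundle = hs.generate_scene(main_scene_config())
    bundle.manifest = hs.make_labeled_dataset(bundle, seed=0)
    return bundle


@pytest.fixture(scope="session")
def ablation_scene():
    bundle = hs.generate_scene(ablation_scene_config())
    bundle.manifest = hs.make_labeled_dataset(bundle, seed=5)
    return bundle


@pytest.fixture(scope="session")
def second_region_scene():
    bundle = hs.generate_scene(second_region_config())
    bundle.manifest = hs.make_labeled_dataset(bundle, seed=9)
    return bundle


@pytest.fixture(scope="session")
def smoke_result(main_scene):
    """Baseline classifier trained on the packaged synthetic set, seed 0."""
    config = hs.TrainingConfig(max_epochs=8, seed=0)
    return hs.train_pipeline(main_scene, main_scene.manifest, config)


# --- independent oracles --------------------------------------------------

def point_segment_distance(p, a, b) -> float:
    """Closed-form point-to-segment distance, independent of shapely."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.hypot(*(p - (a + t * ab))))


def brute_force_pr(scores, labels):
    """Enumerate every distinct threshold; recompute precision/recall from
    scratch at each.  O(n^2) reference for the PR machinery."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    points = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        points.append((t, tp / pred.sum(), tp / n_pos))
    return points


def brute_force_auprc(points) -> float:
    area, prev_r = 0.0, 0.0
    for _, p, r in points:
        area += p * (r - prev_r)
        prev_r = r
    return area


def brute_force_precision_at_recall(points, target) -> float:
    return max(p for _, p, r in points if r >= target)


def brute_force_best_f1(points) -> float:
    return max((2 * p * r / (p + r)) if p + r else 0.0 for _, p, r in points)
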