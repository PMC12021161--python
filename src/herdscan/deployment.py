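"""Region-scale deployment and experiment runners.

Deployment scans every tile of a region grid with a trained classifier,
thresholds scores at a recall-calibrated alpha, merges adjacent flagged tiles
(8-connectivity) into candidate detections at the centroid of their spatial
union, and reports the resulting manual-review search-space reduction.

The module also hosts the controlled experiment runners: the end-to-end
training pipeline (with the GDA fitting subset held out of classifier
training), the spatial-resolution degradation ablation, and the low-data
ablation over fusion strategies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from . import gda as gda_mod
from .classifier import (ClassifierModel, TrainingConfig, TrainingHistory,
                         build_model, train, fine_tune, predict_proba)
from .evaluation import MetricsReport, evaluate, calibrate_threshold
from .geo_features import InfrastructureSet, compute_distance_features
from .geoimagery import (TileGrid, build_tile_grid, extract_tile,
                         extract_window, degrade_resolution)
from .synthetic import SceneBundle, extract_tiles


# --- detections ----------------------------------------------------------

@dataclass
class Detection:
    centroid_xy: tuple[float, float]
    member_tiles: list[tuple[int, int]]    # (col, row)
    max_score: float


@dataclass
class DetectionSet:
    detections: list[Detection]
    total_tiles_scanned: int
    n_flagged_tiles: int
    threshold: float

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class ReductionReport:
    total_candidates: int
    n_for_review: int
    fold_reduction: float | None   # None when nothing was flagged

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "total_candidates": self.total_candidates,
            "n_for_review": self.n_for_review,
            "fold_reduction": self.fold_reduction,
        }, indent=2))


def scan_region(model: ClassifierModel, raster: np.ndarray, grid: TileGrid,
                alpha: float,
                aux_matrix: np.ndarray | None = None,
                batch_size: int = 256,
                checkpoint_path: str | Path | None = None,
                checkpoint_every: int = 1000) -> pd.DataFrame:
    """Score every tile of the grid once; flag = score > alpha.

    ``aux_matrix`` holds one auxiliary feature row per tile in row-major
    (row, col) order and is required for fused models — the mismatch is
    detected before any scanning starts.  A checkpoint file makes 300k-tile
    scans resumable; a resumed scan produces flags identical to a
    single-pass run.
    """
    n = grid.n_tiles
    if model.fusion.uses_aux:
        if aux_matrix is None or len(aux_matrix) != n:
            raise ValueError("fused model needs one aux feature row per tile")
    scores = np.full(n, np.nan)
    start = 0
    ckpt = Path(checkpoint_path) if checkpoint_path else None
    if ckpt is not None and ckpt.exists():
        saved = np.load(ckpt)
        scores[:int(saved["done"])] = saved["scores"][:int(saved["done"])]
        start = int(saved["done"])
    last_saved = start
    for i in range(start, n, batch_size):
        idx = range(i, min(i + batch_size, n))
        tiles = [extract_tile(raster, grid, k % grid.n_cols, k // grid.n_cols)
                 for k in idx]
        aux = aux_matrix[list(idx)] if aux_matrix is not None else None
        scores[list(idx)] = predict_proba(model, tiles, aux)
        if ckpt is not None and (i + batch_size) - last_saved >= checkpoint_every:
            np.savez(ckpt, scores=scores, done=min(i + batch_size, n))
            last_saved = i + batch_size
    if ckpt is not None:
        np.savez(ckpt, scores=scores, done=n)
    rows, cols = np.divmod(np.arange(n), grid.n_cols)
    return pd.DataFrame({"col": cols, "row": rows, "score": scores,
                         "flag": scores > alpha})


def merge_detections(scan: pd.DataFrame, grid: TileGrid,
                     alpha: float | None = None) -> DetectionSet:
    """Merge adjacent flagged tiles (8-connectivity) into detections.

    Each connected component becomes one detection whose location is the
    area centroid of the union polygon of its member tiles — for a
    rectangular block this is its geometric center (e.g. the shared corner
    of a 2x2 block).
    """
    flags = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    flags[scan["row"], scan["col"]] = scan["flag"]
    score_map = np.zeros_like(flags, dtype=float)
    score_map[scan["row"], scan["col"]] = scan["score"]
    labeled, n_comp = ndimage.label(flags, structure=np.ones((3, 3), dtype=int))
    detections = []
    for comp in range(1, n_comp + 1):
        rr, cc = np.nonzero(labeled == comp)
        boxes = [box(*grid.tile_bounds(c, r)) for c, r in zip(cc, rr)]
        centroid = unary_union(boxes).centroid
        detections.append(Detection(
            centroid_xy=(centroid.x, centroid.y),
            member_tiles=[(int(c), int(r)) for c, r in zip(cc, rr)],
            max_score=float(score_map[rr, cc].max())))
    return DetectionSet(detections=detections,
                        total_tiles_scanned=grid.n_tiles,
                        n_flagged_tiles=int(flags.sum()),
                        threshold=float(alpha) if alpha is not None else float("nan"))


def reduction_report(total_tiles: int, detections: DetectionSet) -> ReductionReport:
    """Manual-review search-space reduction: total tiles / merged candidates."""
    n_review = len(detections)
    fold = total_tiles / n_review if n_review > 0 else None
    return ReductionReport(total_candidates=total_tiles,
                           n_for_review=n_review, fold_reduction=fold)


def export_detections(ds: DetectionSet, outdir: str | Path) -> tuple[Path, Path]:
    """GeoJSON points + a CSV review worklist ordered by descending score."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features = [{
        "type": "Feature",
        "properties": {"score": d.max_score, "n_tiles": len(d.member_tiles)},
        "geometry": {"type": "Point",
                     "coordinates": [d.centroid_xy[0], d.centroid_xy[1]]},
    } for d in ds.detections]
    geojson_path = outdir / "detections.geojson"
    geojson_path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
    rows = sorted(ds.detections, key=lambda d: -d.max_score)
    csv_path = outdir / "review_worklist.csv"
    pd.DataFrame({
        "x_m": [d.centroid_xy[0] for d in rows],
        "y_m": [d.centroid_xy[1] for d in rows],
        "score": [d.max_score for d in rows],
        "n_tiles": [len(d.member_tiles) for d in rows],
    }).to_csv(csv_path, index=False)
    return geojson_path, csv_path


# --- end-to-end training pipeline ----------------------------------------

@dataclass
class PipelineResult:
    model: ClassifierModel
    history: TrainingHistory
    gda_models: dict
    val_report: MetricsReport
    test_report: MetricsReport
    alpha: float
    split_checksum: str
    train_positive_ids: tuple


def _split_checksum(manifest: pd.DataFrame) -> str:
    key = manifest[["tile_id", "split"]].to_csv(index=False)
    return hashlib.sha256(key.encode()).hexdigest()[:16]


def _aux_for(manifest: pd.DataFrame, bundle: SceneBundle, kinds, models,
             mode: str, ranges) -> np.ndarray:
    dist = compute_distance_features(manifest, bundle.roads, bundle.waters)
    return gda_mod.build_aux_matrix(models, dist, kinds, mode=mode, ranges=ranges)


def train_pipeline(bundle: SceneBundle, manifest: pd.DataFrame,
                   config: TrainingConfig,
                   fusion_strategy: str = "none",
                   kinds: tuple[str, ...] = (),
                   aux_mode: str = "gda",
                   gda_holdout_frac: float = 0.2,
                   n_positives: int | None = None,
                   degrade_to: float | None = None,
                   init_model: ClassifierModel | None = None,
                   include_inactive: bool = True,
                   augment: bool = False,
                   ) -> PipelineResult:
    """Train and evaluate one classifier under one fusion configuration.

    When fusion is active, a stratified ``gda_holdout_frac`` of the training
    split is held out to fit the GDA models (per infrastructure kind) and
    excluded from classifier training.  ``n_positives`` subsamples the
    training positives with a seed derived from ``config.seed`` while keeping
    negatives constant (the low-data design); the selected ids are recorded so
    paired strategies see identical subsets.  ``degrade_to`` applies the
    resolution-degradation protocol to every tile before training.
    ``augment`` (off by default) adds one randomly shifted and
    flipped/rotated copy of every classifier-training tile.
    """
    man = manifest.copy()
    if not include_inactive:
        man = man[man["stratum"] != "inactive"]
    parts = {s: man[man["split"] == s] for s in ("train", "val", "test")}
    train_man = parts["train"]

    # low-data subsampling: positives only, negatives constant
    pos = train_man[train_man["label"] == 1]
    if n_positives is not None:
        if n_positives > len(pos):
            raise ValueError(f"requested {n_positives} positives, "
                             f"only {len(pos)} available")
        sub_rng = np.random.default_rng((config.seed, n_positives, 7))
        keep = sub_rng.choice(pos.index.to_numpy(), size=n_positives,
                              replace=False)
        train_man = pd.concat([pos.loc[np.sort(keep)],
                               train_man[train_man["label"] == 0]])
        pos = train_man[train_man["label"] == 1]
    train_pos_ids = tuple(sorted(pos["tile_id"]))

    gda_models: dict = {}
    ranges = None
    fit_man = train_man
    if fusion_strategy != "none":
        if not kinds:
            raise ValueError("fusion requires at least one infrastructure kind")
        hold_rng = np.random.default_rng((config.seed, 13))
        hold_idx = []
        for label, grp in train_man.groupby("label"):
            k = max(int(round(gda_holdout_frac * len(grp))), 2)
            hold_idx.extend(hold_rng.choice(grp.index.to_numpy(), size=k,
                                            replace=False))
        holdout = train_man.loc[sorted(hold_idx)]
        fit_man = train_man.drop(index=hold_idx)
        dist = compute_distance_features(holdout, bundle.roads, bundle.waters)
        if aux_mode == "gda":
            for kind in kinds:
                gda_models[kind] = gda_mod.fit_gda(
                    dist[f"d_{kind}_m"], holdout["label"].to_numpy(), kind)
        else:
            ranges = {kind: (float(dist[f"d_{kind}_m"].min()),
                             float(dist[f"d_{kind}_m"].max()))
                      for kind in kinds}

    def tiles_of(m: pd.DataFrame):
        tiles = extract_tiles(bundle, m)
        if degrade_to is not None:
            tiles = [degrade_resolution(t, degrade_to) for t in tiles]
        return tiles

    aux_dim = 0
    aux = {}
    if fusion_strategy != "none":
        per_kind = 3 if aux_mode == "gda" else 1
        aux_dim = per_kind * len(kinds)
        for name, m in (("train", fit_man), ("val", parts["val"]),
                        ("test", parts["test"])):
            aux[name] = _aux_for(m, bundle, kinds, gda_models, aux_mode, ranges)

    fit_tiles = tiles_of(fit_man)
    fit_labels = fit_man["label"].to_numpy()
    fit_aux = aux.get("train")
    if augment:
        # one shifted + flipped/rotated copy per training tile, so the model
        # also sees settlements away from the tile center (the geometry a
        # deployment grid produces); off by default
        aug_rng = np.random.default_rng((config.seed, 29))
        shift = 0.35 * bundle.config.tile_size_m
        extra = []
        for row in fit_man.itertuples():
            dx, dy = aug_rng.uniform(-shift, shift, 2)
            tile = extract_window(bundle.raster, bundle.resolution_m_per_px,
                                  (row.x_m + dx, row.y_m + dy),
                                  bundle.config.tile_size_m, bundle.origin_xy)
            if degrade_to is not None:
                tile = degrade_resolution(tile, degrade_to)
            px = np.rot90(tile.pixels, int(aug_rng.integers(4)))
            if aug_rng.random() < 0.5:
                px = px[:, ::-1]
            tile.pixels = np.ascontiguousarray(px)
            extra.append(tile)
        fit_tiles = fit_tiles + extra
        fit_labels = np.concatenate([fit_labels, fit_labels])
        if fit_aux is not None:
            fit_aux = np.concatenate([fit_aux, fit_aux])

    model = init_model if init_model is not None else build_model(
        fusion_strategy=fusion_strategy, aux_dim=aux_dim, seed=config.seed)
    trainer = train if init_model is None else fine_tune
    trained, history = trainer(
        model, fit_tiles, fit_labels,
        tiles_of(parts["val"]), parts["val"]["label"].to_numpy(), config,
        fit_aux, aux.get("val"))

    val_scores = predict_proba(trained, tiles_of(parts["val"]), aux.get("val"))
    y_val = parts["val"]["label"].to_numpy()
    alpha = calibrate_threshold(val_scores, y_val, config.target_recall)
    test_scores = predict_proba(trained, tiles_of(parts["test"]), aux.get("test"))
    return PipelineResult(
        model=trained, history=history, gda_models=gda_models,
        val_report=evaluate(val_scores, y_val, config.target_recall),
        test_report=evaluate(test_scores, parts["test"]["label"].to_numpy(),
                             config.target_recall),
        alpha=alpha, split_checksum=_split_checksum(man),
        train_positive_ids=train_pos_ids)


# --- experiment runners --------------------------------------------------

def run_resolution_ablation(bundle: SceneBundle, manifest: pd.DataFrame,
                            resolutions: list[float],
                            config: TrainingConfig) -> pd.DataFrame:
    """One train+eval cycle per target resolution on identical splits/seeds."""
    src = bundle.resolution_m_per_px
    rows = []
    for res in resolutions:
        if res < src:
            raise ValueError(f"target {res} finer than source {src} m/px")
        result = train_pipeline(bundle, manifest, config,
                                degrade_to=None if res == src else res)
        rows.append({"resolution_m_per_px": res,
                     "auprc": result.val_report.auprc,
                     "precision_at_recall": result.val_report.precision_at_recall,
                     "best_f1": result.val_report.best_f1,
                     "test_auprc": result.test_report.auprc,
                     "test_precision_at_recall": result.test_report.precision_at_recall,
                     "split_checksum": result.split_checksum})
    return pd.DataFrame(rows)


STRATEGY_KINDS = {"none": (), "water": ("water",), "road": ("road",),
                  "water+road": ("water", "road")}


def run_low_data_ablation(bundle: SceneBundle, manifest: pd.DataFrame,
                          positive_counts: list[int],
                          strategies: list[tuple[str, str]],
                          config: TrainingConfig,
                          aux_mode: str = "gda") -> pd.DataFrame:
    """Low-data grid: positives subsampled per count (fixed derived seed,
    identical subsets across strategies), negatives held constant.

    ``strategies`` pairs an auxiliary-data class ("none", "water", "road",
    "water+road") with a fusion strategy ("none", "aux1", "aux2", "aux12").
    """
    rows = []
    for count in positive_counts:
        for aux_class, fusion_strategy in strategies:
            kinds = STRATEGY_KINDS[aux_class]
            result = train_pipeline(
                bundle, manifest, config,
                fusion_strategy=fusion_strategy if kinds else "none",
                kinds=kinds, aux_mode=aux_mode, n_positives=count)
            rows.append({"n_positives": count, "aux_class": aux_class,
                         "fusion": fusion_strategy if kinds else "none",
                         "auprc": result.val_report.auprc,
                         "precision_at_recall": result.val_report.precision_at_recall,
                         "best_f1": result.val_report.best_f1,
                         "positive_ids": result.train_positive_ids,
                         "split_checksum": result.split_checksum})
    return pd.DataFrame(rows)
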