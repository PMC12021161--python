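"""Seeded generator of georeferenced synthetic scenes for the settlement
localization pipeline.

A scene emulates the statistical structure the method assumes, without any
imagery download: a textured background raster, road and waterway polylines,
active settlements (dark circular livestock enclosures with hut blobs and
grazed bare ground), inactive settlements (burn marks and vegetation
overgrowth, no intact enclosure), and stratified negative points
(near-settlement, random-national, random-continental).  Active settlements
are placed so that their realized distances to the nearest road and waterway
follow class-1 Gaussians truncated at zero; inactive settlements and the
random negative strata follow the class-0 Gaussians.  Near-settlement
negatives are placed uniformly within 1 km of an active settlement (their
infrastructure distances are therefore inherited, which is what makes them
hard negatives).

Placement is by rejection sampling against the realized polyline network: a
distance pair is drawn from the target distributions, candidate locations are
proposed from a distance-transform grid, and a candidate is accepted only if
its exact polyline distances match the draw to within a small tolerance, so
the image content and the distance covariate stay consistent.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.stats import truncnorm

from .geo_features import InfrastructureSet, write_infrastructure, read_infrastructure
from .geoimagery import extract_window, write_raster, read_raster, DEFAULT_TILE_SIZE_M


class PlacementError(RuntimeError):
    """Raised when the region cannot host the requested points without overlap."""


# --- configuration -------------------------------------------------------

@dataclass
class SceneConfig:
    """Generator parameters.  Distance params are (mu0, sigma0, mu1, sigma1)
    in meters: class 1 = active settlements, class 0 = other points."""

    region_width_m: float = 10240.0
    region_height_m: float = 10240.0
    resolution_m_per_px: float = 2.0
    n_active: int = 200
    n_inactive: int = 100
    negative_strata: list = field(default_factory=lambda: [
        ("near_settlement", 150),
        ("random_national", 150),
        ("random_continental", 300),
    ])
    road_distance_params: tuple = (2000.0, 800.0, 200.0, 100.0)
    water_distance_params: tuple = (2000.0, 800.0, 200.0, 100.0)
    seed: int = 0
    tile_size_m: float = DEFAULT_TILE_SIZE_M
    settlement_radius_m: float = 16.0
    near_settlement_max_m: float = 1000.0
    min_separation_m: float | None = None  # default: tile_size_m + 4
    n_waters: int = 3

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("counts must be >= 0")
        for name, count in self.negative_strata:
            if count < 0:
                raise ValueError(f"stratum {name!r} count must be >= 0")
        for params in (self.road_distance_params, self.water_distance_params):
            if params[1] <= 0 or params[3] <= 0:
                raise ValueError("sigma parameters must be > 0")
        if self.resolution_m_per_px <= 0:
            raise ValueError("resolution must be > 0")

    @property
    def separation(self) -> float:
        return (self.min_separation_m if self.min_separation_m is not None
                else self.tile_size_m + 4.0)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["negative_strata"] = [list(s) for s in d["negative_strata"]]
        d["road_distance_params"] = list(d["road_distance_params"])
        d["water_distance_params"] = list(d["water_distance_params"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["negative_strata"] = [tuple(s) for s in d["negative_strata"]]
        d["road_distance_params"] = tuple(d["road_distance_params"])
        d["water_distance_params"] = tuple(d["water_distance_params"])
        return cls(**d)


@dataclass
class SceneBundle:
    """A rendered scene: raster, infrastructure, ground truth, manifest."""

    raster: np.ndarray                      # (H, W, 3) uint8
    origin_xy: tuple[float, float]
    resolution_m_per_px: float
    roads: InfrastructureSet
    waters: InfrastructureSet
    settlements: list                       # (x_m, y_m, active_flag)
    manifest: pd.DataFrame                  # tile_id, x_m, y_m, label, stratum
    config: SceneConfig

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.raster.tobytes())
        for infra in (self.roads, self.waters):
            for line in infra.lines:
                h.update(np.ascontiguousarray(line).tobytes())
        buf = io.StringIO()
        self.manifest.to_csv(buf, index=False)
        h.update(buf.getvalue().encode())
        return h.hexdigest()


# --- infrastructure layout -----------------------------------------------

def _wander(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random lateral wander in [-amplitude, amplitude]."""
    raw = np.cumsum(rng.standard_normal(n))
    raw -= raw.mean()
    peak = np.abs(raw).max()
    return raw / peak * amplitude if peak > 0 else raw


def _make_infrastructure(cfg: SceneConfig, rng: np.random.Generator
                         ) -> tuple[InfrastructureSet, InfrastructureSet]:
    """Waterways as sinuous west-east lines through the central band, roads
    following them with an independent wander (roads track rivers, so the
    road-water gap sweeps continuously through 0..~800 m), plus one
    north-south road through the center."""
    w, h = cfg.region_width_m, cfg.region_height_m
    n_vert = 17
    xs = np.linspace(0.0, w, n_vert)
    waters, roads = [], []
    bases = np.linspace(0.38, 0.62, cfg.n_waters) * h
    water_amp, road_amp = 0.044 * h, 0.034 * h
    for y0 in bases:
        wy = y0 + _wander(n_vert, water_amp, rng)
        waters.append(np.column_stack([xs, wy]))
        ry = y0 + _wander(n_vert, road_amp, rng) + rng.normal(0, road_amp / 6.0)
        roads.append(np.column_stack([xs, ry]))
    # one road crossing the band north-south
    ys = np.linspace(0.30 * h, 0.70 * h, 9)
    rx = 0.5 * w + _wander(9, 0.03 * w, rng)
    roads.append(np.column_stack([rx, ys]))
    clip = lambda lines: [np.column_stack([np.clip(l[:, 0], 0, w),
                                           np.clip(l[:, 1], 0, h)]) for l in lines]
    return (InfrastructureSet(clip(roads), "road"),
            InfrastructureSet(clip(waters), "water"))


# --- placement -----------------------------------------------------------

_EDT_CELL_M = 8.0
_EXACT_TOL_M = 6.0


def _distance_grid(infra: InfrastructureSet, w: float, h: float) -> np.ndarray:
    """Approximate distance-to-network on a coarse grid (meters), used only
    to propose candidates; acceptance uses exact polyline distances."""
    nc, nr = int(np.ceil(w / _EDT_CELL_M)), int(np.ceil(h / _EDT_CELL_M))
    mask = np.ones((nr, nc), dtype=bool)
    for line in infra.lines:
        for (x0, y0), (x1, y1) in zip(line[:-1], line[1:]):
            length = float(np.hypot(x1 - x0, y1 - y0))
            n = max(int(length / (_EDT_CELL_M / 2.0)), 2)
            t = np.linspace(0.0, 1.0, n)
            cc = np.clip(((x0 + t * (x1 - x0)) / _EDT_CELL_M).astype(int), 0, nc - 1)
            rr = np.clip(((y0 + t * (y1 - y0)) / _EDT_CELL_M).astype(int), 0, nr - 1)
            mask[rr, cc] = False
    return ndimage.distance_transform_edt(mask) * _EDT_CELL_M


def _truncnorm(mu: float, sigma: float, rng: np.random.Generator) -> float:
    return float(truncnorm.rvs(-mu / sigma, np.inf, loc=mu, scale=sigma,
                               random_state=rng))


def truncated_normal_mean(mu: float, sigma: float) -> float:
    """Mean of N(mu, sigma^2) truncated at zero (documented placement shift)."""
    return float(truncnorm.mean(-mu / sigma, np.inf, loc=mu, scale=sigma))


class _Placer:
    def __init__(self, cfg: SceneConfig, roads: InfrastructureSet,
                 waters: InfrastructureSet, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.roads_geom = roads.geometry
        self.waters_geom = waters.geometry
        self.Dr = _distance_grid(roads, cfg.region_width_m, cfg.region_height_m)
        self.Dw = _distance_grid(waters, cfg.region_width_m, cfg.region_height_m)
        margin = cfg.tile_size_m
        nr, nc = self.Dr.shape
        ys = (np.arange(nr) + 0.5) * _EDT_CELL_M
        xs = (np.arange(nc) + 0.5) * _EDT_CELL_M
        in_bounds = ((ys >= margin)[:, None] & (ys <= cfg.region_height_m - margin)[:, None]
                     & (xs >= margin)[None, :] & (xs <= cfg.region_width_m - margin)[None, :])
        self.margin = margin
        self.placed: list[tuple[float, float]] = []
        # binned (Dr, Dw) index over in-bounds cells for O(1) proposals
        self._bin = 2.0 * _EDT_CELL_M
        cells = np.flatnonzero(in_bounds)
        dr_flat, dw_flat = self.Dr.ravel()[cells], self.Dw.ravel()[cells]
        self._n_bins_w = int(dw_flat.max() / self._bin) + 2
        keys = ((dr_flat / self._bin).astype(np.int64) * self._n_bins_w
                + (dw_flat / self._bin).astype(np.int64))
        order = np.argsort(keys, kind="stable")
        self._cells_sorted = cells[order]
        self._keys_sorted = keys[order]

    def _candidates(self, dr: float, dw: float) -> np.ndarray:
        """In-bounds grid cells with both distances within one bin of the draw."""
        kr, kw = int(dr / self._bin), int(dw / self._bin)
        chunks = []
        for br in (kr - 1, kr, kr + 1):
            if br < 0:
                continue
            lo = np.searchsorted(self._keys_sorted, br * self._n_bins_w + max(kw - 1, 0))
            hi = np.searchsorted(self._keys_sorted, br * self._n_bins_w + kw + 1,
                                 side="right")
            if hi > lo:
                chunks.append(self._cells_sorted[lo:hi])
        if not chunks:
            return np.empty(0, dtype=np.int64)
        cand = np.concatenate(chunks)
        keep = ((np.abs(self.Dr.ravel()[cand] - dr) < 1.2 * _EDT_CELL_M)
                & (np.abs(self.Dw.ravel()[cand] - dw) < 1.2 * _EDT_CELL_M))
        return cand[keep]

    def _separated(self, x: float, y: float) -> bool:
        if not self.placed:
            return True
        arr = np.asarray(self.placed)
        return bool(np.min(np.hypot(arr[:, 0] - x, arr[:, 1] - y))
                    >= self.cfg.separation)

    def _exact_distances(self, x: float, y: float) -> tuple[float, float]:
        from shapely.geometry import Point
        p = Point(x, y)
        return p.distance(self.roads_geom), p.distance(self.waters_geom)

    def place_with_distances(self, road_mu_sigma, water_mu_sigma,
                             max_attempts: int = 250) -> tuple[float, float]:
        """Place one point whose exact road/water distances realize fresh
        truncated-normal draws (within the acceptance tolerance)."""
        for _ in range(max_attempts):
            dr = _truncnorm(*road_mu_sigma, self.rng)
            dw = _truncnorm(*water_mu_sigma, self.rng)
            cand = self._candidates(dr, dw)
            if len(cand) == 0:
                continue
            picks = self.rng.choice(cand, size=min(len(cand), 60), replace=False)
            nr, nc = self.Dr.shape
            for flat in picks:
                r, c = divmod(int(flat), nc)
                x = (c + 0.5) * _EDT_CELL_M + self.rng.uniform(-4, 4)
                y = (r + 0.5) * _EDT_CELL_M + self.rng.uniform(-4, 4)
                if not self._separated(x, y):
                    continue
                er, ew = self._exact_distances(x, y)
                if abs(er - dr) <= _EXACT_TOL_M and abs(ew - dw) <= _EXACT_TOL_M:
                    self.placed.append((x, y))
                    return x, y
        raise PlacementError(
            "could not place a point with the requested infrastructure "
            "distances; the region is too small or too crowded")

    def place_near(self, anchors: np.ndarray, max_attempts: int = 500
                   ) -> tuple[float, float]:
        """Place one point uniformly in an annulus around a random anchor."""
        cfg = self.cfg
        lo = cfg.separation
        hi = cfg.near_settlement_max_m
        for _ in range(max_attempts):
            ax, ay = anchors[self.rng.integers(len(anchors))]
            r = np.sqrt(self.rng.uniform(lo ** 2, hi ** 2))
            th = self.rng.uniform(0, 2 * np.pi)
            x, y = ax + r * np.cos(th), ay + r * np.sin(th)
            if not (self.margin <= x <= cfg.region_width_m - self.margin
                    and self.margin <= y <= cfg.region_height_m - self.margin):
                continue
            if self._separated(x, y):
                self.placed.append((x, y))
                return x, y
        raise PlacementError("could not place a near-settlement negative")


# --- rendering -----------------------------------------------------------

_BASE_PALETTE = np.array([0.72, 0.65, 0.55])       # semi-arid rangeland
_CONTINENTAL_PALETTES = np.array([
    [0.45, 0.55, 0.35],   # savanna green
    [0.80, 0.72, 0.58],   # sandy
    [0.50, 0.45, 0.40],   # rocky
    [0.35, 0.45, 0.30],   # forested
])
_ROAD_COLOR = np.array([0.82, 0.77, 0.68])
_WATER_COLOR = np.array([0.25, 0.35, 0.32])


def _smooth_field(shape: tuple[int, int], sigma_px: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Low-frequency unit-amplitude noise, synthesized at quarter scale."""
    h, w = shape
    hc, wc = max(h // 4, 1), max(w // 4, 1)
    coarse = ndimage.gaussian_filter(rng.standard_normal((hc, wc)),
                                     sigma=max(sigma_px / 4.0, 0.5))
    field = ndimage.zoom(coarse, (h / hc, w / wc), order=1)[:h, :w]
    return field / max(np.abs(field).max(), 1e-9)


def _background(shape: tuple[int, int], palette: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    low = _smooth_field(shape, 12.0, rng)
    speckle = rng.normal(0.0, 0.02, (h, w))
    canvas = (palette[None, None, :]
              * (1.0 + 0.10 * low + speckle)[:, :, None]).astype(np.float32)
    canvas[:, :, 1] += (0.03 * _smooth_field(shape, 24.0, rng)).astype(np.float32)
    return np.clip(canvas, 0.0, 1.0)


def _draw_lines(canvas: np.ndarray, infra: InfrastructureSet, color: np.ndarray,
                width_m: float, res: float) -> None:
    h, w = canvas.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    step = res / 2.0
    for line in infra.lines:
        for (x0, y0), (x1, y1) in zip(line[:-1], line[1:]):
            length = float(np.hypot(x1 - x0, y1 - y0))
            n = max(int(length / step), 2)
            t = np.linspace(0.0, 1.0, n)
            cc = np.clip(((x0 + t * (x1 - x0)) / res).astype(int), 0, w - 1)
            rr = np.clip(((y0 + t * (y1 - y0)) / res).astype(int), 0, h - 1)
            mask[rr, cc] = True
    radius = max(int(round(width_m / res / 2.0)), 1)
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    mask = ndimage.binary_dilation(mask, structure=yy * yy + xx * xx <= radius * radius)
    canvas[mask] = 0.8 * color + 0.2 * canvas[mask]


def _local_window(canvas: np.ndarray, cx: int, cy: int, half: int):
    h, w = canvas.shape[:2]
    r0, r1 = max(cy - half, 0), min(cy + half + 1, h)
    c0, c1 = max(cx - half, 0), min(cx + half + 1, w)
    yy, xx = np.mgrid[r0 - cy:r1 - cy, c0 - cx:c1 - cx]
    return canvas[r0:r1, c0:c1], np.hypot(yy, xx)


def _draw_active(canvas: np.ndarray, cx: int, cy: int, radius_px: float,
                 rng: np.random.Generator) -> None:
    """Dark circular enclosure (kraal), interior bare ground, hut blobs."""
    half = int(np.ceil(radius_px * 1.8)) + 2
    win, dist = _local_window(canvas, cx, cy, half)
    thickness = max(radius_px * 0.28, 1.2)
    ring = np.abs(dist - radius_px) <= thickness / 2.0
    interior = dist < radius_px - thickness / 2.0
    win[interior] = np.clip(win[interior] * 1.10 + 0.04, 0, 1)   # grazed bare ground
    win[ring] *= 0.45                                            # dark enclosure
    n_huts = int(rng.integers(1, 4))
    for _ in range(n_huts):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, max(radius_px - thickness, 1.0) * 0.6)
        hx = int(round(rad * np.cos(ang)))
        hy = int(round(rad * np.sin(ang)))
        hut_r = max(radius_px * 0.15, 1.0)
        hut = np.hypot(*np.indices(dist.shape) -
                       np.array([dist.shape[0] // 2 + hy,
                                 dist.shape[1] // 2 + hx])[:, None, None]) <= hut_r
        win[hut] = np.clip(win[hut] * 0.5 + np.array([0.30, 0.24, 0.18]), 0, 1)


def _draw_inactive(canvas: np.ndarray, cx: int, cy: int, radius_px: float,
                   rng: np.random.Generator) -> None:
    """Burn-mark blotches and vegetation overgrowth; no intact enclosure."""
    half = int(np.ceil(radius_px * 2.0)) + 2
    win, dist = _local_window(canvas, cx, cy, half)
    n_blotch = int(rng.integers(3, 7))
    for _ in range(n_blotch):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, radius_px * 1.1)
        bx, by = rad * np.cos(ang), rad * np.sin(ang)
        br = rng.uniform(0.25, 0.6) * radius_px
        yy, xx = np.indices(dist.shape)
        d2 = ((yy - dist.shape[0] // 2 - by) ** 2 + (xx - dist.shape[1] // 2 - bx) ** 2)
        blotch = np.exp(-d2 / max(2 * br * br, 1.0))
        win *= (1.0 - 0.45 * blotch)[:, :, None] if win.ndim == 3 else 1
    grow = ndimage.gaussian_filter(rng.standard_normal(dist.shape), sigma=2)
    grow = (grow > 0.3) & (dist < radius_px * 1.6)
    win[grow] = 0.6 * win[grow] + 0.4 * np.array([0.35, 0.50, 0.30])


def render_settlement(active: bool, size_px: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Standalone settlement patch on a textured background, [0, 1] floats.

    Active patches contain a dark annulus at ~30% of the patch size and at
    least one hut blob; inactive patches show burn marks and overgrowth.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    patch = _background((size_px, size_px), _BASE_PALETTE, rng)
    c = size_px // 2
    radius = 0.30 * size_px
    if active:
        _draw_active(patch, c, c, radius, rng)
    else:
        _draw_inactive(patch, c, c, radius, rng)
    return np.clip(patch, 0.0, 1.0)


def annulus_contrast(patch: np.ndarray, radius_frac: float = 0.30,
                     thickness_frac: float = 0.10) -> float:
    """Ring-mean over background-mean intensity; < 1 signals a dark enclosure."""
    size = patch.shape[0]
    c = size // 2
    yy, xx = np.indices(patch.shape[:2])
    dist = np.hypot(yy - c, xx - c)
    radius = radius_frac * size
    ring = np.abs(dist - radius) <= thickness_frac * size / 2.0
    outside = dist > radius * 1.5
    gray = patch.mean(axis=2) if patch.ndim == 3 else patch
    return float(gray[ring].mean() / gray[outside].mean())


# --- scene assembly ------------------------------------------------------

def generate_scene(config: SceneConfig) -> SceneBundle:
    """Render a full synthetic scene; byte-identical for identical configs."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    res = cfg.resolution_m_per_px
    h_px = int(round(cfg.region_height_m / res))
    w_px = int(round(cfg.region_width_m / res))

    roads, waters = _make_infrastructure(cfg, rng)
    placer = _Placer(cfg, roads, waters, rng)

    mu0r, s0r, mu1r, s1r = cfg.road_distance_params
    mu0w, s0w, mu1w, s1w = cfg.water_distance_params

    records = []
    actives = []
    for i in range(cfg.n_active):
        x, y = placer.place_with_distances((mu1r, s1r), (mu1w, s1w))
        actives.append((x, y))
        records.append((f"act{i:04d}", x, y, 1, "active"))
    for i in range(cfg.n_inactive):
        x, y = placer.place_with_distances((mu0r, s0r), (mu0w, s0w))
        records.append((f"ina{i:04d}", x, y, 0, "inactive"))
    anchors = np.asarray(actives) if actives else None
    for stratum, count in cfg.negative_strata:
        for i in range(count):
            if stratum == "near_settlement":
                if anchors is None:
                    raise PlacementError("near-settlement stratum requires actives")
                x, y = placer.place_near(anchors)
            else:
                x, y = placer.place_with_distances((mu0r, s0r), (mu0w, s0w))
            records.append((f"{stratum}{i:04d}", x, y, 0, stratum))

    canvas = _background((h_px, w_px), _BASE_PALETTE, rng)
    # continental negatives sit on visually distinct terrain
    half_px = int(cfg.tile_size_m / res / 2)
    for tile_id, x, y, label, stratum in records:
        if stratum == "random_continental":
            cx, cy = int(x / res), int(y / res)
            pal = _CONTINENTAL_PALETTES[rng.integers(len(_CONTINENTAL_PALETTES))]
            r0, c0 = max(cy - half_px, 0), max(cx - half_px, 0)
            r1, c1 = min(cy + half_px, h_px), min(cx + half_px, w_px)
            canvas[r0:r1, c0:c1] = _background((r1 - r0, c1 - c0), pal, rng)

    _draw_lines(canvas, waters, _WATER_COLOR, width_m=14.0, res=res)
    _draw_lines(canvas, roads, _ROAD_COLOR, width_m=8.0, res=res)

    radius_px = cfg.settlement_radius_m / res
    settlements = []
    for tile_id, x, y, label, stratum in records:
        if stratum == "active":
            _draw_active(canvas, int(x / res), int(y / res), radius_px, rng)
            settlements.append((x, y, True))
        elif stratum == "inactive":
            _draw_inactive(canvas, int(x / res), int(y / res), radius_px, rng)
            settlements.append((x, y, False))

    raster = (np.clip(canvas, 0, 1) * 255).round().astype(np.uint8)
    manifest = pd.DataFrame(records,
                            columns=["tile_id", "x_m", "y_m", "label", "stratum"])
    manifest["col_px"] = (manifest["x_m"] / res).astype(int)
    manifest["row_px"] = (manifest["y_m"] / res).astype(int)
    return SceneBundle(raster=raster, origin_xy=(0.0, 0.0),
                       resolution_m_per_px=res, roads=roads, waters=waters,
                       settlements=settlements, manifest=manifest, config=cfg)


# --- dataset assembly ----------------------------------------------------

def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    quotas = fractions * n
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def make_labeled_dataset(bundle: SceneBundle | pd.DataFrame,
                         split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                         seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test splits, stratified, with largest-remainder
    rounding so split sizes are exact per stratum (within one tile).

    Accepts a SceneBundle or a bare manifest DataFrame.
    """
    fracs = np.asarray(split_fractions, dtype=float)
    if np.any(fracs <= 0) or not np.isclose(fracs.sum(), 1.0):
        raise ValueError("split fractions must be positive and sum to 1")
    manifest = (bundle if isinstance(bundle, pd.DataFrame)
                else bundle.manifest).copy()
    if manifest.empty:
        raise ValueError("bundle manifest is empty")
    rng = np.random.default_rng(seed)
    split_names = np.array(["train", "val", "test"])
    splits = pd.Series(index=manifest.index, dtype=object)
    for stratum, group in manifest.groupby("stratum", sort=True):
        idx = group.index.to_numpy()
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fracs)
        assigned = np.repeat(split_names, counts)
        splits.loc[idx] = assigned
    manifest["split"] = splits
    return manifest


def extract_tiles(bundle: SceneBundle, manifest: pd.DataFrame) -> list:
    """Tile-sized image windows centered on each manifest point."""
    return [extract_window(bundle.raster, bundle.resolution_m_per_px,
                           (row.x_m, row.y_m), bundle.config.tile_size_m,
                           bundle.origin_xy)
            for row in manifest.itertuples()]


# --- IO ------------------------------------------------------------------

def write_scene(bundle: SceneBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_raster(outdir / "scene.tif", bundle.raster, bundle.origin_xy,
                 bundle.resolution_m_per_px)
    write_infrastructure(bundle.roads, outdir / "roads.geojson")
    write_infrastructure(bundle.waters, outdir / "waters.geojson")
    bundle.manifest.to_csv(outdir / "manifest.csv", index=False)
    bundle.config.to_yaml(outdir / "config.yaml")


def read_scene(indir: str | Path) -> SceneBundle:
    indir = Path(indir)
    raster, meta = read_raster(indir / "scene.tif")
    cfg = SceneConfig.from_yaml(indir / "config.yaml")
    manifest = pd.read_csv(indir / "manifest.csv")
    roads = read_infrastructure(indir / "roads.geojson", "road")
    waters = read_infrastructure(indir / "waters.geojson", "water")
    settlements = [(r.x_m, r.y_m, r.stratum == "active")
                   for r in manifest.itertuples()
                   if r.stratum in ("active", "inactive")]
    return SceneBundle(raster=raster, origin_xy=tuple(meta["origin_xy"]),
                       resolution_m_per_px=meta["resolution_m_per_px"],
                       roads=roads, waters=waters, settlements=settlements,
                       manifest=manifest, config=cfg)


def write_tiles(bundle: SceneBundle, manifest: pd.DataFrame,
                outdir: str | Path) -> pd.DataFrame:
    """Write one PNG per manifest tile; returns the manifest with paths."""
    import imageio.v3 as iio
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for row in manifest.itertuples():
        tile = extract_window(bundle.raster, bundle.resolution_m_per_px,
                              (row.x_m, row.y_m), bundle.config.tile_size_m,
                              bundle.origin_xy)
        path = outdir / f"{row.tile_id}.png"
        iio.imwrite(path, (tile.pixels * 255).astype(np.uint8))
        paths.append(str(path))
    manifest["path"] = paths
    return manifest
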