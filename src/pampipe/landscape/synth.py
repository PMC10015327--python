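"""Synthetic landscapes: stratified site networks, land-cover/road/building
layers, and spatially autocorrelated occurrence with 7-day detection
histories at known ground truth."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from shapely.geometry import LineString, Polygon, mapping

from ..review import DetectionHistory, N_DAYS

__all__ = [
    "Site",
    "LandscapeLayers",
    "OccurrenceTruth",
    "synth_sites",
    "synth_layers",
    "synth_occurrence",
    "LAND_USES",
]

LAND_USES = ("old_growth", "secondary", "mangrove", "grassland", "palm", "teak")

#: land uses painted as forest in the raster
FOREST_USES = {"old_growth", "secondary"}


@dataclass(frozen=True)
class Site:
    site_id: str
    x: float
    y: float
    land_use: str
    elevation: float = 0.0


@dataclass
class LandscapeLayers:
    """Raster land-use grid plus vector roads and buildings (planar metres)."""

    raster: np.ndarray  # integer land-use codes, index [iy, ix]
    cell_size: float  # m
    origin: tuple[float, float]  # (x0, y0) of the lower-left raster corner
    forest_codes: frozenset
    primary_roads: list[LineString] = field(default_factory=list)
    secondary_roads: list[LineString] = field(default_factory=list)
    buildings: list[Polygon] = field(default_factory=list)

    def covers(self, x: float, y: float, radius: float) -> bool:
        x0, y0 = self.origin
        ny, nx = self.raster.shape
        return (
            x - radius >= x0
            and y - radius >= y0
            and x + radius <= x0 + nx * self.cell_size
            and y + radius <= y0 + ny * self.cell_size
        )


@dataclass
class OccurrenceTruth:
    """Generating parameters for occurrence and detection.

    ``beta`` are logistic coefficients on the named covariates (standardised
    internally is up to the caller); ``forest_threshold`` adds a steep
    logistic inflection at that percent cover when set.
    """

    intercept: float = 0.0
    beta: dict = field(default_factory=dict)
    scale_true: float = 200.0
    forest_threshold: float | None = 80.0
    threshold_steepness: float = 0.5  # logit units per percent cover
    road_exclusion_m: float | None = 1000.0
    field_sd: float = 0.0  # spatial random-field SD on the logit scale
    field_range_m: float = 2000.0  # exponential covariance range
    p_daily: float = 0.68

    def __post_init__(self):
        if not (0.0 < self.p_daily < 1.0):
            raise ValueError("p_daily must be in (0, 1)")


def synth_sites(
    n: int,
    region: tuple[float, float] = (33000.0, 33000.0),
    strata_weights: dict | None = None,
    min_dist: float = 500.0,
    seed: int = 0,
    max_tries: int = 200,
) -> list[Site]:
    """Place ``n`` sites with pairwise spacing >= ``min_dist`` (dart throwing).

    Stratum (land-use) labels are assigned in proportion to
    ``strata_weights`` within rounding. Raises if the region cannot hold the
    requested packing after bounded retries.
    """
    if strata_weights is None:
        strata_weights = {u: 1.0 for u in LAND_USES}
    w, h = region
    # quick infeasibility bound: disc packing density cannot exceed ~0.9069
    if n * np.pi * (min_dist / 2) ** 2 > 0.9069 * (w + min_dist) * (h + min_dist):
        raise ValueError(f"cannot place {n} sites at {min_dist} m spacing in {w}x{h} m region")
    rng = np.random.default_rng(seed)
    pts: list[tuple[float, float]] = []
    cell = min_dist / np.sqrt(2)
    grid: dict[tuple[int, int], int] = {}

    def ok(x, y):
        gx, gy = int(x // cell), int(y // cell)
        for dx in range(-2, 3):
            for dy in range(-2, 3):
                j = grid.get((gx + dx, gy + dy))
                if j is not None:
                    px, py = pts[j]
                    if (px - x) ** 2 + (py - y) ** 2 < min_dist**2:
                        return False
        return True

    tries = 0
    while len(pts) < n:
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        if ok(x, y):
            grid[(int(x // cell), int(y // cell))] = len(pts)
            pts.append((x, y))
            tries = 0
        else:
            tries += 1
            if tries > max_tries * max(1, n):
                raise ValueError(
                    f"failed to place {n} sites at {min_dist} m spacing in {w}x{h} m region"
                )

    # proportional stratum allocation (largest remainder)
    total_w = sum(strata_weights.values())
    raw = {u: n * wt / total_w for u, wt in strata_weights.items()}
    counts = {u: int(np.floor(v)) for u, v in raw.items()}
    short = n - sum(counts.values())
    for u in sorted(raw, key=lambda u: raw[u] - counts[u], reverse=True)[:short]:
        counts[u] += 1
    labels = [u for u, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)

    elev = rng.uniform(0, 792, size=n)
    return [
        Site(site_id=f"s{i:04d}", x=pts[i][0], y=pts[i][1], land_use=labels[i], elevation=elev[i])
        for i in range(n)
    ]


def synth_layers(
    sites: list[Site],
    cell_size: float = 25.0,
    max_radius: float = 5000.0,
    seed: int = 0,
    n_secondary_roads: int = 6,
    n_building_clusters: int = 4,
) -> LandscapeLayers:
    """Raster + vector layers consistent with the site strata.

    Forest cover in each site's 200 m buffer is painted to a per-site target
    spread over [0, 1] (forest-stratum sites high, open-stratum sites low),
    so covariates span the full range. One primary road crosses the region;
    secondary roads and building clusters are scattered near it.
    """
    rng = np.random.default_rng(seed)
    xs = np.array([s.x for s in sites])
    ys = np.array([s.y for s in sites])
    x0, y0 = xs.min() - max_radius, ys.min() - max_radius
    x1, y1 = xs.max() + max_radius, ys.max() + max_radius
    nx = int(np.ceil((x1 - x0) / cell_size))
    ny = int(np.ceil((y1 - y0) / cell_size))

    # base mosaic: smoothed threshold noise, ~55% forest
    base = rng.random((max(ny // 16, 2), max(nx // 16, 2)))
    # bilinear upsample to full grid
    gy = np.linspace(0, base.shape[0] - 1, ny)
    gx = np.linspace(0, base.shape[1] - 1, nx)
    iy, fy = np.floor(gy).astype(int), gy - np.floor(gy)
    ix, fx = np.floor(gx).astype(int), gx - np.floor(gx)
    iy1 = np.minimum(iy + 1, base.shape[0] - 1)
    ix1 = np.minimum(ix + 1, base.shape[1] - 1)
    up = (
        base[np.ix_(iy, ix)] * np.outer(1 - fy, 1 - fx)
        + base[np.ix_(iy1, ix)] * np.outer(fy, 1 - fx)
        + base[np.ix_(iy, ix1)] * np.outer(1 - fy, fx)
        + base[np.ix_(iy1, ix1)] * np.outer(fy, fx)
    )
    raster = (up < 0.55).astype(np.int8)  # 1 = forest, 0 = open

    # paint per-site 200 m discs to a target cover spanning [0, 1]
    order = np.argsort([-(s.land_use in FOREST_USES) for s in sites])
    n = len(sites)
    targets = np.zeros(n)
    forest_idx = [i for i, s in enumerate(sites) if s.land_use in FOREST_USES]
    open_idx = [i for i, s in enumerate(sites) if s.land_use not in FOREST_USES]
    if forest_idx:
        targets[forest_idx] = np.linspace(1.0, 0.55, len(forest_idx))
    if open_idx:
        targets[open_idx] = np.linspace(0.45, 0.0, len(open_idx))
    paint_r = 300.0
    for i, s in enumerate(sites):
        cx = int((s.x - x0) / cell_size)
        cy = int((s.y - y0) / cell_size)
        r = int(np.ceil(paint_r / cell_size))
        yy, xx = np.mgrid[max(0, cy - r) : min(ny, cy + r + 1), max(0, cx - r) : min(nx, cx + r + 1)]
        ccx = x0 + (xx + 0.5) * cell_size
        ccy = y0 + (yy + 0.5) * cell_size
        d2 = (ccx - s.x) ** 2 + (ccy - s.y) ** 2
        inside = d2 <= paint_r**2
        # deterministic fill: the targets[i] fraction of nearest cells become forest
        flat_d2 = d2[inside]
        k = int(round(targets[i] * flat_d2.size))
        sel = np.zeros(flat_d2.size, dtype=bool)
        sel[np.argsort(flat_d2)[:k]] = True
        block = raster[max(0, cy - r) : min(ny, cy + r + 1), max(0, cx - r) : min(nx, cx + r + 1)]
        vals = block[inside]
        vals[:] = 0
        vals[sel] = 1
        block[inside] = vals

    # one primary road crossing the region horizontally
    ry = float(rng.uniform(y0 + max_radius, y1 - max_radius))
    primary = [LineString([(x0, ry), (x1, ry)])]
    secondary = []
    for _ in range(n_secondary_roads):
        sx = rng.uniform(x0 + max_radius, x1 - max_radius)
        sy = rng.uniform(y0 + max_radius, y1 - max_radius)
        ang = rng.uniform(0, np.pi)
        ln = rng.uniform(2000, 8000)
        dx, dy = np.cos(ang) * ln / 2, np.sin(ang) * ln / 2
        secondary.append(LineString([(sx - dx, sy - dy), (sx + dx, sy + dy)]))
    buildings = []
    for _ in range(n_building_clusters):
        bx = rng.uniform(x0 + max_radius, x1 - max_radius)
        by = ry + rng.uniform(-2000, 2000)
        for _ in range(int(rng.integers(5, 15))):
            ox, oy = bx + rng.uniform(-400, 400), by + rng.uniform(-400, 400)
            side = rng.uniform(10, 40)
            buildings.append(
                Polygon(
                    [(ox, oy), (ox + side, oy), (ox + side, oy + side), (ox, oy + side)]
                )
            )
    return LandscapeLayers(
        raster=raster,
        cell_size=cell_size,
        origin=(x0, y0),
        forest_codes=frozenset({1}),
        primary_roads=primary,
        secondary_roads=secondary,
        buildings=buildings,
    )


def gaussian_field(coords: np.ndarray, sd: float, range_m: float, rng) -> np.ndarray:
    """GRF values at coords with exponential covariance sd²·exp(-d/range)."""
    n = len(coords)
    if sd == 0:
        return np.zeros(n)
    d = cdist(coords, coords)
    cov = sd**2 * np.exp(-d / range_m)
    cov[np.diag_indices(n)] += 1e-9
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def synth_occurrence(
    sites: list[Site],
    covariates: pd.DataFrame,
    truth: OccurrenceTruth,
    seed: int = 0,
    primary_road_dist: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[DetectionHistory]]:
    """Draw occurrence ~ Bernoulli(logistic(eta + spatial field)) and 7-day
    histories (occupied sites: iid Bernoulli(p_daily) days; else all-zero).

    ``covariates`` must hold the columns named in ``truth.beta`` computed at
    ``truth.scale_true``; a ``forest_threshold`` adds a steep inflection on
    the ``forest_cover`` column; sites within ``road_exclusion_m`` of a
    primary road (``primary_road_dist``) are forced absent.
    """
    rng = np.random.default_rng(seed)
    n = len(sites)
    eta = np.full(n, truth.intercept, dtype=float)
    for name, b in truth.beta.items():
        if name not in covariates.columns:
            raise ValueError(f"covariate {name!r} missing at scale {truth.scale_true} m")
        eta += b * covariates[name].to_numpy(dtype=float)
    if truth.forest_threshold is not None:
        fc_col = [c for c in covariates.columns if c.startswith("forest_cover")]
        if not fc_col:
            raise ValueError("forest_threshold set but no forest_cover column present")
        fc = covariates[fc_col[0]].to_numpy(dtype=float)
        eta += truth.threshold_steepness * (fc - truth.forest_threshold)
    coords = np.array([[s.x, s.y] for s in sites])
    eta += gaussian_field(coords, truth.field_sd, truth.field_range_m, rng)
    psi = 1.0 / (1.0 + np.exp(-eta))
    if truth.road_exclusion_m is not None and primary_road_dist is not None:
        psi = np.where(primary_road_dist <= truth.road_exclusion_m, 0.0, psi)
    z = (rng.random(n) < psi).astype(int)
    histories = []
    for i, s in enumerate(sites):
        if z[i]:
            days = tuple((rng.random(N_DAYS) < truth.p_daily).astype(int))
        else:
            days = (0,) * N_DAYS
        histories.append(DetectionHistory(site_id=s.site_id, days=days))
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "psi_true": psi,
            "occupied_true": z,
            "occurrence": [max(h.days) for h in histories],
        }
    )
    return df, histories


# ---- plain-text round-trip helpers ----------------------------------------

def sites_to_frame(sites: list[Site]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
            "land_use": [s.land_use for s in sites],
            "elevation": [s.elevation for s in sites],
        }
    )


def frame_to_sites(df: pd.DataFrame) -> list[Site]:
    return [
        Site(site_id=r.site_id, x=r.x, y=r.y, land_use=r.land_use, elevation=r.elevation)
        for r in df.itertuples()
    ]


def save_layers(layers: LandscapeLayers, prefix: str) -> None:
    """Raster as a plain-text grid with a JSON georeferencing sidecar;
    roads/buildings as GeoJSON."""
    np.savetxt(prefix + "_raster.txt", layers.raster, fmt="%d")
    with open(prefix + "_raster.json", "w") as fh:
        json.dump(
            {
                "cell_size": layers.cell_size,
                "origin": list(layers.origin),
                "forest_codes": sorted(layers.forest_codes),
            },
            fh,
        )
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"kind": kind}, "geometry": mapping(g)}
            for kind, geoms in (
                ("primary_road", layers.primary_roads),
                ("secondary_road", layers.secondary_roads),
                ("building", layers.buildings),
            )
            for g in geoms
        ],
    }
    with open(prefix + "_vectors.geojson", "w") as fh:
        json.dump(fc, fh)


def load_layers(prefix: str) -> LandscapeLayers:
    from shapely.geometry import shape

    raster = np.loadtxt(prefix + "_raster.txt", dtype=np.int8, ndmin=2)
    with open(prefix + "_raster.json") as fh:
        meta = json.load(fh)
    with open(prefix + "_vectors.geojson") as fh:
        fc = json.load(fh)
    prim, sec, bld = [], [], []
    for feat in fc["features"]:
        g = shape(feat["geometry"])
        kind = feat["properties"]["kind"]
        {"primary_road": prim, "secondary_road": sec, "building": bld}[kind].append(g)
    return LandscapeLayers(
        raster=raster,
        cell_size=meta["cell_size"],
        origin=tuple(meta["origin"]),
        forest_codes=frozenset(meta["forest_codes"]),
        primary_roads=prim,
        secondary_roads=sec,
        buildings=bld,
    )
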