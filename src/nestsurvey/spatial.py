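"""Spatial randomization test of nest placement against landscape features.

Tests whether nests lie farther from (or nearer to) linear and point
features — roads, rivers, settlements — than uniformly random locations
restricted to the surveyed region: a buffer of fixed half-width around the
transect lines.  The observed mean nearest straight-line distance is
compared to the distribution of the same mean over repeated uniform
relocations of the nests inside the buffer (a Monte Carlo randomization
test).

All geometry is planar, in metres (e.g. UTM).  Inputs in geographic
longitude/latitude are rejected rather than silently misinterpreted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.ops import unary_union
from scipy import stats

from .errors import SchemaError

LAYER_KINDS = ("road", "river", "settlement")

__all__ = [
    "LandscapeLayer",
    "BufferRegion",
    "RandomizationResult",
    "nearest_feature_distance",
    "transect_buffer",
    "random_points_in_buffer",
    "randomization_test",
    "mean_distance_summary",
    "unique_points",
    "read_geojson_layer",
    "habitat_feature_kruskal",
]


def _maybe_geographic(coords: np.ndarray) -> bool:
    if coords.size == 0:
        return False
    x, y = coords[:, 0], coords[:, 1]
    return bool(np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0))


@dataclass
class LandscapeLayer:
    """A set of planar features (polylines, points or polygons) of one kind."""

    kind: str
    geometries: list

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise SchemaError(f"unknown layer kind {self.kind!r}; expected {LAYER_KINDS}")
        if not self.geometries:
            raise SchemaError("landscape layer is empty")
        coords = np.concatenate([shapely.get_coordinates(g) for g in self.geometries])
        if not np.all(np.isfinite(coords)):
            raise SchemaError("non-finite coordinate in landscape layer")
        self._union = unary_union(self.geometries)

    @property
    def union(self):
        return self._union


@dataclass
class BufferRegion:
    """Union of fixed-half-width buffers around the transect polylines."""

    transects: list
    half_width_m: float
    region: object = field(default=None)

    def __post_init__(self):
        if not self.transects:
            raise SchemaError("no transect geometry supplied")
        if not self.half_width_m > 0:
            raise SchemaError("buffer half-width must be positive")
        if self.region is None:
            raise SchemaError("region geometry missing; use transect_buffer()")
        if not self.region.area > 0:
            raise SchemaError("buffer region has zero area")

    @property
    def area_km2(self) -> float:
        return float(self.region.area) / 1e6


@dataclass
class RandomizationResult:
    """Observed mean nearest-feature distance against its Monte Carlo null.

    ``p_one_sided`` is the fraction of null means falling below the observed
    mean (so values near 1 indicate nests farther from the feature than
    chance, values near 0 nearer); ``p_two_sided`` doubles the smaller tail.
    ``z`` standardizes the observed mean by the null mean and sd.
    """

    layer_kind: str
    n_points: int
    observed_mean_m: float
    null_means_m: np.ndarray
    z: float
    p_one_sided: float
    p_two_sided: float
    R: int
    seed: int


# ---------------------------------------------------------------------------


def _as_point_array(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise SchemaError("points must be an (n, 2) array of planar coordinates")
    if pts.shape[0] == 0:
        raise SchemaError("no points supplied")
    if not np.all(np.isfinite(pts)):
        raise SchemaError("non-finite point coordinate")
    return pts


def nearest_feature_distance(
    points, layer: LandscapeLayer, check_geographic: bool = True
) -> np.ndarray:
    """Shortest straight-line distance (m) from each point to the layer.

    With ``check_geographic`` (the default), coordinates that all fit inside
    the lon/lat box (|x| <= 180, |y| <= 90) are rejected as likely
    unprojected; disable the guard for deliberately small planar toy
    geometries.
    """
    pts = _as_point_array(points)
    if check_geographic and _maybe_geographic(pts):
        raise SchemaError(
            "coordinates look geographic (lon/lat); project to planar metres first"
        )
    geoms = shapely.points(pts)
    return shapely.distance(geoms, layer.union)


def unique_points(points) -> np.ndarray:
    """Collapse duplicated coordinates (several nests sharing one GPS reading)
    to independent locations."""
    pts = _as_point_array(points)
    return np.unique(pts, axis=0)


def transect_buffer(
    transects: Sequence, half_width_m: float, cap_style: str = "flat"
) -> BufferRegion:
    """Buffer each transect polyline by ``half_width_m`` on both sides and
    merge overlaps, so uniform sampling never double-weights shared area."""
    transects = list(transects)
    if not transects:
        raise SchemaError("no transect geometry supplied")
    if not half_width_m > 0:
        raise SchemaError("buffer half-width must be positive")
    buffers = [t.buffer(half_width_m, cap_style=cap_style) for t in transects]
    region = unary_union(buffers)
    return BufferRegion(transects=transects, half_width_m=float(half_width_m), region=region)


def random_points_in_buffer(region: BufferRegion, n: int, seed: int) -> np.ndarray:
    """n points uniform over the buffer, by rejection from the bounding box.

    Deterministic given ``seed``.
    """
    if n < 1:
        raise SchemaError("n must be >= 1")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.region.bounds
    acceptance = region.region.area / ((maxx - minx) * (maxy - miny))
    out = np.empty((0, 2))
    while out.shape[0] < n:
        batch = max(64, int(1.5 * (n - out.shape[0]) / max(acceptance, 1e-6)))
        xs = rng.uniform(minx, maxx, size=batch)
        ys = rng.uniform(miny, maxy, size=batch)
        inside = shapely.contains_xy(region.region, xs, ys)
        out = np.vstack([out, np.column_stack([xs[inside], ys[inside]])])
    return out[:n]


def randomization_test(
    nests,
    layer: LandscapeLayer,
    region: BufferRegion,
    R: int = 1000,
    seed: int = 0,
    collapse_duplicates: bool = True,
    check_geographic: bool = True,
) -> RandomizationResult:
    """Monte Carlo randomization test of mean nearest-feature distance.

    The observed statistic is the mean nearest distance from the (optionally
    de-duplicated) nest locations to the layer; each of the R null replicates
    relocates the same number of points uniformly within the buffer region.
    """
    if R < 1:
        raise SchemaError("R must be >= 1")
    pts = unique_points(nests) if collapse_duplicates else _as_point_array(nests)
    n = pts.shape[0]
    observed = float(
        nearest_feature_distance(pts, layer, check_geographic=check_geographic).mean()
    )

    rng = np.random.default_rng(seed)
    null_means = np.empty(R)
    for i in range(R):
        rand_pts = random_points_in_buffer(
            region, n, seed=int(rng.integers(0, 2**31 - 1))
        )
        null_means[i] = nearest_feature_distance(
            rand_pts, layer, check_geographic=False
        ).mean()

    sd = float(null_means.std(ddof=1)) if R > 1 else 0.0
    z = (observed - float(null_means.mean())) / sd if sd > 0 else float("nan")
    p_below = float(np.mean(null_means < observed))
    p_two = min(1.0, 2.0 * min(p_below, 1.0 - p_below))
    return RandomizationResult(
        layer_kind=layer.kind, n_points=n, observed_mean_m=observed,
        null_means_m=null_means, z=float(z),
        p_one_sided=p_below, p_two_sided=p_two, R=R, seed=seed,
    )


def mean_distance_summary(distances_m) -> tuple[float, float, float]:
    """Mean nearest distance with a normal-approximation 95% CI, in km."""
    d = np.asarray(distances_m, dtype=float)
    if d.size == 0:
        raise SchemaError("no distances supplied")
    mean = d.mean()
    se = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else 0.0
    return mean / 1000.0, (mean - 1.96 * se) / 1000.0, (mean + 1.96 * se) / 1000.0


def habitat_feature_kruskal(distances_m, habitat_labels):
    """Kruskal-Wallis comparison of nearest-feature distances across habitats
    (thin pass-through to scipy)."""
    d = np.asarray(distances_m, dtype=float)
    labels = np.asarray(habitat_labels)
    groups = [d[labels == h] for h in np.unique(labels)]
    if len(groups) < 2:
        raise SchemaError("need at least two habitats to compare")
    return stats.kruskal(*groups)


# ---------------------------------------------------------------------------
# GeoJSON IO (planar coordinates)


def read_geojson_layer(path, kind: str) -> LandscapeLayer:
    """Read one landscape layer from a GeoJSON FeatureCollection (planar
    coordinates in metres)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    geoms = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geoms.append(shapely_shape(feat["geometry"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad geometry in feature {i}: {exc}") from exc
    if not geoms:
        raise SchemaError(f"{path}: no features")
    coords = np.concatenate([shapely.get_coordinates(g) for g in geoms])
    if _maybe_geographic(coords):
        raise SchemaError(
            f"{path}: coordinates look geographic (lon/lat); "
            "project to planar metres first"
        )
    return LandscapeLayer(kind=kind, geometries=geoms)


def write_geojson_layer(path, layer: LandscapeLayer) -> None:
    features = [
        {"type": "Feature", "properties": {"kind": layer.kind},
         "geometry": shapely.geometry.mapping(g)}
        for g in layer.geometries
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
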