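"""Home-range estimation and landscape classification.

Two planar estimators: percent minimum convex polygons (MCP; overall space
use) and adaptive local convex hulls (a-LoCoH; useable space). The adaptive
sphere of influence ``a`` defaults to the maximum pairwise distance between
locations. Comparing the two at matched isopleths gives the home-range
complexity index (MCP - LoCoH) / MCP in [0, 1): 0 when the estimates
coincide, approaching 1 as useable space fragments. Home ranges are
assigned an urbanization class from mean percent imperviousness within the
95% LoCoH isopleth: < 20% natural fragment, 20-50% suburban, > 50% highly
urbanized.

All geometry is planar meters (shapely); areas are m^2 internally and
reported in km^2 (factor 1e-6).
"""
from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import shapely
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint, mapping
from shapely.ops import unary_union

M2_PER_KM2 = 1e6

LANDSCAPE_THRESHOLDS = (20.0, 50.0)  # natural fragment < 20 <= suburban <= 50 < highly urbanized


@dataclasses.dataclass
class HomeRangeEstimate:
    """One isopleth of one estimator for one animal."""

    animal_id: str
    method: str                      # "MCP" or "aLoCoH"
    level_requested: float           # fraction of points targeted
    level_achieved: float            # fraction actually enclosed
    geometry: shapely.Geometry
    n_points: int
    coverage_days: float = np.nan

    def __post_init__(self) -> None:
        if not 0 < self.level_achieved <= 1:
            raise ValueError("achieved isopleth level must lie in (0, 1]")
        if not self.geometry.is_valid:
            self.geometry = shapely.make_valid(self.geometry)

    @property
    def area_km2(self) -> float:
        return self.geometry.area / M2_PER_KM2

    @property
    def n_components(self) -> int:
        return count_components(self.geometry)


@dataclasses.dataclass
class ComplexityReport:
    complexity: float
    mcp_area_km2: float
    locoh_area_km2: float
    n_components: int


@dataclasses.dataclass
class LandscapeClass:
    label: str                        # natural_fragment | suburban | highly_urbanized
    mean_imperviousness: float


def _points_array(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    return pts


def mcp(
    points,
    percent: float = 95.0,
    animal_id: str = "",
    coverage_days: float = np.nan,
) -> HomeRangeEstimate:
    """Percent minimum convex polygon.

    Retains the ``percent``% of points nearest the arithmetic centroid
    (stable sort: on ties, the earlier index is kept) and returns their
    convex hull. A degenerate hull (zero area) is an error.
    """
    pts = _points_array(points)
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    n = pts.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points for an MCP")
    centroid = pts.mean(axis=0)
    dist = np.hypot(*(pts - centroid).T)
    k = max(int(np.floor(n * percent / 100.0 + 1e-9)), 1)
    keep = np.sort(np.argsort(dist, kind="stable")[:k])
    hull = MultiPoint(pts[keep]).convex_hull
    if hull.area == 0:
        raise ValueError("degenerate hull: retained points are collinear")
    return HomeRangeEstimate(
        animal_id, "MCP", percent / 100.0, k / n, hull, n, coverage_days
    )


def max_pairwise_distance(points) -> float:
    """Exact maximum pairwise Euclidean distance (the a-LoCoH default ``a``).

    All-pairs for moderate n, otherwise all pairs among convex-hull
    vertices (the diameter is attained there).
    """
    pts = _points_array(points)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if pts.shape[0] > 3000:
        hull = MultiPoint(pts).convex_hull
        pts = np.asarray(
            hull.exterior.coords if hull.geom_type == "Polygon" else hull.coords
        )
    return float(pdist(pts).max())


def alocoh(
    points,
    a: float | None = None,
    isopleth_targets=(0.50, 0.95),
    animal_id: str = "",
    coverage_days: float = np.nan,
) -> dict[float, HomeRangeEstimate]:
    """Adaptive local convex hull isopleths.

    For each root point, the local hull spans the root plus the maximal
    prefix of its distance-sorted neighbors whose cumulative distance to the
    root stays within ``a`` (zero-distance duplicates are always included).
    Hulls are merged cumulatively from smallest area upward (ties by
    enclosed-point count) — the density-first construction, so dense-core
    hulls enter before sparse peripheral ones — and each requested isopleth
    is the cumulative union whose enclosed-point fraction is nearest the
    target.
    """
    pts = _points_array(points)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a-LoCoH")
    if a is None:
        a = max_pairwise_distance(pts)
    if a <= 0:
        raise ValueError("sphere of influence a must be positive")

    pt_geoms = shapely.points(pts)
    dmat = np.hypot(
        pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
    )
    hulls = []
    for i in range(n):
        order = np.argsort(dmat[i], kind="stable")
        order = order[order != i]
        cum = np.cumsum(dmat[i][order])
        m = int(np.searchsorted(cum, a, side="right"))
        members = np.concatenate([[i], order[:m]])
        hull = MultiPoint(pts[members]).convex_hull
        enclosed = int(np.count_nonzero(shapely.covers(hull, pt_geoms)))
        hulls.append((enclosed, hull.area, hull))
    hulls.sort(key=lambda h: (h[1], h[0]))

    running = None
    path = []  # (achieved fraction, union geometry, area)
    for enclosed, _, hull in hulls:
        running = hull if running is None else unary_union([running, hull])
        frac = np.count_nonzero(shapely.covers(running, pt_geoms)) / n
        path.append((frac, running, running.area))
    if running is None or running.area == 0:
        raise ValueError("all local hulls are degenerate (zero area)")

    out: dict[float, HomeRangeEstimate] = {}
    for target in isopleth_targets:
        if not 0 < target <= 1:
            raise ValueError("isopleth targets must lie in (0, 1]")
        best = min(range(len(path)), key=lambda j: (abs(path[j][0] - target), j))
        frac, geom, area = path[best]
        if area == 0:
            raise ValueError(
                f"isopleth nearest {target:.0%} is degenerate (zero area)"
            )
        out[target] = HomeRangeEstimate(
            animal_id, "aLoCoH", target, frac, geom, n, coverage_days
        )
    return out


def complexity_index(mcp_area: float, locoh_area: float) -> float:
    """(MCP - LoCoH) / MCP, clamped below at zero.

    Uses matching isopleth levels of the two estimators. A LoCoH area larger
    than the MCP area (possible only through boundary effects) is clamped to
    0 with a warning.
    """
    if mcp_area <= 0:
        raise ValueError("MCP area must be positive")
    c = (mcp_area - locoh_area) / mcp_area
    if c < 0:
        warnings.warn(
            "LoCoH area exceeds MCP area; complexity clamped to 0", stacklevel=2
        )
        return 0.0
    return c


def count_components(geometry) -> int:
    """Connected components of a polygon set; touching at a point connects."""
    geom = unary_union(geometry) if not isinstance(geometry, shapely.Geometry) else geometry
    if geom.is_empty:
        return 0
    parts = (
        list(geom.geoms) if geom.geom_type in ("MultiPolygon", "GeometryCollection")
        else [geom]
    )
    n = len(parts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if parts[i].intersects(parts[j]):
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def overlap_fraction(hr_i: HomeRangeEstimate, hr_j: HomeRangeEstimate) -> float:
    """Shared area relative to the smaller home range (same isopleth level)."""
    if hr_i.level_requested != hr_j.level_requested:
        raise ValueError("overlap is defined for matching isopleth levels")
    smaller = min(hr_i.geometry.area, hr_j.geometry.area)
    if smaller == 0:
        return 0.0
    return hr_i.geometry.intersection(hr_j.geometry).area / smaller


def dedup_homeranges(
    estimates: list[HomeRangeEstimate], threshold: float = 0.90
) -> list[HomeRangeEstimate]:
    """Drop near-duplicate home ranges (same social group).

    Pairs overlapping by more than ``threshold`` of the smaller range lose
    the member with less temporal coverage; pairs are processed greedily in
    descending overlap order, and a pair with an already-dropped member is
    skipped, so both members are never dropped on account of each other.
    """
    pairs = []
    for i in range(len(estimates)):
        for j in range(i + 1, len(estimates)):
            frac = overlap_fraction(estimates[i], estimates[j])
            if frac > threshold:
                pairs.append((frac, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[int] = set()
    for _, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        # unknown coverage loses; exact ties keep the first-listed estimate
        ci = estimates[i].coverage_days
        cj = estimates[j].coverage_days
        ci = -np.inf if np.isnan(ci) else ci
        cj = -np.inf if np.isnan(cj) else cj
        dropped.add(j if cj <= ci else i)
    return [e for k, e in enumerate(estimates) if k not in dropped]


def classify_landscape(polygon, raster) -> LandscapeClass:
    """Urbanization class from mean imperviousness of cells inside a polygon.

    Cells count when their centers fall inside (or on the boundary of) the
    polygon; boundary means of exactly 20% or 50% classify as suburban.
    """
    cx, cy = raster.cell_centers()
    inside = shapely.covers(polygon, shapely.points(np.column_stack([cx, cy])))
    if not inside.any():
        raise ValueError("no raster cell centers fall inside the polygon")
    mean = float(raster.values.ravel()[inside].mean())
    lo, hi = LANDSCAPE_THRESHOLDS
    if mean < lo:
        label = "natural_fragment"
    elif mean <= hi:
        label = "suburban"
    else:
        label = "highly_urbanized"
    return LandscapeClass(label, mean)


def to_geojson(estimates: list[HomeRangeEstimate], path=None) -> dict:
    """FeatureCollection of home-range polygons (planar coordinates, meters)."""
    features = []
    for e in estimates:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(e.geometry),
                "properties": {
                    "animal_id": e.animal_id,
                    "method": e.method,
                    "level_requested": e.level_requested,
                    "level_achieved": e.level_achieved,
                    "area_km2": e.area_km2,
                    "n_components": e.n_components,
                    "overlap_denominator": "smaller home range",
                    "hull_order": "enclosed-count then area, ascending",
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
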