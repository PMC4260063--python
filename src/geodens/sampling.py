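"""Adaptive field sampling protocol.

Simulates the survey design used to map app users from the road: at each
stop the observer records either the k nearest profiles or every profile
within a maximum radius, whichever is fewer, then drives the observed
radius further along the route before stopping again. Dense areas thus
get closely spaced small circles and sparse areas widely spaced 2-mile
circles, and the union of circles can tile an entire city from a modest
number of stops.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, shape

from .errors import EmptyInputError, InvalidParameterError, OutOfDomainError, ParseError
from .population import MISSING, RACES, UserProfile
from .region import StudyRegion

__all__ = [
    "SamplePoint",
    "Route",
    "CategorizationRules",
    "observe",
    "run_route",
    "categorize_profile",
    "coverage_fraction",
    "write_sample_points_csv",
    "read_sample_points_csv",
]

log = logging.getLogger(__name__)

#: race categories after analysis-stage collapsing (missing race -> other)
RACE_CATEGORIES = ("white", "black", "other")

# advance at least this far between stops even if the observed radius is
# degenerate (>= k users coincident with the stop), so routes terminate
MIN_STEP_MI = 0.01


@dataclass(frozen=True)
class CategorizationRules:
    """How raw profile marks collapse into analysis categories.

    Missing race is recorded as "other" (the contrast of interest is
    black vs white); missing age maps to ``unknown_label``. ``age_edges``
    are left edges of half-open bins covering [18, inf); with the default
    (18, 25, 31) the groups are 18-24, 25-30 and >30.
    """

    age_edges: tuple[int, ...] = (18, 25, 31)
    unknown_label: str = "unknown"

    def __post_init__(self):
        edges = tuple(self.age_edges)
        if len(edges) < 1 or list(edges) != sorted(set(edges)) or edges[0] != 18:
            raise InvalidParameterError(
                f"age_edges must be strictly increasing and start at 18, got {edges}"
            )
        object.__setattr__(self, "age_edges", edges)

    @property
    def age_labels(self) -> tuple[str, ...]:
        e = self.age_edges
        return tuple(f"{lo}-{hi - 1}" for lo, hi in zip(e[:-1], e[1:])) + (f">{e[-1] - 1}",)

    def age_group(self, age: int | None) -> str:
        if age is None:
            return self.unknown_label
        if age < 18:
            raise OutOfDomainError(f"age {age} < 18; the sampled population is adults")
        idx = int(np.searchsorted(self.age_edges, age, side="right")) - 1
        return self.age_labels[idx]


def categorize_profile(raw_race: str | None, raw_age: int | None, rules: CategorizationRules):
    """Map raw (race, age) marks to (race category, age group)."""
    if raw_race is None or raw_race == MISSING:
        race = "other"
    elif raw_race in RACES:
        race = raw_race
    else:
        raise InvalidParameterError(f"unknown raw race {raw_race!r}")
    return race, rules.age_group(raw_age)


@dataclass
class SamplePoint:
    """One observation event of the adaptive protocol.

    ``radius_mi`` is the adaptive radius: the distance to the k-th nearest
    user when at least k lie within ``r_max``, else ``r_max`` itself.
    ``captured`` lists (profile id, distance) pairs sorted by distance.
    ``race_counts`` / ``age_counts`` are the per-category aggregates the
    field protocol records; ``cross_counts`` keeps the full race x age
    cross-tabulation when the underlying profiles were available (it is
    not recoverable from the marginal CSV format).
    """

    id: str
    x: float
    y: float
    radius_mi: float
    captured: list = field(default_factory=list)
    race_counts: dict = field(default_factory=dict)
    age_counts: dict = field(default_factory=dict)
    cross_counts: dict | None = None
    timestamp: str | None = None

    @property
    def n_total(self) -> int:
        return len(self.captured) if self.captured else sum(self.race_counts.values())

    def stratum_count(self, stratum) -> int:
        """Captured count for a stratum selector.

        ``None`` or "total" -> all captures; a race category or age-group
        label -> the matching marginal; a (race, age_group) pair -> the
        cross-tabulated cell (requires profile-level data).
        """
        if stratum is None or stratum == "total":
            return self.n_total
        if isinstance(stratum, tuple):
            if self.cross_counts is None:
                raise InvalidParameterError(
                    "race x age strata need profile-level captures; this point has only marginals"
                )
            return self.cross_counts.get(tuple(stratum), 0)
        if stratum in self.race_counts:
            return self.race_counts[stratum]
        if stratum in self.age_counts:
            return self.age_counts[stratum]
        raise InvalidParameterError(f"unknown stratum {stratum!r}")


def _aggregate(point: SamplePoint, profiles_by_id: dict, rules: CategorizationRules) -> None:
    race_counts = {r: 0 for r in RACE_CATEGORIES}
    age_counts = {lab: 0 for lab in rules.age_labels + (rules.unknown_label,)}
    cross: dict = {}
    for pid, _dist in point.captured:
        prof = profiles_by_id[pid]
        race, group = categorize_profile(prof.race, prof.age, rules)
        race_counts[race] += 1
        age_counts[group] += 1
        cross[(race, group)] = cross.get((race, group), 0) + 1
    point.race_counts = race_counts
    point.age_counts = age_counts
    point.cross_counts = cross


def observe(
    point: tuple[float, float],
    profiles,
    k: int = 50,
    r_max: float = 2.0,
    rules: CategorizationRules | None = None,
    point_id: str = "s0",
    quantize_distances: bool = False,
) -> SamplePoint:
    """Record one stop of the adaptive protocol.

    Captures the ``k`` nearest profiles when at least ``k`` lie within
    ``r_max`` miles (adaptive radius = distance to the k-th nearest,
    ties at that distance included), otherwise every profile within
    ``r_max`` (radius = ``r_max``). ``quantize_distances`` emulates the
    granularity an app displays: whole feet below one mile, hundredths of
    a mile above.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if r_max <= 0:
        raise InvalidParameterError(f"r_max must be > 0, got {r_max}")
    rules = rules or CategorizationRules()
    profiles = list(profiles)
    px, py = float(point[0]), float(point[1])

    if profiles:
        xs = np.array([p.x for p in profiles])
        ys = np.array([p.y for p in profiles])
        dist = np.hypot(xs - px, ys - py)
        if quantize_distances:
            feet = dist * 5280.0
            dist = np.where(dist < 1.0, np.round(feet) / 5280.0, np.round(dist, 2))
        order = np.lexsort((np.array([p.id for p in profiles]), dist))
        dist_sorted = dist[order]
        within = dist_sorted <= r_max
        n_within = int(within.sum())
        if n_within >= k:
            kth = float(dist_sorted[k - 1])
            take = dist_sorted <= kth  # include ties at the k-th distance
            radius = max(kth, 0.0)
        else:
            take = within
            radius = r_max
        idx = order[take]
        captured = [(profiles[i].id, float(dist[i])) for i in idx]
    else:
        captured = []
        radius = r_max

    sp = SamplePoint(id=point_id, x=px, y=py, radius_mi=float(radius), captured=captured)
    _aggregate(sp, {p.id: p for p in profiles}, rules)
    return sp


@dataclass(frozen=True)
class Route:
    """A driving route as a polyline in planar miles."""

    polyline: tuple[tuple[float, float], ...]
    start_offset: float = 0.0

    def __post_init__(self):
        pts = tuple((float(x), float(y)) for x, y in self.polyline)
        if len(pts) < 2:
            raise InvalidParameterError("a route needs at least two vertices")
        for a, b in zip(pts[:-1], pts[1:]):
            if a == b:
                raise InvalidParameterError(f"consecutive route vertices must be distinct, got {a} twice")
        if self.start_offset < 0:
            raise InvalidParameterError("start_offset must be >= 0")
        object.__setattr__(self, "polyline", pts)

    @property
    def line(self) -> LineString:
        return LineString(self.polyline)

    @property
    def length(self) -> float:
        return self.line.length

    @classmethod
    def from_geojson(cls, path, start_offset: float = 0.0) -> "Route":
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        geom = obj.get("geometry", obj) if obj.get("type") == "Feature" else obj
        if geom.get("type") != "LineString":
            raise ParseError(f"{path}: expected a GeoJSON LineString, got {geom.get('type')!r}")
        return cls(polyline=tuple(map(tuple, geom["coordinates"])), start_offset=start_offset)


def run_route(
    route: Route,
    profiles,
    k: int = 50,
    r_max: float = 2.0,
    rules: CategorizationRules | None = None,
    quantize_distances: bool = False,
) -> list[SamplePoint]:
    """Traverse a route with the adaptive protocol.

    The first stop is ``start_offset`` miles along the polyline (arc
    length); after each observation the next stop is the observed radius
    further along. Traversal ends once the route is exhausted. The
    population is treated as frozen for the whole traversal.
    """
    line = route.line
    length = line.length
    if route.start_offset > length:
        warnings.warn("route is shorter than start_offset; no stops taken", stacklevel=2)
        return []
    stops: list[SamplePoint] = []
    s = route.start_offset
    eps = 1e-9
    while s <= length + eps:
        loc = line.interpolate(min(s, length))
        sp = observe(
            (loc.x, loc.y),
            profiles,
            k=k,
            r_max=r_max,
            rules=rules,
            point_id=f"s{len(stops):03d}",
            quantize_distances=quantize_distances,
        )
        stops.append(sp)
        s += max(sp.radius_mi, MIN_STEP_MI)
    log.info(
        "route of %.1f mi: %d stops, %d captures", length, len(stops), sum(p.n_total for p in stops)
    )
    return stops


def serpentine_route(region: StudyRegion, n_sweeps: int = 7, margin: float = 0.5) -> Route:
    """A boustrophedon route sweeping the region's bounding box.

    ``n_sweeps`` horizontal passes spaced evenly between ``margin`` and
    height - ``margin`` — the simulated analog of driving the major
    east-west roads of a city back and forth.
    """
    if n_sweeps < 1:
        raise InvalidParameterError("n_sweeps must be >= 1")
    xmin, ymin, xmax, ymax = region.bounds
    ys = np.linspace(ymin + margin, ymax - margin, n_sweeps)
    verts: list[tuple[float, float]] = []
    for i, y in enumerate(ys):
        xs = (xmin + margin, xmax - margin) if i % 2 == 0 else (xmax - margin, xmin + margin)
        verts.append((xs[0], float(y)))
        verts.append((xs[1], float(y)))
    return Route(polyline=tuple(verts))


def coverage_fraction(sample_points, region: StudyRegion, resolution: float = 0.05) -> float:
    """Fraction of the region covered by the union of sampling circles.

    Computed on a grid of cell centers at the given ``resolution`` (miles).
    Monotone non-decreasing as circles are added.
    """
    if resolution <= 0:
        raise InvalidParameterError(f"resolution must be > 0, got {resolution}")
    sample_points = list(sample_points)
    if not sample_points:
        return 0.0
    xmin, ymin, xmax, ymax = region.bounds
    xs = np.arange(xmin + resolution / 2, xmax, resolution)
    ys = np.arange(ymin + resolution / 2, ymax, resolution)
    gx, gy = np.meshgrid(xs, ys)
    inside = region.contains(gx.ravel(), gy.ravel()).reshape(gx.shape)
    if not inside.any():
        return 0.0
    covered = np.zeros_like(inside)
    for sp in sample_points:
        covered |= (gx - sp.x) ** 2 + (gy - sp.y) ** 2 <= sp.radius_mi**2
    return float((covered & inside).sum() / inside.sum())


# ---------------------------------------------------------------------------
# CSV round-trip (marginal counts only; the default age-bin convention)
# ---------------------------------------------------------------------------


def _age_col(label: str, unknown_label: str) -> str:
    if label == unknown_label:
        return "n_age_unknown"
    return "n_age_" + label.replace("-", "_").replace(">", "gt")


def write_sample_points_csv(sample_points, path, rules: CategorizationRules | None = None) -> None:
    rules = rules or CategorizationRules()
    age_labels = rules.age_labels + (rules.unknown_label,)
    header = (
        "id,x_mi,y_mi,radius_mi,n_total,n_white,n_black,n_other,"
        + ",".join(_age_col(lab, rules.unknown_label) for lab in age_labels)
        + ",timestamp"
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for sp in sample_points:
            cells = [
                sp.id,
                f"{sp.x:.6g}",
                f"{sp.y:.6g}",
                f"{sp.radius_mi:.6g}",
                str(sp.n_total),
                str(sp.race_counts.get("white", 0)),
                str(sp.race_counts.get("black", 0)),
                str(sp.race_counts.get("other", 0)),
            ]
            cells += [str(sp.age_counts.get(lab, 0)) for lab in age_labels]
            cells.append(sp.timestamp or "")
            fh.write(",".join(cells) + "\n")


def read_sample_points_csv(path, rules: CategorizationRules | None = None) -> list[SamplePoint]:
    rules = rules or CategorizationRules()
    age_labels = rules.age_labels + (rules.unknown_label,)
    expected = (
        "id,x_mi,y_mi,radius_mi,n_total,n_white,n_black,n_other,"
        + ",".join(_age_col(lab, rules.unknown_label) for lab in age_labels)
        + ",timestamp"
    )
    points = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != expected:
            raise ParseError(f"{path}: line 1: unexpected header {header!r}")
        ncol = len(expected.split(","))
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != ncol:
                raise ParseError(f"{path}: line {lineno}: expected {ncol} fields, got {len(parts)}")
            try:
                race_counts = {
                    "white": int(parts[5]),
                    "black": int(parts[6]),
                    "other": int(parts[7]),
                }
                age_counts = {lab: int(v) for lab, v in zip(age_labels, parts[8:-1])}
                sp = SamplePoint(
                    id=parts[0],
                    x=float(parts[1]),
                    y=float(parts[2]),
                    radius_mi=float(parts[3]),
                    captured=[],
                    race_counts=race_counts,
                    age_counts=age_counts,
                    cross_counts=None,
                    timestamp=parts[-1] or None,
                )
                if int(parts[4]) != sp.n_total:
                    raise ParseError(
                        f"{path}: line {lineno}: n_total {parts[4]} != race-count sum {sp.n_total}"
                    )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            points.append(sp)
    return points
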