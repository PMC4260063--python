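"""Synthetic marked point patterns of app users.

The generator stands in for scraped profile data: a planar point pattern
over a study region where each point carries a race mark (white / black /
other) and an adult age, with configurable missingness of both marks.
Spatial structure is an inhomogeneous Poisson process built from isotropic
Gaussian hotspot components plus a uniform background, which is enough to
reproduce the strongly clustered, racially segregated intensity patterns
seen in real geosocial-app data from large US cities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError, InvalidSpecError, ParseError
from .region import StudyRegion

__all__ = [
    "RACES",
    "MISSING",
    "AgeMixture",
    "Component",
    "IntensitySpec",
    "UserProfile",
    "generate_population",
    "assign_missingness",
    "profile_table",
    "write_population_csv",
    "read_population_csv",
    "demo_region",
    "demo_scenario",
]

RACES = ("white", "black", "other")
MISSING = "missing"

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class AgeMixture:
    """Two-component truncated-normal mixture over adult ages.

    Ages are drawn from ``p_young * N(young_mean, young_sd) +
    (1-p_young) * N(old_mean, old_sd)``, resampled until >= 18, then
    rounded to whole years. The two components model the bimodal
    young-adult / established-adult split of app users; defaults are set
    per race so that black users are younger than white users
    (medians near 28 vs 33 years).
    """

    p_young: float = 0.4
    young_mean: float = 23.0
    young_sd: float = 3.0
    old_mean: float = 36.0
    old_sd: float = 8.0

    def __post_init__(self):
        if not 0.0 <= self.p_young <= 1.0:
            raise InvalidSpecError(f"p_young must be in [0,1], got {self.p_young}")
        if self.young_sd <= 0 or self.old_sd <= 0:
            raise InvalidSpecError("age mixture standard deviations must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integer ages >= 18."""
        ages = np.empty(n, dtype=float)
        todo = np.arange(n)
        for _ in range(_MAX_REJECTION_ROUNDS):
            if todo.size == 0:
                break
            young = rng.random(todo.size) < self.p_young
            mu = np.where(young, self.young_mean, self.old_mean)
            sd = np.where(young, self.young_sd, self.old_sd)
            ages[todo] = rng.normal(mu, sd)
            todo = todo[ages[todo] < 18.0]
        if todo.size:
            ages[todo] = 18.0
        return np.floor(ages).astype(int).clip(min=18)


# median ~33 for white, ~28 for black users
DEFAULT_AGE_MODELS = {
    "white": AgeMixture(p_young=0.30, young_mean=24.0, young_sd=3.0, old_mean=38.0, old_sd=8.0),
    "black": AgeMixture(p_young=0.40, young_mean=23.0, young_sd=3.0, old_mean=34.0, old_sd=7.0),
    "other": AgeMixture(p_young=0.35, young_mean=24.0, young_sd=3.0, old_mean=36.0, old_sd=8.0),
}


@dataclass(frozen=True)
class Component:
    """One Gaussian hotspot of a single race.

    ``expected_count`` is the Poisson mean number of users the component
    contributes; ``spread`` is the isotropic standard deviation in miles.
    Points falling outside the study region are resampled (truncation by
    rejection), so realized counts stay Poisson with the stated mean.
    """

    center: tuple[float, float]
    spread: float
    expected_count: float
    race: str
    age_model: AgeMixture | None = None

    def __post_init__(self):
        if self.spread <= 0:
            raise InvalidSpecError(f"component spread must be > 0, got {self.spread}")
        if self.expected_count < 0:
            raise InvalidSpecError(f"expected_count must be >= 0, got {self.expected_count}")
        if self.race not in RACES:
            raise InvalidSpecError(f"race must be one of {RACES}, got {self.race!r}")


@dataclass(frozen=True)
class IntensitySpec:
    """Intensity surface for the population generator.

    The per-race intensity is a sum of Gaussian ``components`` plus a
    uniform ``background_rate`` (users per square mile) inside the region.
    """

    components: tuple[Component, ...] = ()
    background_rate: dict = field(default_factory=dict)  # race -> users / sq mi
    age_models: dict = field(default_factory=dict)  # race -> AgeMixture, for background points

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        for race, rate in self.background_rate.items():
            if race not in RACES:
                raise InvalidSpecError(f"unknown race {race!r} in background_rate")
            if rate < 0:
                raise InvalidSpecError(f"background rate must be >= 0, got {rate} for {race!r}")

    def expected_total(self, region: StudyRegion, race: str | None = None) -> float:
        """Expected number of generated users, overall or for one race."""
        races = RACES if race is None else (race,)
        total = 0.0
        for r in races:
            total += self.background_rate.get(r, 0.0) * region.area
            total += sum(c.expected_count for c in self.components if c.race == r)
        return total

    def intensity(self, x, y, region: StudyRegion, race: str | None = None) -> np.ndarray:
        """True generating intensity (users per square mile) at points.

        Gaussian components contribute their untruncated density; outside
        the region the intensity is zero. Used as ground truth when
        checking how well an estimated surface recovers the generator.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lam = np.zeros(np.broadcast(x, y).shape)
        races = RACES if race is None else (race,)
        for r in races:
            lam += self.background_rate.get(r, 0.0)
            for c in self.components:
                if c.race != r:
                    continue
                d2 = (x - c.center[0]) ** 2 + (y - c.center[1]) ** 2
                lam += c.expected_count * np.exp(-d2 / (2 * c.spread**2)) / (2 * math.pi * c.spread**2)
        return np.where(region.contains(x, y), lam, 0.0)


@dataclass
class UserProfile:
    """One app user: location in planar miles plus self-reported marks.

    ``race`` is one of white/black/other or "missing"; ``age`` is an
    integer number of years >= 18, or None when the profile omits it.
    """

    id: str
    x: float
    y: float
    race: str
    age: int | None

    def __post_init__(self):
        if self.race not in RACES and self.race != MISSING:
            raise InvalidSpecError(f"unknown race {self.race!r}")
        if self.age is not None and self.age < 18:
            raise InvalidSpecError(f"age must be >= 18 or missing, got {self.age}")


def _uniform_in_region(n: int, region: StudyRegion, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample n uniform points inside the region polygon."""
    xmin, ymin, xmax, ymax = region.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        if got >= n:
            break
        m = max(2 * (n - got), 16)
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        keep = region.contains(cx, cy)
        cx, cy = cx[keep], cy[keep]
        take = min(cx.size, n - got)
        xs[got : got + take] = cx[:take]
        ys[got : got + take] = cy[:take]
        got += take
    if got < n:
        raise InvalidSpecError("rejection sampling failed; is the region degenerate?")
    return xs, ys


def _normal_in_region(
    n: int, center: tuple[float, float], spread: float, region: StudyRegion, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic-Gaussian points around a hotspot center, truncated to the region."""
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        if got >= n:
            break
        m = max(2 * (n - got), 16)
        cx = rng.normal(center[0], spread, m)
        cy = rng.normal(center[1], spread, m)
        keep = region.contains(cx, cy)
        cx, cy = cx[keep], cy[keep]
        take = min(cx.size, n - got)
        xs[got : got + take] = cx[:take]
        ys[got : got + take] = cy[:take]
        got += take
    if got < n:
        raise InvalidSpecError(
            f"hotspot at {center} with spread {spread} produced no points inside the region"
        )
    return xs, ys


def generate_population(region: StudyRegion, spec: IntensitySpec, seed: int) -> list[UserProfile]:
    """Realize the marked point pattern described by ``spec``.

    Component counts are Poisson with the stated means; points are placed
    by the component's truncated Gaussian (or uniformly for background
    intensity) and marked with the component's race and an age drawn from
    its age model. Identical ``(region, spec, seed)`` give identical output.
    """
    rng = np.random.default_rng(seed)
    profiles: list[UserProfile] = []

    def emit(xs, ys, race, age_model):
        ages = (age_model or DEFAULT_AGE_MODELS[race]).sample(len(xs), rng)
        for x, y, age in zip(xs, ys, ages):
            profiles.append(
                UserProfile(id=f"u{len(profiles):06d}", x=float(x), y=float(y), race=race, age=int(age))
            )

    for comp in spec.components:
        n = rng.poisson(comp.expected_count)
        if n == 0:
            continue
        xs, ys = _normal_in_region(n, comp.center, comp.spread, region, rng)
        emit(xs, ys, comp.race, comp.age_model)

    for race in RACES:
        rate = spec.background_rate.get(race, 0.0)
        if rate <= 0:
            continue
        n = rng.poisson(rate * region.area)
        if n == 0:
            continue
        xs, ys = _uniform_in_region(n, region, rng)
        emit(xs, ys, race, spec.age_models.get(race))

    return profiles


def assign_missingness(
    profiles, p_missing_race: float, p_missing_age: float, seed: int
) -> list[UserProfile]:
    """Independently blank race / age marks with the given probabilities.

    Returns new profiles; the input is not modified. Race missingness is
    kept as its own category here — collapsing missing race into "other"
    is an analysis-stage categorization choice, not a data property.
    """
    for name, p in (("p_missing_race", p_missing_race), ("p_missing_age", p_missing_age)):
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError(f"{name} must be in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    out = []
    for prof in profiles:
        race = MISSING if rng.random() < p_missing_race else prof.race
        age = None if rng.random() < p_missing_age else prof.age
        out.append(replace(prof, race=race, age=age))
    return out


def profile_table(profiles, age_edges=(18, 25, 31)) -> pd.DataFrame:
    """Tabulate a profile collection the way a field report would.

    Returns a DataFrame indexed by category with ``count`` and ``percent``
    (of all profiles, to full float precision) rows for each race category
    (including missing race) and each age group (including missing age).
    ``age_edges`` are left bin edges; the last bin is open-ended.
    """
    profiles = list(profiles)
    if not profiles:
        raise EmptyInputError("cannot tabulate an empty profile collection")
    n = len(profiles)
    rows = {}
    for race in RACES + (MISSING,):
        c = sum(1 for p in profiles if p.race == race)
        rows[f"race:{race}"] = c
    edges = list(age_edges)
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])] + [f">{edges[-1] - 1}"]
    for i, lab in enumerate(labels):
        lo = edges[i]
        hi = edges[i + 1] if i + 1 < len(edges) else math.inf
        c = sum(1 for p in profiles if p.age is not None and lo <= p.age < hi)
        rows[f"age:{lab}"] = c
    rows["age:missing"] = sum(1 for p in profiles if p.age is None)
    df = pd.DataFrame({"count": pd.Series(rows, dtype=int)})
    df["percent"] = 100.0 * df["count"] / n
    df.attrs["n"] = n
    return df


# ---------------------------------------------------------------------------
# CSV round-trip: header  id,x_mi,y_mi,race,age
# ---------------------------------------------------------------------------

_POP_HEADER = "id,x_mi,y_mi,race,age"


def write_population_csv(profiles, path) -> None:
    with open(path, "w") as fh:
        fh.write(_POP_HEADER + "\n")
        for p in profiles:
            age = "" if p.age is None else str(int(p.age))
            fh.write(f"{p.id},{p.x:.6g},{p.y:.6g},{p.race},{age}\n")


def read_population_csv(path) -> list[UserProfile]:
    profiles = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _POP_HEADER:
            raise ParseError(f"{path}: line 1: expected header {_POP_HEADER!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 fields, got {len(parts)}")
            pid, x, y, race, age = parts
            try:
                profiles.append(
                    UserProfile(
                        id=pid,
                        x=float(x),
                        y=float(y),
                        race=race,
                        age=None if age == "" else int(age),
                    )
                )
            except (ValueError, InvalidSpecError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return profiles


# ---------------------------------------------------------------------------
# Bundled demo scenario
# ---------------------------------------------------------------------------


def demo_region() -> StudyRegion:
    """An 11.5 x 11.5-mile square city (132.25 sq mi), the demo extent."""
    s = 11.5
    return StudyRegion.from_vertices([(0, 0), (s, 0), (s, s), (0, s)], name="demo-city")


def demo_scenario(total: float = 2666.0):
    """The bundled heterogeneous city scenario.

    Returns ``(region, spec, p_missing_race, p_missing_age)``. The layout
    emulates a large, racially segregated US city: a dense central
    "midtown" hotspot shared by both races, white density extending to the
    north-east, black hotspots to the south-west, and a thin uniform
    background. Expected pre-missingness race fractions are chosen so that
    after 5.51% race missingness the expected observed fractions are
    58.63% white / 30.38% black / 5.48% other / 5.51% missing.
    """
    region = demo_region()
    p_missing_race = 0.0551
    p_missing_age = 0.2224
    # pre-missingness fractions: observed fraction / (1 - p_missing_race)
    w = total * 0.5863 / (1 - p_missing_race)
    b = total * 0.3038 / (1 - p_missing_race)
    o = total * 0.0548 / (1 - p_missing_race)
    area = region.area
    components = [
        # shared central hotspot ("midtown")
        Component(center=(6.5, 7.5), spread=0.9, expected_count=0.45 * w, race="white"),
        Component(center=(6.5, 7.5), spread=0.8, expected_count=0.35 * b, race="black"),
        # white density extending north-east
        Component(center=(8.5, 9.0), spread=1.4, expected_count=0.35 * w, race="white"),
        # black hotspots south-west of the center
        Component(center=(4.0, 4.0), spread=1.2, expected_count=0.40 * b, race="black"),
        Component(center=(3.2, 6.0), spread=1.0, expected_count=0.15 * b, race="black"),
    ]
    background = {
        "white": 0.20 * w / area,
        "black": 0.10 * b / area,
        "other": o / area,
    }
    return region, IntensitySpec(components=tuple(components), background_rate=background), p_missing_race, p_missing_age
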