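import numpy as np
import pytest
from hypothesis import settings

import geodens as g

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture
def square_region():
    return g.StudyRegion.from_vertices([(0, 0), (10, 0), (10, 10), (0, 10)], name="square")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_profiles(xy, race="white", age=30, offset=0):
    """Build profiles at given coordinates with constant marks."""
    return [
        g.UserProfile(id=f"p{offset + i:05d}", x=float(x), y=float(y), race=race, age=age)
        for i, (x, y) in enumerate(xy)
    ]


@pytest.fixture
def uniform_population(square_region, rng):
    xy = rng.uniform(0, 10, size=(300, 2))
    return make_profiles(xy)


@pytest.fixture(scope="session")
def demo_pipeline():
    """Full demo scenario run once: population, stops, grid."""
    region, spec, p_race, p_age = g.demo_scenario()
    pop = g.generate_population(region, spec, seed=20140)
    pop = g.assign_missingness(pop, p_race, p_age, seed=20141)
    stops = g.run_route(g.serpentine_route(region), pop)
    grid = g.GridSpec.for_region(region, cell_size=0.1)
    return {"region": region, "spec": spec, "population": pop, "stops": stops, "grid": grid}
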