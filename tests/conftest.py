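import networkx as nx
import pytest
from shapely.geometry import Polygon

from kyojo import hazards, synth
from kyojo.town import Building, Resident, World


@pytest.fixture(scope="session")
def town():
    """Default-scale synthetic district (398 residents, 15 groups)."""
    return synth.generate(synth.TownSpec(seed=7))


@pytest.fixture(scope="session")
def small_town():
    """Compact district for fast simulation tests."""
    return synth.generate(
        synth.TownSpec(
            block_rows=2, block_cols=2, buildings_per_block=4,
            population=80, n_groups=4, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_field(small_town):
    return hazards.rasterize(small_town)


@pytest.fixture(scope="session")
def quiet_timeline(small_town, small_field):
    """No collapse, no fire: a hazard-free baseline timeline."""
    return hazards.build_timeline(
        small_town, small_field,
        fire_params=hazards.FireParams(n_origins=0),
        collapse_enabled=False, horizon=900, seed=0,
    )


@pytest.fixture(scope="session")
def hazard_timeline(small_town, small_field):
    """Collapses and one fire origin on the small district."""
    return hazards.build_timeline(small_town, small_field, horizon=900, seed=5)


def square(x, y, half=4.5):
    return Polygon([(x - half, y - half), (x + half, y - half),
                    (x + half, y + half), (x - half, y + half)])


def line_world(n_buildings=3, spacing=30.0, adults_per_building=1, ages=(40,)):
    """A single straight street with buildings along it; site at the far end.

    Helper for hand-built micro scenarios: building k sits beside node k.
    """
    g = nx.Graph()
    n = n_buildings + 1
    for i in range(n):
        g.add_node(f"n{i}", x=i * spacing, y=0.0)
    for i in range(n - 1):
        g.add_edge(f"n{i}", f"n{i+1}", length=spacing, width=6.0)
    buildings, residents = [], []
    rid = 0
    for k in range(n_buildings):
        x = k * spacing
        b = Building(id=f"b{k}", x=x, y=9.0, structure="wood", floors=1,
                     year_built=1990, footprint=square(x, 9.0))
        buildings.append(b)
        for a in range(adults_per_building):
            residents.append(
                Resident(id=f"r{rid:03d}", building_id=b.id,
                         age=ages[a % len(ages)], gender="male",
                         household_id=f"h{k}_{a}")
            )
            rid += 1
    world = World(buildings, g, sites=[f"n{n - 1}"])
    world.attach_roster(residents)
    return world
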