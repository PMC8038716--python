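"""Self-contained synthetic districts for testing and demonstration.

The generator lays out a rectangular street grid with square wooden/steel/RC
buildings inside each block, designates evacuation sites at street corners,
optionally inserts an impassable barrier, and populates the buildings with a
household roster (ages, genders, commuter flags, small-group membership)
that has the statistical shape of an ageing Japanese residential district:
a default population of 398 of whom roughly a quarter commute away by day,
leaving about 300 present in the evening.

Everything is deterministic under the spec's seed, so fixtures are
regenerated rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Polygon

from .town import BarrierSet, Building, Resident, World

__all__ = ["TownSpec", "generate", "survey_group_fixture"]


@dataclass
class TownSpec:
    """Parameters of a synthetic district."""

    block_rows: int = 3
    block_cols: int = 5
    block_size: float = 60.0           # m between parallel streets
    buildings_per_block: int = 6
    road_width: float = 6.0            # m
    n_sites: int = 2
    barrier: str | None = None         # None or "mid_horizontal"
    n_groups: int = 15                 # small neighbourhood groups
    population: int = 398
    household_weights: dict = field(
        default_factory=lambda: {1: 0.25, 2: 0.30, 3: 0.20, 4: 0.15, 5: 0.10}
    )
    # age pyramid of an ageing district: child / working-age / elderly
    age_band_weights: tuple = (0.12, 0.55, 0.33)
    commuter_probability: float = 0.5  # among working-age adults (20-59)
    wood_fraction: float = 0.7
    pre_code_fraction: float = 0.35    # built before the 1981 seismic code
    assistance_in_roster: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.block_rows, self.block_cols, self.buildings_per_block) < 1:
            raise ValueError("town dimensions must be positive")
        if self.population < 1:
            raise ValueError("population must be positive")
        if self.n_groups > self.block_rows * self.block_cols:
            raise ValueError("more groups than blocks")
        n_nodes = (self.block_rows + 1) * (self.block_cols + 1)
        if self.n_sites > n_nodes:
            raise ValueError("more evacuation sites than network nodes")


def _draw_age(rng: np.random.Generator, weights: tuple) -> int:
    band = rng.choice(3, p=np.asarray(weights) / sum(weights))
    if band == 0:
        return int(rng.integers(0, 15))
    if band == 1:
        return int(rng.integers(15, 65))
    return int(rng.integers(65, 95))


def _make_households(spec: TownSpec, rng: np.random.Generator) -> list[list[dict]]:
    sizes = sorted(spec.household_weights)
    probs = np.array([spec.household_weights[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    households, n = [], 0
    while n < spec.population:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, spec.population - n) or 1
        ages = [_draw_age(rng, spec.age_band_weights) for _ in range(k)]
        # a child under 10 needs a co-resident parent
        if any(a < 10 for a in ages) and not any(a >= 20 for a in ages):
            ages[ages.index(max(ages))] = int(rng.integers(25, 50))
        members = []
        for age in ages:
            gender = "male" if rng.random() < 0.5 else "female"
            commuter = bool(
                20 <= age < 60 and rng.random() < spec.commuter_probability
            )
            members.append({"age": age, "gender": gender, "commuter": commuter})
        households.append(members)
        n += k
    return households


def generate(spec: TownSpec) -> World:
    """Build the synthetic district; byte-identical under the same spec."""
    rng = np.random.default_rng(spec.seed)

    # street grid
    g = nx.Graph()
    for i in range(spec.block_rows + 1):
        for j in range(spec.block_cols + 1):
            g.add_node(
                f"n{i:02d}_{j:02d}", x=j * spec.block_size, y=i * spec.block_size
            )
    for i in range(spec.block_rows + 1):
        for j in range(spec.block_cols + 1):
            if j < spec.block_cols:
                g.add_edge(
                    f"n{i:02d}_{j:02d}", f"n{i:02d}_{j + 1:02d}",
                    length=spec.block_size, width=spec.road_width,
                )
            if i < spec.block_rows:
                g.add_edge(
                    f"n{i:02d}_{j:02d}", f"n{i + 1:02d}_{j:02d}",
                    length=spec.block_size, width=spec.road_width,
                )

    # buildings front the streets, as in a dense Japanese district: spread
    # along the block perimeter, footprints just behind the road edge
    buildings: list[Building] = []
    n_blocks = spec.block_rows * spec.block_cols
    setback = spec.road_width / 2 + 5.5  # centroid distance from street centreline
    for bi in range(spec.block_rows):
        for bj in range(spec.block_cols):
            block = bi * spec.block_cols + bj
            group = f"g{(block * spec.n_groups) // n_blocks + 1:02d}"
            n_side = [spec.buildings_per_block // 4 + (s < spec.buildings_per_block % 4) for s in range(4)]
            placements = []
            for side in range(4):
                for i in range(n_side[side]):
                    frac = (i + 1) / (n_side[side] + 1)
                    along = frac * spec.block_size
                    if side == 0:      # south edge
                        placements.append((along, setback))
                    elif side == 1:    # north edge
                        placements.append((along, spec.block_size - setback))
                    elif side == 2:    # west edge
                        placements.append((setback, along))
                    else:              # east edge
                        placements.append((spec.block_size - setback, along))
            for k in range(spec.buildings_per_block):
                dx, dy = placements[k]
                x = bj * spec.block_size + dx
                y = bi * spec.block_size + dy
                structure = (
                    "wood"
                    if rng.random() < spec.wood_fraction
                    else ("steel" if rng.random() < 0.5 else "rc")
                )
                u = rng.random()
                year = (
                    int(rng.integers(1955, 1981))
                    if u < spec.pre_code_fraction
                    else int(rng.integers(1981, 2001))
                    if u < spec.pre_code_fraction + 0.35
                    else int(rng.integers(2001, 2020))
                )
                h = 4.5
                buildings.append(
                    Building(
                        id=f"b{block:02d}_{k:02d}",
                        x=x,
                        y=y,
                        structure=structure,
                        floors=int(rng.choice([1, 2, 2, 3])),
                        year_built=year,
                        footprint=Polygon(
                            [(x - h, y - h), (x + h, y - h), (x + h, y + h), (x - h, y + h)]
                        ),
                    )
                )
            # stash group label for roster assignment
            for b in buildings[-spec.buildings_per_block:]:
                b.group_id = group  # type: ignore[attr-defined]

    # evacuation sites at the extreme corners, then remaining corners
    corners = [
        f"n{0:02d}_{0:02d}",
        f"n{spec.block_rows:02d}_{spec.block_cols:02d}",
        f"n{0:02d}_{spec.block_cols:02d}",
        f"n{spec.block_rows:02d}_{0:02d}",
    ]
    others = [n for n in sorted(g.nodes) if n not in corners]
    sites = (corners + others)[: spec.n_sites]

    barriers = BarrierSet()
    if spec.barrier == "mid_horizontal":
        y_mid = spec.block_rows / 2 * spec.block_size + spec.block_size / 2
        barriers = BarrierSet(
            [
                LineString(
                    [(-50.0, y_mid), (spec.block_cols * spec.block_size + 50.0, y_mid)]
                )
            ]
        )
    elif spec.barrier is not None:
        raise ValueError(f"unknown barrier placement: {spec.barrier!r}")

    # roster: households assigned to buildings round-robin
    households = _make_households(spec, rng)
    residents: list[Resident] = []
    rid = 0
    for h_idx, members in enumerate(households):
        b = buildings[h_idx % len(buildings)]
        hid = f"h{h_idx:03d}"
        for m in members:
            needs = False
            if spec.assistance_in_roster:
                age = m["age"]
                p = 0.1 if 60 <= age < 70 else 0.2 if age >= 70 else 0.05
                needs = bool(rng.random() < p)
            residents.append(
                Resident(
                    id=f"r{rid:04d}",
                    building_id=b.id,
                    age=m["age"],
                    gender=m["gender"],
                    needs_assistance=needs,
                    group_id=getattr(b, "group_id", None),
                    household_id=hid,
                    commuter=m["commuter"],
                )
            )
            rid += 1

    world = World(buildings, g, sites=sites, barriers=barriers)
    world.attach_roster(residents)
    return world


# Survey returns of a 15-group district: per-group counts of
# assistance-needing members (under-10s included, as surveyed) and of
# children under 10.
_GROUP_N_ASSIST = [6, 2, 6, 1, 1, 3, 2, 0, 3, 5, 6, 5, 2, 3, 2]
_GROUP_N_UNDER10 = [0, 0, 2, 0, 0, 1, 2, 0, 0, 1, 3, 2, 0, 1, 2]


def survey_group_fixture(adults_per_group: int = 4) -> list[Resident]:
    """A 15-group roster with the survey's exact assistance/under-10 counts.

    Each group holds its surveyed number of assistance-needing members
    (children under 10 among them, the rest elderly) plus a few able
    adults.  Group abilities depend on member ages, which the survey does
    not publish; supply transcribed abilities to the accounting functions
    when reproducing a published table.
    """
    residents: list[Resident] = []
    rid = 0
    for gi, (n_assist, n_u10) in enumerate(zip(_GROUP_N_ASSIST, _GROUP_N_UNDER10)):
        gid = f"{gi + 1:02d}"
        bid = f"g{gid}_b0"
        def add(age: int, gender: str, needs: bool):
            nonlocal rid
            residents.append(
                Resident(
                    id=f"r{rid:04d}",
                    building_id=bid,
                    age=age,
                    gender=gender,
                    needs_assistance=needs,
                    group_id=gid,
                    household_id=f"g{gid}_h0",
                )
            )
            rid += 1

        for k in range(n_u10):
            add(5, "male" if k % 2 == 0 else "female", True)
        for k in range(n_assist - n_u10):
            add(80, "male" if k % 2 == 0 else "female", True)
        for k in range(adults_per_group):
            add(40, "male" if k % 2 == 0 else "female", False)
    return residents
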