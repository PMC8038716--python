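"""Precomputed earthquake damage: collapse, rubble blockage, fire spread.

The damage simulation is deliberately separated from the evacuation
simulation.  A :class:`HazardTimeline` is computed once, before any agent
moves, and the evacuation engine reads it step by step without mutating it;
re-running the evacuation under a different behavioural scenario therefore
replays exactly the same disaster.

Space is a hybrid of two representations:

* a grid of 3 m x 3 m cells (the resolution at which rubble and fire are
  tracked), each classified open / building / road;
* the road network graph, on which agents actually move; each road cell
  back-references its network link.

Three sub-models run on this field:

* **collapse** — one Bernoulli draw per building with a probability looked
  up from (structure, floors, construction year);
* **rubble** — a collapsed building spills rubble onto its adjacent road
  link; the link's residual width is the road width minus the intrusion
  depth, and the link is impassable when the residual width falls below
  0.6 m;
* **fire** — a stochastic cellular automaton: each burning cell ignites each
  unburned 8-neighbour *building* cell per second with a base probability
  multiplied by a wind-alignment factor, and burns out after a fixed
  duration.  Open and road cells never ignite.

Each sub-model draws from its own random stream spawned from the master
seed, so switching one hazard off does not perturb another's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from shapely import contains_xy
from shapely.geometry import LineString, Polygon

from .town import Building, World

__all__ = [
    "CELL_SIZE",
    "RUBBLE_PASS_WIDTH",
    "GridField",
    "rasterize",
    "CollapseRule",
    "CollapseConfig",
    "DEFAULT_COLLAPSE_CONFIG",
    "sample_collapses",
    "generate_rubble",
    "FireParams",
    "FireState",
    "ignite",
    "step_fire",
    "HazardTimeline",
    "build_timeline",
]

CELL_SIZE = 3.0  # m; rubble and fire are evaluated in 3 m x 3 m units
RUBBLE_PASS_WIDTH = 0.6  # m; minimum residual road width residents can pass

OPEN, BUILDING, ROAD = 0, 1, 2

# 8-point compass -> unit vector the wind blows FROM (x east, y north)
_COMPASS = {
    "n": (0.0, 1.0), "ne": (1.0, 1.0), "e": (1.0, 0.0), "se": (1.0, -1.0),
    "s": (0.0, -1.0), "sw": (-1.0, -1.0), "w": (-1.0, 0.0), "nw": (-1.0, 1.0),
}


@dataclass
class GridField:
    """3 m grid over the district extent; row 0 at the southern edge."""

    x0: float
    y0: float
    n_rows: int
    n_cols: int
    cls: np.ndarray               # (n_rows, n_cols) uint8: open/building/road
    building_index: np.ndarray    # int32 index into building_ids, -1 if none
    building_ids: list[str]
    link_cells: dict[tuple, np.ndarray]  # edge key -> flat cell indices

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        return (int((y - self.y0) // CELL_SIZE), int((x - self.x0) // CELL_SIZE))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + CELL_SIZE * (np.arange(self.n_cols) + 0.5)
        ys = self.y0 + CELL_SIZE * (np.arange(self.n_rows) + 0.5)
        return np.meshgrid(xs, ys)

    def building_cells(self, building_id: str) -> np.ndarray:
        """Flat indices of the cells a building occupies."""
        idx = self.building_ids.index(building_id)
        return np.flatnonzero(self.building_index.ravel() == idx)


def _footprint(b: Building) -> Polygon:
    if b.footprint is not None:
        return b.footprint
    h = 4.5  # default 9 m x 9 m footprint
    return Polygon(
        [(b.x - h, b.y - h), (b.x + h, b.y - h), (b.x + h, b.y + h), (b.x - h, b.y + h)]
    )


def rasterize(
    world: World,
    margin: float = 9.0,
    extent: tuple[float, float, float, float] | None = None,
) -> GridField:
    """Classify the district extent into open / building / road cells.

    Cells claimed by both a building footprint and a road buffer resolve
    building-first.  Road cells record which network link they belong to.
    Cell membership is half-open: a cell belongs to a footprint when the
    footprint covers a point an epsilon north-east of the cell centre, so a
    geometry edge falling exactly on cell centres claims each cell once.
    Without an explicit ``extent`` the grid covers all inputs plus a margin.
    """
    geoms = [_footprint(b) for b in world.buildings.values()]
    if extent is None:
        xs, ys = [], []
        for g in geoms:
            minx, miny, maxx, maxy = g.bounds
            xs += [minx, maxx]
            ys += [miny, maxy]
        for n in world.graph.nodes:
            xs.append(world.graph.nodes[n]["x"])
            ys.append(world.graph.nodes[n]["y"])
        if not xs:
            raise ValueError("cannot rasterize an empty world")
        extent = (min(xs) - margin, min(ys) - margin, max(xs) + margin, max(ys) + margin)
    x0 = math.floor(extent[0] / CELL_SIZE) * CELL_SIZE
    y0 = math.floor(extent[1] / CELL_SIZE) * CELL_SIZE
    n_cols = int(math.ceil((extent[2] - x0) / CELL_SIZE))
    n_rows = int(math.ceil((extent[3] - y0) / CELL_SIZE))
    if n_rows * n_cols > 50_000_000:
        raise ValueError(f"raster of {n_rows} x {n_cols} cells is implausibly large")

    cls = np.zeros((n_rows, n_cols), dtype=np.uint8)
    bidx = np.full((n_rows, n_cols), -1, dtype=np.int32)
    cx, cy = (
        x0 + CELL_SIZE * (np.arange(n_cols) + 0.5),
        y0 + CELL_SIZE * (np.arange(n_rows) + 0.5),
    )
    gx, gy = np.meshgrid(cx, cy)

    building_ids = list(world.buildings)
    for i, (bid, geom) in enumerate(zip(building_ids, geoms)):
        minx, miny, maxx, maxy = geom.bounds
        if minx < x0 or miny < y0 or maxx > x0 + n_cols * CELL_SIZE or maxy > y0 + n_rows * CELL_SIZE:
            raise ValueError(f"building {bid} extends outside the raster extent")
        r0 = max(0, int((miny - y0) // CELL_SIZE))
        r1 = min(n_rows, int((maxy - y0) // CELL_SIZE) + 1)
        c0 = max(0, int((minx - x0) // CELL_SIZE))
        c1 = min(n_cols, int((maxx - x0) // CELL_SIZE) + 1)
        inside = contains_xy(geom, gx[r0:r1, c0:c1] + 1e-6, gy[r0:r1, c0:c1] + 1e-6)
        cls[r0:r1, c0:c1][inside] = BUILDING
        bidx[r0:r1, c0:c1][inside] = i

    link_cells: dict[tuple, np.ndarray] = {}
    for u, v, data in world.graph.edges(data=True):
        width = float(data.get("width", 4.0))
        if width <= 0:
            raise ValueError(f"road ({u}, {v}) has non-positive width")
        line = LineString(
            [
                (world.graph.nodes[u]["x"], world.graph.nodes[u]["y"]),
                (world.graph.nodes[v]["x"], world.graph.nodes[v]["y"]),
            ]
        )
        buf = line.buffer(max(width / 2.0, CELL_SIZE / 2.0), cap_style="flat")
        minx, miny, maxx, maxy = buf.bounds
        r0 = max(0, int((miny - y0) // CELL_SIZE))
        r1 = min(n_rows, int((maxy - y0) // CELL_SIZE) + 1)
        c0 = max(0, int((minx - x0) // CELL_SIZE))
        c1 = min(n_cols, int((maxx - x0) // CELL_SIZE) + 1)
        inside = contains_xy(buf, gx[r0:r1, c0:c1] + 1e-6, gy[r0:r1, c0:c1] + 1e-6)
        sub = cls[r0:r1, c0:c1]
        road_here = inside & (sub != BUILDING)  # building claims win
        sub[road_here] = ROAD
        rows, colz = np.nonzero(road_here)
        key = tuple(sorted((u, v), key=repr))
        flat = (rows + r0) * n_cols + (colz + c0)
        link_cells[key] = (
            np.concatenate([link_cells[key], flat]) if key in link_cells else flat
        )

    return GridField(x0, y0, n_rows, n_cols, cls, bidx, building_ids, link_cells)


@dataclass(frozen=True)
class CollapseRule:
    """One row of the collapse-probability lookup; None matches anything."""

    structure: str | None
    year_max: int | None      # matches year_built <= year_max
    floors_min: int | None    # matches floors >= floors_min
    probability: float

    def matches(self, b: Building) -> bool:
        return (
            (self.structure is None or b.structure == self.structure)
            and (self.year_max is None or b.year_built <= self.year_max)
            and (self.floors_min is None or b.floors >= self.floors_min)
        )


class CollapseConfig:
    """First-match lookup (structure, year band, floor band) -> probability."""

    def __init__(self, rules: list[CollapseRule]):
        for r in rules:
            if not 0.0 <= r.probability <= 1.0:
                raise ValueError(f"collapse probability out of [0,1]: {r.probability}")
        self.rules = rules

    def probability(self, b: Building) -> float:
        for r in self.rules:
            if r.matches(b):
                return r.probability
        raise KeyError(
            f"no collapse rule matches building {b.id} "
            f"(structure={b.structure}, floors={b.floors}, year={b.year_built})"
        )


# Default fragility lookup.  The covariates (structure, floors, construction
# year; 1981 = Japan's new seismic code, 2000 = its wooden-house revision)
# are the model's; the probabilities are package defaults chosen to be
# monotone in age and in wood fraction, and MUST be replaced with
# study-specific values for real planning work.
DEFAULT_COLLAPSE_CONFIG = CollapseConfig(
    [
        CollapseRule("wood", 1980, 3, 0.40),
        CollapseRule("wood", 1980, None, 0.30),
        CollapseRule("wood", 2000, 3, 0.15),
        CollapseRule("wood", 2000, None, 0.12),
        CollapseRule("wood", None, None, 0.05),
        CollapseRule("steel", 1980, None, 0.15),
        CollapseRule("steel", 2000, None, 0.06),
        CollapseRule("steel", None, None, 0.03),
        CollapseRule("rc", 1980, None, 0.10),
        CollapseRule("rc", 2000, None, 0.04),
        CollapseRule("rc", None, None, 0.01),
        CollapseRule(None, None, None, 0.10),
    ]
)


def sample_collapses(
    buildings: list[Building],
    config: CollapseConfig = DEFAULT_COLLAPSE_CONFIG,
    rng: np.random.Generator | int | None = None,
) -> set[str]:
    """Independent Bernoulli collapse draw per building."""
    rng = np.random.default_rng(rng)
    probs = np.array([config.probability(b) for b in buildings])
    draws = rng.random(len(buildings))
    return {b.id for b, p, u in zip(buildings, probs, draws) if u < p}


def generate_rubble(
    building: Building,
    link: tuple,
    link_width: float,
    intrusion_factor: float = 1.0,
) -> tuple[float, bool]:
    """Residual width and blocked flag for the link beside a collapsed building.

    Rubble intrusion depth is ``intrusion_factor`` times half the building
    height (floors x 3 m storey height), capped at the road width.  The link
    is impassable when the residual width is strictly below 0.6 m.
    """
    intrusion = min(link_width, intrusion_factor * 0.5 * building.floors * CELL_SIZE)
    residual = link_width - intrusion
    return residual, residual < RUBBLE_PASS_WIDTH


@dataclass
class FireParams:
    """Fire cellular-automaton parameters.

    ``wind_direction`` is the 8-point compass direction the wind blows FROM
    (a "northwest" wind pushes fire towards the southeast).  The per-second
    per-neighbour ignition probability is ``p_base`` scaled by
    ``1 + wind_bias * wind_speed * cos(theta)`` (clipped at zero), where
    theta is the angle between the spread direction and the downwind
    direction.
    """

    wind_speed: float = 5.0           # m/s (base scenario)
    wind_direction: str = "nw"        # blows from the northwest
    p_base: float = 0.02              # per-neighbour per-second ignition prob.
    wind_bias: float = 0.12           # per (m/s) directional modulation
    n_origins: int = 1
    burn_duration: int = 300          # s a cell burns before burning out

    def __post_init__(self):
        if self.wind_direction.lower() not in _COMPASS:
            raise ValueError(f"unknown wind direction: {self.wind_direction!r}")
        if not 0.0 <= self.p_base <= 1.0:
            raise ValueError("p_base must be in [0, 1]")
        if self.n_origins < 0:
            raise ValueError("n_origins must be non-negative")

    def direction_probabilities(self) -> dict[tuple[int, int], float]:
        """Ignition probability per (drow, dcol) spread direction."""
        wx, wy = _COMPASS[self.wind_direction.lower()]
        norm = math.hypot(wx, wy)
        downwind = (-wx / norm, -wy / norm)
        out = {}
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                n = math.hypot(dr, dc)
                d = (dc / n, dr / n)  # +row = north = +y
                cos = d[0] * downwind[0] + d[1] * downwind[1]
                f = max(0.0, 1.0 + self.wind_bias * self.wind_speed * cos)
                out[(dr, dc)] = min(1.0, self.p_base * f)
        return out


UNBURNED, BURNING, BURNED = 0, 1, 2


@dataclass
class FireState:
    status: np.ndarray       # (rows, cols) uint8 unburned/burning/burned
    ignition_t: np.ndarray   # int32 step a cell ignited, -1 otherwise
    t: int = 0

    @classmethod
    def initial(cls, field_shape: tuple[int, int]) -> "FireState":
        return cls(
            status=np.zeros(field_shape, dtype=np.uint8),
            ignition_t=np.full(field_shape, -1, dtype=np.int32),
        )


def ignite(
    field: GridField,
    n_origins: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Fire origins: a uniform draw without replacement among building cells."""
    if n_origins < 0:
        raise ValueError("n_origins must be non-negative")
    rng = np.random.default_rng(rng)
    candidates = np.flatnonzero(field.cls.ravel() == BUILDING)
    if n_origins > candidates.size:
        raise ValueError(
            f"n_origins={n_origins} exceeds {candidates.size} building cells"
        )
    if n_origins == 0:
        return np.array([], dtype=np.int64)
    return np.sort(rng.choice(candidates, size=n_origins, replace=False))


def step_fire(
    state: FireState,
    field: GridField,
    params: FireParams,
    rng: np.random.Generator,
) -> FireState:
    """Advance the fire automaton one second (in place; returns state)."""
    burning = state.status == BURNING
    if burning.any():
        flammable = (field.cls == BUILDING) & (state.status == UNBURNED)
        p_no = np.ones(state.status.shape)
        for (dr, dc), p in params.direction_probabilities().items():
            if p <= 0.0:
                continue
            # neighbour at (r-dr, c-dc) burning means fire spreads along (dr, dc)
            src = np.zeros_like(burning)
            rs = slice(max(dr, 0), state.status.shape[0] + min(dr, 0))
            cs = slice(max(dc, 0), state.status.shape[1] + min(dc, 0))
            rs0 = slice(max(-dr, 0), state.status.shape[0] + min(-dr, 0))
            cs0 = slice(max(-dc, 0), state.status.shape[1] + min(-dc, 0))
            src[rs, cs] = burning[rs0, cs0]
            p_no[src] *= 1.0 - p
        p_ignite = np.where(flammable, 1.0 - p_no, 0.0)
        new = rng.random(state.status.shape) < p_ignite
        state.status[new] = BURNING
        state.ignition_t[new] = state.t + 1
        burnout = burning & (state.t + 1 - state.ignition_t >= params.burn_duration)
        state.status[burnout] = BURNED
    state.t += 1
    return state


def _edge_key(u, v) -> tuple:
    return tuple(sorted((u, v), key=repr))


@dataclass
class HazardTimeline:
    """Immutable per-second damage record consumed by the evacuation engine.

    Collapse and rubble are fixed at step 0 (they happen at the earthquake);
    fire evolves, recorded as per-cell ignition and burn-out steps.
    """

    horizon: int
    seed: int
    collapsed: set[str]
    link_residual: dict[tuple, float]
    link_blocked_rubble: dict[tuple, bool]
    rubble_cells: set[int]
    ignition_step: np.ndarray   # flat (rows*cols,) int32, -1 = never ignites
    burnout_step: np.ndarray
    building_fire_step: dict[str, int]   # building id -> first ignition step
    link_fire_step: dict[tuple, int]     # edge key -> step link becomes unsafe
    shape: tuple[int, int] = (0, 0)

    def burning_cells(self, t: int) -> np.ndarray:
        ign = self.ignition_step
        return np.flatnonzero((ign >= 0) & (ign <= t) & (self.burnout_step > t))

    def burned_cells(self, t: int) -> np.ndarray:
        """Cells ignited at or before t (burning or already burnt out)."""
        return np.flatnonzero((self.ignition_step >= 0) & (self.ignition_step <= t))

    def building_burning(self, building_id: str, t: int) -> bool:
        s = self.building_fire_step.get(building_id, -1)
        return s >= 0 and s <= t

    def blocked_links(self, t: int, rubble_blocking: str = "passable") -> set[tuple]:
        """Links an agent cannot traverse at step t.

        ``rubble_blocking='passable'`` means residents can squeeze through
        gaps between rubble heaps, so only fire blocks; ``'impassable'``
        also applies the 0.6 m residual-width rule.  Fire blockage is
        always on.
        """
        blocked = {e for e, s in self.link_fire_step.items() if 0 <= s <= t}
        if rubble_blocking == "impassable":
            blocked |= {e for e, b in self.link_blocked_rubble.items() if b}
        elif rubble_blocking != "passable":
            raise ValueError(f"unknown rubble_blocking mode: {rubble_blocking!r}")
        return blocked

    def fire_change_steps(self) -> list[int]:
        """Steps at which the set of fire-blocked links grows."""
        return sorted({s for s in self.link_fire_step.values() if s >= 0})

    @classmethod
    def from_json(cls, text: str) -> "HazardTimeline":
        d = json.loads(text)
        return cls(
            horizon=d["horizon"],
            seed=d["seed"],
            collapsed=set(d["collapsed"]),
            link_residual={tuple(e): w for e, w in d["link_residual"]},
            link_blocked_rubble={tuple(e): b for e, b in d["link_blocked_rubble"]},
            rubble_cells=set(d["rubble_cells"]),
            ignition_step=np.asarray(d["ignition_step"], dtype=np.int32),
            burnout_step=np.asarray(d["burnout_step"], dtype=np.int32),
            building_fire_step=d["building_fire_step"],
            link_fire_step={tuple(e): s for e, s in d["link_fire_step"]},
            shape=tuple(d["shape"]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "horizon": self.horizon,
                "seed": self.seed,
                "shape": list(self.shape),
                "collapsed": sorted(self.collapsed),
                "link_residual": [
                    [list(map(str, e)), w] for e, w in sorted(self.link_residual.items(), key=repr)
                ],
                "link_blocked_rubble": [
                    [list(map(str, e)), b] for e, b in sorted(self.link_blocked_rubble.items(), key=repr)
                ],
                "rubble_cells": sorted(self.rubble_cells),
                "ignition_step": self.ignition_step.tolist(),
                "burnout_step": self.burnout_step.tolist(),
                "building_fire_step": dict(sorted(self.building_fire_step.items())),
                "link_fire_step": [
                    [list(map(str, e)), s] for e, s in sorted(self.link_fire_step.items(), key=repr)
                ],
            },
            sort_keys=True,
        )


def build_timeline(
    world: World,
    field: GridField,
    collapse_config: CollapseConfig = DEFAULT_COLLAPSE_CONFIG,
    fire_params: FireParams | None = None,
    horizon: int = 1800,
    seed: int = 0,
    intrusion_factor: float = 1.0,
    collapse_enabled: bool = True,
    fire_enabled: bool = True,
) -> HazardTimeline:
    """Run collapse, rubble and fire sub-models; freeze the full timeline.

    One random stream per sub-model (collapse draws, fire origins, fire
    spread) is spawned from the master seed, so disabling one hazard leaves
    the others' realisations unchanged.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    fire_params = fire_params or FireParams()
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_collapse, rng_origin, rng_spread = (np.random.default_rng(s) for s in ss)

    buildings = list(world.buildings.values())
    collapsed = (
        sample_collapses(buildings, collapse_config, rng_collapse)
        if collapse_enabled
        else set()
    )

    link_residual: dict[tuple, float] = {}
    link_blocked: dict[tuple, bool] = {}
    rubble_cells: set[int] = set()
    for u, v, data in world.graph.edges(data=True):
        key = _edge_key(u, v)
        link_residual[key] = float(data.get("width", 4.0))
        link_blocked[key] = False
    for bid in sorted(collapsed):
        b = world.buildings[bid]
        key = world.building_edge.get(bid)
        if key is None:
            continue
        residual, blocked = generate_rubble(
            b, key, link_residual[key], intrusion_factor
        )
        if residual < link_residual[key]:
            link_residual[key] = residual
            link_blocked[key] = link_blocked[key] or blocked
            cells = field.link_cells.get(key, np.array([], dtype=np.int64))
            if cells.size:
                rr, cc = np.divmod(cells, field.n_cols)
                cx = field.x0 + CELL_SIZE * (cc + 0.5)
                cy = field.y0 + CELL_SIZE * (rr + 0.5)
                near = (cx - b.x) ** 2 + (cy - b.y) ** 2 <= (9.0 + residual) ** 2
                rubble_cells |= set(cells[near].tolist())

    state = FireState.initial(field.shape)
    if fire_enabled and fire_params.n_origins > 0:
        origins = ignite(field, fire_params.n_origins, rng_origin)
        rr, cc = np.divmod(origins, field.n_cols)
        state.status[rr, cc] = BURNING
        state.ignition_t[rr, cc] = 0
        for _ in range(horizon):
            step_fire(state, field, fire_params, rng_spread)

    ignition = state.ignition_t.ravel().copy()
    burnout = np.where(ignition >= 0, ignition + fire_params.burn_duration, -1).astype(
        np.int32
    )

    building_fire_step: dict[str, int] = {}
    flat_bidx = field.building_index.ravel()
    for i, bid in enumerate(field.building_ids):
        cells = np.flatnonzero(flat_bidx == i)
        steps = ignition[cells]
        steps = steps[steps >= 0]
        building_fire_step[bid] = int(steps.min()) if steps.size else -1

    # a link becomes unsafe when fire reaches any cell adjacent (8-neighbour,
    # incl. itself) to one of its road cells
    link_fire_step: dict[tuple, int] = {}
    ign2d = state.ignition_t
    n_rows, n_cols = field.shape
    for key, cells in field.link_cells.items():
        best = -1
        rr, cc = np.divmod(cells, n_cols)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r = np.clip(rr + dr, 0, n_rows - 1)
                c = np.clip(cc + dc, 0, n_cols - 1)
                steps = ign2d[r, c]
                steps = steps[steps >= 0]
                if steps.size:
                    s = int(steps.min())
                    best = s if best < 0 else min(best, s)
        link_fire_step[key] = best

    return HazardTimeline(
        horizon=horizon,
        seed=seed,
        collapsed=collapsed,
        link_residual=link_residual,
        link_blocked_rubble=link_blocked,
        rubble_cells=rubble_cells,
        ignition_step=ignition,
        burnout_step=burnout,
        building_fire_step=building_fire_step,
        link_fire_step={k: v for k, v in link_fire_step.items() if v >= 0},
        shape=field.shape,
    )
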