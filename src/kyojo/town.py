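"""Core containers: residents, buildings, barriers and the district world.

All coordinates are planar metres (inputs are assumed already projected);
distances are Euclidean.  The road network is a :class:`networkx.Graph`
whose nodes carry ``x``/``y`` positions and whose edges carry ``length``
(metres) and ``width`` (metres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .rates import DEFAULT_ELIGIBILITY_AGE, DEFAULT_RATE_TABLE, RescueRateTable, expected_value

__all__ = ["Resident", "Building", "BarrierSet", "World"]


@dataclass
class Resident:
    id: str
    building_id: str
    age: int
    gender: str
    needs_assistance: bool = False
    group_id: str | None = None
    household_id: str | None = None
    commuter: bool = False

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"resident {self.id}: age must be non-negative")
        if self.gender not in ("male", "female"):
            raise ValueError(f"resident {self.id}: unknown gender {self.gender!r}")

    def rescuer_eligible(self, eligibility_age: int = DEFAULT_ELIGIBILITY_AGE) -> bool:
        """School children and assistance-needing residents cannot rescue."""
        return self.age >= eligibility_age and not self.needs_assistance

    def expected_value(
        self,
        table: RescueRateTable = DEFAULT_RATE_TABLE,
        eligibility_age: int = DEFAULT_ELIGIBILITY_AGE,
    ) -> float:
        return expected_value(
            self.age, self.gender, table, self.rescuer_eligible(eligibility_age)
        )


@dataclass
class Building:
    id: str
    x: float
    y: float
    structure: str = "wood"
    floors: int = 1
    year_built: int = 1990
    footprint: BaseGeometry | None = None
    residents: list[Resident] = field(default_factory=list)

    def __post_init__(self):
        if self.floors < 1:
            raise ValueError(f"building {self.id}: floors must be >= 1")

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)

    def expected_value(
        self,
        table: RescueRateTable = DEFAULT_RATE_TABLE,
        eligibility_age: int = DEFAULT_ELIGIBILITY_AGE,
    ) -> float:
        """Building expected rescue value Rr: sum over attached residents."""
        return sum(r.expected_value(table, eligibility_age) for r in self.residents)


class BarrierSet:
    """Impassable line/polygon features: rivers, rail tracks, wide trunk roads.

    A straight segment between two points "crosses" the barrier set when it
    intersects any feature; such pairs are mutually unreachable for the
    building-unit capability evaluation and mutually invisible for victim
    perception.
    """

    def __init__(self, features: list[BaseGeometry] | None = None):
        features = list(features or [])
        for g in features:
            if not g.is_valid:
                raise ValueError("barrier geometry is invalid (self-intersecting?)")
        self.features = features
        self._tree = STRtree(features) if features else None

    def __len__(self) -> int:
        return len(self.features)

    def crosses(self, p: tuple[float, float], q: tuple[float, float]) -> bool:
        """True if the straight segment p-q intersects any barrier feature."""
        if self._tree is None:
            return False
        seg = LineString([p, q]) if p != q else Point(p)
        return any(
            self.features[i].intersects(seg)
            for i in self._tree.query(seg)
        )


class World:
    """A district: buildings with residents, road network, sites, barriers."""

    def __init__(
        self,
        buildings: list[Building],
        graph: nx.Graph,
        sites: list[int] | None = None,
        barriers: BarrierSet | None = None,
    ):
        self.buildings = {b.id: b for b in buildings}
        if len(self.buildings) != len(buildings):
            raise ValueError("duplicate building ids")
        self.graph = graph
        self.sites = list(sites or [])
        self.barriers = barriers if barriers is not None else BarrierSet()
        for s in self.sites:
            if s not in graph:
                raise ValueError(f"evacuation site node {s!r} not in road network")
        self._attach_nodes()

    def _attach_nodes(self) -> None:
        """Attach each building to its nearest network node and edge."""
        if self.graph.number_of_nodes() == 0:
            self.building_node = {}
            self.building_edge = {}
            return
        nodes = list(self.graph.nodes)
        xy = np.array([[self.graph.nodes[n]["x"], self.graph.nodes[n]["y"]] for n in nodes])
        self.building_node: dict[str, object] = {}
        self.building_edge: dict[str, tuple] = {}
        edges = list(self.graph.edges)
        edge_geoms = [
            LineString(
                [
                    (self.graph.nodes[u]["x"], self.graph.nodes[u]["y"]),
                    (self.graph.nodes[v]["x"], self.graph.nodes[v]["y"]),
                ]
            )
            for u, v in edges
        ]
        tree = STRtree(edge_geoms) if edge_geoms else None
        for b in self.buildings.values():
            d2 = ((xy - [b.x, b.y]) ** 2).sum(axis=1)
            self.building_node[b.id] = nodes[int(np.argmin(d2))]
            if tree is not None:
                i = int(tree.nearest(Point(b.x, b.y)))
                self.building_edge[b.id] = tuple(sorted(edges[i], key=repr))

    @property
    def residents(self) -> list[Resident]:
        return [r for b in self.buildings.values() for r in b.residents]

    def attach_roster(self, residents: list[Resident]) -> None:
        """Attach residents to buildings, validating every building_id."""
        missing = sorted({r.building_id for r in residents} - set(self.buildings))
        if missing:
            raise ValueError(
                f"roster references unknown building ids: {', '.join(map(str, missing))}"
            )
        for b in self.buildings.values():
            b.residents = []
        for r in residents:
            self.buildings[r.building_id].residents.append(r)
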