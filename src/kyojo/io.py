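"""Readers and writers: GeoJSON geometry, CSV rosters, YAML run configs.

Geometry is exchanged as RFC 7946 GeoJSON (text, diffable); coordinates are
planar metres in a projected CRS declared in the run config — nothing here
does geodesy.  Rosters and results are UTF-8 CSV with a header row; result
files carry a leading ``#``-comment line embedding the master seed and the
config hash so any output can be traced back to its run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .town import BarrierSet, Building, Resident, World

__all__ = [
    "read_buildings",
    "write_buildings",
    "read_roads",
    "write_roads",
    "read_sites",
    "write_sites",
    "read_barriers",
    "write_barriers",
    "read_roster",
    "write_roster",
    "write_world",
    "read_world",
    "RunConfig",
    "load_inputs",
    "stamp",
    "write_csv",
    "read_csv",
]

ROSTER_COLUMNS = [
    "resident_id",
    "building_id",
    "group_id",
    "household_id",
    "age",
    "gender",
    "needs_assistance",
    "commuter",
]


def _feature_collection(features: list[dict], meta: dict | None = None) -> dict:
    fc = {"type": "FeatureCollection", "features": features}
    if meta:
        fc["metadata"] = meta
    return fc


def write_buildings(buildings: list[Building], path, meta: dict | None = None) -> None:
    features = []
    for b in buildings:
        geom = mapping(b.footprint) if b.footprint is not None else {
            "type": "Point",
            "coordinates": [b.x, b.y],
        }
        features.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "id": b.id,
                    "structure": b.structure,
                    "floors": b.floors,
                    "year_built": b.year_built,
                },
            }
        )
    Path(path).write_text(json.dumps(_feature_collection(features, meta), indent=1))


def read_buildings(path) -> list[Building]:
    fc = json.loads(Path(path).read_text())
    buildings = []
    for f in fc["features"]:
        geom = shape(f["geometry"])
        p = f.get("properties") or {}
        if "id" not in p:
            raise ValueError(f"building feature without an 'id' property in {path}")
        c = geom.centroid
        buildings.append(
            Building(
                id=str(p["id"]),
                x=c.x,
                y=c.y,
                structure=p.get("structure", "wood"),
                floors=int(p.get("floors", 1)),
                year_built=int(p.get("year_built", 1990)),
                footprint=geom if geom.geom_type == "Polygon" else None,
            )
        )
    return buildings


def write_roads(graph: nx.Graph, path, meta: dict | None = None) -> None:
    features = []
    for u, v, data in graph.edges(data=True):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [graph.nodes[u]["x"], graph.nodes[u]["y"]],
                        [graph.nodes[v]["x"], graph.nodes[v]["y"]],
                    ],
                },
                "properties": {"u": str(u), "v": str(v), "width": data.get("width", 4.0)},
            }
        )
    Path(path).write_text(json.dumps(_feature_collection(features, meta), indent=1))


def read_roads(path) -> nx.Graph:
    """Road network from LineString features carrying a ``width`` property.

    Node ids come from ``u``/``v`` properties when present, otherwise from
    the endpoint coordinates (rounded to cm, so shared endpoints snap).
    """
    fc = json.loads(Path(path).read_text())
    g = nx.Graph()

    def node_id(coord, explicit):
        if explicit is not None:
            return str(explicit)
        return f"{round(coord[0], 2)}_{round(coord[1], 2)}"

    for f in fc["features"]:
        coords = f["geometry"]["coordinates"]
        p = f.get("properties") or {}
        width = float(p.get("width", 4.0))
        ids = [p.get("u"), p.get("v")] if len(coords) == 2 else [None] * len(coords)
        for a, b, ia, ib in zip(coords[:-1], coords[1:], ids[:-1], ids[1:]):
            na, nb = node_id(a, ia), node_id(b, ib)
            g.add_node(na, x=float(a[0]), y=float(a[1]))
            g.add_node(nb, x=float(b[0]), y=float(b[1]))
            g.add_edge(na, nb, length=float(np.hypot(b[0] - a[0], b[1] - a[1])), width=width)
    return g


def write_sites(graph: nx.Graph, sites: list, path, meta: dict | None = None) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [graph.nodes[s]["x"], graph.nodes[s]["y"]],
            },
            "properties": {"node": str(s)},
        }
        for s in sites
    ]
    Path(path).write_text(json.dumps(_feature_collection(features, meta), indent=1))


def read_sites(path, graph: nx.Graph) -> list:
    """Evacuation sites snapped to the nearest road-network node."""
    fc = json.loads(Path(path).read_text())
    nodes = list(graph.nodes)
    xy = np.array([[graph.nodes[n]["x"], graph.nodes[n]["y"]] for n in nodes])
    sites = []
    for f in fc["features"]:
        p = f.get("properties") or {}
        if p.get("node") in graph:
            sites.append(p["node"])
            continue
        x, y = f["geometry"]["coordinates"][:2]
        sites.append(nodes[int(np.argmin(((xy - [x, y]) ** 2).sum(axis=1)))])
    return sites


def write_barriers(barriers: BarrierSet, path, meta: dict | None = None) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": {"impassable": True}}
        for g in barriers.features
    ]
    Path(path).write_text(json.dumps(_feature_collection(features, meta), indent=1))


def read_barriers(path) -> BarrierSet:
    fc = json.loads(Path(path).read_text())
    return BarrierSet([shape(f["geometry"]) for f in fc.get("features", [])])


def write_roster(residents: list[Resident], path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "resident_id": r.id,
                "building_id": r.building_id,
                "group_id": r.group_id or "",
                "household_id": r.household_id or "",
                "age": r.age,
                "gender": r.gender,
                "needs_assistance": int(r.needs_assistance),
                "commuter": int(r.commuter),
            }
            for r in residents
        ],
        columns=ROSTER_COLUMNS,
    )
    write_csv(df, path, meta)


def read_roster(path) -> list[Resident]:
    df = pd.read_csv(path, comment="#", dtype={"resident_id": str, "building_id": str})
    missing = {"resident_id", "building_id", "age", "gender"} - set(df.columns)
    if missing:
        raise ValueError(f"roster {path} lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            Resident(
                id=str(d["resident_id"]),
                building_id=str(d["building_id"]),
                age=int(d["age"]),
                gender=str(d["gender"]),
                needs_assistance=bool(int(d.get("needs_assistance", 0) or 0)),
                group_id=(str(d["group_id"]) or None) if pd.notna(d.get("group_id")) and str(d.get("group_id")) != "" else None,
                household_id=(str(d["household_id"]) or None) if pd.notna(d.get("household_id")) and str(d.get("household_id")) != "" else None,
                commuter=bool(int(d.get("commuter", 0) or 0)),
            )
        )
    return out


def stamp(seed: int | None, config: dict | None = None) -> dict:
    """Provenance record embedded in every output file."""
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "master_seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV with an optional leading #-comment provenance line."""
    with open(path, "w", newline="") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_world(world: World, outdir, meta: dict | None = None) -> dict[str, Path]:
    """Write the standard input file set; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "buildings": outdir / "buildings.geojson",
        "roads": outdir / "roads.geojson",
        "sites": outdir / "sites.geojson",
        "barriers": outdir / "barriers.geojson",
        "roster": outdir / "roster.csv",
    }
    write_buildings(list(world.buildings.values()), paths["buildings"], meta)
    write_roads(world.graph, paths["roads"], meta)
    write_sites(world.graph, world.sites, paths["sites"], meta)
    write_barriers(world.barriers, paths["barriers"], meta)
    write_roster(world.residents, paths["roster"], meta)
    return paths


def read_world(
    buildings_path,
    roads_path,
    sites_path=None,
    barriers_path=None,
    roster_path=None,
) -> World:
    """Assemble a world from files, validating all cross-references."""
    buildings = read_buildings(buildings_path)
    graph = read_roads(roads_path)
    sites = read_sites(sites_path, graph) if sites_path else []
    barriers = read_barriers(barriers_path) if barriers_path else BarrierSet()
    world = World(buildings, graph, sites=sites, barriers=barriers)
    if roster_path:
        world.attach_roster(read_roster(roster_path))
    return world


@dataclass
class RunConfig:
    """Structured configuration for a full two-stage run."""

    buildings: str = "buildings.geojson"
    roads: str = "roads.geojson"
    sites: str = "sites.geojson"
    barriers: str | None = "barriers.geojson"
    roster: str = "roster.csv"
    outdir: str = "out"
    seed: int = 0
    capability: dict = dc_field(default_factory=dict)   # range_limit, divisor, ...
    hazard: dict = dc_field(default_factory=dict)       # fire params, horizon, ...
    scenario: dict = dc_field(default_factory=dict)     # speed, perception, ...

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def load_inputs(config: RunConfig, base=".") -> World:
    """World from a run config; missing optional files degrade gracefully."""
    base = Path(base)
    barriers = (
        base / config.barriers
        if config.barriers and (base / config.barriers).exists()
        else None
    )
    return read_world(
        base / config.buildings,
        base / config.roads,
        sites_path=base / config.sites if (base / config.sites).exists() else None,
        barriers_path=barriers,
        roster_path=base / config.roster if (base / config.roster).exists() else None,
    )
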