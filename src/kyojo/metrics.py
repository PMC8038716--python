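"""Batch summary statistics and map-form outputs.

A repeated-run batch is condensed into the standard six-column summary:

    (a) residents present
    (b) total successful evacuations over all runs
    (c) evacuation success rate %   = ((b) / n_runs) / (a) x 100
    (d) total residents requiring mutual assistance over all runs
    (e) total residents receiving mutual assistance over all runs
    (f) mutual assistance success rate % = (e) / (d) x 100

plus a per-run table of successful-evacuation counts with total and
average, and a GeoJSON layer of per-building helped / unhelped /
awaiting-public counts for map display.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .rates import round_half_up
from .simulate import AWAITING_PUBLIC, EVACUATED, SimulationResult
from .town import World

__all__ = ["BatchSummary", "summarize", "per_run_table", "map_output"]


@dataclass
class BatchSummary:
    n_residents: int                    # (a)
    total_evacuations: int              # (b), summed over runs
    evacuation_success_rate: float      # (c), %
    total_requiring_assistance: int     # (d), summed over runs
    total_receiving_assistance: int     # (e), summed over runs
    assistance_success_rate: float | None  # (f), %; None when (d) = 0
    per_run_evacuations: list[int]
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "a_residents": self.n_residents,
                    "b_total_evacuations": self.total_evacuations,
                    "c_evacuation_success_rate_pct": self.evacuation_success_rate,
                    "d_requiring_assistance": self.total_requiring_assistance,
                    "e_receiving_assistance": self.total_receiving_assistance,
                    "f_assistance_success_rate_pct": self.assistance_success_rate,
                }
            ]
        )


def evacuation_rate(total_evacuations: int, n_runs: int, n_residents: int) -> float:
    """(b)/n_runs gives the average evacuations; the average over (a), in %."""
    return round_half_up(total_evacuations / n_runs / n_residents * 100.0, 2)


def assistance_rate(receiving: int, requiring: int) -> float:
    """(e)/(d) in %."""
    return round_half_up(receiving / requiring * 100.0, 2)


def summarize(
    results: list[SimulationResult],
    n_residents: int | None = None,
    count_rescued: bool = True,
) -> BatchSummary:
    """Condense a batch of runs into the (a)-(f) summary.

    ``count_rescued=False`` excludes rescued-then-evacuated victims from the
    successful-evacuation count (b).  When nobody required assistance, the
    assistance success rate (f) is undefined (None), not zero.
    """
    if not results:
        raise ValueError("need at least one simulation result")
    if n_residents is None:
        n_residents = results[0].n_present
    per_run = []
    for r in results:
        n = sum(
            1
            for a in r.agents
            if a.state == EVACUATED and (count_rescued or not a.received_assistance)
        )
        per_run.append(n)
    requiring = sum(r.n_requiring_assistance for r in results)
    receiving = sum(r.n_receiving_assistance for r in results)
    total = sum(per_run)
    return BatchSummary(
        n_residents=n_residents,
        total_evacuations=total,
        evacuation_success_rate=evacuation_rate(total, len(results), n_residents),
        total_requiring_assistance=requiring,
        total_receiving_assistance=receiving,
        assistance_success_rate=(
            assistance_rate(receiving, requiring) if requiring > 0 else None
        ),
        per_run_evacuations=per_run,
        n_runs=len(results),
    )


def per_run_table(results_or_counts) -> pd.DataFrame:
    """Per-run successful-evacuation counts with total and average columns.

    Accepts either simulation results or pre-counted integers.

    >>> per_run_table([293, 296, 287, 290, 289, 295, 293, 296, 291, 287])
       1    2    3    4    5    6    7    8    9   10  total  average
    0  293  296  287  290  289  295  293  296  291  287   2917    291.7
    """
    if not len(results_or_counts):
        raise ValueError("need at least one run")
    counts = [
        r.n_evacuated if isinstance(r, SimulationResult) else int(r)
        for r in results_or_counts
    ]
    row = {str(i + 1): c for i, c in enumerate(counts)}
    row["total"] = sum(counts)
    row["average"] = round_half_up(sum(counts) / len(counts), 1)
    return pd.DataFrame([row])


def map_output(result: SimulationResult, world: World) -> dict:
    """Per-building outcome counts as a GeoJSON FeatureCollection.

    Properties per building: residents present, helped (received mutual
    assistance), unhelped (required but never received), awaiting_public,
    evacuated, casualties.
    """
    per_building: dict[str, dict[str, int]] = {
        bid: {
            "n_present": 0,
            "helped": 0,
            "unhelped": 0,
            "awaiting_public": 0,
            "evacuated": 0,
            "casualty": 0,
        }
        for bid in world.buildings
    }
    for a in result.agents:
        c = per_building[a.building_id]
        c["n_present"] += 1
        if a.received_assistance:
            c["helped"] += 1
        elif a.required_assistance:
            c["unhelped"] += 1
        if a.state == EVACUATED:
            c["evacuated"] += 1
        elif a.state == AWAITING_PUBLIC:
            c["awaiting_public"] += 1
        elif a.state == "casualty":
            c["casualty"] += 1
    features = []
    for bid, b in world.buildings.items():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [b.x, b.y]},
                "properties": {"building_id": bid, **per_building[bid]},
            }
        )
    return {"type": "FeatureCollection", "features": features}
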