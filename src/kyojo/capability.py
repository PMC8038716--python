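"""Mutual-assistance capability evaluation.

Two evaluation modes are provided, matching how a district study proceeds:

* **building unit** — each building's capability is the distance-weighted sum
  of the expected rescue values of all buildings within a range limit
  (default 100 m) that are not separated from it by an impassable barrier,
  divided by a fixed divisor (default 5).  This is the wide-area GIS score
  used to extract low-capability neighbourhoods.
* **group unit** — for a district whose neighbourhood association is split
  into small groups with strong internal ties, distance weighting is dropped
  and per-group ability is compared against the count of members who need
  evacuation assistance, giving a surplus/shortage account used when
  drafting a community disaster-management plan (CDMP).

The distance weight is

    dw(D) = log10(1 + X) / (2 * (log10(1 + D) + 1))    for 0 <= D <= X,
    dw(D) = 0                                          for D > X,

which equals ~1.0022 at D = 0 for the default X = 100 m and decreases
strictly with distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .rates import DEFAULT_ELIGIBILITY_AGE, DEFAULT_RATE_TABLE, RescueRateTable, round_half_up
from .town import BarrierSet, Building, Resident, World

__all__ = [
    "DEFAULT_RANGE_LIMIT",
    "DEFAULT_DIVISOR",
    "distance_weight",
    "building_capability",
    "evaluate_buildings",
    "GroupAccount",
    "group_capability",
    "group_accounts",
    "district_totals",
    "accounts_frame",
]

DEFAULT_RANGE_LIMIT = 100.0  # m, discovery range for a trapped neighbour
DEFAULT_DIVISOR = 5.0


def distance_weight(distance: float, range_limit: float = DEFAULT_RANGE_LIMIT) -> float:
    """Distance-decay weight dw applied to a neighbour's rescue value."""
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    if range_limit <= 0:
        raise ValueError(f"range limit must be positive, got {range_limit}")
    if distance > range_limit:
        return 0.0
    return math.log10(1.0 + range_limit) / (2.0 * (math.log10(1.0 + distance) + 1.0))


def building_capability(
    target: Building,
    all_buildings: list[Building],
    barriers: BarrierSet | None = None,
    table: RescueRateTable = DEFAULT_RATE_TABLE,
    range_limit: float = DEFAULT_RANGE_LIMIT,
    divisor: float = DEFAULT_DIVISOR,
    include_self: bool = True,
    eligibility_age: int = DEFAULT_ELIGIBILITY_AGE,
) -> float:
    """Mutual-assistance capability of one building.

    capability = sum_j Rr_j * dw(D_j) / divisor over buildings j within the
    range limit whose straight connection to the target crosses no barrier.
    The target's own residents count at D = 0 unless ``include_self`` is off.
    """
    if barriers is None:
        barriers = BarrierSet()
    total = 0.0
    for b in all_buildings:
        if b.id == target.id:
            if not include_self:
                continue
            d = 0.0
        else:
            d = math.dist(target.location, b.location)
            if d > range_limit:
                continue
            if barriers.crosses(target.location, b.location):
                continue
        total += b.expected_value(table, eligibility_age) * distance_weight(d, range_limit)
    return total / divisor


def evaluate_buildings(world: World, **kwargs) -> pd.DataFrame:
    """Capability of every building in a world; columns id, Rr, capability."""
    blds = list(world.buildings.values())
    table = kwargs.get("table", DEFAULT_RATE_TABLE)
    elig = kwargs.get("eligibility_age", DEFAULT_ELIGIBILITY_AGE)
    rows = [
        {
            "building_id": b.id,
            "x": b.x,
            "y": b.y,
            "n_residents": len(b.residents),
            "expected_value": b.expected_value(table, elig),
            "capability": building_capability(b, blds, world.barriers, **kwargs),
        }
        for b in blds
    ]
    return pd.DataFrame(rows)


@dataclass
class GroupAccount:
    """Surplus/shortage account for one small group.

    ``ability`` is the unweighted sum of member expected rescue values; an
    ability of k means k people could receive sufficient assistance from
    neighbours.  Case 1 counts every assistance-needing member; case 2
    exempts children under 10, who can be led or carried by one adult.
    """

    group_id: str
    n_assist: int
    n_under10: int
    ability: float

    @property
    def surplus_case1(self) -> float:
        return self.ability - self.n_assist

    @property
    def surplus_case2(self) -> float:
        return self.ability - (self.n_assist - self.n_under10)


def group_capability(
    group_id: str,
    residents: list[Resident],
    table: RescueRateTable = DEFAULT_RATE_TABLE,
    eligibility_age: int = DEFAULT_ELIGIBILITY_AGE,
    ability: float | None = None,
) -> GroupAccount:
    """Account for one group; no distance weighting.

    ``ability`` may be supplied directly (e.g. transcribed from a completed
    survey) instead of being recomputed from member ages.
    """
    if ability is None:
        ability = sum(r.expected_value(table, eligibility_age) for r in residents)
    # under-10s are surveyed as needing assistance; row (2) counts that subset
    return GroupAccount(
        group_id=group_id,
        n_assist=sum(1 for r in residents if r.needs_assistance),
        n_under10=sum(1 for r in residents if r.age < 10 and r.needs_assistance),
        ability=ability,
    )


def group_accounts(
    residents: list[Resident],
    table: RescueRateTable = DEFAULT_RATE_TABLE,
    eligibility_age: int = DEFAULT_ELIGIBILITY_AGE,
    abilities: dict[str, float] | None = None,
) -> list[GroupAccount]:
    """Accounts for all groups present in a roster, sorted by group id."""
    groups: dict[str, list[Resident]] = {}
    for r in residents:
        gid = r.group_id if r.group_id is not None else "ungrouped"
        groups.setdefault(gid, []).append(r)
    return [
        group_capability(
            gid,
            members,
            table,
            eligibility_age,
            ability=(abilities or {}).get(gid),
        )
        for gid, members in sorted(groups.items())
    ]


def district_totals(accounts: list[GroupAccount]) -> GroupAccount:
    """District-wide totals: exact sums of the per-group accounts."""
    if not accounts:
        raise ValueError("need at least one group account")
    return GroupAccount(
        group_id="total",
        n_assist=sum(a.n_assist for a in accounts),
        n_under10=sum(a.n_under10 for a in accounts),
        ability=sum(a.ability for a in accounts),
    )


def accounts_frame(accounts: list[GroupAccount], ndigits: int = 4) -> pd.DataFrame:
    """Survey-style table: one column per group plus a total column.

    Rows: (1) people who need assistance, (2) people under 10, (3) ability of
    mutual assistance, (4) surplus/shortage counting all assistance-needing
    members, (5) surplus/shortage exempting under-10s.
    """
    cols = accounts + [district_totals(accounts)]
    data = {
        a.group_id: [
            a.n_assist,
            a.n_under10,
            round_half_up(a.ability, ndigits),
            round_half_up(a.surplus_case1, ndigits),
            round_half_up(a.surplus_case2, ndigits),
        ]
        for a in cols
    }
    return pd.DataFrame(
        data,
        index=[
            "people_needing_assistance",
            "people_under_10",
            "ability",
            "surplus_case1",
            "surplus_case2",
        ],
    )
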