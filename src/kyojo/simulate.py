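"""Multi-agent evacuation with mutual assistance, 1 second per step.

Residents evacuate to the nearest designated evacuation site over the road
network while a precomputed :class:`~kyojo.hazards.HazardTimeline` replays
building collapse, rubble blockage and fire spread around them.  Behaviour
follows six rules:

1. *Evacuation* — households evacuate together (residents will not leave
   without their families); children under 10 move with a parent.
2. *Waiting for rescue* — residents buried under a collapsed building wait;
   residents inside a burning building receive no neighbour help.
3. *Rescuing* — an evacuating household that detects a buried victim within
   the perception range diverts to the victim, unless it is escorting a
   child under 10 (those households prioritise evacuation).  The victim is
   freed once the summed expected rescue value of everyone gathered exceeds
   a threshold (default 1); if the threshold is not reached by the give-up
   time (default 5 min after the earthquake) rescuers resume evacuation.
4. *Needing evacuation support* — residents who cannot evacuate alone wait.
5. *Supporting* — mirrors rule 3 for assistance-needing residents.
6. *Awaiting public help* — residents in burning buildings, victims nobody
   could free, and residents cut off from every site wait for public
   rescue teams.

Residents do not fight fires, and they start evacuating at random times
within a start window rather than simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .hazards import HazardTimeline
from .rates import DEFAULT_ELIGIBILITY_AGE
from .town import World

__all__ = [
    "Scenario",
    "AgentRecord",
    "SimulationResult",
    "init_population",
    "choose_destination",
    "Simulation",
    "run",
    "run_batch",
]

# agent states
PRE_START = "pre_start"
EVACUATING = "evacuating"
WAITING_RESCUE = "waiting_rescue"
NEEDS_SUPPORT_WAITING = "needs_support_waiting"
GOING_TO_VICTIM = "going_to_victim"
RESCUING = "rescuing"
SUPPORTING = "supporting"
AWAITING_PUBLIC = "awaiting_public"
EVACUATED = "evacuated"
CASUALTY = "casualty"

TERMINAL = {AWAITING_PUBLIC, EVACUATED, CASUALTY}
WAITING = {WAITING_RESCUE, NEEDS_SUPPORT_WAITING}

#: Default share of residents who cannot evacuate alone, by age band.
DEFAULT_ASSIST_RATIOS = {"60": 0.1, "70": 0.2, "other": 0.05}


@dataclass
class Scenario:
    """Behavioural parameters of one simulation case.

    Defaults follow the base morning scenario: 1.5 m/s walking speed, 15 m
    (5-cell) perception range, rubble passable (people squeeze between
    heaps), fire always impassable, give-up 5 minutes after the quake.
    """

    speed: float = 1.5                       # m/s walking speed
    perception_range: float = 15.0           # m, multiple of 3 (grid cells)
    assist_ratios: dict = field(default_factory=lambda: dict(DEFAULT_ASSIST_RATIOS))
    children_10_15_assist: bool = False      # let 10-15 year olds take part
    rubble_blocking: str = "passable"        # or "impassable"
    rescue_give_up: float = 300.0            # s from earthquake
    rescue_threshold: float = 1.0            # summed expected value to free a victim
    start_window: tuple = (0.0, 120.0)       # s, uniform evacuation start draw
    time_of_day: str = "morning"             # or "evening" (commuters absent)
    mutual_assistance: bool = True
    give_up_from_start: bool = True          # clock runs from t=0, not rescue start
    eligibility_age: int = DEFAULT_ELIGIBILITY_AGE
    buried_probability: float = 1.0          # P(buried | building collapsed, present)
    count_rescued_in_success: bool = True

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.perception_range < 0 or self.perception_range % 3.0 != 0:
            raise ValueError("perception range must be a non-negative multiple of 3 m")
        if self.time_of_day not in ("morning", "evening"):
            raise ValueError(f"unknown time of day: {self.time_of_day!r}")

    def effective_eligibility_age(self) -> int:
        return 10 if self.children_10_15_assist else self.eligibility_age

    def assist_ratio_for_age(self, age: int) -> float:
        if 60 <= age < 70:
            return float(self.assist_ratios.get("60", 0.1))
        if age >= 70:
            return float(self.assist_ratios.get("70", 0.2))
        return float(self.assist_ratios.get("other", 0.05))


@dataclass
class AgentRecord:
    """Per-resident behavioural record; one resident = one agent."""

    resident_id: str
    building_id: str
    household_id: str
    age: int
    gender: str
    needs_assistance: bool
    ev: float                      # expected rescue value under the scenario
    state: str = PRE_START
    buried: bool = False
    required_assistance: bool = False
    received_assistance: bool = False
    start_time: float = 0.0
    end_time: float | None = None
    party_id: int | None = None


@dataclass
class _Party:
    """A household (or its present subset) moving as one unit."""

    id: int
    household_id: str
    building_id: str
    member_ids: list[str]
    start_time: float
    node: object                     # current / last network node
    escorting_under10: bool = False
    state: str = PRE_START
    edge: tuple | None = None        # (frm, to, offset m) while traversing
    route: list = field(default_factory=list)   # upcoming nodes
    target_victim: str | None = None
    x: float = 0.0
    y: float = 0.0


@dataclass
class SimulationResult:
    """Terminal outcomes and event log of one run."""

    agents: list[AgentRecord]
    events: list[dict]
    seed: int
    horizon: int

    @property
    def n_present(self) -> int:
        return len(self.agents)

    @property
    def n_evacuated(self) -> int:
        return sum(1 for a in self.agents if a.state == EVACUATED)

    @property
    def n_requiring_assistance(self) -> int:
        return sum(1 for a in self.agents if a.required_assistance)

    @property
    def n_receiving_assistance(self) -> int:
        return sum(1 for a in self.agents if a.received_assistance)

    def terminal_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.agents:
            out[a.state] = out.get(a.state, 0) + 1
        return out


def init_population(
    world: World,
    scenario: Scenario,
    seed: int | np.random.Generator | None = None,
    collapsed: set[str] | None = None,
    draw_assistance: bool | None = None,
) -> list[AgentRecord]:
    """Create the agent roster for one run.

    Morning scenarios place every resident at home; evening scenarios drop
    residents flagged as commuters.  Needs-assistance flags are taken from
    the roster when any are set there, otherwise drawn per the scenario's
    age-band ratios.  Residents of collapsed buildings are buried with the
    scenario's buried probability.
    """
    rng = np.random.default_rng(seed)
    residents = world.residents
    if not residents:
        raise ValueError("world has no residents")
    if scenario.time_of_day == "evening":
        residents = [r for r in residents if not r.commuter]
    if draw_assistance is None:
        draw_assistance = not any(r.needs_assistance for r in world.residents)
    elig = scenario.effective_eligibility_age()
    collapsed = collapsed or set()

    agents = []
    for r in residents:
        needs = r.needs_assistance
        if draw_assistance and not needs:
            needs = rng.random() < scenario.assist_ratio_for_age(r.age)
        buried = r.building_id in collapsed and rng.random() < scenario.buried_probability
        ev = 0.0
        if not needs:
            from .rates import expected_value

            ev = expected_value(r.age, r.gender, rescuer_eligible=r.age >= elig)
        agents.append(
            AgentRecord(
                resident_id=r.id,
                building_id=r.building_id,
                household_id=r.household_id or r.building_id,
                age=r.age,
                gender=r.gender,
                needs_assistance=needs,
                ev=ev,
                buried=buried,
            )
        )
    return agents


def choose_destination(
    node,
    sites: list,
    graph: nx.Graph,
    blocked: set[tuple] | None = None,
) -> tuple[object, list] | None:
    """Shortest route (by link length) from ``node`` to the nearest site.

    Blocked links are excluded.  Ties between equally near sites break
    towards the smallest site id.  Returns ``(site, path)`` with ``path``
    starting at ``node``, or None when no site is reachable.
    """
    blocked = blocked or set()
    g = graph.edge_subgraph(
        [e for e in graph.edges if tuple(sorted(e, key=repr)) not in blocked]
    ).copy()
    g.add_nodes_from(graph.nodes)
    if node not in g:
        return None
    dist, paths = nx.single_source_dijkstra(g, node, weight="length")
    best = None
    for s in sorted(sites, key=repr):
        if s in dist and (best is None or dist[s] < dist[best] - 1e-12):
            best = s
    if best is None:
        return None
    return best, paths[best]


class Simulation:
    """One evacuation run under a fixed hazard timeline."""

    def __init__(
        self,
        world: World,
        timeline: HazardTimeline,
        scenario: Scenario,
        seed: int = 0,
        agents: list[AgentRecord] | None = None,
    ):
        if not world.sites:
            raise ValueError("world has no evacuation sites")
        self.world = world
        self.timeline = timeline
        self.scenario = scenario
        self.seed = seed
        self.events: list[dict] = []
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        if agents is None:
            agents = init_population(world, scenario, rng, collapsed=timeline.collapsed)
        self.agents = {a.resident_id: a for a in agents}
        self._setup_parties(rng)
        self._blocked: set[tuple] = set()
        self._blocked_epoch = -1
        self._site_routes: dict = {}
        self._victim_routes: dict = {}
        self._fire_steps = timeline.fire_change_steps()

    # -- setup ---------------------------------------------------------------

    def _setup_parties(self, rng: np.random.Generator) -> None:
        households: dict[str, list[AgentRecord]] = {}
        for a in self.agents.values():
            households.setdefault(a.household_id, []).append(a)
        self.parties: list[_Party] = []
        self.victims: dict[str, AgentRecord] = {}
        lo, hi = self.scenario.start_window
        for hid in sorted(households):
            members = sorted(households[hid], key=lambda a: a.resident_id)
            start = float(rng.uniform(lo, hi))
            movers = []
            for a in members:
                a.start_time = start
                if a.buried:
                    a.state = WAITING_RESCUE
                    a.required_assistance = True
                    self.victims[a.resident_id] = a
                elif a.needs_assistance:
                    a.state = NEEDS_SUPPORT_WAITING
                    a.required_assistance = True
                    self.victims[a.resident_id] = a
                else:
                    movers.append(a)
            if not movers:
                continue
            b = self.world.buildings[movers[0].building_id]
            party = _Party(
                id=len(self.parties),
                household_id=hid,
                building_id=movers[0].building_id,
                member_ids=[a.resident_id for a in movers],
                start_time=start,
                node=self.world.building_node[movers[0].building_id],
                escorting_under10=any(a.age < 10 for a in movers),
                x=b.x,
                y=b.y,
            )
            for a in movers:
                a.party_id = party.id
            self.parties.append(party)

    # -- routing -------------------------------------------------------------

    def _update_blocked(self, t: int) -> None:
        blocked = self.timeline.blocked_links(t, self.scenario.rubble_blocking)
        if blocked != self._blocked:
            self._blocked = blocked
            self._blocked_epoch += 1
            self._site_routes = {}
            self._victim_routes = {}

    def _route_to_site(self, node) -> list | None:
        """Upcoming nodes towards the nearest reachable site (cached)."""
        if node not in self._site_routes:
            dest = choose_destination(node, self.world.sites, self.world.graph, self._blocked)
            self._site_routes[node] = None if dest is None else dest[1][1:]
        return self._site_routes[node]

    def _route_to_node(self, node, target) -> list | None:
        key = (target, node)
        if key not in self._victim_routes:
            g = self.world.graph.edge_subgraph(
                [
                    e
                    for e in self.world.graph.edges
                    if tuple(sorted(e, key=repr)) not in self._blocked
                ]
            ).copy()
            g.add_nodes_from(self.world.graph.nodes)
            try:
                path = nx.dijkstra_path(g, node, target, weight="length")
                self._victim_routes[key] = path[1:]
            except nx.NetworkXNoPath:
                self._victim_routes[key] = None
        return self._victim_routes[key]

    # -- stepping ------------------------------------------------------------

    def _set_party_state(self, party: _Party, state: str, t: float) -> None:
        party.state = state
        for rid in party.member_ids:
            a = self.agents[rid]
            a.state = state
            if state in TERMINAL:
                a.end_time = t

    def _victim_pos(self, v: AgentRecord) -> tuple[float, float]:
        b = self.world.buildings[v.building_id]
        return (b.x, b.y)

    def _party_ev(self, party: _Party) -> float:
        return sum(self.agents[rid].ev for rid in party.member_ids)

    def _resume_evacuation(self, party: _Party, t: float) -> None:
        party.target_victim = None
        party.route = []
        if party.edge is None:
            route = self._route_to_site(party.node)
            if route is None:
                self._set_party_state(party, AWAITING_PUBLIC, t)
                return
            party.route = list(route)
        self._set_party_state(party, EVACUATING, t)

    def step(self, t: int) -> None:
        """Advance the world from step t to t+1."""
        sc = self.scenario
        self._update_blocked(t)

        # fire overtakes waiting victims; burning buildings get no help
        for rid in list(self.victims):
            v = self.victims[rid]
            if v.state in WAITING and self.timeline.building_burning(v.building_id, t):
                v.state = CASUALTY
                v.end_time = t
                del self.victims[rid]
                self.events.append({"t": t, "event": "fire_casualty", "agent": rid})
        for party in self.parties:
            if party.state == PRE_START and self.timeline.building_burning(
                party.building_id, t
            ):
                self._set_party_state(party, AWAITING_PUBLIC, t)
                self.events.append(
                    {"t": t, "event": "burning_building", "party": party.id}
                )

        # give-up: after the deadline nobody attempts mutual assistance
        give_up = sc.rescue_give_up if sc.give_up_from_start else math.inf
        if t >= give_up:
            for party in self.parties:
                if party.state in (GOING_TO_VICTIM, RESCUING, SUPPORTING):
                    self.events.append(
                        {"t": t, "event": "rescue_abandoned", "party": party.id,
                         "victim": party.target_victim}
                    )
                    self._resume_evacuation(party, t)
            for rid in list(self.victims):
                v = self.victims[rid]
                if v.state in WAITING:
                    v.state = AWAITING_PUBLIC
                    v.end_time = t
                    del self.victims[rid]

        # households start evacuating
        for party in self.parties:
            if party.state == PRE_START and t >= party.start_time:
                route = self._route_to_site(party.node)
                if route is None:
                    self._set_party_state(party, AWAITING_PUBLIC, t)
                    self.events.append(
                        {"t": t, "event": "no_route", "party": party.id}
                    )
                else:
                    party.route = list(route)
                    self._set_party_state(party, EVACUATING, t)

        # perception: evacuating households divert to victims in range
        if (
            sc.mutual_assistance
            and sc.perception_range > 0
            and t < give_up
            and self.victims
        ):
            active = [v for v in self.victims.values() if v.state in WAITING]
            if active:
                vx = np.array([self._victim_pos(v)[0] for v in active])
                vy = np.array([self._victim_pos(v)[1] for v in active])
                for party in self.parties:
                    if party.state != EVACUATING or party.escorting_under10:
                        continue
                    if self._party_ev(party) <= 0:
                        continue
                    d = np.hypot(vx - party.x, vy - party.y)
                    order = np.argsort(d, kind="stable")
                    for i in order:
                        if d[i] > sc.perception_range:
                            break
                        v = active[int(i)]
                        if self.world.barriers.crosses(
                            (party.x, party.y), self._victim_pos(v)
                        ):
                            continue
                        party.target_victim = v.resident_id
                        party.route = []
                        self._set_party_state(party, GOING_TO_VICTIM, t)
                        self.events.append(
                            {"t": t, "event": "victim_detected", "party": party.id,
                             "victim": v.resident_id}
                        )
                        break

        # rescue resolution at gathered victims
        gathered: dict[str, list[_Party]] = {}
        for party in self.parties:
            if party.state in (RESCUING, SUPPORTING) and party.target_victim:
                gathered.setdefault(party.target_victim, []).append(party)
        for rid, parties in sorted(gathered.items()):
            v = self.victims.get(rid)
            if v is None or v.state not in WAITING:  # resolved meanwhile
                for party in parties:
                    self._resume_evacuation(party, t)
                continue
            total = sum(self._party_ev(p) for p in parties)
            if total > sc.rescue_threshold:
                was = v.state
                v.received_assistance = True
                del self.victims[rid]
                host = min(parties, key=lambda p: p.id)
                v.party_id = host.id
                host.member_ids.append(rid)
                v.ev = 0.0 if v.needs_assistance else v.ev
                self.events.append(
                    {
                        "t": t,
                        "event": "rescued" if was == WAITING_RESCUE else "supported",
                        "victim": rid,
                        "parties": [p.id for p in parties],
                        "total_ev": round(total, 4),
                    }
                )
                for party in parties:
                    self._resume_evacuation(party, t)

        # movement
        for party in self.parties:
            if party.state not in (EVACUATING, GOING_TO_VICTIM):
                continue
            self._move_party(party, t)

    def _move_party(self, party: _Party, t: float) -> None:
        g = self.world.graph
        budget = self.scenario.speed  # metres per 1 s step
        if party.state == GOING_TO_VICTIM:
            v = self.victims.get(party.target_victim)
            if v is None or v.state not in WAITING:
                self._resume_evacuation(party, t)
                if party.state != EVACUATING:
                    return
            elif party.edge is None and not party.route:
                target = self.world.building_node[v.building_id]
                if party.node == target:
                    kind = SUPPORTING if v.state == NEEDS_SUPPORT_WAITING else RESCUING
                    self._set_party_state(party, kind, t)
                    self.events.append(
                        {"t": t, "event": "rescuer_arrived", "party": party.id,
                         "victim": v.resident_id}
                    )
                    return
                route = self._route_to_node(party.node, target)
                if route is None:
                    self._resume_evacuation(party, t)
                    if party.state != EVACUATING:
                        return
                else:
                    party.route = list(route)

        while budget > 1e-9:
            if party.edge is not None:
                frm, to, off = party.edge
                key = tuple(sorted((frm, to), key=repr))
                length = g.edges[frm, to]["length"]
                if key in self._blocked:
                    # caught on a link that just became unsafe: back out
                    party.edge = (to, frm, length - off)
                    frm, to, off = party.edge
                step = min(budget, length - off)
                off += step
                budget -= step
                if off >= length - 1e-9:
                    party.node = to
                    party.edge = None
                else:
                    party.edge = (frm, to, off)
                continue
            # at a node
            if party.state == EVACUATING and party.node in self.world.sites:
                self._set_party_state(party, EVACUATED, t)
                self.events.append(
                    {"t": t, "event": "evacuated", "party": party.id,
                     "site": repr(party.node)}
                )
                break
            if not party.route:
                if party.state == EVACUATING:
                    route = self._route_to_site(party.node)
                    if route is None:
                        self._set_party_state(party, AWAITING_PUBLIC, t)
                        self.events.append(
                            {"t": t, "event": "no_route", "party": party.id}
                        )
                        break
                    if not route:
                        continue
                    party.route = list(route)
                else:
                    break  # reached the victim's node; handled next step
            nxt = party.route[0]
            key = tuple(sorted((party.node, nxt), key=repr))
            if key in self._blocked:
                # reroute around the blockage
                party.route = []
                if party.state == EVACUATING:
                    route = self._route_to_site(party.node)
                    if route is None:
                        self._set_party_state(party, AWAITING_PUBLIC, t)
                        self.events.append(
                            {"t": t, "event": "no_route", "party": party.id}
                        )
                        break
                    party.route = list(route)
                    self.events.append(
                        {"t": t, "event": "reroute", "party": party.id}
                    )
                    continue
                break
            party.route.pop(0)
            party.edge = (party.node, nxt, 0.0)

        # update planar position for perception
        if party.edge is not None:
            frm, to, off = party.edge
            x0, y0 = g.nodes[frm]["x"], g.nodes[frm]["y"]
            x1, y1 = g.nodes[to]["x"], g.nodes[to]["y"]
            f = off / max(g.edges[frm, to]["length"], 1e-9)
            party.x, party.y = x0 + f * (x1 - x0), y0 + f * (y1 - y0)
        else:
            party.x = g.nodes[party.node]["x"]
            party.y = g.nodes[party.node]["y"]

    def run(self, horizon: int | None = None) -> SimulationResult:
        horizon = horizon if horizon is not None else self.timeline.horizon
        if horizon > self.timeline.horizon:
            raise ValueError("horizon exceeds the precomputed hazard timeline")
        for t in range(horizon):
            self.step(t)
            if all(a.state in TERMINAL for a in self.agents.values()):
                break
        # whoever is still out there at the horizon waits for public help
        for a in self.agents.values():
            if a.state not in TERMINAL:
                a.state = AWAITING_PUBLIC
                a.end_time = float(horizon)
        return SimulationResult(
            agents=list(self.agents.values()),
            events=self.events,
            seed=self.seed,
            horizon=horizon,
        )


def run(
    world: World,
    timeline: HazardTimeline,
    scenario: Scenario,
    seed: int = 0,
    horizon: int | None = None,
) -> SimulationResult:
    """One evacuation run; deterministic given (world, timeline, scenario, seed)."""
    return Simulation(world, timeline, scenario, seed).run(horizon)


def run_batch(
    world: World,
    timeline: HazardTimeline,
    scenario: Scenario,
    n_runs: int = 10,
    master_seed: int = 0,
    horizon: int | None = None,
) -> list[SimulationResult]:
    """Independent repeated runs with per-run seeds spawned from a master seed."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_runs) % (2**31)
    return [
        run(world, timeline, scenario, int(s), horizon) for s in seeds
    ]
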