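# kyojo

Support tooling for district-level earthquake disaster-management planning
in Japan: quantify a neighbourhood's **mutual-assistance (kyojo) capability**
— the capacity of residents to rescue and help each other right after a
large earthquake — and simulate the evacuation that follows, so that
residents and local governments drafting a Community Disaster Management
Plan (CDMP) can see where the capability falls short and what closing the
gap would buy.

The package has two stages, mirroring how the planning process works:

1. **Capability evaluation (GIS stage).** Every resident gets an *expected
   rescue value* `Rr = strength x executing rate x activity rate`, a
   dimensionless score of rescue capacity tabulated by decade age band and
   gender from rescue activity observed after the 1995 Hanshin-Awaji
   earthquake (school children and people who themselves need assistance
   score 0). A building's value is the sum over its residents. The
   building-unit capability weights every neighbour within a range limit
   *X* (default 100 m) by distance,

       dw(D) = log10(1 + X) / (2 (log10(1 + D) + 1)),   0 <= D <= X,
       capability(i) = sum_j Rr_j dw(D_ij) / 5,

   skipping neighbours separated by an impassable barrier (river, railway,
   trunk road). For a district organised into small neighbourhood groups
   with strong internal ties, the group-unit variant drops the distance
   weighting and books, per group, `ability - (people needing assistance)`
   — the surplus or shortage of mutual-assistance capability, optionally
   exempting children under 10 (one adult can lead or carry a child).

2. **Evacuation simulation (multi-agent stage).** A precomputed hazard
   timeline — Bernoulli building collapse by structure/floors/year, rubble
   that blocks a road when its residual width drops under 0.6 m, and a
   wind-biased cellular-automaton fire on a 3 m grid — is replayed under a
   1-second-step agent simulation on the road network. Households evacuate
   together to the nearest evacuation site; buried and assistance-needing
   residents wait; an evacuating household that perceives a victim within
   the perception range diverts and joins the rescue, which succeeds once
   the gathered expected values sum above 1. Repeated runs are condensed
   into the standard summary: residents (a), successful evacuations (b),
   evacuation success rate (c), requiring (d) / receiving (e) mutual
   assistance, assistance success rate (f), plus map-form GeoJSON output.

A synthetic-town generator produces fully self-contained districts
(geometry, road network, sites, household roster) so everything runs
without any external GIS or census data.

## Worked example

```sh
kyojo synth --population 398 --assistance --seed 1 --out town
kyojo capability --buildings town/buildings.geojson --roster town/roster.csv \
    --mode group --out results
kyojo hazard --town town --seed 1 --horizon 900 --out results/timeline.json
kyojo simulate --town town --timeline results/timeline.json \
    --runs 10 --seed 1 --horizon 900 --out results
```

The group-unit evaluation prints

```
groups=15 ability=28.8771 surplus_case1=-7.1229 surplus_case2=-4.1229
```

— this district's 15 groups could fully assist about 29 people, but 36
need assistance, a district-wide shortage of 7.1 (4.1 if under-10s are
exempted); `results/group_accounts.csv` holds the per-group rows, where a
negative surplus flags a group that cannot cover its own assistance need.
The hazard and simulation stages print

```
timeline: 10 collapsed, 1 rubble-blocked links, 9 cells burned by horizon
batch of 10 runs: (a)=398 (b)=3298 (c)=82.86% (d)=730 (e)=90 (f)=12.33%
```

i.e. over ten repeated runs, on average 329.8 of 398 residents reached an
evacuation site (82.86 %), 730 person-runs needed rescue or evacuation
support, and 90 received it from neighbours (12.33 %). Re-running `simulate`
with `--perception 0` (nobody notices victims: mutual assistance absent)
drives (e) to exactly 0 — the difference is the head count that mutual
assistance saves. `results/map_run01.geojson` maps helped / unhelped /
awaiting-public counts per building for workshop display.

The same pipeline is available as a library: `synth.generate(TownSpec(...))`,
`capability.evaluate_buildings`, `hazards.build_timeline`,
`simulate.run_batch`, `metrics.summarize`.

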