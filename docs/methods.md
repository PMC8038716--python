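# Methods

## Expected rescue value

The per-person expected rescue value is `strength x executing rate x
activity rate` by decade age band (10, 20, ..., 70-and-over) and gender.
Strength is normalised to 1 for a man in his teens/twenties; the executing
rate is the observed share of residents who actually carried out rescue
work after the 1995 Hanshin-Awaji earthquake; the activity rate is the
gender split of those available in each band (the two genders' rates sum
to 1 in every band). Products are rounded half-up to 4 decimals and those
rounded values are the canonical per-person scores used everywhere else
(sums of buildings and groups therefore reproduce tabulated sums exactly).
Residents below the youngest band, school children below the eligibility
age (default 16: junior high school ends at 15; a toggle lowers it to 10
when 10–15-year-olds are allowed to take part), and residents who
themselves need assistance score 0.

## Distance weight and building capability

The distance decay adopted is

    dw(D) = log10(1 + X) / (2 (log10(1 + D) + 1))   for 0 <= D <= X, else 0.

The typeset source formula for this weight is ambiguous about the log base
and the placement of the constants; this reading reproduces the printed
token order as numerator/denominator and gives dw(0) ≈ 1.0022 at the
default X = 100 m, so an unweighted neighbour at distance zero contributes
its full expected value. It is strictly decreasing on [0, X] and truncates
to 0 beyond the range limit. Building capability is
`Σ_j Rr_j · dw(D_ij) / divisor` over in-range neighbours, divisor 5 by
default and exposed in config; the target's own residents are included at
D = 0 (flag to exclude). Distances are Euclidean between building centroids
in planar metres — inputs must already be projected. A neighbour is
excluded iff the straight segment between centroids intersects any barrier
feature; no detour routing is attempted at this stage, matching the
"cannot cross" semantics without requiring a pedestrian network.

## Group-unit surplus accounting

Where a district is organised in small neighbourhood groups with strong
ties, distance weighting is dropped: a group's ability is the plain sum of
member expected values (or a transcribed survey value), and the account
books `ability − n_assist` (case 1) and `ability − (n_assist − n_under10)`
(case 2). Surveyed under-10s are themselves counted as needing assistance,
so `n_under10` counts the under-10 subset of the assistance-needing — on a
roster without assistance flags the two cases coincide instead of
producing a spurious bonus.

## Hazard timeline

Damage is precomputed, then replayed read-only by the evacuation engine, so
the same disaster realisation can be re-simulated under different
behavioural scenarios. Space is a 3 m × 3 m grid (cells classified
open/building/road, half-open coverage rule so aligned footprints claim
each cell exactly once) coupled to the road network graph on which agents
move; road cells back-reference their link.

* **Collapse** — one Bernoulli draw per building from a first-match lookup
  on (structure, floors, construction year). The covariates are the
  model's; the shipped probabilities are package defaults (wooden pre-1981
  highest at 0.30–0.40, RC post-2000 lowest at 0.01, monotone in age and
  wood fraction) and must be replaced with study-specific fragility values
  for real planning work.
* **Rubble** — a collapsed building intrudes onto its nearest road link by
  `min(width, k · 0.5 · floors · 3 m)` (k configurable, default 1); the
  link is impassable when the residual width is strictly below 0.6 m. In
  the base scenario rubble is *passable* (residents squeeze between
  heaps); the impassable mode applies the threshold.
* **Fire** — a stochastic cellular automaton on building cells only: each
  burning cell ignites each unburned 8-neighbour building cell per second
  with probability `p_base · max(0, 1 + bias · wind_speed · cos θ)`
  clipped to 1, θ the angle between the spread direction and downwind
  (wind direction named by the compass point it blows *from*); cells burn
  out after a fixed duration (default 300 s). Defaults p_base 0.02, bias
  0.12 /(m/s), wind 5 m/s from the northwest, one origin drawn uniformly
  among building cells. The referenced urban-fire models behind the
  original tool are not public; this automaton preserves their interface
  (wind speed/direction, random origins) with all constants in config.
* A link counts as fire-blocked from the first step fire reaches any cell
  within one cell of its road cells; fire blockage is always on.

Collapse draws, origin draws and spread draws use three independent
streams spawned from the master seed, so toggling one hazard leaves the
others' realisations unchanged. The timeline serialises to JSON and
round-trips exactly; node ids are strings.

## Evacuation simulation

One step is one second. Households move as single parties (residents do
not leave without their families; a child under 10 is always co-located
with the household), at the scenario walking speed (1.5 m/s morning,
1.0 m/s evening defaults), continuously along links — the grid is used
only for hazard state. Start times are drawn uniformly per household over
a start window (default 0–120 s; the parameter is named in the source
material but no window is printed). Routing is shortest-path by link
length to the nearest evacuation site, ties toward the smallest site id;
the currently blocked link set is global knowledge, and routes are
recomputed whenever it changes (a party caught mid-link when fire arrives
backs out to the node it came from). A party with no open route to any
site waits for public help.

Victims are residents of collapsed buildings (buried with probability 1
when present, configurable) and assistance-needing residents (flags from
the roster when present, otherwise drawn per age band: 0.05 under 60, 0.1
for 60–69, 0.2 for 70+). An evacuating party — unless escorting a child
under 10, who get evacuation priority — that perceives a victim within the
perception range (straight-line, barrier-occluded) diverts to the victim;
a rescue resolves the moment the summed expected values of everyone
gathered exceeds the threshold (default 1), the victim then evacuating
with the first-arrived party. The give-up clock runs from the earthquake
(t = 0): at 300 s all unresolved attempts are abandoned, rescuers restart
evacuation, and still-waiting victims transition to awaiting-public (a
per-attempt clock is available as a flag). Residents in a building that is
burning before they leave get no neighbour help and await public support;
a waiting victim whose building ignites later is recorded as a casualty.
Residents never fight fires. At the horizon every non-terminal agent is
classified awaiting-public, so terminal counts always conserve the
population.

Repeated runs draw per-run seeds from a master seed; the hazard timeline
is shared across the batch (the disaster is fixed; behavioural randomness
— start times, assistance draws — varies).

## Summary statistics

(c) = ((b)/n_runs)/(a) × 100 and (f) = (e)/(d) × 100, reported half-up at
2 decimals; (f) is undefined (not 0) when nobody required assistance.
Whether rescued-then-evacuated victims count in (b) is configurable
(default: they count). Per-run tables report counts, total, and the
average at 1 decimal.

## Synthetic districts

The generator emulates a small ageing Japanese residential district: a
rectangular street grid (default 3 × 5 blocks of 60 m, 6 m roads),
9 m × 9 m buildings fronting the streets about 8.5 m from the centreline
(so that 9 m and 15 m perception ranges are meaningfully different),
evacuation sites at opposite corners, 15 small groups partitioning the
blocks, and a household roster drawn from a child/working-age/elderly
pyramid (0.12/0.55/0.33) with half the working-age adults commuting away
— a default population of 398 leaves roughly 300 present in the evening.
Structure mix is 70 % wood and 35 % of stock pre-dates the 1981 seismic
code. Everything is reproducible bit-for-bit under the spec seed.

What the generator does *not* emulate: real parcel geometry, non-grid
street patterns, multi-unit housing, daytime visitor populations, and
building-level correlation between age and occupancy. Passing tests on
these districts therefore demonstrates the mechanics and invariants of
the models, not calibrated absolute casualty rates for any real place —
the published absolute rates for the demonstration district depend on its
unpublished GIS and roster data and are deliberately not targeted; the
suite instead pins the structural properties (conservation, zero
assistance at zero perception, monotone benefit of a wider perception
range, wind-direction bias, determinism under seed).

A separate 15-group fixture reproduces a published survey's per-group
counts of assistance-needing members and under-10s exactly; the groups'
ability values depend on member ages the survey does not publish, so
abilities are supplied as transcribed inputs when reproducing that table.

## Numerical and design choices

* Rounding for all reported tables is decimal round-half-up (the 70+ male
  expected value 0.075465 prints as 0.0755; banker's rounding would not).
* The range condition typeset as "(0 ≥ j ≥ X)" is read as 0 ≤ D ≤ X;
  D = X is in range.
* Buildings attach to their nearest network node (evacuation starts there)
  and nearest link (rubble falls there).
* Simulation problem sizes in the test suite and acceptance script — a
  398-resident district, 600–900 s horizons, batches of 10–50 runs — were
  chosen as the smallest sizes at which every modelled effect (rescue
  gathering, fire blockage, perception-range response) is reliably
  expressed.
* Known limitations: no congestion or panic dynamics, no public rescue
  teams, instantaneous rescue completion at threshold, global blockage
  knowledge rather than per-agent discovery, and victims are perceived at
  their building centroid.
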