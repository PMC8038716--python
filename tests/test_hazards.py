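"""Grid rasterization, collapse draws, rubble widths, fire spread, timeline."""

import numpy as np
import pytest

from kyojo import hazards
from kyojo.hazards import (
    BUILDING,
    ROAD,
    CollapseConfig,
    CollapseRule,
    FireParams,
    FireState,
    build_timeline,
    generate_rubble,
    ignite,
    rasterize,
    sample_collapses,
    step_fire,
)
from kyojo.town import Building, World

from conftest import line_world, square

# ---------------------------------------------------------------- rasterize


def test_nine_by_nine_building_covers_nine_cells(small_town, small_field):
    # synthetic footprints are 9 m x 9 m -> exactly 3 x 3 cells of 3 m
    bid = next(iter(small_town.buildings))
    assert small_field.building_cells(bid).size == 9


def test_building_first_precedence(small_field):
    # no cell is both: road cells were assigned only where no building claims
    assert ((small_field.cls == BUILDING) & (small_field.building_index < 0)).sum() == 0
    for cells in small_field.link_cells.values():
        assert (small_field.cls.ravel()[cells] == ROAD).all()


def test_world_without_buildings_rasterizes_open_and_road():
    import networkx as nx

    g = nx.Graph()
    g.add_node("a", x=0.0, y=0.0)
    g.add_node("b", x=30.0, y=0.0)
    g.add_edge("a", "b", length=30.0, width=6.0)
    field = rasterize(World([], g))
    assert (field.cls == BUILDING).sum() == 0
    assert (field.cls == ROAD).sum() > 0


def test_building_outside_extent_rejected(small_town):
    w = line_world()
    w.buildings["b0"].footprint = square(200.0, 200.0)
    with pytest.raises(ValueError, match="outside"):
        rasterize(w, extent=(-10.0, -10.0, 100.0, 30.0))


# ---------------------------------------------------------------- collapse


def _stock(n, structure="wood", year=1970):
    return [Building(id=f"b{i}", x=0, y=0, structure=structure, year_built=year)
            for i in range(n)]


def test_collapse_degenerate_probabilities():
    all_p0 = CollapseConfig([CollapseRule(None, None, None, 0.0)])
    all_p1 = CollapseConfig([CollapseRule(None, None, None, 1.0)])
    stock = _stock(50)
    assert sample_collapses(stock, all_p0, rng=1) == set()
    assert sample_collapses(stock, all_p1, rng=1) == {b.id for b in stock}


def test_collapse_fraction_binomial():
    cfg = CollapseConfig([CollapseRule(None, None, None, 0.3)])
    n = 10_000
    frac = len(sample_collapses(_stock(n), cfg, rng=7)) / n
    sigma = np.sqrt(0.3 * 0.7 / n)
    assert abs(frac - 0.3) < 3 * sigma


def test_unmatched_building_is_a_config_error():
    cfg = CollapseConfig([CollapseRule("rc", None, None, 0.1)])
    with pytest.raises(KeyError, match="no collapse rule"):
        sample_collapses(_stock(1, structure="wood"), cfg, rng=0)


def test_default_config_monotone_in_age_and_wood():
    cfg = hazards.DEFAULT_COLLAPSE_CONFIG
    old_wood = Building(id="a", x=0, y=0, structure="wood", year_built=1970)
    new_wood = Building(id="b", x=0, y=0, structure="wood", year_built=2010)
    old_rc = Building(id="c", x=0, y=0, structure="rc", year_built=1970)
    assert cfg.probability(old_wood) > cfg.probability(new_wood)
    assert cfg.probability(old_wood) > cfg.probability(old_rc)


# ---------------------------------------------------------------- rubble


def test_rubble_residual_width_threshold():
    b2 = Building(id="b", x=0, y=0, floors=2)  # intrusion 0.5*2*3 = 3 m
    residual, blocked = generate_rubble(b2, ("u", "v"), 4.0, intrusion_factor=7 / 6)
    assert residual == pytest.approx(0.5)
    assert blocked  # 0.5 m < 0.6 m

    residual, blocked = generate_rubble(b2, ("u", "v"), 4.0, intrusion_factor=0.0)
    assert residual == 4.0 and not blocked

    # residual exactly 0.6 m stays passable (strict "under 0.6 m")
    residual, blocked = generate_rubble(b2, ("u", "v"), 3.6, intrusion_factor=1.0)
    assert residual == pytest.approx(0.6) and not blocked


# ---------------------------------------------------------------- fire


def test_ignite_degenerate_and_deterministic(small_field):
    assert ignite(small_field, 0, rng=1).size == 0
    a = ignite(small_field, 3, rng=9)
    b = ignite(small_field, 3, rng=9)
    assert (a == b).all()
    assert (small_field.cls.ravel()[a] == BUILDING).all()
    with pytest.raises(ValueError):
        ignite(small_field, -1)
    with pytest.raises(ValueError, match="exceeds"):
        ignite(small_field, 10**7)


def _burn(field, params, steps, seed=0):
    rng = np.random.default_rng(seed)
    state = FireState.initial(field.shape)
    origin = ignite(field, 1, rng=123)
    rr, cc = np.divmod(origin, field.n_cols)
    state.status[rr, cc] = hazards.BURNING
    state.ignition_t[rr, cc] = 0
    for _ in range(steps):
        step_fire(state, field, params, rng)
    return state, (int(rr[0]), int(cc[0]))


def test_fire_zero_probability_never_spreads(small_field):
    state, _ = _burn(small_field, FireParams(p_base=0.0, burn_duration=10), 30)
    assert (state.ignition_t >= 0).sum() == 1  # only the origin
    assert (state.status == hazards.BURNED).sum() == 1  # and it burnt out


def test_fire_confined_to_building_cells(small_field):
    state, _ = _burn(small_field, FireParams(p_base=0.5, wind_speed=0.0), 120)
    burned = state.ignition_t.ravel() >= 0
    assert (small_field.cls.ravel()[burned] == BUILDING).all()
    assert (state.ignition_t >= 0).sum() > 1  # it did spread


def _dense_field():
    """One solid block of building cells, for isotropy/wind checks."""
    import networkx as nx

    g = nx.Graph()
    g.add_node("a", x=0.0, y=0.0)
    g.add_node("b", x=3.0, y=0.0)
    g.add_edge("a", "b", length=3.0, width=1.0)
    b = Building(id="big", x=90.0, y=90.0, footprint=square(90.0, 90.0, half=87.0))
    return rasterize(World([b], g), margin=3.0)


def _mean_spread(params, n_rep=40, steps=40):
    """Mean burned-cell displacement (dx, dy) from a centre ignition."""
    field = _dense_field()
    r0, c0 = field.cell_of(90.0, 90.0)
    disp = []
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        state = FireState.initial(field.shape)
        state.status[r0, c0] = hazards.BURNING
        state.ignition_t[r0, c0] = 0
        for _ in range(steps):
            step_fire(state, field, params, rng)
        rr, cc = np.nonzero(state.ignition_t >= 0)
        disp.append(((cc - c0).mean(), (rr - r0).mean()))
    return np.array(disp).mean(axis=0)


def test_fire_no_wind_spreads_symmetrically():
    dx, dy = _mean_spread(FireParams(wind_speed=0.0, p_base=0.06, burn_duration=999))
    assert abs(dx) < 1.0 and abs(dy) < 1.0  # centroid stays near the origin


def test_fire_wind_pushes_downwind():
    # wind from the northwest pushes fire east (+x) and south (-y)
    dx, dy = _mean_spread(
        FireParams(wind_speed=5.0, wind_direction="nw", p_base=0.06, burn_duration=999)
    )
    assert dx > 1.0 and dy < -1.0


def test_burned_set_monotone(small_town, small_field):
    tl = build_timeline(small_town, small_field, horizon=300, seed=3)
    counts = [tl.burned_cells(t).size for t in range(0, 300, 10)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------- timeline


def test_timeline_deterministic_serialization(small_town, small_field):
    a = build_timeline(small_town, small_field, horizon=200, seed=11).to_json()
    b = build_timeline(small_town, small_field, horizon=200, seed=11).to_json()
    assert a == b
    c = build_timeline(small_town, small_field, horizon=200, seed=12).to_json()
    assert a != c


def test_timeline_roundtrip(small_town, small_field):
    tl = build_timeline(small_town, small_field, horizon=200, seed=11)
    back = hazards.HazardTimeline.from_json(tl.to_json())
    assert back.to_json() == tl.to_json()


def test_blocked_iff_residual_below_threshold(small_town, small_field):
    tl = build_timeline(small_town, small_field, horizon=60, seed=5)
    blocked = tl.blocked_links(0, rubble_blocking="impassable")
    fire_blocked = tl.blocked_links(0, rubble_blocking="passable")
    for e, residual in tl.link_residual.items():
        rubble_blocked = e in blocked and e not in fire_blocked
        assert rubble_blocked == (residual < hazards.RUBBLE_PASS_WIDTH)


def test_passable_mode_ignores_rubble(small_town, small_field):
    tl = build_timeline(
        small_town, small_field, horizon=60, seed=5,
        fire_params=FireParams(n_origins=0),
    )
    assert tl.blocked_links(59, rubble_blocking="passable") == set()


def test_zero_hazard_timeline_is_quiet(quiet_timeline):
    assert quiet_timeline.collapsed == set()
    assert quiet_timeline.blocked_links(899, "impassable") == set()
    assert (quiet_timeline.ignition_step >= 0).sum() == 0


def test_disabling_fire_leaves_collapse_draws_unchanged(small_town, small_field):
    with_fire = build_timeline(small_town, small_field, horizon=60, seed=21)
    no_fire = build_timeline(
        small_town, small_field, horizon=60, seed=21,
        fire_params=FireParams(n_origins=0),
    )
    assert with_fire.collapsed == no_fire.collapsed
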