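"""Timetable routing: footpaths, the time-expanded graph, minimum-duration
journeys vs exhaustive enumeration, round trips and their invariants."""

import dataclasses

import numpy as np
import pytest

from ruralaccess import (
    NO_CONNECTION,
    OK,
    AccessParams,
    District,
    EventGraph,
    Practice,
    RideLeg,
    Timetable,
    TransitRouter,
    WaitLeg,
    WalkLeg,
    candidate_access_stops,
    footpaths,
    generate_region,
    minimum_duration_leg,
    transit_accessibility,
    walking_time,
)
from conftest import (
    SMALL_CONFIG,
    brute_force_min_leg,
    fps_from_parts,
    line_network,
    make_bundle,
    random_timetable,
    simple_trip,
)

PARAMS = AccessParams()

H = 3600


# ---------------------------------------------------------------------------
# Walking-time conversion
# ---------------------------------------------------------------------------


def test_walking_time_conversions():
    # 1 m/s corresponds to 3.6 km/h: 1 km in 16.67 min
    assert walking_time(1000.0, 3.6) == pytest.approx(16.6667, abs=1e-3)
    # elderly walking speed 1.8 km/h: twice as long
    assert walking_time(1000.0, 1.8) == pytest.approx(33.3333, abs=1e-3)
    assert walking_time(0.0, 1.8) == 0.0


def test_walking_time_rejects_bad_speed():
    with pytest.raises(ValueError):
        walking_time(100.0, 0.0)
    with pytest.raises(ValueError):
        walking_time(-5.0, 1.8)


# ---------------------------------------------------------------------------
# Footpaths
# ---------------------------------------------------------------------------


def test_footpaths_respect_caps_and_measure_street_distance():
    net = line_network(n_nodes=11, spacing_m=300.0)  # 0..3000 m
    origins = {"O": (0.0, 0.0)}
    stops = {"near": (900.0, 0.0), "far": (1200.0, 0.0)}
    practices = {"P": (300.0, 0.0)}
    fps = footpaths(net, origins, stops, practices, PARAMS)
    # 900 m straight street: in cap, exact distance, 30 min at 1.8 km/h
    assert fps.origin_stop[("O", "near")] == pytest.approx(900.0)
    assert walking_time(fps.origin_stop[("O", "near")], 1.8) == \
        pytest.approx(30.0)
    # 1200 m from centroid: beyond the 1000 m cap, pair absent
    assert ("O", "far") not in fps.origin_stop
    # stop->practice cap is 500 m: near stop is 600 m from the practice
    assert ("near", "P") not in fps.stop_practice
    assert fps.origin_practice[("O", "P")] == pytest.approx(300.0)


def test_footpaths_match_all_pairs_enumeration():
    rng = np.random.default_rng(2)
    net = line_network(n_nodes=9, spacing_m=150.0)
    origins = {f"O{i}": (float(rng.integers(0, 1200)), 0.0) for i in range(3)}
    stops = {f"S{i}": net.nodes[int(rng.integers(0, 9))] for i in range(4)}
    fps = footpaths(net, origins, stops, {}, PARAMS)
    # brute force: on a straight line the street distance between snapped
    # nodes is |x_a - x_b|; add each point's offset to its nearest node
    xs = sorted(x for x, _ in net.nodes.values())

    def snap(x):
        node_x = min(xs, key=lambda v: abs(v - x))
        return node_x, abs(node_x - x)

    for oid, (ox, _) in origins.items():
        onode, ooff = snap(ox)
        for sid, (sx, _) in stops.items():
            snode, soff = snap(sx)
            d = ooff + abs(onode - snode) + soff
            if d <= PARAMS.max_walk_origin_to_stop_m:
                assert fps.origin_stop[(oid, sid)] == pytest.approx(d)
            else:
                assert (oid, sid) not in fps.origin_stop


def test_stop_stop_footpaths_symmetric():
    net = line_network(n_nodes=11, spacing_m=100.0)
    stops = {"A": (0.0, 0.0), "B": (200.0, 0.0), "C": (600.0, 0.0)}
    fps = footpaths(net, {}, stops, {}, PARAMS)
    assert fps.stop_stop[("A", "B")] == fps.stop_stop[("B", "A")] == \
        pytest.approx(200.0)
    assert ("A", "C") not in fps.stop_stop  # 600 m > 250 m transfer cap


@pytest.mark.parametrize("n_in_cap,expect", [(5, 3), (2, 2), (0, 0)])
def test_candidate_access_stops_k_nearest(n_in_cap, expect):
    fps = fps_from_parts(access=[(f"S{i}", 100.0 * (i + 1))
                                 for i in range(n_in_cap)])
    got = candidate_access_stops(fps, "O", PARAMS)
    assert len(got) == expect
    assert got == sorted(got, key=lambda p: p[1])[:3]


# ---------------------------------------------------------------------------
# Event graph structure
# ---------------------------------------------------------------------------


def test_single_trip_gives_two_ride_edges():
    tt = Timetable(
        stops={"A": (0, 0), "B": (500, 0), "C": (1000, 0)},
        trips=[simple_trip("T", [("A", 8 * H), ("B", 8 * H + 300),
                                 ("C", 8 * H + 600)])])
    g = EventGraph(tt, fps_from_parts(), PARAMS)
    assert g.n_edges("ride") == 2


def test_transfer_edges_only_within_cap():
    tt = Timetable(
        stops={"A": (0, 0), "B": (200, 0), "C": (500, 0)},
        trips=[simple_trip("T1", [("A", 8 * H), ("C", 8 * H + 600)]),
               simple_trip("T2", [("B", 9 * H), ("C", 9 * H + 600)])])
    near = fps_from_parts(stop_stop={("A", "B"): 200.0, ("B", "A"): 200.0})
    g = EventGraph(tt, near, PARAMS)
    assert g.n_edges("transfer") > 0
    far = fps_from_parts()  # 300 m pair would be absent from the FootpathSet
    g2 = EventGraph(tt, far, PARAMS)
    assert g2.n_edges("transfer") == 0


def test_wait_edges_chain_time_points_in_order():
    tt = Timetable(
        stops={"A": (0, 0), "B": (500, 0)},
        trips=[simple_trip("T1", [("A", 8 * H), ("B", 8 * H + 300)]),
               simple_trip("T2", [("A", 9 * H), ("B", 9 * H + 300)]),
               simple_trip("T3", [("A", 10 * H), ("B", 10 * H + 300)])])
    g = EventGraph(tt, fps_from_parts(), PARAMS)
    # at stop A: 8:00 -> 9:00 -> 10:00
    assert g.n_edges("wait") == 2 + 2  # at A and at B
    times = [t for t, _ in g.stop_points["A"]]
    assert times == sorted(times)


# ---------------------------------------------------------------------------
# Minimum-duration journeys
# ---------------------------------------------------------------------------


def _leg(tt, access, egress, stop_stop=None, window=(7 * H, 11 * H),
         params=PARAMS):
    fps = fps_from_parts(access=access, egress=egress, stop_stop=stop_stop)
    g = EventGraph(tt, fps, params)
    return minimum_duration_leg(g, list(access), list(egress), window[0],
                                window[1], params)


def test_single_feasible_journey_timed_to_the_bus():
    # bus 10:00 -> 10:30; 10-minute walks on both sides (300 m at 1.8 km/h)
    tt = Timetable(stops={"A": (0, 0), "B": (5000, 0)},
                   trips=[simple_trip("T", [("A", 10 * H), ("B", 10 * H + 1800)])])
    leg = _leg(tt, access=[("A", 300.0)], egress=[("B", 300.0)])
    assert leg is not None
    assert leg.duration_s == pytest.approx(50 * 60)
    assert leg.departure_s == pytest.approx(10 * H - 600)  # 09:50
    assert leg.arrival_s == pytest.approx(10 * H + 1800 + 600)


def test_shorter_duration_wins_even_if_it_departs_later():
    # slow early bus (60 min in vehicle) vs tight later bus (20 min)
    tt = Timetable(
        stops={"A": (0, 0), "B": (5000, 0)},
        trips=[simple_trip("slow", [("A", 8 * H), ("B", 9 * H)]),
               simple_trip("fast", [("A", 10 * H), ("B", 10 * H + 1200)])])
    leg = _leg(tt, access=[("A", 90.0)], egress=[("B", 90.0)])
    assert leg.duration_s == pytest.approx(1200 + 2 * 180)
    assert leg.departure_s == pytest.approx(10 * H - 180)


def test_infeasible_window_returns_none():
    tt = Timetable(stops={"A": (0, 0), "B": (5000, 0)},
                   trips=[simple_trip("T", [("A", 12 * H), ("B", 13 * H)])])
    leg = _leg(tt, access=[("A", 100.0)], egress=[("B", 100.0)],
               window=(7 * H, 11 * H))
    assert leg is None


@pytest.mark.parametrize("seed", range(40))
def test_min_duration_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    tt, access, egress, stop_stop = random_timetable(rng)
    fps = fps_from_parts(access=access, egress=egress, stop_stop=stop_stop)
    g = EventGraph(tt, fps, PARAMS)
    leg = minimum_duration_leg(g, access, egress, 7 * H, 16 * H, PARAMS)
    oracle = brute_force_min_leg(tt, access, egress, stop_stop,
                                 7 * H, 16 * H, PARAMS)
    if oracle is None:
        assert leg is None
    else:
        assert leg is not None
        assert leg.duration_s == pytest.approx(oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# Round trips on hand-built bundles
# ---------------------------------------------------------------------------


def _two_stop_bundle(out_dep=9 * H, out_min=30, back_dep=13 * H,
                     back_min=30, d_origin=300.0, d_practice=300.0):
    """Straight street; district at x=0, practice at x=3000; one stop at
    each end; one outbound and one return trip."""
    net = line_network(n_nodes=11, spacing_m=300.0)
    tt = Timetable(
        stops={"SA": (d_origin, 0.0), "SB": (3000.0 - d_practice, 0.0)},
        trips=[simple_trip("out", [("SA", out_dep),
                                   ("SB", out_dep + out_min * 60)]),
               simple_trip("back", [("SB", back_dep),
                                    ("SA", back_dep + back_min * 60)])])
    district = District("D", (0.0, 0.0), 100)
    practice = Practice("P", "GP", (3000.0, 0.0))
    return make_bundle(net, [district], [practice], tt)


def test_symmetric_timetable_gives_equal_legs():
    bundle = _two_stop_bundle()
    router = TransitRouter(bundle, dataclasses.replace(
        PARAMS, allow_direct_walk=False))
    rt = router.round_trip("D", "P")
    assert rt.status == OK
    assert rt.outbound_min == pytest.approx(rt.return_min)
    assert rt.total_min == pytest.approx(rt.outbound_min + rt.return_min)


def test_no_service_after_noon_means_no_connection():
    bundle = _two_stop_bundle(back_dep=11 * H + 1800)  # return before 12:00
    router = TransitRouter(bundle, dataclasses.replace(
        PARAMS, allow_direct_walk=False))
    rt = router.round_trip("D", "P")
    assert rt.status == NO_CONNECTION


def test_return_must_not_arrive_after_midnight():
    bundle = _two_stop_bundle(back_dep=23 * H + 3000, back_min=30)
    router = TransitRouter(bundle, dataclasses.replace(
        PARAMS, allow_direct_walk=False))
    assert router.round_trip("D", "P").status == NO_CONNECTION


def test_direct_walk_fallback_within_cap():
    # practice 900 m from the centroid, no transit at all
    net = line_network(n_nodes=11, spacing_m=300.0)
    district = District("D", (0.0, 0.0), 100)
    practice = Practice("P", "GP", (900.0, 0.0))
    bundle = make_bundle(net, [district], [practice],
                         Timetable(stops={}, trips=[]))
    router = TransitRouter(bundle, PARAMS)
    rt = router.round_trip("D", "P")
    assert rt.status == OK
    assert rt.total_min == pytest.approx(2 * walking_time(900.0, 1.8))
    strict = TransitRouter(bundle, dataclasses.replace(
        PARAMS, allow_direct_walk=False))
    assert strict.round_trip("D", "P").status == NO_CONNECTION


def test_nearest_reachable_takes_minimum_total():
    net = line_network(n_nodes=21, spacing_m=300.0)
    tt = Timetable(
        stops={"SA": (0.0, 0.0), "S1": (3000.0, 0.0), "S2": (6000.0, 0.0)},
        trips=[simple_trip("o", [("SA", 9 * H), ("S1", 9 * H + 2400),
                                 ("S2", 9 * H + 3600)]),
               simple_trip("b", [("S2", 13 * H), ("S1", 13 * H + 1200),
                                 ("SA", 13 * H + 3600)])])
    district = District("D", (0.0, 0.0), 10)
    near = Practice("near", "GP", (3000.0, 0.0))
    far = Practice("far", "GP", (6000.0, 0.0))
    bundle = make_bundle(net, [district], [near, far], tt)
    router = TransitRouter(bundle, dataclasses.replace(
        PARAMS, allow_direct_walk=False))
    rt = router.nearest_reachable_practice("D", "GP")
    assert rt.status == OK
    assert rt.practice_id == "near"
    totals = {p: router.round_trip("D", p).total_min for p in ("near", "far")}
    assert rt.total_min == min(totals.values())


def test_all_infeasible_gives_no_connection():
    bundle = _two_stop_bundle()
    router = TransitRouter(bundle, dataclasses.replace(
        PARAMS, allow_direct_walk=False, max_walk_origin_to_stop_m=10.0,
        max_walk_origin_to_practice_m=10.0))
    rt = router.nearest_reachable_practice("D", "GP")
    assert rt.status == NO_CONNECTION
    assert rt.practice_id is None


# ---------------------------------------------------------------------------
# Invariants on generated regions
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_pt(small_region):
    return transit_accessibility(small_region)


def test_adding_a_trip_never_worsens_accessibility(small_region, small_pt):
    # duplicate every school trip shifted by 20 min: strictly more service
    tt = small_region.timetable
    extra = []
    for t in tt.trips:
        if t.service != "school":
            continue
        shifted = tuple(dataclasses.replace(
            ev, arrival_s=ev.arrival_s + 1200,
            departure_s=ev.departure_s + 1200) for ev in t.events)
        if shifted[-1].arrival_s <= 24 * H:
            extra.append(dataclasses.replace(
                t, trip_id=t.trip_id + "x", events=shifted))
    richer = dataclasses.replace(small_region,
                                 timetable=Timetable(stops=dict(tt.stops),
                                                     trips=tt.trips + extra))
    pt2 = transit_accessibility(richer)
    merged = small_pt.merge(pt2, on=["district_id", "group"],
                            suffixes=("_base", "_more"))
    for row in merged.itertuples():
        if row.status_base == OK:
            assert row.status_more == OK
            assert row.total_min_more <= row.total_min_base + 1e-9


def test_shrinking_caps_never_improves(small_region, small_pt):
    tight = dataclasses.replace(PARAMS, max_walk_origin_to_stop_m=500.0,
                                max_walk_stop_to_practice_m=250.0,
                                max_walk_transfer_m=100.0,
                                max_walk_origin_to_practice_m=500.0)
    pt2 = transit_accessibility(small_region, tight)
    merged = small_pt.merge(pt2, on=["district_id", "group"],
                            suffixes=("_base", "_tight"))
    for row in merged.itertuples():
        if row.status_tight == OK:
            assert row.status_base == OK
            assert row.total_min_tight >= row.total_min_base - 1e-9
    n_nc_base = (merged.status_base == NO_CONNECTION).sum()
    n_nc_tight = (merged.status_tight == NO_CONNECTION).sum()
    assert n_nc_tight >= n_nc_base


def test_no_connection_count_nonincreasing_in_origin_walk_cap(small_region):
    caps = [200.0, 600.0, 1000.0]
    counts = []
    for cap in caps:
        params = dataclasses.replace(PARAMS, max_walk_origin_to_stop_m=cap)
        pt = transit_accessibility(small_region, params, groups=["GP"])
        counts.append(int((pt.status == NO_CONNECTION).sum()))
    assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize("headway_min", [15, 30, 60, 120])
def test_straight_route_duration_bounded_by_headway(headway_min):
    """On one straight line with headway h and in-vehicle time v, the best
    duration lies in [v + walks, v + walks + h)."""
    net = line_network(n_nodes=11, spacing_m=300.0)
    v_s = 1800
    trips = []
    k = 0
    t0 = 7 * H
    while t0 + v_s <= 11 * H:
        trips.append(simple_trip(f"T{k}", [("SA", t0), ("SB", t0 + v_s)]))
        t0 += headway_min * 60
        k += 1
    tt = Timetable(stops={"SA": (300.0, 0.0), "SB": (2700.0, 0.0)},
                   trips=trips)
    district = District("D", (0.0, 0.0), 10)
    practice = Practice("P", "GP", (3000.0, 0.0))
    bundle = make_bundle(net, [district], [practice], tt)
    router = TransitRouter(bundle, dataclasses.replace(
        PARAMS, allow_direct_walk=False))
    j = router.min_duration_journey("D", "P")
    walks_s = 2 * 3.6 * 300.0 / 1.8
    assert v_s + walks_s <= j.duration_min * 60 < v_s + walks_s \
        + headway_min * 60


def test_returned_journeys_validate_leg_by_leg(small_region):
    router = TransitRouter(small_region)
    trips = {t.trip_id: t for t in small_region.timetable.trips}
    checked = 0
    for district in small_region.districts:
        for p in small_region.practices[:6]:
            j = router.min_duration_journey(district.id, p.id)
            if j is None or j.n_rides == 0:
                continue
            checked += 1
            assert sum(leg.duration_min for leg in j.legs) == pytest.approx(
                j.duration_min)
            t_cursor = j.departure_s
            for leg in j.legs:
                if isinstance(leg, RideLeg):
                    trip = trips[leg.trip_id]
                    evs = {e.stop_id: e for e in trip.events}
                    assert evs[leg.board_stop].departure_s == leg.board_time_s
                    assert evs[leg.alight_stop].arrival_s == leg.alight_time_s
                    assert leg.board_time_s == pytest.approx(t_cursor)
                    t_cursor = leg.alight_time_s
                elif isinstance(leg, WalkLeg):
                    assert leg.distance_m <= 1000.0 + 1e-9
                    t_cursor += leg.duration_min * 60
                elif isinstance(leg, WaitLeg):
                    t_cursor += leg.duration_min * 60
            assert t_cursor == pytest.approx(j.arrival_s)
            if checked >= 25:
                return
    assert checked > 0


def test_zero_routes_means_no_connection_without_walking():
    cfg = dataclasses.replace(SMALL_CONFIG, n_routes=0)
    bundle = generate_region(cfg)
    params = dataclasses.replace(PARAMS, allow_direct_walk=False)
    pt = transit_accessibility(bundle, params)
    assert (pt.status == NO_CONNECTION).all()
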