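"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive exhaustive enumeration (all simple paths
on street graphs; all ride/walk action sequences on timetables) so routing
results can be checked against an implementation-independent reference on
small instances.
"""

from __future__ import annotations

import numpy as np
import pytest

from ruralaccess import (
    AccessParams,
    FootpathSet,
    RegionBundle,
    RegionConfig,
    StopEvent,
    StreetEdge,
    StreetNetwork,
    Timetable,
    Trip,
    generate_region,
)

# ---------------------------------------------------------------------------
# Generated-region fixtures
# ---------------------------------------------------------------------------

SMALL_CONFIG = RegionConfig(
    extent_km=(10.0, 10.0), n_districts=15, total_population=8000,
    n_gp=6, n_ophthalmologist=2, n_internist=2, n_urologist=1,
    buffer_km=3.0, n_routes=3, headway_min=30.0, seed=3)


@pytest.fixture(scope="session")
def small_region() -> RegionBundle:
    return generate_region(SMALL_CONFIG)


# ---------------------------------------------------------------------------
# Hand-built bundles for transit unit tests
# ---------------------------------------------------------------------------


def line_network(n_nodes: int = 11, spacing_m: float = 300.0,
                 speed_kmh: float = 50.0) -> StreetNetwork:
    """A straight street of ``n_nodes`` equally spaced nodes."""
    nodes = {i: (i * spacing_m, 0.0) for i in range(n_nodes)}
    edges = [StreetEdge(i, i + 1, spacing_m, speed_kmh)
             for i in range(n_nodes - 1)]
    return StreetNetwork(nodes=nodes, edges=edges)


def make_bundle(network: StreetNetwork, districts, practices,
                timetable: Timetable) -> RegionBundle:
    cfg = RegionConfig(extent_km=(50.0, 50.0), n_districts=max(
        1, len(districts)), total_population=max(1, len(districts)))
    return RegionBundle(config=cfg, districts=list(districts),
                        network=network, practices=list(practices),
                        timetable=timetable)


def simple_trip(trip_id: str, stops_times, service: str = "school",
                route: str = "R") -> Trip:
    """Trip from (stop_id, arrival_s[, departure_s]) tuples."""
    events = []
    for item in stops_times:
        if len(item) == 2:
            sid, arr = item
            dep = arr
        else:
            sid, arr, dep = item
        events.append(StopEvent(sid, arr, dep))
    return Trip(trip_id=trip_id, route_id=route, service=service,
                events=tuple(events))


# ---------------------------------------------------------------------------
# Car routing oracle: exhaustive simple-path enumeration
# ---------------------------------------------------------------------------


def enumerate_labels(graph, source):
    """Min (time, distance) label per node over all simple paths."""
    best = {source: (0.0, 0.0)}

    def dfs(u, t, d, visited):
        for v, attr in graph[u].items():
            if v in visited:
                continue
            nt, nd = t + attr["time_s"], d + attr["length_m"]
            cur = best.get(v)
            if cur is None or (nt, nd) < cur:
                best[v] = (nt, nd)
            dfs(v, nt, nd, visited | {v})

    dfs(source, 0.0, 0.0, {source})
    return best


def random_car_graph(rng: np.random.Generator, n_max: int = 10):
    """Small random directed street-time graph with positions."""
    import networkx as nx

    n = int(rng.integers(4, n_max + 1))
    g = nx.DiGraph()
    pos = rng.uniform(0, 5000, size=(n, 2))
    for i in range(n):
        g.add_node(i, pos=tuple(pos[i]))
    m = int(rng.integers(n, 2 * n + 1))
    for _ in range(m):
        u, v = rng.integers(0, n, size=2)
        if u == v:
            continue
        length = float(rng.uniform(100, 3000))
        speed = float(rng.choice([30.0, 70.0, 100.0]))
        t = 3.6 * length / speed
        if not g.has_edge(u, v) or g[int(u)][int(v)]["time_s"] > t:
            g.add_edge(int(u), int(v), time_s=t, length_m=length)
        if rng.uniform() < 0.7:  # most streets two-way
            if not g.has_edge(v, u) or g[int(v)][int(u)]["time_s"] > t:
                g.add_edge(int(v), int(u), time_s=t, length_m=length)
    return g


# ---------------------------------------------------------------------------
# Transit oracle: exhaustive journey enumeration
# ---------------------------------------------------------------------------


def brute_force_min_leg(timetable: Timetable, access, egress, stop_stop,
                        t_earliest, t_latest, params: AccessParams,
                        service_day: str | None = None):
    """Minimum duration (seconds) over all feasible transit journeys.

    Enumerates every action sequence under strictly alternating walk and
    vehicle legs: walk to an access stop, board any ride departing at or
    after presence there (waiting at the stop is free), alight anywhere
    later on the trip, then either egress-walk to the destination,
    re-board at the same stop, or transfer-walk once (within the cap set
    given) and re-board there.  Departure time is boarding time minus the
    access walk (the traveller leaves just in time).  Returns ``None`` when
    nothing is feasible.  Independent of the event-graph router.
    """
    day = service_day or params.service_day
    trips = [t for t in timetable.trips if t.service == day
             and (not t.events or t.events[-1].arrival_s
                  <= params.latest_home_arrival_s)]
    speed = params.walk_speed_kmh

    def walk_s(d):
        return 3.6 * d / speed

    egress_at = {}
    for sid, d in egress:
        egress_at[sid] = min(egress_at.get(sid, np.inf), walk_s(d))
    results: list[float] = []

    def extend(stop, time, nrides, dep_home, walked):
        if not walked and nrides >= 1 and stop in egress_at:
            arr = time + egress_at[stop]
            if arr <= t_latest:
                results.append(arr - dep_home)
        if nrides >= 6:
            return
        for trip in trips:
            for i, ev in enumerate(trip.events[:-1]):
                if ev.stop_id == stop and ev.departure_s >= time:
                    for j in range(i + 1, len(trip.events)):
                        extend(trip.events[j].stop_id,
                               trip.events[j].arrival_s,
                               nrides + 1, dep_home, False)
        if not walked:
            for (a, b), d in stop_stop.items():
                if a == stop:
                    extend(b, time + walk_s(d), nrides, dep_home, True)

    for sid, dist in access:
        w = walk_s(dist)
        for trip in trips:
            for ev in trip.events[:-1]:
                if ev.stop_id == sid and ev.departure_s >= t_earliest + w:
                    extend(sid, ev.departure_s, 0,
                           ev.departure_s - w, True)
    return min(results) if results else None


def random_timetable(rng: np.random.Generator):
    """A random tiny timetable (<= 30 stop events) plus random footpaths.

    Returns (timetable, access, egress, stop_stop) where access/egress are
    (stop_id, metres) lists within the default caps.
    """
    n_stops = int(rng.integers(3, 6))
    stop_ids = [f"S{i}" for i in range(n_stops)]
    stops = {sid: (float(i * 400), 0.0) for i, sid in enumerate(stop_ids)}
    trips = []
    total_events = 0
    n_trips = int(rng.integers(2, 5))
    for k in range(n_trips):
        length = int(rng.integers(2, min(4, n_stops) + 1))
        route = list(rng.choice(n_stops, size=length, replace=False))
        t = int(rng.integers(7 * 3600, 14 * 3600))
        events = []
        for sid_idx in route:
            arr = t
            dep = arr + int(rng.integers(0, 90))
            events.append((stop_ids[sid_idx], arr, dep))
            t = dep + int(rng.integers(120, 1500))
            total_events += 1
            if total_events >= 30:
                break
        if len(events) >= 2:
            trips.append(simple_trip(f"T{k}", events))
        if total_events >= 30:
            break
    tt = Timetable(stops=stops, trips=trips)
    tt.validate()
    access = [(sid, float(rng.uniform(50, 900)))
              for sid in rng.choice(stop_ids, size=min(2, n_stops),
                                    replace=False)]
    egress = [(sid, float(rng.uniform(50, 450)))
              for sid in rng.choice(stop_ids, size=min(2, n_stops),
                                    replace=False)]
    stop_stop = {}
    for _ in range(int(rng.integers(0, 3))):
        a, b = rng.choice(n_stops, size=2, replace=False)
        d = float(rng.uniform(20, 240))
        stop_stop[(stop_ids[a], stop_ids[b])] = d
        stop_stop[(stop_ids[b], stop_ids[a])] = d
    return tt, access, egress, stop_stop


def fps_from_parts(access=(), egress=(), stop_stop=None,
                   origin_id="O", practice_id="P") -> FootpathSet:
    """FootpathSet wired for one origin and one practice."""
    return FootpathSet(
        origin_stop={(origin_id, sid): d for sid, d in access},
        stop_practice={(sid, practice_id): d for sid, d in egress},
        stop_stop=dict(stop_stop or {}),
        origin_practice={})
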