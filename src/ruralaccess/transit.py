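"""Public-transport accessibility: timetable-based round trips from district
centroids to medical practices under walking-distance and time-window
constraints.

The model targets an elderly patient travelling to a fixed appointment:
walking speed 1.8 km/h, at most 1,000 m on foot from the district centre to
one of its three nearest stops, at most 500 m from the alighting stop to the
practice, at most 250 m between stops when changing vehicles, travel starting
no earlier than 07:00, arrival by the 11:00 appointment, return starting no
earlier than 12:00 (the appointment hour is not counted) and home arrival by
midnight, on a school-day Tuesday timetable.

Routing runs on a time-expanded graph whose nodes are (stop, clock-time)
events connected by ride, wait and transfer-walk edges; a label-setting
(Dijkstra) search from each candidate boarding event yields earliest arrivals
at every stop, and a profile over boarding events minimizes journey duration
(arrival minus home departure — the traveller leaves home just in time for
the chosen vehicle, so origin-stop waiting never inflates the duration).
A district whose round trip is infeasible for every practice of a group is
flagged NO_CONNECTION.
"""

from __future__ import annotations

import heapq
from bisect import bisect_left
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic_region import RegionBundle, StreetNetwork, Timetable

OK = "OK"
NO_CONNECTION = "NO_CONNECTION"


@dataclass(frozen=True)
class AccessParams:
    """Walking caps, speeds and time windows of the round-trip model.

    Times are integer seconds since service-day midnight; no overnight
    wraparound (vehicle events past 24:00 are ignored).
    """

    walk_speed_kmh: float = 1.8
    max_walk_origin_to_stop_m: float = 1000.0
    max_walk_stop_to_practice_m: float = 500.0
    max_walk_transfer_m: float = 250.0
    max_walk_origin_to_practice_m: float = 1000.0
    k_access_stops: int = 3
    earliest_departure_s: int = 7 * 3600
    appointment_time_s: int = 11 * 3600
    appointment_duration_min: float = 60.0  # excluded from travel time
    return_earliest_s: int = 12 * 3600
    latest_home_arrival_s: int = 24 * 3600
    service_day: str = "school"  # Tuesday during school time
    #: permit a pure-walking round trip when the practice is within the
    #: origin-to-practice cap, reporting min(walk-only, transit) totals
    allow_direct_walk: bool = True
    #: count waiting at the practice before the appointment as travel time
    count_practice_wait: bool = False

    def validate(self) -> None:
        for name in ("walk_speed_kmh", "max_walk_origin_to_stop_m",
                     "max_walk_stop_to_practice_m", "max_walk_transfer_m",
                     "max_walk_origin_to_practice_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_access_stops < 1:
            raise ValueError("k_access_stops must be >= 1")
        if not (self.earliest_departure_s < self.appointment_time_s
                < self.return_earliest_s <= self.latest_home_arrival_s):
            raise ValueError("time windows must be ordered: departure < "
                             "appointment < return <= home arrival")


def walking_time(distance_m: float, walk_speed_kmh: float) -> float:
    """Walking duration in minutes: ``0.06 * distance_m / speed_kmh``
    (1 m/s corresponds to 3.6 km/h)."""
    if walk_speed_kmh <= 0:
        raise ValueError("walking speed must be positive")
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    return 0.06 * distance_m / walk_speed_kmh


def _walk_seconds(distance_m: float, walk_speed_kmh: float) -> float:
    return 3.6 * distance_m / walk_speed_kmh


# ---------------------------------------------------------------------------
# Footpaths (street-network walking distances under the caps)
# ---------------------------------------------------------------------------


@dataclass
class FootpathSet:
    """Street-network walking distances, only for pairs within their caps.

    Distances include the straight-line offset from each off-network point to
    its snapped street node.  ``stop_stop`` is stored symmetrically.
    """

    origin_stop: dict  # (origin_id, stop_id) -> metres
    stop_practice: dict  # (stop_id, practice_id) -> metres
    stop_stop: dict  # (stop_a, stop_b) -> metres, both orders
    origin_practice: dict  # (origin_id, practice_id) -> metres


def footpaths(network: StreetNetwork, origins: dict, stops: dict,
              practices: dict, params: AccessParams,
              snap_tolerance_m: float = 500.0) -> FootpathSet:
    """All in-cap walking distances between district centroids, stops and
    practices, measured along the street network (one-way flags ignored)."""
    params.validate()
    walk = network.walking_graph()
    node_ids = sorted(walk.nodes)
    tree = cKDTree(np.array([walk.nodes[n]["pos"] for n in node_ids]))

    def snap(points: dict) -> dict:
        out = {}
        for pid, xy in points.items():
            off, k = tree.query(xy)
            if off <= snap_tolerance_m:
                out[pid] = (node_ids[int(k)], float(off))
        return out

    o_snap, s_snap, p_snap = snap(origins), snap(stops), snap(practices)
    stops_at: dict[int, list] = {}
    for sid, (node, off) in s_snap.items():
        stops_at.setdefault(node, []).append((sid, off))
    practices_at: dict[int, list] = {}
    for pid, (node, off) in p_snap.items():
        practices_at.setdefault(node, []).append((pid, off))

    _cache: dict[tuple[int, float], dict] = {}

    def reach(node: int, cutoff: float) -> dict:
        key = (node, cutoff)
        if key not in _cache:
            _cache[key] = nx.single_source_dijkstra_path_length(
                walk, node, cutoff=cutoff, weight="length_m")
        return _cache[key]

    cap_os = params.max_walk_origin_to_stop_m
    cap_op = params.max_walk_origin_to_practice_m
    cap_sp = params.max_walk_stop_to_practice_m
    cap_tr = params.max_walk_transfer_m

    origin_stop, origin_practice = {}, {}
    o_cut = max(cap_os, cap_op)
    for oid, (onode, ooff) in o_snap.items():
        lengths = reach(onode, o_cut)
        for node, net in lengths.items():
            for sid, soff in stops_at.get(node, ()):
                d = ooff + net + soff
                if d <= cap_os:
                    prev = origin_stop.get((oid, sid))
                    if prev is None or d < prev:
                        origin_stop[(oid, sid)] = d
            for pid, poff in practices_at.get(node, ()):
                d = ooff + net + poff
                if d <= cap_op:
                    prev = origin_practice.get((oid, pid))
                    if prev is None or d < prev:
                        origin_practice[(oid, pid)] = d

    stop_practice, stop_stop = {}, {}
    s_cut = max(cap_sp, cap_tr)
    for sid, (snode, soff) in sorted(s_snap.items()):
        lengths = reach(snode, s_cut)
        for node, net in lengths.items():
            for pid, poff in practices_at.get(node, ()):
                d = soff + net + poff
                if d <= cap_sp:
                    prev = stop_practice.get((sid, pid))
                    if prev is None or d < prev:
                        stop_practice[(sid, pid)] = d
            for sid2, s2off in stops_at.get(node, ()):
                if sid2 == sid:
                    continue
                d = soff + net + s2off
                if d <= cap_tr:
                    prev = stop_stop.get((sid, sid2))
                    if prev is None or d < prev:
                        stop_stop[(sid, sid2)] = d
                        stop_stop[(sid2, sid)] = d
    return FootpathSet(origin_stop=origin_stop, stop_practice=stop_practice,
                       stop_stop=stop_stop, origin_practice=origin_practice)


def candidate_access_stops(fps: FootpathSet, origin_id,
                           params: AccessParams) -> list[tuple[str, float]]:
    """Up to ``k_access_stops`` nearest in-cap stops of a district, as
    (stop_id, walking metres), nearest first; ties broken by stop id."""
    pairs = [(d, sid) for (oid, sid), d in fps.origin_stop.items()
             if oid == origin_id]
    pairs.sort()
    return [(sid, d) for d, sid in pairs[:params.k_access_stops]]


# ---------------------------------------------------------------------------
# Time-expanded event graph
# ---------------------------------------------------------------------------


class EventGraph:
    """Time-expanded transit graph for one service day.

    Nodes are (stop, clock-time) pairs; being at a node means standing at
    that stop at that time.  Edges: *ride* (consecutive stop events of a
    trip), *wait* (consecutive time points at one stop), *transfer*
    (walk to a stop within the transfer cap, landing on the first time point
    at or after arrival there).  Every edge moves forward in time.
    """

    def __init__(self, timetable: Timetable, fps: FootpathSet,
                 params: AccessParams):
        params.validate()
        day = params.service_day
        horizon = params.latest_home_arrival_s
        points: set[tuple[str, int]] = set()
        rides: list[tuple[str, int, str, int, str]] = []
        for trip in timetable.trips:
            if trip.service != day:
                continue
            if trip.events and trip.events[-1].arrival_s > horizon:
                continue
            for a, b in zip(trip.events[:-1], trip.events[1:]):
                points.add((a.stop_id, a.departure_s))
                points.add((b.stop_id, b.arrival_s))
                rides.append((a.stop_id, a.departure_s,
                              b.stop_id, b.arrival_s, trip.trip_id))

        self.nodes: list[tuple[str, int]] = sorted(points,
                                                   key=lambda p: (p[1], p[0]))
        self.index: dict[tuple[str, int], int] = {
            p: i for i, p in enumerate(self.nodes)}
        self.adj: list[list[tuple[int, str, object]]] = [
            [] for _ in self.nodes]

        self.stop_points: dict[str, list[tuple[int, int]]] = {}
        for i, (stop, t) in enumerate(self.nodes):
            self.stop_points.setdefault(stop, []).append((t, i))
        for stop, pts in self.stop_points.items():
            pts.sort()
            for (t1, i1), (t2, i2) in zip(pts[:-1], pts[1:]):
                self.adj[i1].append((i2, "wait", None))

        self.ride_departures: dict[str, list[tuple[int, int]]] = {}
        for stop_a, dep, stop_b, arr, trip_id in rides:
            i, j = self.index[(stop_a, dep)], self.index[(stop_b, arr)]
            self.adj[i].append((j, "ride", trip_id))
            self.ride_departures.setdefault(stop_a, []).append((dep, i))
        for lst in self.ride_departures.values():
            lst.sort()

        walk_pairs = sorted({(a, b) for (a, b) in fps.stop_stop})
        for a, b in walk_pairs:
            if a not in self.stop_points or b not in self.stop_points:
                continue
            d = fps.stop_stop[(a, b)]
            w = _walk_seconds(d, params.walk_speed_kmh)
            b_pts = self.stop_points[b]
            b_times = [t for t, _ in b_pts]
            for t, i in self.stop_points[a]:
                k = bisect_left(b_times, t + w)
                if k < len(b_pts):
                    self.adj[i].append((b_pts[k][1], "transfer", d))

        self._profiles: dict[int, dict] = {}

    def n_edges(self, kind: str | None = None) -> int:
        return sum(1 for out in self.adj for _, k, _ in out
                   if kind is None or k == kind)

    def profile(self, start: int) -> dict:
        """Cached earliest-arrival profile from a start node."""
        prof = self._profiles.get(start)
        if prof is None:
            prof = self.earliest_arrivals(start)
            self._profiles[start] = prof
        return prof

    def earliest_arrivals(self, start: int, with_preds: bool = False):
        """Label-setting search from a boarding node.

        Walking legs must alternate with vehicle legs: the traveller has
        already walked to the boarding stop, so the first move (after any
        waiting there) must be a ride; a transfer walk is allowed only
        directly after alighting, and the final egress walk likewise.  The
        search state is therefore (event node, walked-since-last-ride).

        Returns ``{stop: (arrival_s, n_rides, node_index)}`` giving, per
        stop, the earliest moment the traveller can stand there having just
        alighted (fewest rides among equal times) — the states an egress
        walk may start from — and optionally a predecessor map over
        (node, walked) states for journey reconstruction.
        """
        settled: set[tuple[int, int]] = set()
        preds: dict[tuple[int, int], tuple[int, int, str, object]] = {}
        by_stop: dict[str, tuple[int, int, int]] = {}
        t0 = self.nodes[start][1]
        # (time, rides, walked, node, prev_node, prev_walked, kind, payload)
        heap: list = [(t0, 0, 1, start, -1, 1, "", None)]
        while heap:
            t, rides, w, i, prev, pw, kind, payload = heapq.heappop(heap)
            if (i, w) in settled:
                continue
            settled.add((i, w))
            if prev >= 0 and with_preds:
                preds[(i, w)] = (prev, pw, kind, payload)
            stop = self.nodes[i][0]
            if w == 0 and stop not in by_stop:
                by_stop[stop] = (t, rides, i)
            for j, ekind, epayload in self.adj[i]:
                if ekind == "ride":
                    nw = 0
                elif ekind == "wait":
                    nw = w
                else:  # transfer walk: only straight after alighting
                    if w == 1:
                        continue
                    nw = 1
                if (j, nw) not in settled:
                    heapq.heappush(
                        heap, (self.nodes[j][1],
                               rides + (1 if ekind == "ride" else 0),
                               nw, j, i, w, ekind, epayload))
        if with_preds:
            return by_stop, preds
        return by_stop


def build_event_graph(timetable: Timetable, fps: FootpathSet,
                      params: AccessParams) -> EventGraph:
    return EventGraph(timetable, fps, params)


# ---------------------------------------------------------------------------
# Journeys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WalkLeg:
    distance_m: float
    duration_min: float


@dataclass(frozen=True)
class WaitLeg:
    stop_id: str
    duration_min: float


@dataclass(frozen=True)
class RideLeg:
    trip_id: str
    board_stop: str
    board_time_s: int
    alight_stop: str
    alight_time_s: int

    @property
    def duration_min(self) -> float:
        return (self.alight_time_s - self.board_time_s) / 60.0


def _merge_ride_legs(legs: list) -> list:
    """Collapse consecutive stop-to-stop hops of the same trip (and the
    dwell waits between them) into a single boarding-to-alighting ride."""
    out: list = []
    i = 0
    while i < len(legs):
        leg = legs[i]
        if isinstance(leg, RideLeg):
            j = i
            last = leg
            while j + 2 < len(legs):
                mid, nxt = legs[j + 1], legs[j + 2]
                if (isinstance(mid, WaitLeg) and isinstance(nxt, RideLeg)
                        and nxt.trip_id == last.trip_id
                        and nxt.board_stop == last.alight_stop):
                    last = nxt
                    j += 2
                else:
                    break
            out.append(RideLeg(leg.trip_id, leg.board_stop, leg.board_time_s,
                               last.alight_stop, last.alight_time_s))
            i = j + 1
        else:
            out.append(leg)
            i += 1
    return out


@dataclass
class Journey:
    legs: list
    departure_s: float
    arrival_s: float

    @property
    def duration_min(self) -> float:
        return (self.arrival_s - self.departure_s) / 60.0

    @property
    def n_rides(self) -> int:
        return sum(1 for leg in self.legs if isinstance(leg, RideLeg))


@dataclass(frozen=True)
class _LegResult:
    duration_s: float
    departure_s: float
    arrival_s: float
    rides: int
    access_stop: str | None  # None for a pure walking leg
    board_node: int | None
    egress_stop: str | None
    walk_only: bool = False


@dataclass(frozen=True)
class RoundTripResult:
    district_id: str
    group: str | None
    practice_id: str | None
    outbound_min: float | None
    return_min: float | None
    status: str

    @property
    def total_min(self) -> float | None:
        if self.status != OK:
            return None
        return self.outbound_min + self.return_min


def minimum_duration_leg(graph: EventGraph, access: list[tuple[str, float]],
                         egress: list[tuple[str, float]], t_earliest: float,
                         t_latest: float, params: AccessParams
                         ) -> _LegResult | None:
    """Minimum-duration transit leg within a time window.

    ``access``/``egress`` are (stop_id, walking metres) pairs; the traveller
    leaves the origin just in time to board, so duration = arrival at the
    destination minus that implied departure.  Among equal durations the
    latest departure wins, then the fewest rides.  ``None`` when no journey
    with at least one vehicle leg fits the window.
    """
    speed = params.walk_speed_kmh
    egress_w = [(sid, d, _walk_seconds(d, speed)) for sid, d in egress]
    best: tuple | None = None
    for sid, dist in access:
        w_s = _walk_seconds(dist, speed)
        deps = graph.ride_departures.get(sid, ())
        for t_board, node in deps:
            if t_board > t_latest:
                break
            if t_board < t_earliest + w_s:
                continue
            dep = t_board - w_s
            prof = graph.profile(node)
            for esid, edist, ew_s in egress_w:
                hit = prof.get(esid)
                if hit is None:
                    continue
                t_arr, rides, _enode = hit
                arrival = t_arr + ew_s
                if arrival > t_latest:
                    continue
                key = (arrival - dep, -dep, rides)
                if best is None or key < best[:3]:
                    best = (arrival - dep, -dep, rides, sid, dist, node,
                            esid, edist, arrival)
    if best is None:
        return None
    dur, negdep, rides, sid, dist, node, esid, edist, arrival = best
    return _LegResult(duration_s=dur, departure_s=-negdep, arrival_s=arrival,
                      rides=rides, access_stop=sid, board_node=node,
                      egress_stop=esid)


# ---------------------------------------------------------------------------
# Router
# ---------------------------------------------------------------------------


class TransitRouter:
    """Round-trip journey planner over a region bundle.

    Builds footpaths and the time-expanded graph once; earliest-arrival
    profiles from boarding events are cached, so batch queries over many
    districts and practices share work.
    """

    def __init__(self, bundle: RegionBundle, params: AccessParams | None = None):
        self.params = params or AccessParams()
        self.params.validate()
        self.bundle = bundle
        self.fps = footpaths(bundle.network, bundle.district_centroids(),
                             dict(bundle.timetable.stops),
                             bundle.practice_locations(), self.params)
        self.graph = EventGraph(bundle.timetable, self.fps, self.params)
        self._practice_stops: dict[str, list[tuple[str, float]]] = {}
        for (sid, pid), d in self.fps.stop_practice.items():
            self._practice_stops.setdefault(pid, []).append((sid, d))
        for lst in self._practice_stops.values():
            lst.sort(key=lambda p: (p[1], p[0]))
        self._groups: dict[str, list[str]] = {}
        for p in bundle.practices:
            self._groups.setdefault(p.group, []).append(p.id)

    # -- internals ---------------------------------------------------------

    def _min_leg(self, access: list[tuple[str, float]],
                 egress: list[tuple[str, float]],
                 t_earliest: int, t_latest: int) -> _LegResult | None:
        return minimum_duration_leg(self.graph, access, egress, t_earliest,
                                    t_latest, self.params)

    def _walk_leg(self, origin_id, practice_id, t_earliest: int,
                  t_latest: int) -> _LegResult | None:
        if not self.params.allow_direct_walk:
            return None
        d = self.fps.origin_practice.get((origin_id, practice_id))
        if d is None:
            return None
        w_s = _walk_seconds(d, self.params.walk_speed_kmh)
        if t_earliest + w_s > t_latest:
            return None
        # schedule the walk to end exactly at the window close
        return _LegResult(duration_s=w_s, departure_s=t_latest - w_s,
                          arrival_s=t_latest, rides=0, access_stop=None,
                          board_node=None, egress_stop=None, walk_only=True)

    def _access(self, origin_id) -> list[tuple[str, float]]:
        return candidate_access_stops(self.fps, origin_id, self.params)

    def _egress(self, practice_id) -> list[tuple[str, float]]:
        return self._practice_stops.get(practice_id, [])

    # -- public queries ----------------------------------------------------

    def min_duration_journey(self, origin_id, practice_id,
                             window: tuple[int, int] | None = None
                             ) -> Journey | None:
        """Minimum-duration outbound journey (transit, or a direct walk when
        allowed and shorter); ``None`` when no connection exists."""
        p = self.params
        t0, t1 = window or (p.earliest_departure_s, p.appointment_time_s)
        leg = self._min_leg(self._access(origin_id), self._egress(practice_id),
                            t0, t1)
        walk = self._walk_leg(origin_id, practice_id, t0, t1)
        if walk is not None and (leg is None or walk.duration_s < leg.duration_s):
            leg = walk
        if leg is None:
            return None
        return self._reconstruct(leg, origin_id, practice_id)

    def round_trip(self, origin_id, practice_id, group: str | None = None
                   ) -> RoundTripResult:
        """Round trip district -> practice -> district under the windows.

        Outbound within [earliest departure, appointment]; return within
        [return earliest, latest home arrival].  The appointment hour is not
        travel time.  A pure-walking round trip is used when allowed and
        faster.  Either leg infeasible => NO_CONNECTION for this practice.
        """
        p = self.params
        access = self._access(origin_id)
        egress = self._egress(practice_id)
        out = self._min_leg(access, egress, p.earliest_departure_s,
                            p.appointment_time_s)
        ret = self._min_leg([(s, d) for s, d in egress], access,
                            p.return_earliest_s, p.latest_home_arrival_s)
        transit_total = (out.duration_s + ret.duration_s
                         if out is not None and ret is not None else None)
        wout = self._walk_leg(origin_id, practice_id, p.earliest_departure_s,
                              p.appointment_time_s)
        wret = self._walk_leg(origin_id, practice_id, p.return_earliest_s,
                              p.latest_home_arrival_s)
        walk_total = (wout.duration_s + wret.duration_s
                      if wout is not None and wret is not None else None)
        if transit_total is None and walk_total is None:
            return RoundTripResult(origin_id, group, practice_id, None, None,
                                   NO_CONNECTION)
        if walk_total is not None and (transit_total is None
                                       or walk_total < transit_total):
            out, ret = wout, wret
        out_min, ret_min = out.duration_s / 60.0, ret.duration_s / 60.0
        if p.count_practice_wait:
            out_min = (p.appointment_time_s - out.departure_s) / 60.0
        return RoundTripResult(origin_id, group, practice_id, out_min,
                               ret_min, OK)

    def nearest_reachable_practice(self, origin_id, group: str
                                   ) -> RoundTripResult:
        """Round trip to the practice of ``group`` minimizing total travel
        time; NO_CONNECTION iff every practice of the group is infeasible."""
        if group not in self._groups:
            raise ValueError(f"no practices of group {group!r}")
        best: RoundTripResult | None = None
        for pid in sorted(self._groups[group]):
            rt = self.round_trip(origin_id, pid, group)
            if rt.status != OK:
                continue
            if best is None or (rt.total_min, rt.practice_id) < (
                    best.total_min, best.practice_id):
                best = rt
        if best is None:
            return RoundTripResult(origin_id, group, None, None, None,
                                   NO_CONNECTION)
        return best

    # -- journey reconstruction -------------------------------------------

    def _reconstruct(self, leg: _LegResult, origin_id, practice_id) -> Journey:
        speed = self.params.walk_speed_kmh
        if leg.walk_only:
            d = self.fps.origin_practice[(origin_id, practice_id)]
            return Journey(legs=[WalkLeg(d, walking_time(d, speed))],
                           departure_s=leg.departure_s,
                           arrival_s=leg.arrival_s)
        legs: list = []
        d_access = self.fps.origin_stop[(origin_id, leg.access_stop)]
        legs.append(WalkLeg(d_access, walking_time(d_access, speed)))
        by_stop, preds = self.graph.earliest_arrivals(leg.board_node,
                                                      with_preds=True)
        node, walked = by_stop[leg.egress_stop][2], 0
        chain: list[tuple[int, str, object]] = []
        while not (node == leg.board_node and walked == 1):
            prev, pw, kind, payload = preds[(node, walked)]
            chain.append((node, kind, payload))
            node, walked = prev, pw
        chain.reverse()
        cur = leg.board_node
        for node, kind, payload in chain:
            t_prev = self.graph.nodes[cur][1]
            stop_prev = self.graph.nodes[cur][0]
            t_cur = self.graph.nodes[node][1]
            if kind == "ride":
                legs.append(RideLeg(payload, stop_prev, t_prev,
                                    self.graph.nodes[node][0], t_cur))
            elif kind == "wait":
                legs.append(WaitLeg(stop_prev, (t_cur - t_prev) / 60.0))
            else:  # transfer: walk plus residual wait at the new stop
                wmin = walking_time(payload, speed)
                legs.append(WalkLeg(payload, wmin))
                residual = (t_cur - t_prev) / 60.0 - wmin
                if residual > 1e-9:
                    legs.append(WaitLeg(self.graph.nodes[node][0], residual))
            cur = node
        d_egress = self.fps.stop_practice[(leg.egress_stop, practice_id)]
        legs.append(WalkLeg(d_egress, walking_time(d_egress, speed)))
        return Journey(legs=_merge_ride_legs(legs), departure_s=leg.departure_s,
                       arrival_s=leg.arrival_s)


def transit_accessibility(bundle: RegionBundle,
                          params: AccessParams | None = None,
                          groups=None) -> pd.DataFrame:
    """End-to-end public-transport pipeline: one row per district x group
    with outbound, return and total minutes, status and chosen practice."""
    router = TransitRouter(bundle, params)
    if groups is None:
        groups = sorted({p.group for p in bundle.practices})
    rows = []
    for district in bundle.districts:
        for group in groups:
            rt = router.nearest_reachable_practice(district.id, group)
            rows.append((district.id, group, rt.practice_id, rt.outbound_min,
                         rt.return_min, rt.total_min, rt.status))
    return pd.DataFrame(rows, columns=[
        "district_id", "group", "practice_id", "outbound_min", "return_min",
        "total_min", "status"])
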