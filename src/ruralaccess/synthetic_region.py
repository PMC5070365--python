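"""Seeded synthetic study regions for accessibility analysis.

A generated region stands in for the proprietary inputs of a rural
health-accessibility study: a routable street network with speed classes and
one-way flags, population districts with heavily skewed sizes, four physician
groups (dispersed general practitioners, town-clustered specialists, plus a
buffer ring of extra providers outside the core region), and weekday transit
timetables whose routes follow street paths.

Coordinates are planar metres in an arbitrary projected frame; the core study
region is the rectangle ``[0, W] x [0, H]`` and the buffer ring extends it by
``buffer_km`` on every side.  All randomness flows from ``RegionConfig.seed``
through a single :class:`numpy.random.Generator`, so a config generates a
byte-identical bundle every time.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as _shapely_mapping
from shapely.geometry import shape as _shapely_shape

PRACTICE_GROUPS = ("GP", "OPHTHALMOLOGIST", "INTERNIST", "UROLOGIST")

#: speed classes in km/h: local road, secondary road, trunk/motorway-like
SPEED_CLASSES = (30.0, 70.0, 100.0)

SERVICE_DAYS = ("school", "vacation")


class ConfigError(ValueError):
    """An infeasible or invalid region configuration."""


class ParseError(ValueError):
    """A malformed input file; message names the file and line."""

    def __init__(self, filename: str, line: int | None, message: str):
        self.filename = filename
        self.line = line
        where = f"{filename}:{line}" if line is not None else filename
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of a synthetic study region.

    Defaults emulate the scale of a sparsely populated rural county:
    464 districts totalling 239,102 inhabitants on a ~63 x 63 km core with a
    15 km buffer ring, 17 transit routes at an hourly base headway.
    """

    extent_km: tuple[float, float] = (63.0, 63.0)
    n_districts: int = 464
    total_population: int = 239_102
    population_skew: float = 1.3  # log-normal sigma of district sizes
    n_gp: int = 160
    n_ophthalmologist: int = 18
    n_internist: int = 25
    n_urologist: int = 8
    buffer_km: float = 15.0
    n_routes: int = 17
    headway_min: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.extent_km[0] <= 0 or self.extent_km[1] <= 0:
            raise ConfigError("extent_km must be positive")
        if self.buffer_km < 0:
            raise ConfigError("buffer_km must be >= 0")
        for name in ("n_districts", "total_population", "n_gp",
                     "n_ophthalmologist", "n_internist", "n_urologist"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_routes < 0:
            raise ConfigError("n_routes must be >= 0")
        if self.headway_min <= 0:
            raise ConfigError("headway_min must be positive")
        n_max = max(self.n_gp, self.n_ophthalmologist,
                    self.n_internist, self.n_urologist)
        if n_max > self.n_districts:
            raise ConfigError(
                f"more practices of one group ({n_max}) than districts "
                f"({self.n_districts})")

    @property
    def group_counts(self) -> dict[str, int]:
        return {
            "GP": self.n_gp,
            "OPHTHALMOLOGIST": self.n_ophthalmologist,
            "INTERNIST": self.n_internist,
            "UROLOGIST": self.n_urologist,
        }


@dataclass(frozen=True)
class District:
    id: str
    centroid: tuple[float, float]
    population: int


@dataclass(frozen=True)
class StreetEdge:
    u: int
    v: int
    length_m: float
    speed_kmh: float
    oneway: bool = False


@dataclass
class StreetNetwork:
    """Directed, speed-attributed street graph.

    ``edges`` are stored once per physical road segment; a segment with
    ``oneway=False`` is traversable in both directions by car, and every
    segment is traversable in both directions on foot.
    """

    nodes: dict[int, tuple[float, float]]
    edges: list[StreetEdge]

    def walking_graph(self) -> nx.Graph:
        """Undirected view with edge lengths; walking ignores one-way flags."""
        g = nx.Graph()
        for nid, pos in self.nodes.items():
            g.add_node(nid, pos=pos)
        for e in self.edges:
            # keep the shorter segment if a pair of nodes is doubly connected
            if g.has_edge(e.u, e.v):
                if g[e.u][e.v]["length_m"] <= e.length_m:
                    continue
            g.add_edge(e.u, e.v, length_m=e.length_m)
        return g


@dataclass(frozen=True)
class Practice:
    id: str
    group: str
    location: tuple[float, float]
    in_buffer: bool = False

    def __post_init__(self):
        if self.group not in PRACTICE_GROUPS:
            raise ValueError(f"unknown practice group {self.group!r}")


@dataclass(frozen=True)
class StopEvent:
    stop_id: str
    arrival_s: int
    departure_s: int


@dataclass(frozen=True)
class Trip:
    trip_id: str
    route_id: str
    service: str  # "school" | "vacation"
    events: tuple[StopEvent, ...]


@dataclass
class Timetable:
    stops: dict[str, tuple[float, float]]
    trips: list[Trip]

    def validate(self) -> None:
        for trip in self.trips:
            if trip.service not in SERVICE_DAYS:
                raise ValueError(f"unknown service tag {trip.service!r}")
            prev = None
            for ev in trip.events:
                if ev.stop_id not in self.stops:
                    raise ValueError(
                        f"trip {trip.trip_id} references unknown stop "
                        f"{ev.stop_id}")
                if ev.arrival_s > ev.departure_s:
                    raise ValueError(
                        f"trip {trip.trip_id}: arrival after departure at "
                        f"{ev.stop_id}")
                if prev is not None and ev.arrival_s <= prev:
                    raise ValueError(
                        f"trip {trip.trip_id}: event times must strictly "
                        f"increase")
                prev = ev.departure_s


@dataclass
class RegionBundle:
    config: RegionConfig
    districts: list[District]
    network: StreetNetwork
    practices: list[Practice]
    timetable: Timetable

    def district_centroids(self) -> dict[str, tuple[float, float]]:
        return {d.id: d.centroid for d in self.districts}

    def district_populations(self) -> dict[str, int]:
        return {d.id: d.population for d in self.districts}

    def practice_locations(self, group: str | None = None
                           ) -> dict[str, tuple[float, float]]:
        return {p.id: p.location for p in self.practices
                if group is None or p.group == group}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing exactly to
    ``total``, each share >= 1, by the largest-remainder rule."""
    n = len(weights)
    if total < n:
        raise ConfigError(f"total population {total} < number of units {n}")
    spare = total - n  # one inhabitant per district guaranteed
    exact = weights / weights.sum() * spare
    base = np.floor(exact).astype(np.int64)
    short = spare - int(base.sum())
    # ties in the fractional parts broken by index for determinism
    order = np.lexsort((np.arange(n), -(exact - base)))
    base[order[:short]] += 1
    return base + 1


def _generate_network(cfg: RegionConfig, rng: np.random.Generator
                      ) -> StreetNetwork:
    """Perturbed-lattice street network over core + buffer with pruning,
    three speed classes and sparse one-way flags; car graph kept strongly
    connected so no generated point is a routing dead end."""
    w_m = cfg.extent_km[0] * 1000.0
    h_m = cfg.extent_km[1] * 1000.0
    buf = cfg.buffer_km * 1000.0
    # node spacing chosen so the 1 km walking cap spans adjacent junctions
    spacing = min(800.0, max(250.0, min(w_m, h_m) / 5.0))
    xs = np.arange(-buf, w_m + buf + spacing / 2, spacing)
    ys = np.arange(-buf, h_m + buf + spacing / 2, spacing)
    nx_, ny_ = len(xs), len(ys)

    jitter = rng.uniform(-0.25, 0.25, size=(ny_, nx_, 2)) * spacing
    nodes: dict[int, tuple[float, float]] = {}
    for j in range(ny_):
        for i in range(nx_):
            nid = j * nx_ + i
            nodes[nid] = (float(xs[i] + jitter[j, i, 0]),
                          float(ys[j] + jitter[j, i, 1]))

    # 4-neighbour lattice edges
    candidates: list[tuple[int, int]] = []
    for j in range(ny_):
        for i in range(nx_):
            nid = j * nx_ + i
            if i + 1 < nx_:
                candidates.append((nid, nid + 1))
            if j + 1 < ny_:
                candidates.append((nid, nid + nx_))

    # prune ~18% of edges while keeping the lattice connected: a shuffled
    # spanning tree is mandatory, the rest survive with fixed probability
    order = rng.permutation(len(candidates))
    parent = list(range(len(nodes)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    keep = np.zeros(len(candidates), dtype=bool)
    for idx in order:
        u, v = candidates[idx]
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            keep[idx] = True
    extra = rng.uniform(size=len(candidates)) > 0.18
    keep |= extra

    # speed classes: every 4th grid line is secondary (70), the central
    # horizontal line is a motorway-like trunk (100), the rest local (30)
    trunk_row = ny_ // 2

    def edge_speed(u: int, v: int) -> float:
        ju, iu = divmod(u, nx_)
        jv, iv = divmod(v, nx_)
        if ju == jv == trunk_row:
            return SPEED_CLASSES[2]
        if (ju == jv and ju % 4 == 0) or (iu == iv and iu % 4 == 0):
            return SPEED_CLASSES[1]
        return SPEED_CLASSES[0]

    oneway_draw = rng.uniform(size=len(candidates)) < 0.03
    edges: list[StreetEdge] = []
    for idx, (u, v) in enumerate(candidates):
        if not keep[idx]:
            continue
        xu, yu = nodes[u]
        xv, yv = nodes[v]
        length = float(math.hypot(xu - xv, yu - yv))
        edges.append(StreetEdge(u, v, length, edge_speed(u, v),
                                bool(oneway_draw[idx])))

    # drop isolated nodes (none expected, but keep the invariant tight)
    used = {e.u for e in edges} | {e.v for e in edges}
    nodes = {nid: pos for nid, pos in nodes.items() if nid in used}

    # one-way flags must not break car strong connectivity
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for e in edges:
        g.add_edge(e.u, e.v)
        if not e.oneway:
            g.add_edge(e.v, e.u)
    while not nx.is_strongly_connected(g):
        comps = sorted(nx.strongly_connected_components(g), key=len)
        small = comps[0]
        fixed = False
        for k, e in enumerate(edges):
            if e.oneway and (e.u in small or e.v in small):
                edges[k] = replace(e, oneway=False)
                g.add_edge(e.v, e.u)
                fixed = True
                break
        if not fixed:  # pragma: no cover - pruning keeps the graph connected
            raise RuntimeError("street network generation lost connectivity")

    return StreetNetwork(nodes=nodes, edges=edges)


def _core_nodes(network: StreetNetwork, cfg: RegionConfig) -> list[int]:
    w_m = cfg.extent_km[0] * 1000.0
    h_m = cfg.extent_km[1] * 1000.0
    return sorted(nid for nid, (x, y) in network.nodes.items()
                  if 0.0 <= x <= w_m and 0.0 <= y <= h_m)


def _buffer_nodes(network: StreetNetwork, cfg: RegionConfig) -> list[int]:
    w_m = cfg.extent_km[0] * 1000.0
    h_m = cfg.extent_km[1] * 1000.0
    buf = cfg.buffer_km * 1000.0
    return sorted(
        nid for nid, (x, y) in network.nodes.items()
        if not (0.0 <= x <= w_m and 0.0 <= y <= h_m)
        and -buf <= x <= w_m + buf and -buf <= y <= h_m + buf)


def _generate_districts(cfg: RegionConfig, network: StreetNetwork,
                        rng: np.random.Generator) -> list[District]:
    core = _core_nodes(network, cfg)
    if len(core) < cfg.n_districts:
        raise ConfigError(
            f"extent too small: {len(core)} street nodes in the core for "
            f"{cfg.n_districts} districts")
    w_m = cfg.extent_km[0] * 1000.0
    h_m = cfg.extent_km[1] * 1000.0
    chosen = rng.choice(len(core), size=cfg.n_districts, replace=False)
    weights = rng.lognormal(mean=0.0, sigma=cfg.population_skew,
                            size=cfg.n_districts)
    pops = _largest_remainder(weights, cfg.total_population)
    districts = []
    for k, ci in enumerate(sorted(chosen)):
        x, y = network.nodes[core[ci]]
        dx, dy = rng.uniform(-200.0, 200.0, size=2)
        cx = float(min(max(x + dx, 0.0), w_m))
        cy = float(min(max(y + dy, 0.0), h_m))
        districts.append(District(id=f"D{k:04d}", centroid=(cx, cy),
                                  population=int(pops[k])))
    return districts


def _generate_practices(cfg: RegionConfig, districts: list[District],
                        network: StreetNetwork, rng: np.random.Generator
                        ) -> list[Practice]:
    """GPs spread uniformly over districts; specialists drawn preferentially
    into the highest-population districts; ~10% extra providers per group in
    the buffer ring."""
    n = len(districts)
    pops = np.array([d.population for d in districts], dtype=float)
    town_weights = pops ** 2 / (pops ** 2).sum()
    buffer_nodes = _buffer_nodes(network, cfg)

    practices: list[Practice] = []
    for group, count in cfg.group_counts.items():
        if group == "GP":
            host = rng.choice(n, size=count, replace=False)
        else:
            host = rng.choice(n, size=count, replace=False, p=town_weights)
        for k, di in enumerate(host):
            cx, cy = districts[int(di)].centroid
            dx, dy = rng.uniform(-300.0, 300.0, size=2)
            practices.append(Practice(
                id=f"{group[:3]}{k:03d}", group=group,
                location=(float(cx + dx), float(cy + dy)), in_buffer=False))
        if cfg.buffer_km > 0 and buffer_nodes:
            n_buf = max(1, round(0.10 * count))
            picks = rng.choice(len(buffer_nodes), size=n_buf, replace=False)
            for k, bi in enumerate(picks):
                bx, by = network.nodes[buffer_nodes[int(bi)]]
                practices.append(Practice(
                    id=f"{group[:3]}B{k:02d}", group=group,
                    location=(bx, by), in_buffer=True))
    return practices


def _generate_timetable(cfg: RegionConfig, districts: list[District],
                        network: StreetNetwork, rng: np.random.Generator
                        ) -> Timetable:
    """Hub-and-spoke transit network over street shortest paths, with stops
    at street nodes every 400-800 m.

    Rural bus networks radiate from the central town and are laid out to
    serve the villages where people live, so each route connects the
    highest-population district (the hub) with the most populous district
    not yet within reach of a stop; villages along the way are served en
    route.  School-day service runs 06:00-20:00 at the base headway;
    vacation service at twice the headway 07:00-19:00.  Bus speed 40 km/h
    plus 30 s dwell per stop."""
    stops: dict[str, tuple[float, float]] = {}
    trips: list[Trip] = []
    if cfg.n_routes == 0:
        return Timetable(stops=stops, trips=trips)

    walk = network.walking_graph()
    pops = np.array([d.population for d in districts], dtype=float)
    pw = pops / pops.sum()

    # snap district centroids to nearest street node once
    from scipy.spatial import cKDTree
    node_ids = sorted(network.nodes)
    node_xy = np.array([network.nodes[i] for i in node_ids])
    tree = cKDTree(node_xy)

    def node_of(district: District) -> int:
        _, k = tree.query(district.centroid)
        return node_ids[int(k)]

    by_pop = sorted(districts, key=lambda d: (-d.population, d.id))
    hub_node = node_of(by_pop[0])
    served_nodes: set[int] = set()

    bus_speed_kmh = 40.0
    dwell_s = 30
    for r in range(cfg.n_routes):
        target = next(
            (d for d in by_pop[1:]
             if node_of(d) != hub_node and node_of(d) not in served_nodes),
            None)
        if target is None:
            k = int(rng.choice(len(districts), p=pw))
            target = districts[k]
        na, nb = hub_node, node_of(target)
        if na == nb:  # pragma: no cover - only for one-district configs
            continue
        try:
            path = nx.shortest_path(walk, na, nb, weight="length_m")
        except nx.NetworkXNoPath:  # pragma: no cover
            continue
        if len(path) < 3:  # pragma: no cover
            continue

        # stops every 400-800 m along the path, always incl. both endpoints
        stop_nodes = [path[0]]
        acc = 0.0
        target = float(rng.uniform(400.0, 800.0))
        for u, v in zip(path[:-1], path[1:]):
            acc += walk[u][v]["length_m"]
            if acc >= target or v == path[-1]:
                stop_nodes.append(v)
                acc = 0.0
                target = float(rng.uniform(400.0, 800.0))
        seg_s: list[float] = []
        prev = stop_nodes[0]
        for sn in stop_nodes[1:]:
            d = nx.shortest_path_length(walk, prev, sn, weight="length_m")
            seg_s.append(3.6 * d / bus_speed_kmh)
            prev = sn
        served_nodes.update(stop_nodes)
        for sn in stop_nodes:
            sid = f"S{sn}"
            stops.setdefault(sid, network.nodes[sn])

        route_id = f"R{r:02d}"
        offset = int(rng.integers(0, int(cfg.headway_min * 60)))
        for service, (start_h, end_h, headway_s) in {
            "school": (6, 20, int(cfg.headway_min * 60)),
            "vacation": (7, 19, int(cfg.headway_min * 120)),
        }.items():
            t0s = range(start_h * 3600 + offset, end_h * 3600 + 1, headway_s)
            for direction, snodes, segs in (
                    (0, stop_nodes, seg_s),
                    (1, stop_nodes[::-1], seg_s[::-1])):
                for k, t0 in enumerate(t0s):
                    events = [StopEvent(f"S{snodes[0]}", t0, t0)]
                    t = float(t0)
                    for sn, s in zip(snodes[1:], segs):
                        t += max(s, 1.0)
                        arr = int(round(t))
                        last = sn == snodes[-1]
                        dep = arr if last else arr + dwell_s
                        if arr <= events[-1].departure_s:
                            arr = events[-1].departure_s + 1
                            dep = arr if last else arr + dwell_s
                        events.append(StopEvent(f"S{sn}", arr, dep))
                        t = float(dep)
                    if events[-1].arrival_s > 24 * 3600:
                        continue  # no overnight wraparound
                    trips.append(Trip(
                        trip_id=f"{route_id}_{service[:3]}_{direction}_{k:02d}",
                        route_id=route_id, service=service,
                        events=tuple(events)))
    tt = Timetable(stops=stops, trips=trips)
    tt.validate()
    return tt


def demo_config(seed: int = 0) -> RegionConfig:
    """A scaled-down study region — 100 districts, ~51,500 inhabitants on a
    30 x 30 km core — that runs the complete car and public-transport
    pipelines in well under a minute while keeping the structural features
    of the full-scale region (dispersed GPs, town-clustered specialists, a
    buffer ring, school-day timetables)."""
    return RegionConfig(
        extent_km=(30.0, 30.0), n_districts=100, total_population=51_500,
        n_gp=35, n_ophthalmologist=8, n_internist=10, n_urologist=4,
        buffer_km=15.0, n_routes=8, headway_min=60.0, seed=seed)


def generate_region(config: RegionConfig) -> RegionBundle:
    """Generate a complete synthetic region; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    network = _generate_network(config, rng)
    districts = _generate_districts(config, network, rng)
    practices = _generate_practices(config, districts, network, rng)
    timetable = _generate_timetable(config, districts, network, rng)
    return RegionBundle(config=config, districts=districts, network=network,
                        practices=practices, timetable=timetable)


# ---------------------------------------------------------------------------
# GTFS I/O
# ---------------------------------------------------------------------------

_GTFS_SERVICES = {"school": ("20120903", "20121221"),
                  "vacation": ("20120625", "20120901")}


def _fmt_time(seconds: int) -> str:
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def _parse_time(text: str, filename: str, line: int) -> int:
    parts = text.split(":")
    if len(parts) != 3:
        raise ParseError(filename, line, f"bad time value {text!r}")
    try:
        h, m, s = (int(p) for p in parts)
    except ValueError:
        raise ParseError(filename, line, f"bad time value {text!r}") from None
    if not (0 <= m < 60 and 0 <= s < 60):
        raise ParseError(filename, line, f"bad time value {text!r}")
    return h * 3600 + m * 60 + s


def write_gtfs(timetable: Timetable, directory: str) -> None:
    """Write stops.txt, routes.txt, trips.txt, stop_times.txt, calendar.txt.

    Planar metre coordinates are stored in stop_lon (x) / stop_lat (y); the
    frame is the region's arbitrary projected frame, not WGS84.
    """
    timetable.validate()
    os.makedirs(directory, exist_ok=True)
    stops = pd.DataFrame(
        [(sid, sid, y, x) for sid, (x, y) in sorted(timetable.stops.items())],
        columns=["stop_id", "stop_name", "stop_lat", "stop_lon"])
    stops.to_csv(os.path.join(directory, "stops.txt"), index=False,
                 float_format="%.17g")

    route_ids = sorted({t.route_id for t in timetable.trips})
    routes = pd.DataFrame(
        [(rid, rid, 3) for rid in route_ids],
        columns=["route_id", "route_short_name", "route_type"])
    routes.to_csv(os.path.join(directory, "routes.txt"), index=False)

    trips = pd.DataFrame(
        [(t.route_id, t.service, t.trip_id)
         for t in sorted(timetable.trips, key=lambda t: t.trip_id)],
        columns=["route_id", "service_id", "trip_id"])
    trips.to_csv(os.path.join(directory, "trips.txt"), index=False)

    rows = []
    for t in sorted(timetable.trips, key=lambda t: t.trip_id):
        for seq, ev in enumerate(t.events, start=1):
            rows.append((t.trip_id, _fmt_time(ev.arrival_s),
                         _fmt_time(ev.departure_s), ev.stop_id, seq))
    pd.DataFrame(rows, columns=["trip_id", "arrival_time", "departure_time",
                                "stop_id", "stop_sequence"]).to_csv(
        os.path.join(directory, "stop_times.txt"), index=False)

    cal_rows = []
    for service in sorted({t.service for t in timetable.trips}):
        start, end = _GTFS_SERVICES.get(service, ("20120101", "20121231"))
        cal_rows.append((service, 1, 1, 1, 1, 1, 0, 0, start, end))
    pd.DataFrame(cal_rows, columns=[
        "service_id", "monday", "tuesday", "wednesday", "thursday", "friday",
        "saturday", "sunday", "start_date", "end_date"]).to_csv(
        os.path.join(directory, "calendar.txt"), index=False)


def _read_table(directory: str, name: str, required: list[str],
                optional: bool = False) -> pd.DataFrame | None:
    path = os.path.join(directory, name)
    if not os.path.exists(path):
        if optional:
            return None
        raise ParseError(name, None, "file missing")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(name, None, f"unreadable CSV: {exc}") from None
    for col in required:
        if col not in df.columns:
            raise ParseError(name, 1, f"missing column {col!r}")
    return df


def read_gtfs(directory: str) -> Timetable:
    """Read a GTFS directory back into a :class:`Timetable`.

    Raises :class:`ParseError` naming file and line for malformed values and
    broken references.
    """
    stops_df = _read_table(directory, "stops.txt",
                           ["stop_id", "stop_lat", "stop_lon"])
    stops: dict[str, tuple[float, float]] = {}
    for idx, row in stops_df.iterrows():
        line = int(idx) + 2
        try:
            x, y = float(row["stop_lon"]), float(row["stop_lat"])
        except ValueError:
            raise ParseError("stops.txt", line, "bad coordinate") from None
        if row["stop_id"] in stops:
            raise ParseError("stops.txt", line,
                             f"duplicate stop_id {row['stop_id']!r}")
        stops[row["stop_id"]] = (x, y)

    trips_df = _read_table(directory, "trips.txt",
                           ["route_id", "service_id", "trip_id"])
    trip_meta: dict[str, tuple[str, str]] = {}
    for idx, row in trips_df.iterrows():
        line = int(idx) + 2
        if row["trip_id"] in trip_meta:
            raise ParseError("trips.txt", line,
                             f"duplicate trip_id {row['trip_id']!r}")
        if row["service_id"] not in SERVICE_DAYS:
            raise ParseError("trips.txt", line,
                             f"unknown service_id {row['service_id']!r}")
        trip_meta[row["trip_id"]] = (row["route_id"], row["service_id"])

    cal_df = _read_table(directory, "calendar.txt", ["service_id"],
                         optional=True)
    if cal_df is not None:
        known = set(cal_df["service_id"])
        for idx, row in trips_df.iterrows():
            if row["service_id"] not in known:
                raise ParseError("trips.txt", int(idx) + 2,
                                 f"service_id {row['service_id']!r} not in "
                                 f"calendar.txt")

    st_df = _read_table(directory, "stop_times.txt",
                        ["trip_id", "arrival_time", "departure_time",
                         "stop_id", "stop_sequence"])
    events: dict[str, list[tuple[int, StopEvent]]] = {}
    for idx, row in st_df.iterrows():
        line = int(idx) + 2
        tid = row["trip_id"]
        if tid not in trip_meta:
            raise ParseError("stop_times.txt", line,
                             f"unknown trip_id {tid!r}")
        if row["stop_id"] not in stops:
            raise ParseError("stop_times.txt", line,
                             f"unknown stop_id {row['stop_id']!r}")
        try:
            seq = int(row["stop_sequence"])
        except ValueError:
            raise ParseError("stop_times.txt", line,
                             "bad stop_sequence") from None
        ev = StopEvent(row["stop_id"],
                       _parse_time(row["arrival_time"], "stop_times.txt", line),
                       _parse_time(row["departure_time"], "stop_times.txt",
                                   line))
        events.setdefault(tid, []).append((seq, ev))

    trips = []
    for tid in sorted(trip_meta):
        route_id, service = trip_meta[tid]
        evs = tuple(ev for _, ev in sorted(events.get(tid, []),
                                           key=lambda p: p[0]))
        trips.append(Trip(trip_id=tid, route_id=route_id, service=service,
                          events=evs))
    tt = Timetable(stops=stops, trips=trips)
    try:
        tt.validate()
    except ValueError as exc:
        raise ParseError("stop_times.txt", None, str(exc)) from None
    return tt


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------


def write_geojson(items, path: str) -> None:
    """Write districts, practices or (geometry, properties) features.

    ``items`` may be a list of :class:`District`, of :class:`Practice`, of
    ``(shapely geometry, properties-dict)`` pairs, or a mapping
    ``id -> shapely geometry``.
    """
    features = []
    if isinstance(items, dict):
        items = [(geom, {"id": key}) for key, geom in sorted(items.items())]
    for item in items:
        if isinstance(item, District):
            geom = shapely.Point(item.centroid)
            props = {"id": item.id, "population": item.population}
        elif isinstance(item, Practice):
            geom = shapely.Point(item.location)
            props = {"id": item.id, "group": item.group,
                     "in_buffer": item.in_buffer}
        else:
            geom, props = item
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for feature {props.get('id')}")
        features.append({"type": "Feature", "geometry": _shapely_mapping(geom),
                         "properties": dict(props)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str):
    """Read a FeatureCollection into a list of (shapely geometry, properties)."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ParseError(os.path.basename(path), None,
                         "not a FeatureCollection")
    out = []
    for feat in data.get("features", []):
        geom = _shapely_shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid geometry in {path}")
        out.append((geom, dict(feat.get("properties") or {})))
    return out


def districts_from_geojson(path: str) -> list[District]:
    out = []
    for geom, props in read_geojson(path):
        out.append(District(id=str(props["id"]),
                            centroid=(geom.x, geom.y),
                            population=int(props["population"])))
    return out


def practices_from_geojson(path: str) -> list[Practice]:
    out = []
    for geom, props in read_geojson(path):
        out.append(Practice(id=str(props["id"]), group=str(props["group"]),
                            location=(geom.x, geom.y),
                            in_buffer=bool(props.get("in_buffer", False))))
    return out


# ---------------------------------------------------------------------------
# Region bundle persistence (network as CSV, points as GeoJSON, GTFS dir)
# ---------------------------------------------------------------------------


def write_region(bundle: RegionBundle, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    write_geojson(bundle.districts, os.path.join(directory, "districts.geojson"))
    write_geojson(bundle.practices, os.path.join(directory, "practices.geojson"))
    write_gtfs(bundle.timetable, os.path.join(directory, "gtfs"))
    nodes = pd.DataFrame(
        [(nid, x, y) for nid, (x, y) in sorted(bundle.network.nodes.items())],
        columns=["node_id", "x", "y"])
    nodes.to_csv(os.path.join(directory, "nodes.csv"), index=False,
                 float_format="%.17g")
    edges = pd.DataFrame(
        [(e.u, e.v, e.length_m, e.speed_kmh, int(e.oneway))
         for e in bundle.network.edges],
        columns=["u", "v", "length_m", "speed_kmh", "oneway"])
    edges.to_csv(os.path.join(directory, "edges.csv"), index=False,
                 float_format="%.17g")
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(bundle.config.__dict__, fh, indent=1)


def read_region(directory: str) -> RegionBundle:
    with open(os.path.join(directory, "config.json")) as fh:
        raw = json.load(fh)
    raw["extent_km"] = tuple(raw["extent_km"])
    config = RegionConfig(**raw)
    districts = districts_from_geojson(
        os.path.join(directory, "districts.geojson"))
    practices = practices_from_geojson(
        os.path.join(directory, "practices.geojson"))
    timetable = read_gtfs(os.path.join(directory, "gtfs"))
    nodes_df = pd.read_csv(os.path.join(directory, "nodes.csv"),
                           float_precision="round_trip")
    edges_df = pd.read_csv(os.path.join(directory, "edges.csv"),
                           float_precision="round_trip")
    network = StreetNetwork(
        nodes={int(r.node_id): (float(r.x), float(r.y))
               for r in nodes_df.itertuples()},
        edges=[StreetEdge(int(r.u), int(r.v), float(r.length_m),
                          float(r.speed_kmh), bool(r.oneway))
               for r in edges_df.itertuples()])
    return RegionBundle(config=config, districts=districts, network=network,
                        practices=practices, timetable=timetable)
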