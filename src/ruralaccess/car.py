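"""Car accessibility: street-graph travel times from district centroids to
the nearest practice of each physician group.

The street network becomes a directed graph whose edge weight is free-flow
travel time in seconds (``3.6 * length_m / speed_kmh``); one-way segments get
a single direction.  An origin-destination cost matrix between district
centroids and practice locations yields, per district and group, minutes and
kilometres to the nearest practice, which feed service-area band assignment
and per-group summary statistics.  No congestion, turn restrictions or
parking-search time are modelled.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic_region import Practice, RegionBundle, StreetNetwork

#: default service-area band breaks for car travel, minutes
DEFAULT_CAR_BREAKS = (5.0, 10.0, 15.0, 20.0)

DEFAULT_SNAP_TOLERANCE_M = 500.0


def build_car_graph(network: StreetNetwork) -> nx.DiGraph:
    """Directed graph with ``time_s`` and ``length_m`` edge attributes."""
    g = nx.DiGraph()
    for nid, pos in network.nodes.items():
        g.add_node(nid, pos=pos)
    for e in network.edges:
        if e.speed_kmh <= 0:
            raise ValueError(f"non-positive speed on edge {e.u}-{e.v}")
        if e.length_m <= 0:
            raise ValueError(f"non-positive length on edge {e.u}-{e.v}")
        t = 3.6 * e.length_m / e.speed_kmh
        directions = [(e.u, e.v)] if e.oneway else [(e.u, e.v), (e.v, e.u)]
        for u, v in directions:
            if g.has_edge(u, v) and g[u][v]["time_s"] <= t:
                continue
            g.add_edge(u, v, time_s=t, length_m=e.length_m)
    return g


def shortest_paths(graph: nx.DiGraph, source) -> dict:
    """Single-source time-optimal labels.

    Returns ``{node: (time_s, distance_m)}`` for every reachable node, where
    ``distance_m`` is the length of the time-optimal path (ties between
    equal-time paths broken toward shorter distance).  Unreachable nodes are
    absent from the mapping rather than carrying a sentinel value.
    """
    if source not in graph:
        raise KeyError(f"source {source!r} not in graph")
    dist: dict = {}
    heap = [(0.0, 0.0, source)]
    while heap:
        t, d, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = (t, d)
        for v, attr in graph[u].items():
            if v not in dist:
                heapq.heappush(heap, (t + attr["time_s"],
                                      d + attr["length_m"], v))
    return dist


def snap_points(graph: nx.DiGraph, points: dict,
                tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M
                ) -> tuple[dict, list]:
    """Snap point coordinates to the nearest graph node within tolerance.

    Returns ``(snapped, excluded)`` where ``snapped`` maps point id to node id
    and ``excluded`` lists ids beyond the tolerance (warned about, not fatal).
    """
    node_ids = sorted(graph.nodes)
    tree = cKDTree(np.array([graph.nodes[n]["pos"] for n in node_ids]))
    snapped: dict = {}
    excluded: list = []
    for pid, xy in points.items():
        d, k = tree.query(xy)
        if d > tolerance_m:
            excluded.append(pid)
        else:
            snapped[pid] = node_ids[int(k)]
    if excluded:
        warnings.warn(
            f"{len(excluded)} point(s) farther than {tolerance_m:.0f} m from "
            f"the street network were excluded: {excluded[:5]}...",
            stacklevel=2)
    return snapped, excluded


@dataclass
class ODMatrix:
    """Origin-destination travel costs; NaN marks an unreachable pair."""

    minutes: pd.DataFrame  # index: origin ids, columns: destination ids
    km: pd.DataFrame
    excluded_origins: list
    excluded_destinations: list

    def entry(self, origin, destination) -> tuple[float, float] | None:
        t = self.minutes.at[origin, destination]
        if pd.isna(t):
            return None
        return float(t), float(self.km.at[origin, destination])


def od_cost_matrix(graph: nx.DiGraph, origins: dict, destinations: dict,
                   snap_tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M
                   ) -> ODMatrix:
    """Time-optimal minutes and kilometres between every origin and
    destination; kilometres are measured along the time-optimal path."""
    o_snap, o_excl = snap_points(graph, origins, snap_tolerance_m)
    d_snap, d_excl = snap_points(graph, destinations, snap_tolerance_m)
    o_ids = list(o_snap)
    d_ids = list(d_snap)
    minutes = pd.DataFrame(np.nan, index=o_ids, columns=d_ids, dtype=float)
    km = pd.DataFrame(np.nan, index=o_ids, columns=d_ids, dtype=float)
    for oid in o_ids:
        labels = shortest_paths(graph, o_snap[oid])
        for did in d_ids:
            lab = labels.get(d_snap[did])
            if lab is not None:
                minutes.at[oid, did] = lab[0] / 60.0
                km.at[oid, did] = lab[1] / 1000.0
    return ODMatrix(minutes=minutes, km=km, excluded_origins=o_excl,
                    excluded_destinations=d_excl)


def nearest_practice(odm: ODMatrix, practices: list[Practice], group: str
                     ) -> pd.DataFrame:
    """Per origin: minutes, km and id of the nearest practice of ``group``.

    Buffer practices compete on equal terms with core ones.  Ties on minutes
    are broken by smaller km, then lexicographic practice id.  An origin with
    no reachable practice gets NaN minutes/km and a null practice id.
    """
    ids = [p.id for p in practices
           if p.group == group and p.id in odm.minutes.columns]
    if not ids:
        raise ValueError(f"no practice of group {group!r} in the OD matrix")
    rows = []
    for oid in odm.minutes.index:
        best = None
        for pid in ids:
            t = odm.minutes.at[oid, pid]
            if pd.isna(t):
                continue
            key = (float(t), float(odm.km.at[oid, pid]), pid)
            if best is None or key < best:
                best = key
        if best is None:
            rows.append((oid, np.nan, np.nan, None))
        else:
            rows.append((oid, best[0], best[1], best[2]))
    return pd.DataFrame(rows, columns=["district_id", "minutes", "km",
                                       "practice_id"]).set_index("district_id")


def band_label(index: int, breaks=DEFAULT_CAR_BREAKS, unit: str = "min"
               ) -> str:
    """Label of the ``index``-th half-open band defined by ``breaks``."""

    def fmt(x: float) -> str:
        return f"{x:g}"

    if index == 0:
        return f"<{fmt(breaks[0])} {unit}"
    if index == len(breaks):
        return f"≥{fmt(breaks[-1])} {unit}"
    return f"{fmt(breaks[index - 1])} to <{fmt(breaks[index])} {unit}"


def band_assign(minutes: float, breaks=DEFAULT_CAR_BREAKS, unit: str = "min"
                ) -> str:
    """Assign a value to its half-open band ``[a, b)``; an exact break value
    belongs to the upper band, values past the last break to the open-ended
    terminal band."""
    if minutes < 0 or math.isnan(minutes):
        raise ValueError(f"invalid travel time {minutes!r}")
    br = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(br, br[1:])) or br[0] <= 0:
        raise ValueError("breaks must be strictly increasing and positive")
    idx = int(np.searchsorted(br, minutes, side="right"))
    return band_label(idx, br, unit)


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    max: float
    n: int


def summarize_group(values) -> GroupSummary:
    """Arithmetic mean, sample standard deviation (n-1) and maximum."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no values to summarize")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(mean=float(np.mean(arr)), sd=sd,
                        max=float(np.max(arr)), n=int(arr.size))


def car_accessibility(bundle: RegionBundle, groups=None,
                      breaks=DEFAULT_CAR_BREAKS,
                      snap_tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M
                      ) -> pd.DataFrame:
    """End-to-end car pipeline for a region bundle.

    Returns a tidy frame with one row per district x group: minutes, km,
    nearest practice id and travel-time band.
    """
    if groups is None:
        groups = sorted({p.group for p in bundle.practices})
    graph = build_car_graph(bundle.network)
    odm = od_cost_matrix(graph, bundle.district_centroids(),
                         {p.id: p.location for p in bundle.practices},
                         snap_tolerance_m)
    frames = []
    for group in groups:
        near = nearest_practice(odm, bundle.practices, group)
        near = near.assign(
            group=group,
            band=[band_assign(m, breaks) if not pd.isna(m) else None
                  for m in near["minutes"]])
        frames.append(near.reset_index())
    return pd.concat(frames, ignore_index=True)
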