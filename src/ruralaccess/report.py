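"""Population-weighted tabulation, group comparison and map layers.

Per-district travel times are tabulated into half-open time bands with
district and inhabitant counts and percentages (integer, mirroring printed
tables whose rounded columns may sum to 99-101, and exact to one decimal).
Physician groups are compared with the tie-corrected Kruskal-Wallis test and
a rank-based Tukey-type (Nemenyi) post-hoc procedure, Dunn-Bonferroni as an
alternative.  Thiessen (Voronoi) polygons around district centroids paint
district-level results as a gap-free partition of the study extent.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .car import band_assign, band_label
from .transit import NO_CONNECTION

#: default public-transport round-trip bands: 1-hour steps up to >= 5 h
DEFAULT_PT_BREAKS_MIN = (60.0, 120.0, 180.0, 240.0, 300.0)

TOTAL_ROW = "Total"


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10.0 ** decimals
    return math.floor(x * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# Zone tables
# ---------------------------------------------------------------------------


def zone_table(values_min: dict, populations: dict, breaks,
               no_connection: set | None = None, unit: str = "min"
               ) -> pd.DataFrame:
    """Travel-time band table with district and inhabitant counts.

    ``values_min`` maps district id to a travel time in minutes; districts in
    ``no_connection`` (or with a missing/NaN value) fall into a NO_CONNECTION
    row.  Percentages are reported exact to one decimal (``pct_*``) and as
    half-up-rounded integers (``pct_*_int``), whose sum may deviate from 100.
    """
    no_connection = set(no_connection or ())
    ids = sorted(populations)
    missing = [i for i in ids if i not in values_min and i not in no_connection]
    if missing:
        raise ValueError(f"districts without value or NO_CONNECTION flag: "
                         f"{missing[:5]}")
    for i in values_min:
        if i not in populations:
            raise ValueError(f"missing population for district {i!r}")

    br = list(breaks)
    labels = [band_label(k, br, unit) for k in range(len(br) + 1)]
    counts = {lab: [0, 0] for lab in labels}
    nc = [0, 0]
    for i in ids:
        pop = populations[i]
        v = values_min.get(i)
        if i in no_connection or v is None or (isinstance(v, float)
                                               and math.isnan(v)):
            nc[0] += 1
            nc[1] += pop
        else:
            lab = band_assign(v, br, unit)
            counts[lab][0] += 1
            counts[lab][1] += pop

    n_total = len(ids)
    pop_total = sum(populations.values())
    rows = []
    for lab in labels:
        nd, ni = counts[lab]
        rows.append((lab, nd, ni))
    if nc != [0, 0] or no_connection:
        rows.append((NO_CONNECTION, nc[0], nc[1]))
    out = pd.DataFrame(rows, columns=["band", "n_districts", "n_inhabitants"])
    out["pct_districts"] = [
        _round_half_up(100.0 * n / n_total, 1) for n in out["n_districts"]]
    out["pct_inhabitants"] = [
        _round_half_up(100.0 * n / pop_total, 1) for n in out["n_inhabitants"]]
    out["pct_districts_int"] = [
        int(_round_half_up(100.0 * n / n_total)) for n in out["n_districts"]]
    out["pct_inhabitants_int"] = [
        int(_round_half_up(100.0 * n / pop_total))
        for n in out["n_inhabitants"]]
    total = pd.DataFrame([(TOTAL_ROW, n_total, pop_total,
                           100.0, 100.0,
                           int(out["pct_districts_int"].sum()),
                           int(out["pct_inhabitants_int"].sum()))],
                         columns=out.columns)
    return pd.concat([out, total], ignore_index=True)


def zone_table_from_counts(labels, district_counts, inhabitant_counts,
                           no_connection: tuple[int, int] | None = None
                           ) -> pd.DataFrame:
    """Build a zone table directly from printed per-band counts.

    Used to recompute the proportion arithmetic of published tables, where
    only band counts (not per-district values) are available.
    ``no_connection`` is an optional (districts, inhabitants) pair.
    """
    rows = list(zip(labels, district_counts, inhabitant_counts))
    if no_connection is not None:
        rows.append((NO_CONNECTION, no_connection[0], no_connection[1]))
    out = pd.DataFrame(rows, columns=["band", "n_districts", "n_inhabitants"])
    n_total = int(out["n_districts"].sum())
    pop_total = int(out["n_inhabitants"].sum())
    out["pct_districts"] = [
        _round_half_up(100.0 * n / n_total, 1) for n in out["n_districts"]]
    out["pct_inhabitants"] = [
        _round_half_up(100.0 * n / pop_total, 1) for n in out["n_inhabitants"]]
    out["pct_districts_int"] = [
        int(_round_half_up(100.0 * n / n_total)) for n in out["n_districts"]]
    out["pct_inhabitants_int"] = [
        int(_round_half_up(100.0 * n / pop_total))
        for n in out["n_inhabitants"]]
    total = pd.DataFrame([(TOTAL_ROW, n_total, pop_total, 100.0, 100.0,
                           int(out["pct_districts_int"].sum()),
                           int(out["pct_inhabitants_int"].sum()))],
                         columns=out.columns)
    return pd.concat([out, total], ignore_index=True)


def cumulative_share(table: pd.DataFrame, up_to_band: str,
                     of: str = "inhabitants") -> float:
    """Exact cumulative percentage of districts/inhabitants in all bands up
    to and including ``up_to_band`` (band order as tabulated)."""
    body = table[table["band"] != TOTAL_ROW]
    bands = list(body["band"])
    if up_to_band not in bands:
        raise ValueError(f"unknown band {up_to_band!r}; have {bands}")
    k = bands.index(up_to_band)
    col = f"n_{of}"
    total = int(body[col].sum())
    part = int(body[col].iloc[: k + 1].sum())
    return 100.0 * part / total


# ---------------------------------------------------------------------------
# Group comparison: Kruskal-Wallis + rank-based post hoc
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    h: float
    df: int
    p_value: float
    pairwise: pd.DataFrame  # adjusted p-values, symmetric, NaN diagonal
    significant: pd.DataFrame  # boolean flags at alpha
    method: str
    alpha: float


def kruskal_wallis(groups: dict, alpha: float = 0.05,
                   post_hoc: str = "nemenyi") -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value and pairwise
    post-hoc comparisons.

    ``post_hoc``: ``"nemenyi"`` (rank-based Tukey-type, studentized-range
    distribution) or ``"dunn"`` (z tests with Bonferroni correction).
    All-identical pooled values yield H = 0, p = 1, no significant pair.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [np.asarray(list(groups[g]), dtype=float) for g in names]
    for g, s in zip(names, samples):
        if s.size < 1:
            raise ValueError(f"group {g!r} is empty")
        if np.isnan(s).any():
            raise ValueError(f"group {g!r} contains NaN")
    pooled = np.concatenate(samples)
    k = len(names)
    df = k - 1

    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = scipy.stats.kruskal(*samples)
        h, p = float(h), float(p)

    n = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    sizes = [s.size for s in samples]
    mean_ranks = []
    pos = 0
    for sz in sizes:
        mean_ranks.append(float(ranks[pos:pos + sz].mean()))
        pos += sz

    # tie correction term for Dunn's z statistic
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))

    padj = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a in range(k):
        for b in range(a + 1, k):
            diff = abs(mean_ranks[a] - mean_ranks[b])
            inv = 1.0 / sizes[a] + 1.0 / sizes[b]
            if np.all(pooled == pooled[0]):
                p_ab = 1.0
            elif post_hoc == "nemenyi":
                se = math.sqrt(n * (n + 1) / 12.0 * inv)
                q = diff / se * math.sqrt(2.0)
                p_ab = float(scipy.stats.studentized_range.sf(q, k, np.inf))
            elif post_hoc == "dunn":
                se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * inv)
                z = diff / se if se > 0 else 0.0
                m = k * (k - 1) / 2.0
                p_ab = float(min(1.0, 2.0 * scipy.stats.norm.sf(z) * m))
            else:
                raise ValueError(f"unknown post_hoc {post_hoc!r}")
            padj.iat[a, b] = padj.iat[b, a] = p_ab
    sig = padj < alpha
    np.fill_diagonal(sig.values, False)
    return GroupComparison(h=h, df=df, p_value=p, pairwise=padj,
                           significant=sig, method=post_hoc, alpha=alpha)


# ---------------------------------------------------------------------------
# Thiessen (Voronoi) polygons
# ---------------------------------------------------------------------------


def thiessen_polygons(centroids: dict, extent: tuple[float, float, float, float]
                      ) -> dict:
    """Voronoi partition of a rectangular extent around seed points.

    Returns ``{id: shapely Polygon}``; polygons tile the extent without gaps
    or overlaps (up to numerical tolerance) and each contains its seed.
    Implemented by reflecting the seeds across the four extent edges so every
    core Voronoi cell is finite, then clipping to the extent.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    ids = sorted(centroids)
    pts = np.array([centroids[i] for i in ids], dtype=float)
    if len(ids) == 0:
        raise ValueError("need at least one centroid")
    for i, (x, y) in zip(ids, pts):
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"centroid {i!r} outside the extent")
    uniq = {(float(x), float(y)) for x, y in pts}
    if len(uniq) < len(ids):
        raise ValueError("duplicate centroids")
    rect = box(xmin, ymin, xmax, ymax)
    if len(ids) == 1:
        return {ids[0]: rect}

    reflections = [
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ]
    allpts = np.vstack([pts] + reflections)
    vor = Voronoi(allpts)
    out = {}
    for k, i in enumerate(ids):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or len(region) < 3:  # pragma: no cover
            raise RuntimeError(f"unbounded Voronoi cell for {i!r}")
        poly = Polygon(vor.vertices[region]).intersection(rect)
        out[i] = poly
    return out


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def render_report(out_dir: str, zone_tables: dict | None = None,
                  comparisons: dict | None = None, polygons: dict | None = None,
                  polygon_bands: dict | None = None) -> list[str]:
    """Write zone tables (CSV), group comparisons (CSV + Markdown) and
    Thiessen polygons (GeoJSON, with a band attribute when given).

    Deterministic: inputs are written in sorted key order.  Returns the list
    of files written.
    """
    from .synthetic_region import write_geojson

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name in sorted(zone_tables or {}):
        path = os.path.join(out_dir, f"zones_{name}.csv")
        zone_tables[name].to_csv(path, index=False)
        written.append(path)
    md_lines = []
    for name in sorted(comparisons or {}):
        comp = comparisons[name]
        path = os.path.join(out_dir, f"comparison_{name}.csv")
        comp.pairwise.to_csv(path)
        written.append(path)
        md_lines.append(f"## {name}\n")
        md_lines.append(f"Kruskal-Wallis H = {comp.h:.3f}, "
                        f"df = {comp.df}, p = {comp.p_value:.3g} "
                        f"(post hoc: {comp.method}, alpha = {comp.alpha})\n")
        for a in comp.pairwise.index:
            for b in comp.pairwise.columns:
                if a < b:
                    flag = ("significant"
                            if bool(comp.significant.at[a, b])
                            else "not significant")
                    md_lines.append(
                        f"- {a} vs {b}: adj. p = "
                        f"{comp.pairwise.at[a, b]:.4g} ({flag})")
        md_lines.append("")
    if md_lines:
        path = os.path.join(out_dir, "comparisons.md")
        with open(path, "w") as fh:
            fh.write("\n".join(md_lines))
        written.append(path)
    if polygons:
        feats = []
        for key in sorted(polygons):
            props = {"id": key}
            if polygon_bands and key in polygon_bands:
                props["band"] = polygon_bands[key]
            feats.append((polygons[key], props))
        path = os.path.join(out_dir, "thiessen.geojson")
        write_geojson(feats, path)
        written.append(path)
    return written
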