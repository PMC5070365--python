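# Methods

This note documents the models behind `ruralaccess`, the parameters that
matter, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Problem setting

The unit of analysis is the **population district**: its centroid is the
origin of every trip, its resident count the weight of every tabulation.
Destinations are physician practices in four groups — general practitioners
(GPs), internists, ophthalmologists, urologists — including practices in a
buffer ring around the core region, so that districts near the border are
not artificially cut off from a closer provider outside it.  The outcome per
district and group is the travel time to the *nearest* practice: one-way
minutes by car, and round-trip minutes by public transport (or
`NO_CONNECTION`).

## Car model

The street network is a directed graph; an edge of length `L` metres with
speed class `v` km/h costs `3.6·L/v` seconds.  Speed classes are free-flow:
congestion, rush hours, turn restrictions and parking-search time are out of
scope.  One-way segments are traversable in a single direction by car and in
both directions on foot.

Origins and destinations snap to the nearest street node within a 500 m
tolerance (configurable; points beyond it are excluded with a warning).
Dijkstra labels carry `(time, distance)` lexicographically, so the reported
kilometres are measured **along the time-optimal path**, with ties between
equal-time paths broken toward shorter distance.  Whether published
kilometre figures for such analyses are path lengths of time-optimal routes
or separately optimized distances is generally ambiguous; this package
commits to the former and states it here.

Travel-time zones use half-open bands `[a, b)` over breaks 5/10/15/20
minutes: a value exactly on a break belongs to the upper band (a "5 to <10"
label dictates this), and everything past the last break falls into the
open-ended terminal band.  Group summaries are the arithmetic mean, the
sample standard deviation (n−1) and the maximum.

## Public-transport model

The traveller is elderly: walking speed 1.8 km/h, half the conventional
1 m/s (3.6 km/h).  Walking time in minutes is `0.06·d/v` for `d` metres at
`v` km/h.  The appointment is at 11:00 on a school-day Tuesday and lasts one
hour (not counted as travel); travel may start at 07:00, the return starts
no earlier than 12:00, and home arrival must be by midnight.  Clock times
are integer seconds since service-day midnight with no overnight
wraparound: vehicle trips arriving after 24:00 are ignored.

Walking caps (all street-network distances, not Euclidean; a snapped
point's straight-line offset to its street node is included):

| walk                              | cap     |
|-----------------------------------|---------|
| district centre → boarding stop   | 1,000 m |
| alighting stop → practice         | 500 m   |
| between stops at a vehicle change | 250 m   |
| district centre → practice direct | 1,000 m |

Per district only the **three nearest in-cap stops** are candidate boarding
points — the nearest stop does not necessarily provide the fastest
connection, but considering all stops would be redundant with these caps.

**Walk legs strictly alternate with vehicle legs.**  The access walk ends at
the boarding stop; a transfer walk is allowed only directly after alighting;
the egress walk starts at the final alighting stop.  Chained walks (e.g.
alight, 250 m transfer walk, then 500 m egress walk from a different stop)
are disallowed: each cap is defined relative to a boarding or alighting
event, and chaining would construct pedestrian legs longer than any single
cap permits.  The routing search carries a walked-since-last-ride bit to
enforce this.

**Time-expanded graph.**  Nodes are (stop, clock-time) events taken from the
timetable of the chosen service day; edges are rides (consecutive stop
events of a trip), waits (consecutive time points at one stop) and transfer
walks (landing on the first time point at the target stop at or after
arrival there, so transfer waiting always reflects the actual timetable —
there is no fixed minimum-transfer buffer beyond the walk itself).

**Objective.**  Among all feasible journeys in the window, the one of
minimum *duration* — arrival at the destination minus departure from the
origin — wins; ties go to the latest departure, then the fewest boardings.
The traveller leaves home exactly in time to catch the chosen vehicle, so
waiting at the origin stop never inflates the duration, and waiting at the
practice before the appointment is not counted (an `AccessParams.
count_practice_wait` switch restores the stricter reading in which the
outbound leg runs until the appointment).  The implementation is a profile
search: one earliest-arrival run per candidate boarding event, cached and
shared across districts and practices.

**Round trip.**  Outbound within [07:00, 11:00], return within
[12:00, 24:00]; "return starts at 12" is read as noon — the appointment
(11:00 + 1 h) ends then, and midnight is already the home-arrival bound, so
no other reading is self-consistent.  `total = outbound + return`.  When the
practice lies within the 1,000 m direct-walk cap, a pure walking round trip
is permitted and the smaller of walk-only and transit totals is reported
(`allow_direct_walk=False` restores the strict always-transit reading).
A district is `NO_CONNECTION` for a group iff no practice of that group
admits both legs.

## Statistics and map layers

Zone tables report band counts of districts and inhabitants with
percentages both exact to one decimal and as half-up-rounded integers
(mirroring printed tables, where the integer columns may sum to 99–101; the
package reports both precisions rather than forcing the sum to 100).
Cumulative shares are computed from the raw counts, not the rounded
percentages.

Group differences use the tie-corrected Kruskal–Wallis H with the
chi-square approximation (df = groups − 1); all-identical pooled values
yield H = 0, p = 1.  The post-hoc procedure is rank-based **Nemenyi**
(Tukey-type, studentized-range distribution on mean-rank differences,
α = 0.05) — a "Kruskal–Wallis followed by a Tukey correction" is not a fully
specified method, so the Tukey-type rank procedure is the default and
Dunn–Bonferroni is available as an alternative (`post_hoc="dunn"`).

Thiessen (Voronoi) polygons partition the rectangular study extent around
district centroids: seeds are reflected across the four extent edges so
every core cell is finite, then clipped to the extent.  The partition is
gap- and overlap-free up to numerical tolerance (the test suite checks area
conservation at 10⁻⁶ relative tolerance and nearest-seed membership by
Monte-Carlo sampling); duplicate centroids are rejected.

## Synthetic regions

The generator stands in for proprietary street, population, practice and
timetable data.  All randomness flows from one seed; a fixed config
reproduces a byte-identical bundle.

- **Street network**: a perturbed lattice (spacing ≤ 800 m so the 1 km
  walking cap spans adjacent junctions) with ~18 % random edge pruning under
  a spanning-tree connectivity guarantee; three speed classes (30/70/100
  km/h) with secondary roads on every fourth grid line and one central
  motorway-like trunk; ~3 % of segments one-way, with flags cleared where
  they would break car strong connectivity.  Coordinates are planar metres
  in an arbitrary projected frame — the study region is small enough that
  no geodesy is needed.
- **Districts**: centroids jittered around distinct street nodes of the
  core extent; populations drawn log-normal (σ = 1.3, heavily skewed) and
  largest-remainder-rounded so they sum *exactly* to the configured total,
  each district at least 1.
- **Practices**: GPs uniformly across districts; specialists drawn without
  replacement with probability ∝ population², clustering them in towns;
  ~10 % extra providers per group placed in the buffer ring.  Default core
  counts (GP 160, internist 25, ophthalmologist 18, urologist 8 at full
  scale) are not published for the study region; they were chosen once as
  realistic for a rural county of ~240,000 inhabitants, ordered by group
  utilization, and give the observed ordering of travel times (GPs closest,
  urologists farthest) by construction.
- **Timetables**: hub-and-spoke — each route follows the street shortest
  path from the most populous district to the most populous district not
  yet served by a stop, with stops at street nodes every 400–800 m (hence
  always within 50 m of a street node); school-day service 06:00–20:00 at
  the base headway, vacation service 07:00–19:00 at twice the headway
  (rural transport is organized around school traffic); in-vehicle speed
  40 km/h plus 30 s dwell.  GTFS text files (stops, routes, trips,
  stop_times, calendar) are the interchange format; the planar metre
  coordinates are stored in the stop_lat/stop_lon columns of the arbitrary
  projected frame.

**What the generator does not emulate.**  Real settlement geography
(villages string along roads; the lattice scatters them), the density of a
17-company regional network, demand-responsive and school-special services,
fares and capacity, turn restrictions, and the aggregation step from raw
municipalities to analysis districts.  Synthetic transit coverage is much
sparser than in the real region, so the absolute `NO_CONNECTION` shares of
generated regions are far larger than published ones; the per-group
*orderings* (GPs best served, urologists worst) and every structural
invariant are reproduced, and only those are asserted by the tests.
Passing tests therefore validate the algorithms and the qualitative
pattern, not absolute regional travel times, which depend on proprietary
inputs.

## Problem sizes and defaults

The full-scale default config (464 districts, 239,102 inhabitants,
63 × 63 km core, 15 km buffer, 17 routes) matches the study region's scale
and generates in under a second.  The bundled `demo_config` — 100 districts,
51,500 inhabitants on a 30 × 30 km core, 35/10/8/4 practices, 8 routes at
hourly headway — is the package's own choice of a region that exercises
every pipeline stage end to end in seconds, and is what the test suite and
the acceptance script run.  Routing caches earliest-arrival profiles per
boarding event, so batch queries over all district × practice pairs share
almost all of their work.

## Known limitations

- Distance figures follow time-optimal paths; no separately
  distance-optimal OD matrix is computed.
- The event-graph search minimizes duration per boarding event; with
  `count_practice_wait=True` the profile over boarding events still
  enumerates all candidates, so the switch only changes the reported
  outbound minutes, not feasibility.
- Nemenyi p-values use the studentized-range tail without a tie
  correction (Dunn's z does correct for ties); exact replication of any
  particular commercial statistics package is not attempted beyond the
  chi-square approximation.
- Percentages are half-up rounded; banker's rounding would change integer
  columns by at most one point.
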