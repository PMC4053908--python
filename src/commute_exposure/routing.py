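"""Route simulation: shortest paths by distance, trip completion, filters."""

from __future__ import annotations

import copy
import math
from collections import Counter

import networkx as nx
import numpy as np
from scipy import stats

from .models import Leg, RoadNetwork, Route, Subject, Trip, Wait, polyline_length
from .synthetic import MODE_SPEEDS_KMH

#: Maximum snap distance from a geocode to a network node (metres).
SNAP_TOLERANCE_M = 50.0


class RoutingError(ValueError):
    pass


class DisconnectedError(RoutingError):
    pass


class DegenerateTripError(RoutingError):
    pass


def shortest_route(network: RoadNetwork, origin: int, destination: int) -> Route:
    """Minimum-total-length path between two nodes.

    Distance (road segment length) is the cost factor.  Ties are broken
    deterministically: among all minimum-length paths the lexicographically
    smallest node sequence wins.
    """
    if origin == destination:
        raise DegenerateTripError(
            f"degenerate trip: origin and destination are the same node ({origin})"
        )
    g = network.to_graph()
    if origin not in g or destination not in g:
        raise RoutingError(f"origin {origin} or destination {destination} not on network")
    try:
        dist_to_dest = nx.single_source_dijkstra_path_length(g, destination, weight="length")
    except nx.NetworkXError as e:  # pragma: no cover - defensive
        raise RoutingError(str(e)) from e
    if origin not in dist_to_dest:
        raise DisconnectedError(f"disconnected: no path from {origin} to {destination}")

    # greedy descent on the distance-to-destination field yields the
    # lexicographically smallest shortest path without enumerating ties
    total = dist_to_dest[origin]
    path = [origin]
    u = origin
    while u != destination:
        best = None
        for v in g.neighbors(u):
            if v not in dist_to_dest:
                continue
            w = g[u][v]["length"]
            if math.isclose(dist_to_dest[u], w + dist_to_dest[v], rel_tol=1e-12, abs_tol=1e-9):
                if best is None or v < best:
                    best = v
        if best is None:  # pragma: no cover - defensive
            raise RoutingError("shortest-path reconstruction failed")
        path.append(best)
        u = best

    seg_ids: list[int] = []
    points: list[tuple[float, float]] = []
    for a, b in zip(path[:-1], path[1:]):
        sid = g[a][b]["segment_id"]
        seg = network.segment_by_id(sid)
        pts = list(seg.points)
        if _close(pts[0], network.nodes[b]):  # orient a -> b
            pts = pts[::-1]
        if points:
            pts = pts[1:]
        points.extend(pts)
        seg_ids.append(sid)
    return Route(segment_ids=seg_ids, points=points, total_length=float(total))


def _close(p, q, tol=1e-6):
    return math.hypot(p[0] - q[0], p[1] - q[1]) <= tol


def snap_to_node(network: RoadNetwork, xy: tuple[float, float]) -> int:
    """Nearest network node within SNAP_TOLERANCE_M, else RoutingError."""
    nid, d = network.nearest_node(xy)
    if d > SNAP_TOLERANCE_M:
        raise RoutingError(f"location {xy} is {d:.1f} m from the nearest node (> {SNAP_TOLERANCE_M} m)")
    return nid


def route_subject(network: RoadNetwork, subject: Subject) -> Subject:
    """Fill in leg geometry, lengths, durations and sequential start times."""
    for trip in subject.trips:
        t = float(trip.start_min)
        wait_iter = iter(trip.waits)
        for k, leg in enumerate(trip.legs):
            route = shortest_route(network, leg.origin_node, leg.dest_node)
            leg.points = route.points
            leg.length_m = route.total_length
            leg.start_min = int(round(t))
            speed = MODE_SPEEDS_KMH[leg.mode] * 1000.0 / 60.0  # m/min
            leg.duration_min = max(leg.length_m / speed, 0.1)
            t += leg.duration_min
            if k < len(trip.legs) - 1:
                try:
                    wait = next(wait_iter)
                except StopIteration:
                    wait = None
                if wait is not None:
                    wait.start_min = int(round(t))
                    t += wait.duration_min
    return subject


def route_population(network: RoadNetwork, subjects: list[Subject]) -> list[Subject]:
    return [route_subject(network, s) for s in subjects]


def complete_trips(subject: Subject) -> Subject:
    """Duplicate the unmatched trip of an odd home/work trip set.

    The mirrored trip has reversed geometry and reversed leg order, modes
    preserved; its start time is the reported leave time of the opposite
    location.  Idempotent: even trip counts pass through unchanged.
    """
    subject = copy.deepcopy(subject)
    n = len(subject.trips)
    if n == 0 or n % 2 == 0:
        return subject
    outbound = sum(1 for t in subject.trips if t.origin_node == subject.home_node)
    inbound = n - outbound
    if outbound > inbound:
        # mirror the last home->work trip into a work->home return
        src = next(t for t in reversed(subject.trips) if t.origin_node == subject.home_node)
        start = subject.leave_work_min
    else:
        src = next(t for t in reversed(subject.trips) if t.origin_node != subject.home_node)
        start = subject.leave_home_min
    mirrored = _mirror_trip(src, start, new_trip_id=max(t.id for t in subject.trips) + 1)
    subject.trips.append(mirrored)
    return subject


def _mirror_trip(trip: Trip, start_min: int, new_trip_id: int) -> Trip:
    new = Trip(
        id=new_trip_id,
        origin_node=trip.dest_node,
        dest_node=trip.origin_node,
        start_min=start_min,
    )
    t = float(start_min)
    legs = list(reversed(trip.legs))
    waits = list(reversed(trip.waits))
    for k, leg in enumerate(legs):
        rev = Leg(
            id=-leg.id - 1,  # negative ids mark duplicated legs
            subject_id=leg.subject_id,
            trip_id=new_trip_id,
            mode=leg.mode,
            origin_node=leg.dest_node,
            dest_node=leg.origin_node,
            points=list(reversed(leg.points)),
            start_min=int(round(t)),
            duration_min=leg.duration_min,
            road_class=leg.road_class,
            length_m=leg.length_m,
        )
        new.legs.append(rev)
        t += rev.duration_min
        if k < len(legs):
            if k < len(waits):
                w = waits[k]
                new.waits.append(
                    Wait(location=w.location, start_min=int(round(t)),
                         duration_min=w.duration_min, road_class=w.road_class)
                )
                if k < len(legs) - 1:
                    t += w.duration_min
    # waits list must have one entry fewer than legs
    new.waits = new.waits[: max(len(new.legs) - 1, 0)]
    return new


def filter_subjects(
    subjects: list[Subject], extent: tuple[float, float, float, float]
) -> tuple[list[Subject], Counter]:
    """Apply the inclusion criteria; returns (kept, rejection reason counts).

    Criteria: home and work inside the study extent and not the same
    place; at least one reported trip; geocode quality at house or street
    level.
    """
    xmin, ymin, xmax, ymax = extent

    def inside(xy):
        return xmin <= xy[0] <= xmax and ymin <= xy[1] <= ymax

    kept: list[Subject] = []
    reasons: Counter = Counter()
    for s in subjects:
        if not (inside(s.home_xy) and inside(s.work_xy)):
            reasons["outside_area"] += 1
        elif s.home_node == s.work_node or _close(s.home_xy, s.work_xy):
            reasons["same_place"] += 1
        elif not s.trips:
            reasons["no_trip"] += 1
        elif s.geocode_quality not in ("house", "street"):
            reasons["geocode_quality"] += 1
        else:
            kept.append(s)
    return kept, reasons


def distance_agreement(reported: list[float], routed: list[float]) -> float:
    """Unadjusted R^2 of a simple linear fit of routed on reported distances."""
    reported = np.asarray(reported, dtype=float)
    routed = np.asarray(routed, dtype=float)
    if reported.shape != routed.shape or reported.size < 3:
        raise ValueError("need equal-length inputs with at least 3 pairs")
    if np.var(reported) == 0:
        raise ValueError("reported distances have zero variance")
    res = stats.linregress(reported, routed)
    return float(res.rvalue**2)
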