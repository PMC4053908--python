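"""Road classification of commuter legs.

Each leg gets a single main/side class from the longest overlapped road
segment; legs that do not coincide with the network (e.g. tram tracks)
are classified from segment lengths within a 15 m buffer.
"""

from __future__ import annotations

from collections import defaultdict

import shapely
from shapely import LineString, Point, STRtree

from .models import Leg, RoadNetwork, Subject, Wait

#: Distance below which a leg piece is considered to lie on a segment.
ON_NETWORK_TOLERANCE_M = 5.0
#: Buffer for off-network (e.g. rail-bound public transport) legs.
OFFNETWORK_BUFFER_M = 15.0


class UnclassifiableLegError(ValueError):
    pass


def _segment_tree(network: RoadNetwork) -> tuple[STRtree, list]:
    geoms = [LineString(seg.points) for seg in network.segments]
    return STRtree(geoms), geoms


def classify_leg(leg: Leg, network: RoadNetwork) -> str:
    """Main/side class of the segment with the greatest overlapped length.

    Each vertex-to-vertex piece of the leg is attributed to the nearest
    segment within 5 m; pieces farther away fall back to the buffer rule.
    Ties go to main.
    """
    if len(leg.points) < 2:
        return classify_offnetwork_leg(leg, network)
    tree, geoms = _segment_tree(network)
    overlap: dict[int, float] = defaultdict(float)
    for p, q in zip(leg.points[:-1], leg.points[1:]):
        piece = LineString([p, q])
        if piece.length == 0:
            continue
        # attribute by the piece midpoint: pieces touching a junction are
        # at distance 0 from two segments, the midpoint disambiguates
        mid = piece.interpolate(0.5, normalized=True)
        idx = tree.nearest(mid)
        if geoms[idx].distance(mid) <= ON_NETWORK_TOLERANCE_M:
            overlap[int(idx)] += piece.length
    if not overlap:
        return classify_offnetwork_leg(leg, network)
    best_len = max(overlap.values())
    top = [network.segments[i].road_class for i, ln in overlap.items() if ln >= best_len - 1e-9]
    return "main" if "main" in top else "side"


def classify_offnetwork_leg(
    leg: Leg, network: RoadNetwork, buffer_m: float = OFFNETWORK_BUFFER_M
) -> str:
    """Class with the greatest total segment length inside the leg buffer."""
    geom = LineString(leg.points) if len(leg.points) >= 2 else Point(leg.points[0])
    buf = geom.buffer(buffer_m)
    by_class: dict[str, float] = defaultdict(float)
    for seg in network.segments:
        inter = LineString(seg.points).intersection(buf)
        if not inter.is_empty:
            by_class[seg.road_class] += inter.length
    if not by_class:
        raise UnclassifiableLegError(
            f"leg {leg.id}: no road segment within {buffer_m} m buffer"
        )
    main_len = by_class.get("main", 0.0)
    side_len = by_class.get("side", 0.0)
    return "main" if main_len >= side_len else "side"


def classify_wait(wait: Wait, network: RoadNetwork, buffer_m: float = OFFNETWORK_BUFFER_M) -> str:
    """Class of the nearest segment within 15 m of the wait location; side if none."""
    pt = Point(wait.location)
    tree, geoms = _segment_tree(network)
    idx = tree.nearest(pt)
    if geoms[idx].distance(pt) <= buffer_m:
        return network.segments[int(idx)].road_class
    return "side"


def classify_subjects(subjects: list[Subject], network: RoadNetwork) -> list[Subject]:
    """Annotate every leg and wait of every subject in place."""
    for s in subjects:
        for trip in s.trips:
            for leg in trip.legs:
                leg.road_class = classify_leg(leg, network)
            for wait in trip.waits:
                wait.road_class = classify_wait(wait, network)
    return subjects
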