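"""The exposure engine.

Per-cell path lengths of a leg across a raster, length-weighted leg
concentrations, duration-weighted subject concentration and cumulative
exposure including waiting times, time-weighted exposure, and
ventilation-adjusted dose.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .models import (
    VENTILATION_RATIOS,
    ConcentrationGrid,
    GridExtentError,
    Leg,
    RatioTable,
    Subject,
    Wait,
)
from .temporal import lookup_ratio


def cell_path_lengths(
    points: Sequence[tuple[float, float]], grid: ConcentrationGrid
) -> list[tuple[tuple[int, int], float]]:
    """Exact in-cell lengths of a polyline clipped to each traversed cell.

    Returns [((col, row), length_m), ...] with the lengths summing to the
    polyline arc length.  Every vertex must lie inside the grid extent;
    geometry on the exact top/right boundary belongs to the last cell.
    """
    pts = [(float(x), float(y)) for x, y in points]
    for x, y in pts:
        if not grid.contains(x, y):
            raise GridExtentError(
                f"leg outside grid: vertex ({x}, {y}) not in extent "
                f"[{grid.x0}, {grid.xmax}] x [{grid.y0}, {grid.ymax}]"
            )
    acc: dict[tuple[int, int], float] = defaultdict(float)
    c = grid.cell_size
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        seg_len = math.hypot(x1 - x0, y1 - y0)
        if seg_len == 0:
            continue
        # parameters where the segment crosses cell boundary lines
        ts = {0.0, 1.0}
        for p0, p1, origin in ((x0, x1, grid.x0), (y0, y1, grid.y0)):
            if p0 == p1:
                continue
            lo, hi = sorted((p0, p1))
            k0 = math.ceil((lo - origin) / c)
            k1 = math.floor((hi - origin) / c)
            for k in range(k0, k1 + 1):
                t = (origin + k * c - p0) / (p1 - p0)
                if 0.0 < t < 1.0:
                    ts.add(t)
        cuts = sorted(ts)
        for ta, tb in zip(cuts[:-1], cuts[1:]):
            tm = 0.5 * (ta + tb)
            cell = grid.cell_index(x0 + tm * (x1 - x0), y0 + tm * (y1 - y0))
            acc[cell] += (tb - ta) * seg_len
    return sorted(acc.items())


def leg_concentration(leg: Leg, grid: ConcentrationGrid) -> float:
    """Length-weighted mean grid concentration along the leg.

    C_leg = sum_cells C_grid(cell) * len(cell) / sum_cells len(cell); a
    zero-length leg degrades to a point lookup of the containing cell.
    """
    pts = leg.points
    if len(pts) < 2 or all(p == pts[0] for p in pts):
        x, y = pts[0]
        return grid.value_at(x, y)
    pieces = cell_path_lengths(pts, grid)
    total = sum(ln for _, ln in pieces)
    if total == 0:
        x, y = pts[0]
        return grid.value_at(x, y)
    return sum(grid.values[j, i] * ln for (i, j), ln in pieces) / total


def _components(
    legs: Iterable[Leg], waits: Iterable[Wait], ratios: RatioTable, grid: ConcentrationGrid
) -> list[dict]:
    """Adjusted concentration, duration and metadata per leg and wait."""
    comps: list[dict] = []
    for leg in legs:
        if leg.duration_min < 0:
            raise ValueError(f"leg {leg.id}: negative duration")
        c = leg_concentration(leg, grid)
        r = lookup_ratio(ratios, leg.road_class, leg.start_hour)
        comps.append(
            {
                "kind": "leg",
                "id": leg.id,
                "mode": leg.mode,
                "road_class": leg.road_class,
                "start_hour": leg.start_hour,
                "c_raw": c,
                "ratio": r,
                "c_adjusted": c * r,
                "duration_min": float(leg.duration_min),
            }
        )
    for w in waits:
        if w.duration_min == 0:
            continue
        c = grid.value_at(*w.location)
        r = lookup_ratio(ratios, w.road_class, w.start_hour)
        comps.append(
            {
                "kind": "wait",
                "id": None,
                "mode": None,
                "road_class": w.road_class,
                "start_hour": w.start_hour,
                "c_raw": c,
                "ratio": r,
                "c_adjusted": c * r,
                "duration_min": float(w.duration_min),
            }
        )
    return comps


def subject_concentration(
    legs: Sequence[Leg], waits: Sequence[Wait], ratios: RatioTable, grid: ConcentrationGrid
) -> float:
    """Duration-weighted mean of ratio-adjusted concentrations.

    C_subject = sum(C_leg*r*t_leg + C_wait*r_w*t_wait) / sum(t_leg + t_wait).
    """
    comps = _components(legs, waits, ratios, grid)
    total = sum(c["duration_min"] for c in comps)
    if total <= 0:
        raise ValueError("total commute duration is zero")
    return sum(c["c_adjusted"] * c["duration_min"] for c in comps) / total


def subject_exposure(
    legs: Sequence[Leg], waits: Sequence[Wait], ratios: RatioTable, grid: ConcentrationGrid
) -> tuple[float, float]:
    """(E_subject, time-weighted exposure).

    E_subject = sum(C_leg*r*t_leg + C_wait*r_w*t_wait); the time-weighted
    exposure is E_subject divided by the total commute duration, and so
    coincides with C_subject.
    """
    comps = _components(legs, waits, ratios, grid)
    total = sum(c["duration_min"] for c in comps)
    if total <= 0:
        raise ValueError("total commute duration is zero")
    e = sum(c["c_adjusted"] * c["duration_min"] for c in comps)
    return e, e / total


def leg_dose(exposure: float, mode: str) -> float:
    """Ventilation-adjusted dose: exposure x 1.7 (walking), 2.0 (bicycle), 1.0 otherwise."""
    try:
        return exposure * VENTILATION_RATIOS[mode]
    except KeyError:
        raise ValueError(f"unknown travel mode {mode!r}") from None


def subject_record(
    subject: Subject, ratios: RatioTable, grid: ConcentrationGrid
) -> "ExposureRecord":
    """Full per-subject exposure record against one model grid."""
    from .models import ExposureRecord

    comps = _components(subject.all_legs(), subject.all_waits(), ratios, grid)
    total = sum(c["duration_min"] for c in comps)
    if total <= 0:
        raise ValueError(f"subject {subject.id}: total commute duration is zero")
    e = sum(c["c_adjusted"] * c["duration_min"] for c in comps)
    dose = 0.0
    for c in comps:
        part = c["c_adjusted"] * c["duration_min"]
        dose += leg_dose(part, c["mode"]) if c["kind"] == "leg" else part
        c["exposure"] = part
        c["dose"] = part * (VENTILATION_RATIOS[c["mode"]] if c["kind"] == "leg" else 1.0)
    return ExposureRecord(
        subject_id=subject.id,
        model_name=grid.model_name,
        c_subject=e / total,
        e_subject=e,
        time_weighted=e / total,
        dose=dose,
        total_duration_min=total,
        legs=comps,
    )


def compute_exposures(
    subjects: Sequence[Subject], ratios: RatioTable, grids: Sequence[ConcentrationGrid]
) -> list["ExposureRecord"]:
    """Exposure records for every subject x model grid combination."""
    return [subject_record(s, ratios, g) for g in grids for s in subjects]
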