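"""Domain types shared across the pipeline.

All coordinates are planar metres.  Clock times are stored as integer
minutes since midnight (local time, no DST handling).  Concentrations are
in µg m^-3 unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

ROAD_CLASSES = ("main", "side")
MODES = ("walking", "bicycle", "motorized", "public", "other")

#: Ventilation ratios relative to motorized / public transport, used as a
#: proxy for the mode-specific inhaled dose.
VENTILATION_RATIOS = {
    "walking": 1.7,
    "bicycle": 2.0,
    "motorized": 1.0,
    "public": 1.0,
    "other": 1.0,
}


def polyline_length(points: Sequence[tuple[float, float]]) -> float:
    """Arc length of a polyline given as a sequence of (x, y) vertices."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))))


@dataclass
class Segment:
    """One road segment between two network nodes."""

    id: int
    u: int
    v: int
    points: list[tuple[float, float]]
    road_class: str
    length: float = 0.0

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(f"road_class must be one of {ROAD_CLASSES}, got {self.road_class!r}")
        arc = polyline_length(self.points)
        if self.length == 0.0:
            self.length = arc
        elif not math.isclose(self.length, arc, rel_tol=0, abs_tol=1e-6):
            raise ValueError(
                f"segment {self.id}: declared length {self.length} differs from arc length {arc}"
            )


@dataclass
class RoadNetwork:
    """Planar road network: nodes (id -> coordinates) and classified segments."""

    nodes: dict[int, tuple[float, float]]
    segments: list[Segment]

    def to_graph(self):
        """Undirected networkx graph with edge attributes length and segment_id."""
        import networkx as nx

        g = nx.Graph()
        for nid, xy in self.nodes.items():
            g.add_node(nid, xy=xy)
        for seg in self.segments:
            # keep the shorter edge if the input ever carries parallels
            if g.has_edge(seg.u, seg.v) and g[seg.u][seg.v]["length"] <= seg.length:
                continue
            g.add_edge(seg.u, seg.v, length=seg.length, segment_id=seg.id)
        return g

    def segment_by_id(self, sid: int) -> Segment:
        for seg in self.segments:
            if seg.id == sid:
                return seg
        raise KeyError(f"no segment with id {sid}")

    def nearest_node(self, xy: tuple[float, float]) -> tuple[int, float]:
        """Nearest node id and its distance to ``xy``."""
        best, bd = None, math.inf
        for nid, (x, y) in self.nodes.items():
            d = math.hypot(x - xy[0], y - xy[1])
            if d < bd or (d == bd and (best is None or nid < best)):
                best, bd = nid, d
        if best is None:
            raise ValueError("network has no nodes")
        return best, bd


@dataclass
class Route:
    """A routed path: ordered segment ids plus concatenated geometry."""

    segment_ids: list[int]
    points: list[tuple[float, float]]
    total_length: float


@dataclass
class Leg:
    """Contiguous part of a trip covered with a single travel mode."""

    id: int
    subject_id: int
    trip_id: int
    mode: str
    origin_node: int
    dest_node: int
    points: list[tuple[float, float]] = field(default_factory=list)
    start_min: int = 0
    duration_min: float = 0.0
    road_class: str = "unset"
    length_m: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def start_hour(self) -> int:
        return (self.start_min // 60) % 24


@dataclass
class Wait:
    """Waiting period between two legs (e.g. at a public transport stop)."""

    location: tuple[float, float]
    start_min: int
    duration_min: float
    road_class: str = "unset"

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValueError("wait duration must be >= 0")

    @property
    def start_hour(self) -> int:
        return (self.start_min // 60) % 24


@dataclass
class Trip:
    """Ordered legs between home and work/school, with waits between legs."""

    id: int
    origin_node: int
    dest_node: int
    start_min: int
    legs: list[Leg] = field(default_factory=list)
    waits: list[Wait] = field(default_factory=list)  # waits[i] precedes legs[i+1]


@dataclass
class Subject:
    id: int
    home_node: int
    work_node: int
    home_xy: tuple[float, float]
    work_xy: tuple[float, float]
    geocode_quality: str = "house"  # house | street | poor
    leave_home_min: int = 7 * 60
    leave_work_min: int = 17 * 60
    main_mode: str = "walking"
    trips: list[Trip] = field(default_factory=list)

    def all_legs(self) -> list[Leg]:
        return [leg for trip in self.trips for leg in trip.legs]

    def all_waits(self) -> list[Wait]:
        return [w for trip in self.trips for w in trip.waits]


class GridExtentError(ValueError):
    """A geometry falls outside a concentration grid."""


@dataclass
class ConcentrationGrid:
    """Georeferenced annual-mean raster.

    Cell (col i, row j) covers the half-open square
    [x0 + i*c, x0 + (i+1)*c) x [y0 + j*c, y0 + (j+1)*c); row 0 is the
    bottom row.  Geometry touching the exact top/right boundary belongs to
    the last cell.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray  # shape (nrows, ncols), row 0 at the bottom
    model_name: str = "model"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def xmax(self) -> float:
        return self.x0 + self.ncols * self.cell_size

    @property
    def ymax(self) -> float:
        return self.y0 + self.nrows * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.xmax and self.y0 <= y <= self.ymax

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(col, row) of the cell containing (x, y); top/right edge clamps."""
        if not self.contains(x, y):
            raise GridExtentError(
                f"point ({x}, {y}) outside grid extent "
                f"[{self.x0}, {self.xmax}] x [{self.y0}, {self.ymax}]"
            )
        i = min(int((x - self.x0) // self.cell_size), self.ncols - 1)
        j = min(int((y - self.y0) // self.cell_size), self.nrows - 1)
        return max(i, 0), max(j, 0)

    def value_at(self, x: float, y: float) -> float:
        i, j = self.cell_index(x, y)
        return float(self.values[j, i])


@dataclass
class StationSeries:
    """30-min NO2 series from a fixed monitoring station."""

    site_type: str  # street | background
    timestamps: "object"  # pandas DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.site_type not in ("street", "background"):
            raise ValueError(f"site_type must be street or background, got {self.site_type!r}")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must align")
        if np.any(self.values < 0):
            raise ValueError("station values must be >= 0")


@dataclass
class RatioTable:
    """Hour-of-day temporal adjustment factors per road class."""

    ratio_m: np.ndarray  # main streets, 24 entries
    ratio_s: np.ndarray  # side streets, 24 entries

    def __post_init__(self) -> None:
        self.ratio_m = np.asarray(self.ratio_m, dtype=float)
        self.ratio_s = np.asarray(self.ratio_s, dtype=float)
        for name, arr in (("ratio_m", self.ratio_m), ("ratio_s", self.ratio_s)):
            if arr.shape != (24,):
                raise ValueError(f"{name} must have 24 entries, got shape {arr.shape}")
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be strictly positive")

    @classmethod
    def identity(cls) -> "RatioTable":
        return cls(np.ones(24), np.ones(24))


@dataclass
class ExposureRecord:
    """Per-subject concentration, exposure, time-weighted exposure and dose."""

    subject_id: int
    model_name: str
    c_subject: float  # duration-weighted mean concentration, µg m^-3
    e_subject: float  # cumulative exposure, µg m^-3 * min
    time_weighted: float  # e_subject / total duration == c_subject
    dose: float  # µg m^-3 * min * ventilation ratio
    total_duration_min: float
    legs: list[dict] = field(default_factory=list)  # per-leg/wait breakdown


@dataclass
class ComparisonResult:
    """Paired inter-model statistics for one model pair."""

    model_a: str
    model_b: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    spearman_rho: float
    fit_degree: int
    fit_r2: dict[int, float]
    wilcoxon_p: float
    fisher_pitman_p: float
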