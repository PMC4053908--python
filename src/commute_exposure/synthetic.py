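"""Synthetic scenario generation.

Produces every input the pipeline needs — a latent concentration field,
multi-resolution rasters sharing that field, a grid-of-streets road
network with main/side classes, a commuter population with multi-leg
trips, and station time series — with known ground-truth parameters so
recovery tests can check the downstream estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import shapely

from .models import (
    ConcentrationGrid,
    Leg,
    RatioTable,
    RoadNetwork,
    Segment,
    StationSeries,
    Subject,
    Trip,
    Wait,
)

#: Mode speeds used to derive leg durations from routed lengths (km/h).
MODE_SPEEDS_KMH = {"walking": 5.0, "bicycle": 15.0, "motorized": 30.0, "public": 20.0, "other": 5.0}

_DEFAULT_MAIN_PROFILE = [
    0.55, 0.45, 0.40, 0.40, 0.50, 0.75, 1.20, 1.55, 1.50, 1.25, 1.10, 1.05,
    1.10, 1.05, 1.05, 1.15, 1.35, 1.55, 1.45, 1.20, 1.00, 0.90, 0.75, 0.65,
]
_DEFAULT_SIDE_PROFILE = [
    0.70, 0.60, 0.55, 0.55, 0.60, 0.80, 1.10, 1.35, 1.30, 1.15, 1.05, 1.00,
    1.05, 1.00, 1.00, 1.10, 1.20, 1.35, 1.30, 1.15, 1.00, 0.95, 0.85, 0.80,
]


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    ``domain_extent`` is (xmin, ymin, xmax, ymax) in metres.  Every entry
    of ``grid_sizes`` must divide both domain side lengths, as must
    ``street_spacing``.
    """

    domain_extent: tuple[float, float, float, float] = (0.0, 0.0, 2000.0, 2000.0)
    grid_sizes: list[float] = dc_field(default_factory=lambda: [25.0, 50.0, 100.0])
    background_level: float = 23.5
    road_increment: float = 30.0
    decay_length: float = 60.0
    n_subjects: int = 100
    mode_shares: dict[str, float] = dc_field(
        default_factory=lambda: {"walking": 0.27, "bicycle": 0.30, "motorized": 0.11, "public": 0.32}
    )
    diurnal_profile: dict[str, list[float]] = dc_field(
        default_factory=lambda: {"main": list(_DEFAULT_MAIN_PROFILE), "side": list(_DEFAULT_SIDE_PROFILE)}
    )
    noise_sd: float = 2.0
    seed: int = 0
    # network shape
    street_spacing: float = 200.0
    side_street_share: float = 0.6
    # side streets carry this fraction of the main-road increment, so finer
    # rasters resolve the main/side contrast that coarser ones blur out
    side_increment_factor: float = 0.3
    # per-model additive offsets, one per grid size (defaults to zero)
    model_bias: list[float] | None = None
    # population details
    four_trip_fraction: float = 0.16
    max_wait_min: float = 10.0
    n_weekday_days: int = 260
    year: int = 2010

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.domain_extent
        w, h = xmax - xmin, ymax - ymin
        if w <= 0 or h <= 0:
            raise ValueError("domain_extent must be a non-degenerate rectangle")
        for name, v in (
            ("background_level", self.background_level),
            ("decay_length", self.decay_length),
            ("street_spacing", self.street_spacing),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.road_increment < 0:
            raise ValueError("road_increment must be >= 0")
        total = sum(self.mode_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_shares must sum to 1 (got {total})")
        for c in self.grid_sizes:
            if c <= 0:
                raise ValueError("grid sizes must be strictly positive")
            for side in (w, h):
                if abs(side / c - round(side / c)) > 1e-9:
                    raise ValueError(f"grid size {c} does not divide the domain extent {side}")
        for cls in ("main", "side"):
            prof = self.diurnal_profile.get(cls)
            if prof is None or len(prof) != 24:
                raise ValueError(f"diurnal_profile[{cls!r}] must have 24 entries")
            if any(p <= 0 for p in prof):
                raise ValueError("diurnal profile multipliers must be strictly positive")
        if not 0.0 <= self.side_street_share <= 1.0:
            raise ValueError("side_street_share must be in [0, 1]")
        if self.model_bias is not None and len(self.model_bias) != len(self.grid_sizes):
            raise ValueError("model_bias must provide one offset per grid size")

    @property
    def width(self) -> float:
        return self.domain_extent[2] - self.domain_extent[0]

    @property
    def height(self) -> float:
        return self.domain_extent[3] - self.domain_extent[1]

    def street_station_mean(self) -> float:
        """Annual mean emulated for the street station (kerbside level)."""
        return self.background_level + self.road_increment / 2.0

    def true_ratio_table(self) -> RatioTable:
        m = np.asarray(self.diurnal_profile["main"], dtype=float)
        s = np.asarray(self.diurnal_profile["side"], dtype=float)
        return RatioTable(m / m.mean(), s / s.mean())


@dataclass
class GroundTruth:
    """Parameters the generators used, kept for recovery tests."""

    latent_field: Callable[[np.ndarray, np.ndarray], np.ndarray]
    true_ratios: RatioTable
    true_model_bias: dict[str, float]


def generate_network(config: ScenarioConfig) -> RoadNetwork:
    """Grid-of-streets network over the domain.

    Nodes sit on a lattice with ``street_spacing``; every lattice line
    (row or column) is a street whose class is drawn once per line, so the
    result is always connected and planar.
    """
    xmin, ymin, xmax, ymax = config.domain_extent
    s = config.street_spacing
    nbx = round(config.width / s)
    nby = round(config.height / s)
    if abs(config.width / s - nbx) > 1e-9 or abs(config.height / s - nby) > 1e-9:
        raise ValueError("street_spacing must divide the domain extent")
    if nbx < 1 or nby < 1:
        raise ValueError(
            f"street_spacing {s} too large for domain_extent {config.domain_extent}: "
            "network would be unconnectable"
        )
    rng = np.random.default_rng(config.seed)

    def draw_class() -> str:
        return "side" if rng.random() < config.side_street_share else "main"

    row_class = [draw_class() for _ in range(nby + 1)]
    col_class = [draw_class() for _ in range(nbx + 1)]

    nodes: dict[int, tuple[float, float]] = {}
    for j in range(nby + 1):
        for i in range(nbx + 1):
            nodes[j * (nbx + 1) + i] = (xmin + i * s, ymin + j * s)

    segments: list[Segment] = []
    sid = 0
    for j in range(nby + 1):  # horizontal streets
        for i in range(nbx):
            u = j * (nbx + 1) + i
            v = u + 1
            segments.append(Segment(sid, u, v, [nodes[u], nodes[v]], row_class[j]))
            sid += 1
    for j in range(nby):  # vertical streets
        for i in range(nbx + 1):
            u = j * (nbx + 1) + i
            v = u + (nbx + 1)
            segments.append(Segment(sid, u, v, [nodes[u], nodes[v]], col_class[i]))
            sid += 1
    return RoadNetwork(nodes=nodes, segments=segments)


def latent_field_function(
    config: ScenarioConfig, network: RoadNetwork
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Latent concentration surface: background + road-proximity increment.

    f(x, y) = background
              + increment * exp(-d_main(x, y) / decay_length)
              + increment * side_increment_factor * exp(-d_side(x, y) / decay_length)

    with d_main/d_side the distances to the nearest main/side segment.
    Deterministic given the network, hence given the seed.
    """
    by_class = {
        cls: [seg.points for seg in network.segments if seg.road_class == cls]
        for cls in ("main", "side")
    }
    terms = []
    for cls, inc in (
        ("main", config.road_increment),
        ("side", config.road_increment * config.side_increment_factor),
    ):
        if by_class[cls] and inc > 0:
            terms.append((shapely.MultiLineString(by_class[cls]), inc))

    def f(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pts = shapely.points(np.stack([x.ravel(), y.ravel()], axis=-1))
        out = np.full(x.shape, config.background_level, dtype=float)
        for lines, inc in terms:
            d = shapely.distance(pts, lines).reshape(x.shape)
            out += inc * np.exp(-d / config.decay_length)
        return out

    return f


def generate_rasters(config: ScenarioConfig, network: RoadNetwork) -> list[ConcentrationGrid]:
    """One raster per grid size, all cell-area averages of one latent field.

    Averaging uses a common fine quadrature lattice nested in every cell
    size, so a coarse cell is exactly the mean of the fine cells it
    contains: resolution is the only inter-raster difference unless a
    per-model bias is configured.
    """
    xmin, ymin, _, _ = config.domain_extent
    cmin = min(config.grid_sizes)
    # fine lattice step: divides every configured cell size
    step = cmin / 4.0
    for c in config.grid_sizes:
        if abs(c / step - round(c / step)) > 1e-9:
            # fall back to a step that divides all sizes (gcd in integer units)
            units = [round(c * 1000) for c in config.grid_sizes]
            step = math.gcd(*units) / 1000.0 / 4.0
            break
    nx = round(config.width / step)
    ny = round(config.height / step)
    f = latent_field_function(config, network)
    xs = xmin + (np.arange(nx) + 0.5) * step
    ys = ymin + (np.arange(ny) + 0.5) * step
    gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
    fine = f(gx, gy)

    bias = config.model_bias or [0.0] * len(config.grid_sizes)
    grids: list[ConcentrationGrid] = []
    for c, b in zip(config.grid_sizes, bias):
        k = round(c / step)
        ncols = nx // k
        nrows = ny // k
        vals = fine[: nrows * k, : ncols * k].reshape(nrows, k, ncols, k).mean(axis=(1, 3))
        vals = vals + b
        if np.any(vals < 0):
            raise ValueError("configured model_bias drives concentrations negative")
        grids.append(
            ConcentrationGrid(
                x0=xmin, y0=ymin, cell_size=float(c), values=vals,
                model_name=f"model_{c:g}m",
            )
        )
    return grids


def _rush_hour_minutes(rng: np.random.Generator, window: tuple[int, int]) -> int:
    lo, hi = window
    return int(rng.integers(lo * 60, hi * 60))


def generate_population(config: ScenarioConfig, network: RoadNetwork) -> list[Subject]:
    """Commuter population with geo-coded multi-leg trips.

    Each subject gets distinct home and work nodes, 2 or 4 trips per day
    (4 with probability ``four_trip_fraction``), and a main travel mode
    drawn from ``mode_shares``.  Public-transport commutes are split into
    walk / public / walk legs with waits at the interchange nodes; other
    modes are single-leg trips.  Geometry and durations are filled in by
    the routing stage.
    """
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if len(network.nodes) < 2:
        raise ValueError("network must have at least 2 nodes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    node_ids = sorted(network.nodes)
    modes = sorted(config.mode_shares)
    probs = np.array([config.mode_shares[m] for m in modes], dtype=float)
    probs = probs / probs.sum()

    g = network.to_graph()
    neighbors = {n: sorted(g.neighbors(n)) for n in node_ids}

    subjects: list[Subject] = []
    leg_id = 0
    trip_id = 0
    for sidx in range(config.n_subjects):
        home, work = rng.choice(node_ids, size=2, replace=False)
        home, work = int(home), int(work)
        quality = rng.choice(["house", "street", "poor"], p=[0.90, 0.08, 0.02])
        mode = str(modes[int(rng.choice(len(modes), p=probs))])
        leave_home = _rush_hour_minutes(rng, (6, 8))
        leave_work = _rush_hour_minutes(rng, (16, 18))
        n_trips = 4 if rng.random() < config.four_trip_fraction else 2

        # trip schedule: (origin, dest, start_min)
        if n_trips == 2:
            schedule = [(home, work, leave_home), (work, home, leave_work)]
        else:
            midday_back = int(rng.integers(11 * 60 + 30, 12 * 60 + 30))
            midday_out = int(rng.integers(13 * 60, 14 * 60))
            schedule = [
                (home, work, leave_home),
                (work, home, midday_back),
                (home, work, midday_out),
                (work, home, leave_work),
            ]

        subj = Subject(
            id=sidx,
            home_node=home,
            work_node=work,
            home_xy=network.nodes[home],
            work_xy=network.nodes[work],
            geocode_quality=str(quality),
            leave_home_min=leave_home,
            leave_work_min=leave_work,
            main_mode=mode,
        )
        for origin, dest, start in schedule:
            trip = Trip(id=trip_id, origin_node=origin, dest_node=dest, start_min=start)
            trip_id += 1
            if mode == "public":
                stop_a = _pick_interchange(rng, neighbors[origin], exclude={origin, dest})
                stop_b = _pick_interchange(rng, neighbors[dest], exclude={origin, dest, stop_a})
                if stop_a is None or stop_b is None:
                    trip.legs.append(
                        Leg(leg_id, sidx, trip.id, "public", origin, dest, start_min=start)
                    )
                    leg_id += 1
                else:
                    for lmode, o, d in (
                        ("walking", origin, stop_a),
                        ("public", stop_a, stop_b),
                        ("walking", stop_b, dest),
                    ):
                        trip.legs.append(Leg(leg_id, sidx, trip.id, lmode, o, d, start_min=start))
                        leg_id += 1
                    for stop in (stop_a, stop_b):
                        trip.waits.append(
                            Wait(
                                location=network.nodes[stop],
                                start_min=start,
                                duration_min=float(rng.uniform(0.0, config.max_wait_min)),
                            )
                        )
            else:
                trip.legs.append(Leg(leg_id, sidx, trip.id, mode, origin, dest, start_min=start))
                leg_id += 1
            subj.trips.append(trip)
        subjects.append(subj)
    return subjects


def _pick_interchange(rng, candidates: list[int], exclude: set) -> int | None:
    options = [c for c in candidates if c not in exclude]
    if not options:
        return None
    return int(options[int(rng.integers(len(options)))])


def generate_station_series(config: ScenarioConfig) -> list[StationSeries]:
    """Weekday 30-min series for the street and background stations.

    Each half-hour value is annual_mean * profile[hour] / mean(profile)
    plus Gaussian noise, so the hourly-mean / annual-mean ratios recover
    the normalised profile exactly in the noiseless case.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    days = pd.bdate_range(f"{config.year}-01-01", periods=config.n_weekday_days)
    halfhours = pd.timedelta_range("0h", "23.5h", freq="30min")
    timestamps = pd.DatetimeIndex(
        np.add.outer(days.values, halfhours.values).ravel()
    )
    hours = timestamps.hour.to_numpy()

    out: list[StationSeries] = []
    for site, cls, annual_mean in (
        ("street", "main", config.street_station_mean()),
        ("background", "side", config.background_level),
    ):
        prof = np.asarray(config.diurnal_profile[cls], dtype=float)
        base = annual_mean * prof[hours] / prof.mean()
        noise = rng.normal(0.0, config.noise_sd, size=base.shape) if config.noise_sd > 0 else 0.0
        values = np.maximum(base + noise, 0.0)
        out.append(StationSeries(site_type=site, timestamps=timestamps, values=values))
    return out


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[RoadNetwork, list[ConcentrationGrid], list[Subject], list[StationSeries], GroundTruth]:
    """Generate every pipeline input for one scenario."""
    network = generate_network(config)
    grids = generate_rasters(config, network)
    subjects = generate_population(config, network)
    stations = generate_station_series(config)
    bias = config.model_bias or [0.0] * len(config.grid_sizes)
    truth = GroundTruth(
        latent_field=latent_field_function(config, network),
        true_ratios=config.true_ratio_table(),
        true_model_bias={g.model_name: b for g, b in zip(grids, bias)},
    )
    return network, grids, subjects, stations, truth
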