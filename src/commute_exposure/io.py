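"""Format round-tripping: ESRI ASCII grids, GeoJSON, CSVs, JSON manifest.

ESRI ASCII was chosen over binary rasters for diffability and
zero-dependency parsing; values are written with full repr precision so
write-then-read is exact.  NODATA value is -9999.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

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

NODATA = -9999.0


class GridParseError(ValueError):
    pass


# ---------------------------------------------------------------- ASCII grid

def write_ascii_grid(grid: ConcentrationGrid, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        f"xllcorner {grid.x0!r}",
        f"yllcorner {grid.y0!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {NODATA!r}",
    ]
    for j in range(grid.nrows - 1, -1, -1):  # ESRI rows run top to bottom
        lines.append(" ".join(repr(float(v)) for v in grid.values[j]))
    path.write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path, model_name: str | None = None) -> ConcentrationGrid:
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    keys = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")
    i = 0
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if len(parts) != 2 or parts[0].lower() not in keys:
            raise GridParseError(f"{path.name}:{i + 1}: malformed header line {line!r}")
        try:
            header[parts[0].lower()] = float(parts[1])
        except ValueError:
            raise GridParseError(f"{path.name}:{i + 1}: non-numeric header value {parts[1]!r}")
    for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if k not in header:
            raise GridParseError(f"{path.name}: missing header field {k}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for j, line in enumerate(lines[6 : 6 + nrows]):
        vals = line.split()
        if len(vals) != ncols:
            raise GridParseError(
                f"{path.name}:{j + 7}: expected {ncols} values, found {len(vals)}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise GridParseError(f"{path.name}:{j + 7}: non-numeric cell value")
    if len(rows) != nrows:
        raise GridParseError(f"{path.name}: expected {nrows} data rows, found {len(rows)}")
    values = np.asarray(rows[::-1], dtype=float)  # back to bottom-up rows
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return ConcentrationGrid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        model_name=model_name or path.stem,
    )


# ------------------------------------------------------------------- GeoJSON

def network_to_geojson(network: RoadNetwork) -> dict:
    features = []
    for seg in network.segments:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(p) for p in seg.points]},
                "properties": {
                    "feature_type": "segment",
                    "id": seg.id,
                    "u": seg.u,
                    "v": seg.v,
                    "road_class": seg.road_class,
                    "length_m": seg.length,
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "features": features,
        "nodes": {str(k): list(v) for k, v in network.nodes.items()},
    }


def network_from_geojson(obj: dict) -> RoadNetwork:
    nodes = {int(k): (float(v[0]), float(v[1])) for k, v in obj.get("nodes", {}).items()}
    segments = []
    for feat in obj["features"]:
        p = feat["properties"]
        if p.get("feature_type") != "segment":
            continue
        pts = [tuple(map(float, c)) for c in feat["geometry"]["coordinates"]]
        segments.append(
            Segment(
                id=int(p["id"]), u=int(p["u"]), v=int(p["v"]),
                points=pts, road_class=p["road_class"],
            )
        )
    if not nodes:  # reconstruct endpoints if node table absent
        for seg in segments:
            nodes.setdefault(seg.u, seg.points[0])
            nodes.setdefault(seg.v, seg.points[-1])
    return RoadNetwork(nodes=nodes, segments=segments)


def subjects_to_geojson(subjects: list[Subject]) -> dict:
    """Legs as LineString features, waits as Point features, plus subject table."""
    features = []
    subj_meta = {}
    for s in subjects:
        subj_meta[str(s.id)] = {
            "home_node": s.home_node,
            "work_node": s.work_node,
            "home_xy": list(s.home_xy),
            "work_xy": list(s.work_xy),
            "geocode_quality": s.geocode_quality,
            "leave_home_min": s.leave_home_min,
            "leave_work_min": s.leave_work_min,
            "main_mode": s.main_mode,
            "trips": [
                {
                    "id": t.id,
                    "origin_node": t.origin_node,
                    "dest_node": t.dest_node,
                    "start_min": t.start_min,
                }
                for t in s.trips
            ],
        }
        for t in s.trips:
            for leg in t.legs:
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {
                            "type": "LineString",
                            "coordinates": [list(p) for p in leg.points],
                        },
                        "properties": {
                            "feature_type": "leg",
                            "id": leg.id,
                            "subject_id": leg.subject_id,
                            "trip_id": leg.trip_id,
                            "mode": leg.mode,
                            "origin_node": leg.origin_node,
                            "dest_node": leg.dest_node,
                            "road_class": leg.road_class,
                            "start_min": leg.start_min,
                            "start_hour": leg.start_hour,
                            "duration_min": leg.duration_min,
                            "length_m": leg.length_m,
                        },
                    }
                )
            for w in t.waits:
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "Point", "coordinates": list(w.location)},
                        "properties": {
                            "feature_type": "wait",
                            "trip_id": t.id,
                            "start_min": w.start_min,
                            "duration_min": w.duration_min,
                            "road_class": w.road_class,
                        },
                    }
                )
    return {"type": "FeatureCollection", "features": features, "subjects": subj_meta}


def subjects_from_geojson(obj: dict) -> list[Subject]:
    subjects: dict[int, Subject] = {}
    trips: dict[int, Trip] = {}
    for sid_str, meta in obj.get("subjects", {}).items():
        sid = int(sid_str)
        s = Subject(
            id=sid,
            home_node=int(meta["home_node"]),
            work_node=int(meta["work_node"]),
            home_xy=tuple(meta["home_xy"]),
            work_xy=tuple(meta["work_xy"]),
            geocode_quality=meta["geocode_quality"],
            leave_home_min=int(meta["leave_home_min"]),
            leave_work_min=int(meta["leave_work_min"]),
            main_mode=meta["main_mode"],
        )
        for tmeta in meta["trips"]:
            t = Trip(
                id=int(tmeta["id"]),
                origin_node=int(tmeta["origin_node"]),
                dest_node=int(tmeta["dest_node"]),
                start_min=int(tmeta["start_min"]),
            )
            s.trips.append(t)
            trips[t.id] = t
        subjects[sid] = s
    for feat in obj["features"]:
        p = feat["properties"]
        if p["feature_type"] == "leg":
            leg = Leg(
                id=int(p["id"]),
                subject_id=int(p["subject_id"]),
                trip_id=int(p["trip_id"]),
                mode=p["mode"],
                origin_node=int(p["origin_node"]),
                dest_node=int(p["dest_node"]),
                points=[tuple(map(float, c)) for c in feat["geometry"]["coordinates"]],
                start_min=int(p["start_min"]),
                duration_min=float(p["duration_min"]),
                road_class=p.get("road_class", "unset"),
                length_m=float(p.get("length_m", 0.0)),
            )
            trips[leg.trip_id].legs.append(leg)
        elif p["feature_type"] == "wait":
            trips[int(p["trip_id"])].waits.append(
                Wait(
                    location=tuple(map(float, feat["geometry"]["coordinates"])),
                    start_min=int(p["start_min"]),
                    duration_min=float(p["duration_min"]),
                    road_class=p.get("road_class", "unset"),
                )
            )
    return [subjects[k] for k in sorted(subjects)]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ----------------------------------------------------------------------- CSV

def stations_to_csv(stations: list[StationSeries], path: str | Path) -> None:
    frames = []
    for st in stations:
        frames.append(
            pd.DataFrame(
                {"timestamp": st.timestamps, "site_type": st.site_type, "value": st.values}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def stations_from_csv(path: str | Path) -> list[StationSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for site, grp in df.groupby("site_type", sort=True):
        out.append(
            StationSeries(
                site_type=str(site),
                timestamps=pd.DatetimeIndex(grp["timestamp"]),
                values=grp["value"].to_numpy(),
            )
        )
    return out


def ratios_to_csv(table: RatioTable, path: str | Path) -> None:
    pd.DataFrame(
        {"hour": np.arange(24), "ratio_m": table.ratio_m, "ratio_s": table.ratio_s}
    ).to_csv(path, index=False)


def ratios_from_csv(path: str | Path) -> RatioTable:
    df = pd.read_csv(path).sort_values("hour")
    return RatioTable(df["ratio_m"].to_numpy(), df["ratio_s"].to_numpy())


def exposures_to_csv(records: list, path: str | Path, legs_path: str | Path | None = None) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "model_name": r.model_name,
            "c_subject": r.c_subject,
            "e_subject": r.e_subject,
            "time_weighted": r.time_weighted,
            "dose": r.dose,
            "total_duration_min": r.total_duration_min,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    if legs_path is not None:
        leg_rows = []
        for r in records:
            for c in r.legs:
                leg_rows.append({"subject_id": r.subject_id, "model_name": r.model_name, **c})
        pd.DataFrame(leg_rows).to_csv(legs_path, index=False)


def exposures_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -------------------------------------------------------------------- hashes

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
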