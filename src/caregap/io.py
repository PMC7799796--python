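"""CSV / GeoJSON / YAML serialisation of datasets and results.

All tabular interchange is plain CSV.  Times of day are serialised as
HH:MM; unreachable travel times (infinity) serialise as an empty field.
The optional GeoJSON export writes municipalities and facilities as
point features.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .synthetic import (
    ConfigError,
    District,
    Facility,
    Municipality,
    SyntheticDataset,
)
from .travel import RoadNetwork, TransitConnection

__all__ = [
    "minutes_to_hhmm",
    "hhmm_to_minutes",
    "dataset_frames",
    "write_dataset",
    "load_dataset",
    "write_geojson",
    "LoadError",
]

DATASET_FILES = (
    "districts.csv",
    "municipalities.csv",
    "facilities.csv",
    "road_edges.csv",
    "transit_connections.csv",
)


class LoadError(ValueError):
    """Malformed input file; the message names file, row and column."""


def minutes_to_hhmm(minutes: int) -> str:
    minutes = int(minutes)
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def hhmm_to_minutes(text: str) -> int:
    try:
        hh, mm = text.strip().split(":")
        out = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError):
        raise LoadError(f"invalid HH:MM time {text!r}") from None
    if not 0 <= out < 24 * 60:
        raise LoadError(f"time of day out of range: {text!r}")
    return out


def dataset_frames(ds: SyntheticDataset) -> dict[str, pd.DataFrame]:
    districts = pd.DataFrame(
        [{"district_id": d.id, "region_id": d.region_id, "name": d.name}
         for d in ds.districts]
    )
    municipalities = pd.DataFrame(
        [
            {
                "municipality_id": m.id,
                "district_id": m.district_id,
                "x": m.x,
                "y": m.y,
                "recipients_65plus": m.recipients_65plus,
                "network_node": m.network_node,
            }
            for m in ds.municipalities
        ]
    )
    facilities = pd.DataFrame(
        [
            {
                "facility_id": f.id,
                "service_class": f.service_class,
                "subtype": f.subtype,
                "municipality_id": f.municipality_id,
                "capacity": f.capacity,
            }
            for f in ds.facilities
        ],
        columns=[
            "facility_id", "service_class", "subtype", "municipality_id", "capacity",
        ],
    )
    road_edges = pd.DataFrame(
        [{"from_node": u, "to_node": v, "minutes": w} for u, v, w in ds.road_network.edges],
        columns=["from_node", "to_node", "minutes"],
    )
    transit = pd.DataFrame(
        [
            {
                "origin": c.origin,
                "destination": c.destination,
                "departure": minutes_to_hhmm(c.departure),
                "arrival": minutes_to_hhmm(c.arrival),
                "minutes": c.travel_minutes,
                "transfers": c.transfers,
                "price": c.price,
                "distance_km": c.distance_km,
            }
            for c in ds.timetable
        ],
        columns=[
            "origin", "destination", "departure", "arrival",
            "minutes", "transfers", "price", "distance_km",
        ],
    )
    return {
        "districts.csv": districts,
        "municipalities.csv": municipalities,
        "facilities.csv": facilities,
        "road_edges.csv": road_edges,
        "transit_connections.csv": transit,
    }


def write_dataset(ds: SyntheticDataset, outdir: str | Path, geojson: bool = False):
    """Write the five dataset CSVs (plus optional GeoJSON); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in dataset_frames(ds).items():
        path = outdir / name
        frame.to_csv(path, index=False)
        paths[name] = path
    if geojson:
        path = outdir / "study_area.geojson"
        write_geojson(ds, path)
        paths["study_area.geojson"] = path
    return paths


def write_geojson(ds: SyntheticDataset, path: str | Path) -> None:
    features = []
    for m in ds.municipalities:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [m.x, m.y]},
                "properties": {
                    "kind": "municipality",
                    "id": m.id,
                    "district_id": m.district_id,
                    "recipients_65plus": m.recipients_65plus,
                },
            }
        )
    coords = {m.id: (m.x, m.y) for m in ds.municipalities}
    for f in ds.facilities:
        x, y = coords[f.municipality_id]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {
                    "kind": "facility",
                    "id": f.id,
                    "service_class": f.service_class,
                    "subtype": f.subtype,
                    "capacity": f.capacity,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path.name}: missing column(s) {missing}")
    return df


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Load a dataset from its five CSVs, validating referential integrity.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    directory = Path(directory)
    ddf = _read_csv(directory / "districts.csv", ["district_id", "region_id", "name"])
    mdf = _read_csv(
        directory / "municipalities.csv",
        ["municipality_id", "district_id", "x", "y", "recipients_65plus", "network_node"],
    )
    fdf = _read_csv(
        directory / "facilities.csv",
        ["facility_id", "service_class", "subtype", "municipality_id", "capacity"],
    )
    edf = _read_csv(directory / "road_edges.csv", ["from_node", "to_node", "minutes"])
    tdf = _read_csv(
        directory / "transit_connections.csv",
        ["origin", "destination", "departure", "arrival",
         "minutes", "transfers", "price", "distance_km"],
    )

    districts = [
        District(str(r.district_id), str(r.region_id), str(r.name))
        for r in ddf.itertuples()
    ]
    district_ids = {d.id for d in districts}
    regions = sorted({d.region_id for d in districts})

    municipalities = []
    for i, r in enumerate(mdf.itertuples(), start=1):
        if str(r.district_id) not in district_ids:
            raise LoadError(
                f"municipalities.csv row {i}: unknown district {r.district_id!r}"
            )
        municipalities.append(
            Municipality(
                str(r.municipality_id), str(r.district_id),
                float(r.x), float(r.y),
                int(r.recipients_65plus), str(r.network_node),
            )
        )
    mun_ids = {m.id for m in municipalities}

    facilities = []
    for i, r in enumerate(fdf.itertuples(), start=1):
        if str(r.municipality_id) not in mun_ids:
            raise LoadError(
                f"facilities.csv row {i}: unknown municipality {r.municipality_id!r}"
            )
        try:
            facilities.append(
                Facility(
                    str(r.facility_id), str(r.service_class), str(r.subtype),
                    str(r.municipality_id), int(r.capacity),
                )
            )
        except ConfigError as exc:
            raise LoadError(f"facilities.csv row {i}: {exc}") from None

    net = RoadNetwork()
    for m in municipalities:
        net.nodes[m.network_node] = (m.x, m.y)
    for i, r in enumerate(edf.itertuples(), start=1):
        if str(r.from_node) not in net.nodes or str(r.to_node) not in net.nodes:
            raise LoadError(f"road_edges.csv row {i}: unknown node")
        minutes = float(r.minutes)
        if not math.isfinite(minutes) or minutes < 0:
            raise LoadError(f"road_edges.csv row {i}: invalid minutes {r.minutes!r}")
        net.edges.append((str(r.from_node), str(r.to_node), minutes))

    timetable = []
    for i, r in enumerate(tdf.itertuples(), start=1):
        if str(r.origin) not in mun_ids or str(r.destination) not in mun_ids:
            raise LoadError(f"transit_connections.csv row {i}: unknown municipality")
        try:
            timetable.append(
                TransitConnection(
                    str(r.origin), str(r.destination),
                    hhmm_to_minutes(str(r.departure)), hhmm_to_minutes(str(r.arrival)),
                    float(r.minutes), int(r.transfers),
                    float(r.price), float(r.distance_km),
                )
            )
        except LoadError as exc:
            raise LoadError(f"transit_connections.csv row {i}: {exc}") from None

    ds = SyntheticDataset(
        regions=regions,
        districts=districts,
        municipalities=municipalities,
        facilities=facilities,
        road_network=net,
        timetable=timetable,
    )
    ds.validate()
    return ds
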