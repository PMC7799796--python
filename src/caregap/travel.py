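"""Travel-time reachability by individual and public transport.

Individual transport (IT) is modelled as shortest paths on a road network
whose edge weights are travel minutes.  Public transport (PT) is modelled
from a timetable of municipality-to-municipality connections: connections
are filtered by hard feasibility rules (maximum duration, transfers,
direct distance, and arrival at one of the configured target times), the
best connection per origin-destination pair is picked by a weighing
function, and band membership is read off its total travel time.

Reachability is always measured to the municipality hosting the nearest
facility of a service class, not to the facility door; regional timetables
describe station-to-station links, so the municipality is the natural
common endpoint for both modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RoadNetwork",
    "TransitConnection",
    "WeighingWeights",
    "AccessConfig",
    "shortest_travel_times",
    "band_membership",
    "filter_connections",
    "select_best_connection",
    "connection_frame",
    "compute_reachability",
    "MODES",
    "SERVICE_CLASSES",
]

MODES = ("IT", "PT")
SERVICE_CLASSES = ("residential", "clinic")


class InputError(ValueError):
    """Raised for unknown node, municipality or service identifiers."""


@dataclass
class RoadNetwork:
    """Undirected road graph with per-edge travel minutes.

    nodes maps node id -> (x, y) planar coordinates (km); edges are
    (u, v, minutes) with minutes >= 0.
    """

    nodes: dict[str, tuple[float, float]] = field(default_factory=dict)
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node, xy in self.nodes.items():
            g.add_node(node, x=xy[0], y=xy[1])
        for u, v, minutes in self.edges:
            if minutes < 0:
                raise InputError(f"negative travel time on edge {u}-{v}")
            # parallel edges collapse to the fastest one
            if g.has_edge(u, v):
                minutes = min(minutes, g[u][v]["minutes"])
            g.add_edge(u, v, minutes=float(minutes))
        return g

    def validate(self) -> None:
        for u, v, minutes in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise InputError(f"edge {u}-{v} references an unknown node")
            if minutes < 0:
                raise InputError(f"negative travel time on edge {u}-{v}")


@dataclass(frozen=True)
class TransitConnection:
    """One timetable record between two municipalities (same day).

    departure/arrival are minutes-of-day; travel_minutes is the total
    door-to-door duration including transfer waits.
    """

    origin: str
    destination: str
    departure: int
    arrival: int
    travel_minutes: float
    transfers: int
    price: float
    distance_km: float

    def __post_init__(self) -> None:
        if self.travel_minutes < 0:
            raise InputError("travel_minutes must be >= 0")
        if self.transfers < 0:
            raise InputError("transfers must be >= 0")


@dataclass(frozen=True)
class WeighingWeights:
    """Nonnegative weights of the connection-scoring function.

    Travel time dominates by default; arrival slack (waiting at the
    destination before the target time), departure earliness, transfer
    count and ticket price refine the choice among otherwise similar
    connections.
    """

    travel: float = 0.5
    arrival: float = 0.1
    departure: float = 0.1
    transfers: float = 0.2
    price: float = 0.1

    def as_dict(self) -> dict[str, float]:
        return {
            "travel": self.travel,
            "arrival": self.arrival,
            "departure": self.departure,
            "transfers": self.transfers,
            "price": self.price,
        }


def _default_arrival_times() -> dict[str, tuple[int, ...]]:
    # residential visits target early afternoon; clinics the morning drop-off
    return {"residential": (14 * 60,), "clinic": (7 * 60, 8 * 60)}


@dataclass(frozen=True)
class AccessConfig:
    """Parameters of the reachability analysis.

    bands: ordered travel-time budgets (minutes); arrival_times: target
    arrival minutes-of-day per service class on the reference weekday;
    pt_* : hard feasibility filters on timetable records (duration strictly
    below pt_max_minutes, at most pt_max_transfers changes, direct distance
    strictly below pt_max_distance_km); arrival_tolerance_min widens the
    exact-minute arrival match symmetrically.
    """

    bands: tuple[float, ...] = (30.0, 60.0)
    arrival_times: Mapping[str, tuple[int, ...]] = field(
        default_factory=_default_arrival_times
    )
    weekday: str = "Tuesday"
    pt_max_minutes: float = 90.0
    pt_max_transfers: int = 5
    pt_max_distance_km: float = 150.0
    arrival_tolerance_min: int = 0
    weights: WeighingWeights = field(default_factory=WeighingWeights)
    it_target: str = "municipality"  # or "facility" for door-level IT runs

    def __post_init__(self) -> None:
        if list(self.bands) != sorted(set(self.bands)):
            raise InputError("bands must be strictly increasing")
        if min(self.pt_max_minutes, self.pt_max_distance_km) <= 0:
            raise InputError("PT filters must be positive")
        if self.pt_max_transfers < 0:
            raise InputError("pt_max_transfers must be >= 0")


def shortest_travel_times(
    network: RoadNetwork,
    origins: Iterable[str],
    targets: Iterable[str],
) -> dict[str, float]:
    """Minutes from each origin to its nearest target over the road graph.

    Returns math.inf for origins disconnected from every target (and for
    every origin when the target set is empty).
    """
    origins = list(origins)
    targets = list(targets)
    g = network.graph()
    for node in [*origins, *targets]:
        if node not in g:
            raise InputError(f"unknown network node: {node!r}")
    if not targets:
        return {o: math.inf for o in origins}
    dist = nx.multi_source_dijkstra_path_length(g, targets, weight="minutes")
    return {o: float(dist.get(o, math.inf)) for o in origins}


def band_membership(minutes: float, bands: Sequence[float]) -> tuple[bool, ...]:
    """Cumulative band flags: flag_b is true iff minutes <= b."""
    return tuple(minutes <= b for b in bands)


def _arrival_matches(arrival: int, targets: Sequence[int], tolerance: int) -> bool:
    return any(abs(arrival - t) <= tolerance for t in targets)


def filter_connections(
    timetable: Iterable[TransitConnection],
    cfg: AccessConfig,
    arrival_times: Sequence[int],
) -> list[TransitConnection]:
    """Apply the hard feasibility filters to a timetable.

    A record survives iff its duration is strictly below the maximum, its
    transfer count does not exceed the maximum, its direct distance is
    strictly below the maximum, and it arrives at one of the target times
    (exact minute unless a tolerance is configured).
    """
    out = []
    for c in timetable:
        if c.travel_minutes >= cfg.pt_max_minutes:
            continue
        if c.transfers > cfg.pt_max_transfers:
            continue
        if c.distance_km >= cfg.pt_max_distance_km:
            continue
        if not _arrival_matches(c.arrival, arrival_times, cfg.arrival_tolerance_min):
            continue
        out.append(c)
    return out


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def _scores(
    feasible: Sequence[TransitConnection],
    weights: WeighingWeights,
    arrival_times: Sequence[int],
) -> np.ndarray:
    travel = np.array([c.travel_minutes for c in feasible], dtype=float)
    slack = np.array(
        [min(abs(c.arrival - t) for t in arrival_times) for c in feasible],
        dtype=float,
    )
    # later departure = less time lost before the trip, so earliness is the cost
    earliness = np.array([-c.departure for c in feasible], dtype=float)
    transfers = np.array([c.transfers for c in feasible], dtype=float)
    price = np.array([c.price for c in feasible], dtype=float)
    w = weights
    return (
        w.travel * _minmax(travel)
        + w.arrival * _minmax(slack)
        + w.departure * _minmax(earliness)
        + w.transfers * _minmax(transfers)
        + w.price * _minmax(price)
    )


class NoFeasibleConnection(LookupError):
    """No timetable record between the pair passes every filter."""


def select_best_connection(
    feasible: Sequence[TransitConnection],
    weights: WeighingWeights,
    arrival_times: Sequence[int],
) -> TransitConnection:
    """Pick the connection minimising the weighted, min-max-normalised score.

    Ties break deterministically: lowest travel time, then fewest
    transfers, then lowest price, then input order.
    """
    feasible = list(feasible)
    if not feasible:
        raise NoFeasibleConnection("empty feasible set")
    s = _scores(feasible, weights, arrival_times)
    order = sorted(
        range(len(feasible)),
        key=lambda i: (
            s[i],
            feasible[i].travel_minutes,
            feasible[i].transfers,
            feasible[i].price,
            i,
        ),
    )
    return feasible[order[0]]


def connection_frame(timetable: Iterable[TransitConnection]) -> pd.DataFrame:
    rows = [
        {
            "origin": c.origin,
            "destination": c.destination,
            "departure": c.departure,
            "arrival": c.arrival,
            "minutes": c.travel_minutes,
            "transfers": c.transfers,
            "price": c.price,
            "distance_km": c.distance_km,
        }
        for c in timetable
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "origin",
            "destination",
            "departure",
            "arrival",
            "minutes",
            "transfers",
            "price",
            "distance_km",
        ],
    )


def _pt_minutes(
    timetable: Sequence[TransitConnection],
    cfg: AccessConfig,
    service_class: str,
    facility_municipalities: set[str],
    origins: Sequence[str],
) -> dict[str, float]:
    """Best PT minutes per origin municipality to the nearest hosting one."""
    targets = cfg.arrival_times[service_class]
    minutes = {o: math.inf for o in origins}
    for o in facility_municipalities:
        if o in minutes:
            minutes[o] = 0.0
    feasible = [
        c
        for c in filter_connections(timetable, cfg, targets)
        if c.destination in facility_municipalities and c.origin in minutes
    ]
    if not feasible:
        return minutes
    by_pair: dict[tuple[str, str], list[TransitConnection]] = {}
    for c in feasible:
        by_pair.setdefault((c.origin, c.destination), []).append(c)
    for (origin, _dest), conns in by_pair.items():
        best = select_best_connection(conns, cfg.weights, targets)
        if best.travel_minutes < minutes[origin]:
            minutes[origin] = float(best.travel_minutes)
    return minutes


def compute_reachability(dataset, cfg: AccessConfig | None = None) -> pd.DataFrame:
    """Per (municipality, service class, mode) minimal minutes and band flags.

    Returns a long-form frame with columns municipality, district_id,
    service_class, mode, minutes (inf when unreachable) and one boolean
    ``within<b>`` column per configured band.
    """
    cfg = cfg or AccessConfig()
    host: dict[str, set[str]] = {cls: set() for cls in SERVICE_CLASSES}
    mun_by_id = {m.id: m for m in dataset.municipalities}
    for f in dataset.facilities:
        host[f.service_class].add(f.municipality_id)

    origins_nodes = [m.network_node for m in dataset.municipalities]
    rows = []
    for cls in SERVICE_CLASSES:
        target_nodes = {mun_by_id[mid].network_node for mid in host[cls]}
        it = shortest_travel_times(dataset.road_network, origins_nodes, target_nodes)
        pt = _pt_minutes(
            dataset.timetable, cfg, cls, host[cls], [m.id for m in dataset.municipalities]
        )
        for m in dataset.municipalities:
            for mode, minutes in (("IT", it[m.network_node]), ("PT", pt[m.id])):
                flags = band_membership(minutes, cfg.bands)
                row = {
                    "municipality": m.id,
                    "district_id": m.district_id,
                    "service_class": cls,
                    "mode": mode,
                    "minutes": minutes,
                }
                for b, flag in zip(cfg.bands, flags):
                    row[f"within{int(b)}"] = bool(flag)
                rows.append(row)
    return pd.DataFrame(rows)
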