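"""Seeded synthetic study areas: regions, districts, municipalities,
care facilities, a road network and a public-transport timetable.

The generator emulates the structural features the gap analysis relies
on — a three-level administrative hierarchy, overdispersed counts of
allowance recipients aged 65+, two facility classes with very different
densities (bed-based residential care is roughly an order of magnitude
more common than day-care clinics, so districts without any clinic are a
normal outcome), a connected per-district road graph, and a timetable of
direct-or-few-transfer connections arriving at the analysis target times.

``plant_gap_scenario`` deterministically edits a dataset so that one
district lands in a chosen accessibility class for a chosen service and
mode, recording every edit; it exists so the classifier can be exercised
against a known ground truth.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .travel import RoadNetwork, TransitConnection, SERVICE_CLASSES

__all__ = [
    "DrawSpec",
    "RegionConfig",
    "District",
    "Municipality",
    "Facility",
    "SyntheticDataset",
    "generate_region",
    "plant_gap_scenario",
    "ConfigError",
    "InfeasiblePlantError",
    "RESIDENTIAL_SUBTYPES",
    "CLINIC_SUBTYPES",
]

RESIDENTIAL_SUBTYPES = ("home_for_elderly", "special_regime_home")
CLINIC_SUBTYPES = ("day_care_centre", "day_services_centre")


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


class InfeasiblePlantError(ValueError):
    """The requested planted scenario cannot be constructed."""


@dataclass(frozen=True)
class DrawSpec:
    """A named distribution with parameters, drawn via numpy Generator.

    Supported: negative_binomial(mean, shape), poisson(mean),
    uniform_int(low, high), uniform(low, high), lognormal(mean, sigma)
    (mean is the arithmetic mean), constant(value).
    """

    dist: str
    params: Mapping[str, float] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        p = self.params
        try:
            if self.dist == "negative_binomial":
                if p["mean"] <= 0 or p["shape"] <= 0:
                    raise ConfigError(f"{name}: mean and shape must be > 0")
            elif self.dist == "poisson":
                if p["mean"] < 0:
                    raise ConfigError(f"{name}: mean must be >= 0")
            elif self.dist in ("uniform_int", "uniform"):
                if p["low"] > p["high"]:
                    raise ConfigError(f"{name}: low > high")
            elif self.dist == "lognormal":
                if p["mean"] <= 0 or p["sigma"] <= 0:
                    raise ConfigError(f"{name}: mean and sigma must be > 0")
            elif self.dist == "constant":
                p["value"]
            else:
                raise ConfigError(f"{name}: unknown distribution {self.dist!r}")
        except KeyError as exc:
            raise ConfigError(f"{name}: missing parameter {exc.args[0]!r}") from None

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.params
        if self.dist == "negative_binomial":
            shape = p["shape"]
            prob = shape / (shape + p["mean"])
            return rng.negative_binomial(shape, prob, size=size)
        if self.dist == "poisson":
            return rng.poisson(p["mean"], size=size)
        if self.dist == "uniform_int":
            return rng.integers(int(p["low"]), int(p["high"]) + 1, size=size)
        if self.dist == "uniform":
            return rng.uniform(p["low"], p["high"], size=size)
        if self.dist == "lognormal":
            sigma = p["sigma"]
            mu = math.log(p["mean"]) - sigma**2 / 2.0
            return rng.lognormal(mu, sigma, size=size)
        if self.dist == "constant":
            value = p["value"]
            return value if size is None else np.full(size, value)
        raise ConfigError(f"unknown distribution {self.dist!r}")

    def mean(self) -> float:
        p = self.params
        if self.dist in ("negative_binomial", "poisson", "lognormal"):
            return float(p["mean"])
        if self.dist in ("uniform_int", "uniform"):
            return (float(p["low"]) + float(p["high"])) / 2.0
        return float(p["value"])


def _default_recipients() -> DrawSpec:
    # overdispersed municipality counts; district totals then spread widely
    return DrawSpec("negative_binomial", {"mean": 220.0, "shape": 1.8})


def _default_capacity() -> dict[str, DrawSpec]:
    return {
        "residential": DrawSpec("lognormal", {"mean": 53.0, "sigma": 0.5}),
        "clinic": DrawSpec("uniform_int", {"low": 5, "high": 15}),
    }


def _default_density() -> dict[str, float]:
    # national totals of ~760 residential and ~133 clinic facilities over
    # 76 districts: 10 and 1.75 expected facilities per district
    return {"residential": 10.0, "clinic": 1.75}


def _default_edge_minutes() -> DrawSpec:
    return DrawSpec("uniform", {"low": 8.0, "high": 26.0})


@dataclass(frozen=True)
class RegionConfig:
    """Study-area generator configuration (all randomness from ``seed``)."""

    n_regions: int = 13
    districts_per_region: tuple[int, int] = (3, 12)
    municipalities_per_district: tuple[int, int] = (6, 12)
    recipients_per_municipality: DrawSpec = field(default_factory=_default_recipients)
    facility_density: Mapping[str, float] = field(default_factory=_default_density)
    capacity_spec: Mapping[str, DrawSpec] = field(default_factory=_default_capacity)
    road_edge_minutes: DrawSpec = field(default_factory=_default_edge_minutes)
    transit_coverage: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions: must be >= 1")
        for name, rng_ in (
            ("districts_per_region", self.districts_per_region),
            ("municipalities_per_district", self.municipalities_per_district),
        ):
            if rng_[0] < 1 or rng_[0] > rng_[1]:
                raise ConfigError(f"{name}: invalid count range {rng_}")
        for cls in SERVICE_CLASSES:
            if cls not in self.facility_density:
                raise ConfigError(f"facility_density: missing class {cls!r}")
            if self.facility_density[cls] < 0:
                raise ConfigError(f"facility_density[{cls}]: must be >= 0")
            if cls not in self.capacity_spec:
                raise ConfigError(f"capacity_spec: missing class {cls!r}")
            self.capacity_spec[cls].validate(f"capacity_spec[{cls}]")
        self.recipients_per_municipality.validate("recipients_per_municipality")
        self.road_edge_minutes.validate("road_edge_minutes")
        if not 0.0 <= self.transit_coverage <= 1.0:
            raise ConfigError("transit_coverage: must be in [0, 1]")


@dataclass
class District:
    id: str
    region_id: str
    name: str


@dataclass
class Municipality:
    id: str
    district_id: str
    x: float
    y: float
    recipients_65plus: int
    network_node: str


@dataclass
class Facility:
    id: str
    service_class: str
    subtype: str
    municipality_id: str
    capacity: int

    def __post_init__(self) -> None:
        ok = (
            self.subtype in RESIDENTIAL_SUBTYPES
            if self.service_class == "residential"
            else self.subtype in CLINIC_SUBTYPES
        )
        if not ok:
            raise ConfigError(
                f"facility {self.id}: subtype {self.subtype!r} inconsistent "
                f"with class {self.service_class!r}"
            )
        if self.capacity <= 0:
            raise ConfigError(f"facility {self.id}: capacity must be > 0")


@dataclass
class SyntheticDataset:
    """A full simulated study area plus the log of planted edits."""

    regions: list[str]
    districts: list[District]
    municipalities: list[Municipality]
    facilities: list[Facility]
    road_network: RoadNetwork
    timetable: list[TransitConnection]
    edit_log: list[dict] = field(default_factory=list)

    def municipalities_in(self, district_id: str) -> list[Municipality]:
        return [m for m in self.municipalities if m.district_id == district_id]

    def facilities_in(self, district_id: str, service_class: str | None = None):
        muns = {m.id for m in self.municipalities_in(district_id)}
        return [
            f
            for f in self.facilities
            if f.municipality_id in muns
            and (service_class is None or f.service_class == service_class)
        ]

    def copy(self) -> "SyntheticDataset":
        return copy.deepcopy(self)

    def content_hash(self) -> str:
        """Deterministic digest of the dataset's full content."""
        h = hashlib.sha256()
        for r in self.regions:
            h.update(r.encode())
        for d in self.districts:
            h.update(f"{d.id}|{d.region_id}|{d.name}".encode())
        for m in self.municipalities:
            h.update(
                f"{m.id}|{m.district_id}|{m.x:.9f}|{m.y:.9f}|"
                f"{m.recipients_65plus}|{m.network_node}".encode()
            )
        for f in self.facilities:
            h.update(
                f"{f.id}|{f.service_class}|{f.subtype}|"
                f"{f.municipality_id}|{f.capacity}".encode()
            )
        for node in sorted(self.road_network.nodes):
            x, y = self.road_network.nodes[node]
            h.update(f"{node}|{x:.9f}|{y:.9f}".encode())
        for u, v, w in self.road_network.edges:
            h.update(f"{u}|{v}|{w:.9f}".encode())
        for c in self.timetable:
            h.update(
                f"{c.origin}|{c.destination}|{c.departure}|{c.arrival}|"
                f"{c.travel_minutes:.9f}|{c.transfers}|{c.price:.9f}|"
                f"{c.distance_km:.9f}".encode()
            )
        return h.hexdigest()

    def validate(self) -> None:
        district_ids = {d.id for d in self.districts}
        if len(district_ids) != len(self.districts):
            raise ConfigError("duplicate district ids")
        region_ids = set(self.regions)
        for d in self.districts:
            if d.region_id not in region_ids:
                raise ConfigError(f"district {d.id}: unknown region {d.region_id}")
        mun_ids = set()
        for m in self.municipalities:
            if m.id in mun_ids:
                raise ConfigError(f"duplicate municipality id {m.id}")
            mun_ids.add(m.id)
            if m.district_id not in district_ids:
                raise ConfigError(f"municipality {m.id}: unknown district")
            if m.recipients_65plus < 0:
                raise ConfigError(f"municipality {m.id}: negative recipients")
            if m.network_node not in self.road_network.nodes:
                raise ConfigError(f"municipality {m.id}: node not in road network")
        for f in self.facilities:
            if f.municipality_id not in mun_ids:
                raise ConfigError(f"facility {f.id}: unknown municipality")
        self.road_network.validate()


def _district_subgraph_connected(ds: SyntheticDataset, district_id: str) -> bool:
    import networkx as nx

    nodes = [m.network_node for m in ds.municipalities_in(district_id)]
    g = ds.road_network.graph().subgraph(nodes)
    return len(nodes) <= 1 or nx.is_connected(g)


def generate_region(config: RegionConfig) -> SyntheticDataset:
    """Generate a seeded study area satisfying all structural invariants.

    The road network restricted to any single district is connected (hub
    spokes plus a chain); district hubs are chained within a region and
    region gateways across regions, so the full graph is connected too.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    regions: list[str] = []
    districts: list[District] = []
    municipalities: list[Municipality] = []
    facilities: list[Facility] = []
    net = RoadNetwork()
    timetable: list[TransitConnection] = []
    fac_counter = 0

    def edge_minutes(scale: float = 1.0) -> float:
        return float(config.road_edge_minutes.sample(rng)) * scale

    region_hubs: list[str] = []
    for ri in range(config.n_regions):
        region_id = f"R{ri + 1:02d}"
        regions.append(region_id)
        rx = (ri % 4) * 220.0
        ry = (ri // 4) * 220.0
        lo, hi = config.districts_per_region
        n_d = int(rng.integers(lo, hi + 1))
        district_hubs: list[tuple[str, Municipality]] = []
        for di in range(n_d):
            district_id = f"{region_id}-D{di + 1:02d}"
            districts.append(District(district_id, region_id, f"District {district_id}"))
            angle = 2 * math.pi * di / max(n_d, 1)
            dx = rx + 55.0 * math.cos(angle) + rng.uniform(-8, 8)
            dy = ry + 55.0 * math.sin(angle) + rng.uniform(-8, 8)
            mlo, mhi = config.municipalities_per_district
            n_m = int(rng.integers(mlo, mhi + 1))
            recipients = config.recipients_per_municipality.sample(rng, n_m)
            local: list[Municipality] = []
            for mi in range(n_m):
                mun_id = f"{district_id}-M{mi + 1:02d}"
                if mi == 0:
                    mx, my = dx, dy  # hub sits at the district centre
                else:
                    mx = dx + rng.uniform(-12, 12)
                    my = dy + rng.uniform(-12, 12)
                mun = Municipality(
                    id=mun_id,
                    district_id=district_id,
                    x=float(mx),
                    y=float(my),
                    recipients_65plus=int(recipients[mi]),
                    network_node=mun_id,
                )
                local.append(mun)
                net.nodes[mun_id] = (mun.x, mun.y)
            municipalities.extend(local)
            hub = local[0]
            for mun in local[1:]:
                net.edges.append((hub.network_node, mun.network_node, edge_minutes()))
            for a, b in zip(local[1:], local[2:]):
                net.edges.append((a.network_node, b.network_node, edge_minutes()))
            district_hubs.append((district_id, hub))

            # capacity networks follow demand: the expected facility count
            # scales with the district's share of recipients (mean preserved)
            expected_total = config.recipients_per_municipality.mean() * n_m
            demand_factor = (
                sum(m.recipients_65plus for m in local) / expected_total
                if expected_total > 0
                else 1.0
            )
            for cls in SERVICE_CLASSES:
                n_f = int(rng.poisson(config.facility_density[cls] * demand_factor))
                subtypes = (
                    RESIDENTIAL_SUBTYPES if cls == "residential" else CLINIC_SUBTYPES
                )
                for _ in range(n_f):
                    fac_counter += 1
                    host = local[int(rng.integers(0, n_m))]
                    subtype = subtypes[0] if rng.uniform() < 0.75 else subtypes[1]
                    cap = max(1, int(round(float(config.capacity_spec[cls].sample(rng)))))
                    facilities.append(
                        Facility(
                            id=f"F{fac_counter:05d}",
                            service_class=cls,
                            subtype=subtype,
                            municipality_id=host.id,
                            capacity=cap,
                        )
                    )

        # inter-district links: chain of hubs plus spokes to the first hub
        for (_, a), (_, b) in zip(district_hubs, district_hubs[1:]):
            net.edges.append((a.network_node, b.network_node, edge_minutes(2.0)))
        for _, h in district_hubs[2:]:
            net.edges.append(
                (district_hubs[0][1].network_node, h.network_node, edge_minutes(2.0))
            )
        region_hubs.append(district_hubs[0][1].network_node)

        # timetable: connections within the region arriving at the target times
        region_muns = [m for m in municipalities if m.district_id.startswith(region_id)]
        hub_ids = {d_id: h.id for d_id, h in district_hubs}
        mun_lookup = {m.id: m for m in region_muns}
        for origin in region_muns:
            dests: list[str] = []
            own_hub = hub_ids[origin.district_id]
            if origin.id != own_hub:
                dests.append(own_hub)
            for other in region_muns:
                if other.id == origin.id or other.id == own_hub:
                    continue
                same_district = other.district_id == origin.district_id
                is_hub = other.id in hub_ids.values()
                if (same_district or is_hub) and rng.uniform() < config.transit_coverage:
                    dests.append(other.id)
            for dest_id in dests:
                dest = mun_lookup[dest_id]
                dist_km = math.hypot(origin.x - dest.x, origin.y - dest.y)
                for target in (7 * 60, 8 * 60, 14 * 60):
                    base = dist_km * 1.4 + rng.uniform(5.0, 20.0)
                    n_alt = 1 + (rng.uniform() < 0.3)
                    for alt in range(int(n_alt)):
                        travel = int(round(base + alt * rng.uniform(5.0, 25.0)))
                        travel = max(travel, 3)
                        transfers = int(rng.poisson(0.8)) + alt
                        price = round(20.0 + 2.2 * travel + rng.uniform(0, 10), 1)
                        timetable.append(
                            TransitConnection(
                                origin=origin.id,
                                destination=dest.id,
                                departure=target - travel,
                                arrival=target,
                                travel_minutes=float(travel),
                                transfers=transfers,
                                price=price,
                                distance_km=round(dist_km, 3),
                            )
                        )

    # gateways between consecutive regions keep the whole road graph connected
    for a, b in zip(region_hubs, region_hubs[1:]):
        net.edges.append((a, b, edge_minutes(3.0)))

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


_BLOCK_MINUTES = 10_000.0  # sentinel making a road link useless within any band


def plant_gap_scenario(
    dataset: SyntheticDataset,
    district_id: str,
    service_class: str,
    mode: str,
    target_class: str,
) -> SyntheticDataset:
    """Return an edited copy whose district lands in ``target_class``.

    The edit strategy isolates the district for the planted mode, equalises
    its per-municipality recipient counts (so a planted share of connected
    municipalities is exactly the planted coverage share), then wires a
    chosen fraction of municipalities to a facility host within the 30-min
    band: all of them for class I (coverage 100%), ~60% for class II
    (coverage in the 50-70% band with a provider present), none for class
    III (provider removed, nothing reachable within 60 min).  Every edit is
    appended to ``edit_log``.
    """
    if target_class not in ("I", "II", "III"):
        raise InfeasiblePlantError(f"unknown target class {target_class!r}")
    if service_class not in SERVICE_CLASSES:
        raise InfeasiblePlantError(f"unknown service class {service_class!r}")
    if mode not in ("IT", "PT"):
        raise InfeasiblePlantError(f"unknown mode {mode!r}")
    if district_id not in {d.id for d in dataset.districts}:
        raise InfeasiblePlantError(f"unknown district {district_id!r}")

    ds = dataset.copy()
    log = ds.edit_log
    muns = ds.municipalities_in(district_id)
    n = len(muns)
    mun_ids = {m.id for m in muns}
    nodes = {m.network_node for m in muns}

    if target_class == "II" and n < 2:
        raise InfeasiblePlantError(
            f"district {district_id} has {n} municipality; a 50-70% coverage "
            "share cannot be constructed"
        )

    for m in muns:
        if m.recipients_65plus != 100:
            m.recipients_65plus = 100
            log.append(
                {"action": "set_recipients", "municipality": m.id, "value": 100}
            )

    if mode == "IT":
        # neutralise every road link touching the district, then re-wire
        new_edges = []
        blocked = 0
        for u, v, w in ds.road_network.edges:
            if (u in nodes) or (v in nodes):
                new_edges.append((u, v, _BLOCK_MINUTES))
                blocked += 1
            else:
                new_edges.append((u, v, w))
        ds.road_network.edges = new_edges
        log.append({"action": "block_road_edges", "district": district_id, "n": blocked})
    else:
        before = len(ds.timetable)
        ds.timetable = [c for c in ds.timetable if c.origin not in mun_ids]
        log.append(
            {
                "action": "remove_pt_connections",
                "district": district_id,
                "n": before - len(ds.timetable),
            }
        )

    if target_class == "III":
        removed = [f.id for f in ds.facilities_in(district_id, service_class)]
        ds.facilities = [f for f in ds.facilities if f.id not in removed]
        log.append(
            {
                "action": "remove_facilities",
                "district": district_id,
                "service_class": service_class,
                "ids": removed,
            }
        )
        return ds

    existing = ds.facilities_in(district_id, service_class)
    if existing:
        host = next(m for m in muns if m.id == existing[0].municipality_id)
    else:
        host = muns[0]
        subtype = (
            RESIDENTIAL_SUBTYPES[0]
            if service_class == "residential"
            else CLINIC_SUBTYPES[0]
        )
        fac = Facility(
            id=f"F-PLANT-{district_id}",
            service_class=service_class,
            subtype=subtype,
            municipality_id=host.id,
            capacity=50,
        )
        ds.facilities.append(fac)
        log.append({"action": "add_facility", "facility": fac.id, "host": host.id})

    if target_class == "II":
        # other hosting municipalities would sit at 0 minutes and inflate
        # coverage past the planted share, so the class's facilities are
        # consolidated onto the single host
        stray = [
            f.id
            for f in ds.facilities_in(district_id, service_class)
            if f.municipality_id != host.id
        ]
        if stray:
            ds.facilities = [f for f in ds.facilities if f.id not in stray]
            log.append(
                {
                    "action": "remove_facilities",
                    "district": district_id,
                    "service_class": service_class,
                    "ids": stray,
                }
            )
        if not ds.facilities_in(district_id, service_class):
            raise InfeasiblePlantError(
                f"district {district_id}: no facility left at host"
            )  # pragma: no cover - host facility is guaranteed above

    if target_class == "I":
        k = n
    else:
        k = max(1, round(0.6 * n))
        while k / n >= 0.8:
            k -= 1
        if k / n < 0.5 and k + 1 <= n and (k + 1) / n < 0.8:
            k += 1
    ordered = sorted(muns, key=lambda m: (m.id != host.id, m.id))
    chosen = ordered[:k]  # host first, then lexicographic

    arrival_targets = (14 * 60,) if service_class == "residential" else (7 * 60, 8 * 60)
    for m in chosen:
        if m.id == host.id:
            continue
        if mode == "IT":
            ds.road_network.edges.append((m.network_node, host.network_node, 10.0))
            log.append(
                {"action": "add_road_edge", "from": m.id, "to": host.id, "minutes": 10.0}
            )
        else:
            dist_km = math.hypot(m.x - host.x, m.y - host.y)
            for target in arrival_targets:
                ds.timetable.append(
                    TransitConnection(
                        origin=m.id,
                        destination=host.id,
                        departure=target - 15,
                        arrival=target,
                        travel_minutes=15.0,
                        transfers=0,
                        price=25.0,
                        distance_km=round(min(dist_km, 140.0), 3),
                    )
                )
            log.append({"action": "add_pt_connection", "from": m.id, "to": host.id})

    log.append(
        {
            "action": "plant",
            "district": district_id,
            "service_class": service_class,
            "mode": mode,
            "target_class": target_class,
            "covered": len(chosen),
            "municipalities": n,
        }
    )
    return ds
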