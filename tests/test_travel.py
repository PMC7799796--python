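"""Reachability: shortest paths, PT filters, the weighing function."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from caregap.travel import (
    AccessConfig,
    InputError,
    NoFeasibleConnection,
    RoadNetwork,
    TransitConnection,
    WeighingWeights,
    band_membership,
    compute_reachability,
    filter_connections,
    select_best_connection,
    shortest_travel_times,
)


def _net(nodes, edges):
    return RoadNetwork(nodes={n: (0.0, 0.0) for n in nodes}, edges=edges)


class TestShortestTravelTimes:
    def test_single_edge(self):
        net = _net("AB", [("A", "B", 10.0)])
        assert shortest_travel_times(net, ["A"], ["B"]) == {"A": 10.0}

    def test_origin_is_target(self):
        net = _net("AB", [("A", "B", 10.0)])
        assert shortest_travel_times(net, ["A"], ["A", "B"])["A"] == 0.0

    def test_disconnected_is_inf(self):
        net = _net("ABC", [("A", "B", 5.0)])
        assert shortest_travel_times(net, ["C"], ["A"])["C"] == math.inf

    def test_empty_target_set(self):
        net = _net("AB", [("A", "B", 5.0)])
        assert shortest_travel_times(net, ["A"], [])["A"] == math.inf

    def test_unknown_node_rejected(self):
        net = _net("AB", [("A", "B", 5.0)])
        with pytest.raises(InputError):
            shortest_travel_times(net, ["Z"], ["B"])

    def test_matches_exhaustive_path_enumeration(self):
        """Dijkstra equals brute-force simple-path enumeration on small
        random graphs (the heavier 100-graph sweep runs in acceptance)."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.uniform() < 0.45:
                    edges.append((nodes[i], nodes[j], float(rng.uniform(1, 30))))
            net = _net(nodes, edges)
            g = net.graph()
            targets = [nodes[k] for k in rng.choice(n, size=2, replace=False)]
            got = shortest_travel_times(net, nodes, targets)
            for origin in nodes:
                best = math.inf
                for t in targets:
                    if origin == t:
                        best = 0.0
                        continue
                    for path in nx.all_simple_paths(g, origin, t):
                        w = sum(
                            g[u][v]["minutes"] for u, v in zip(path, path[1:])
                        )
                        best = min(best, w)
                assert got[origin] == pytest.approx(best)

    def test_adding_an_edge_never_increases_times(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j], float(rng.uniform(1, 30)))
                for i, j in itertools.combinations(range(n), 2)
                if rng.uniform() < 0.4
            ]
            net = _net(nodes, edges)
            targets = [nodes[0]]
            before = shortest_travel_times(net, nodes, targets)
            i, j = rng.choice(n, size=2, replace=False)
            net.edges.append((nodes[i], nodes[j], float(rng.uniform(1, 30))))
            after = shortest_travel_times(net, nodes, targets)
            for o in nodes:
                assert after[o] <= before[o] + 1e-12


@pytest.mark.parametrize(
    "minutes,expected",
    [(29.9, (True, True)), (30.0, (True, True)), (45.0, (False, True)),
     (60.0, (False, True)), (61.0, (False, False)), (math.inf, (False, False))],
)
def test_band_membership(minutes, expected):
    assert band_membership(minutes, (30, 60)) == expected


def test_band_membership_monotone_in_bands():
    for minutes in (0.0, 15.0, 31.0, 59.0, 61.0, math.inf):
        flags = band_membership(minutes, (30, 60, 90))
        # within a tighter band implies within every wider one
        assert all(b or not a for a, b in zip(flags, flags[1:]))


def _conn(**kw):
    base = dict(
        origin="A", destination="B", departure=800, arrival=840,
        travel_minutes=40.0, transfers=1, price=50.0, distance_km=20.0,
    )
    base.update(kw)
    return TransitConnection(**base)


class TestFilterConnections:
    cfg = AccessConfig()

    def test_too_many_transfers_excluded(self):
        assert filter_connections([_conn(transfers=6)], self.cfg, [840]) == []
        assert filter_connections([_conn(transfers=5)], self.cfg, [840]) != []

    def test_ninety_minutes_exactly_excluded(self):
        c = _conn(travel_minutes=90.0, departure=750)
        assert filter_connections([c], self.cfg, [840]) == []
        c = _conn(travel_minutes=89.0, departure=751)
        assert filter_connections([c], self.cfg, [840]) != []

    def test_distance_filter_strict(self):
        assert filter_connections([_conn(distance_km=150.0)], self.cfg, [840]) == []
        assert filter_connections([_conn(distance_km=149.9)], self.cfg, [840]) != []

    def test_satisfying_every_filter_retained(self):
        c = _conn(transfers=0, travel_minutes=30.0, departure=810, distance_km=12.0)
        assert filter_connections([c], self.cfg, [840]) == [c]

    def test_arrival_must_match_configured_minute(self):
        assert filter_connections([_conn(arrival=841)], self.cfg, [840]) == []
        tol = AccessConfig(arrival_tolerance_min=5)
        assert filter_connections([_conn(arrival=841)], tol, [840]) != []


class TestSelectBestConnection:
    weights = WeighingWeights()

    def test_singleton(self):
        c = _conn()
        assert select_best_connection([c], self.weights, [840]) is c

    def test_fewer_transfers_dominates(self):
        a = _conn(transfers=0)
        b = _conn(transfers=2)
        assert select_best_connection([b, a], self.weights, [840]) is a

    def test_empty_set_signals_unreachable(self):
        with pytest.raises(NoFeasibleConnection):
            select_best_connection([], self.weights, [840])

    def test_matches_exhaustive_scoring(self):
        """The selected connection is the argmin of the independently
        recomputed min-max-normalised weighted score."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            conns = []
            for _ in range(5):
                travel = float(rng.integers(20, 80))
                arrival = int(rng.choice([830, 835, 840]))
                conns.append(
                    _conn(
                        travel_minutes=travel,
                        departure=int(arrival - travel),
                        arrival=arrival,
                        transfers=int(rng.integers(0, 4)),
                        price=float(rng.integers(20, 120)),
                    )
                )
            targets = [840]
            w = WeighingWeights(0.5, 0.1, 0.1, 0.2, 0.1)

            def norm(vals):
                lo, hi = min(vals), max(vals)
                return [0.0 if hi == lo else (v - lo) / (hi - lo) for v in vals]

            t = norm([c.travel_minutes for c in conns])
            s = norm([min(abs(c.arrival - a) for a in targets) for c in conns])
            dep = norm([-c.departure for c in conns])
            tr = norm([c.transfers for c in conns])
            pr = norm([c.price for c in conns])
            scores = [
                0.5 * t[i] + 0.1 * s[i] + 0.1 * dep[i] + 0.2 * tr[i] + 0.1 * pr[i]
                for i in range(5)
            ]
            best = min(
                range(5),
                key=lambda i: (
                    scores[i], conns[i].travel_minutes, conns[i].transfers,
                    conns[i].price, i,
                ),
            )
            assert select_best_connection(conns, w, targets) is conns[best]


def test_pt_membership_subset_of_filter(small_dataset):
    """Every municipality reachable by PT has >= 1 connection passing
    every hard filter to a hosting municipality."""
    cfg = AccessConfig()
    reach = compute_reachability(small_dataset, cfg)
    hosts = {
        cls: {
            m.id
            for m in small_dataset.municipalities
            for f in small_dataset.facilities
            if f.municipality_id == m.id and f.service_class == cls
        }
        for cls in ("residential", "clinic")
    }
    pt = reach[(reach["mode"] == "PT") & reach["within60"]]
    for row in pt.itertuples():
        cls = row.service_class
        if row.municipality in hosts[cls]:
            continue  # hosts are reachable at zero minutes by definition
        feasible = [
            c
            for c in filter_connections(
                small_dataset.timetable, cfg, cfg.arrival_times[cls]
            )
            if c.origin == row.municipality and c.destination in hosts[cls]
        ]
        assert feasible, row.municipality


def test_reachability_band_flags_consistent(small_dataset):
    reach = compute_reachability(small_dataset)
    assert ((reach["minutes"] <= 30) == reach["within30"]).all()
    assert ((reach["minutes"] <= 60) == reach["within60"]).all()
    assert (reach["within60"] | ~reach["within30"]).all()  # 30 => 60
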