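"""Spatial clustering, trip counting and network metrics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import hauloutnet as hn

from conftest import make_events


class TestHaversine:
    def test_identity(self):
        assert hn.haversine(10.0, 59.0, 10.0, 59.0) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert hn.haversine(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.1950, abs=0.01)

    def test_antipodal_maximum(self):
        assert hn.haversine(0.0, 0.0, 180.0, 0.0) == pytest.approx(
            np.pi * 6371.0088, abs=0.01)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            hn.haversine(0.0, 95.0, 1.0, 0.0)


class TestClustering:
    def test_single_event_single_node(self):
        labels = hn.ProximitySiteClusterer().fit_predict([10.0], [59.0])
        assert list(labels) == ["A"]

    def test_chain_rule_links_distant_endpoints(self):
        # collinear points at ~0, 8.9, 17.8 km: endpoints > 10 km apart but chained
        lat = 0.0
        lon = np.array([0.0, 0.08, 0.16])  # 0.08 deg ~ 8.9 km at the equator
        labels = hn.ProximitySiteClusterer().fit_predict(lon, [lat] * 3)
        assert len(set(labels)) == 1

    def test_two_far_points_two_nodes(self):
        labels = hn.ProximitySiteClusterer().fit_predict([0.0, 0.12], [0.0, 0.0])
        assert len(set(labels)) == 2

    def test_labels_west_to_east(self):
        labels = hn.ProximitySiteClusterer().fit_predict([5.0, -3.0, 12.0], [0.0] * 3)
        assert list(labels) == ["B", "A", "C"]

    def test_matches_brute_force_connected_components(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            n = int(rng.integers(2, 120))
            lon = rng.uniform(9, 10, n)
            lat = rng.uniform(58, 59, n)
            labels = hn.ProximitySiteClusterer(10.0).fit_predict(lon, lat)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i, j in itertools.combinations(range(n), 2):
                if hn.haversine(lon[i], lat[i], lon[j], lat[j]) <= 10.0:
                    g.add_edge(i, j)
            comps = {i: k for k, comp in enumerate(nx.connected_components(g))
                     for i in comp}
            # same partition
            seen = {}
            for i in range(n):
                key = comps[i]
                if key in seen:
                    assert labels[i] == seen[key]
                else:
                    assert labels[i] not in seen.values()
                    seen[key] = labels[i]


class TestTransitions:
    def _events(self, nodes, seal="s1"):
        ev = make_events(seal, [(f"{i}D", f"{i}D1h") for i in range(len(nodes))])
        ev["node"] = nodes
        return ev

    def test_no_movement_no_edges(self):
        assert len(hn.count_transitions(self._events(["A", "A", "A"]))) == 0

    def test_shuttle_counts(self):
        out = hn.count_transitions(self._events(["A", "B", "A", "B"]))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["node_u"], row["node_v"]) == ("A", "B")
        assert row["density"] == 3 and row["occupancy"] == 1

    def test_multi_seal_occupancy(self):
        frames = [self._events(["E", "F"] * 3, seal=f"s{k}") for k in range(7)]
        out = hn.count_transitions(pd.concat(frames, ignore_index=True))
        assert out.iloc[0]["density"] == 35 and out.iloc[0]["occupancy"] == 7

    def test_trip_conservation(self, small_cohort):
        events, _, _ = small_cohort
        labelled = hn.cluster_sites(events)
        out = hn.count_transitions(labelled)
        expected = 0
        for _, grp in labelled.sort_values("start").groupby("seal_id"):
            nodes = grp["node"].to_numpy()
            expected += int((nodes[1:] != nodes[:-1]).sum())
        assert out["density"].sum() == expected
        assert (out["occupancy"] <= out["density"]).all()


class TestEdgeWeight:
    @pytest.mark.parametrize("density, occupancy, expected", [
        (34, 7, 4.9), (11, 6, 1.8), (6, 1, 6.0), (5, 5, 1.0),
    ])
    def test_printed_worked_examples(self, density, occupancy, expected):
        assert round(hn.edge_weight(density, occupancy), 1) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hn.edge_weight(5, 0)
        with pytest.raises(ValueError):
            hn.edge_weight(2, 3)


class TestBetweenness:
    def _graph(self, edges):
        g = nx.Graph()
        for u, v, dcw in edges:
            g.add_edge(u, v, dc_weight=dcw)
        return g

    def test_path_graph_middle_node(self):
        g = self._graph([("A", "B", 1.0), ("B", "C", 1.0)])
        sc = hn.betweenness(g)
        assert sc["B"] == pytest.approx(1.0)
        assert sc["A"] == sc["C"] == 0.0

    def test_complete_graph_all_zero(self):
        g = self._graph([(a, b, 1.0) for a, b in itertools.combinations("ABCD", 2)])
        assert (hn.betweenness(g) == 0).all()

    def test_invalid_convention_rejected(self):
        g = self._graph([("A", "B", 1.0)])
        with pytest.raises(ValueError):
            hn.betweenness(g, cost="nope")
        with pytest.raises(ValueError):
            hn.betweenness(g, normalization="nope")

    def test_matches_exhaustive_path_enumeration(self):
        """Brandes scores equal a brute-force all-pairs shortest-path
        enumeration on random small graphs, both cost conventions."""
        rng = np.random.default_rng(5)
        for trial in range(12):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: chr(65 + i) for i in range(n)})
            for _, _, d in g.edges(data=True):
                d["dc_weight"] = float(rng.uniform(0.1, 5.0))
            for cost in ("inverse_dc_weight", "dc_weight"):
                got = hn.betweenness(g, cost=cost, normalization="pairs")
                raw = {v: 0.0 for v in g}
                costof = {(u, v): (1.0 / d["dc_weight"] if cost == "inverse_dc_weight"
                                   else d["dc_weight"])
                          for u, v, d in g.edges(data=True)}
                costof.update({(v, u): c for (u, v), c in list(costof.items())})
                nodes = sorted(g)
                for s, t in itertools.combinations(nodes, 2):
                    paths = list(nx.all_simple_paths(g, s, t))
                    if not paths:
                        continue
                    lengths = [sum(costof[(p[i], p[i + 1])] for i in range(len(p) - 1))
                               for p in paths]
                    best = min(lengths)
                    shortest = [p for p, L in zip(paths, lengths)
                                if L <= best + 1e-12]
                    for v in nodes:
                        if v in (s, t):
                            continue
                        frac = sum(v in p for p in shortest) / len(shortest)
                        raw[v] += frac
                denom = (len(nodes) - 1) * (len(nodes) - 2) / 2
                for v in nodes:
                    assert got[v] == pytest.approx(raw[v] / denom, abs=1e-9)


class TestPrintedNetwork:
    def test_reconstruction_counts(self, printed_network):
        assert printed_network.graph.number_of_nodes() == 13
        assert printed_network.graph.number_of_edges() == 17
        assert printed_network.node_degree()["H"] == 6

    def test_isolated_node_degree_zero(self):
        g = nx.Graph()
        g.add_node("Z")
        g.add_edge("A", "B", dc_weight=1.0)
        deg = pd.Series(dict(g.degree()))
        assert deg["Z"] == 0

    def test_anchor_convention_reproduces_published_scores(self, printed_network):
        cost, norm, scores, err = hn.select_convention(
            printed_network, {"H": 0.62, "B": 0.64})
        assert (cost, norm) == ("inverse_dc_weight", "pairs")
        assert round(scores["H"], 2) == 0.62
        assert round(scores["B"], 2) == 0.64

    def test_edge_invariants(self, printed_network):
        e = printed_network.edges
        assert (e["occupancy"] <= e["density"]).all()
        assert (e["weight"] >= 1.0 - 1e-9).all()
        assert (e["dc_weight"] > 0).all()


class TestBuildNetwork:
    def test_two_site_shuttle(self):
        ev = make_events("s1", [(f"{i}D", f"{i}D1h") for i in range(4)],
                         lon=[0.0, 0.5, 0.0, 0.5], lat=[0.0] * 4)
        nw = hn.build_network(ev)
        assert nw.graph.number_of_nodes() == 2
        assert nw.graph.number_of_edges() == 1
        e = nw.edges.iloc[0]
        assert e["density"] == 3 and e["occupancy"] == 1
        assert e["distance_km"] == pytest.approx(hn.haversine(0, 0, 0.5, 0), rel=1e-6)

    def test_single_sedentary_seal(self):
        ev = make_events("s1", [("0D", "0D1h"), ("1D", "1D1h")])
        nw = hn.build_network(ev)
        assert nw.graph.number_of_nodes() == 1
        assert nw.graph.number_of_edges() == 0

    def test_simulated_trips_match_ground_truth(self, small_cohort):
        events, _, truth = small_cohort
        nw = hn.build_network(events)
        # map node letters back to generator sites via centroids
        sites = hn.SimulationConfig(n_seals=1).sites
        node_site = {}
        for _, r in nw.nodes.iterrows():
            d = hn.haversine(r["lon"], r["lat"], sites["lon"].to_numpy(),
                             sites["lat"].to_numpy())
            node_site[r["node"]] = sites["site_id"].iloc[int(np.argmin(d))]
        got = {}
        for _, e in nw.edges.iterrows():
            key = tuple(sorted((node_site[e["node_u"]], node_site[e["node_v"]])))
            got[key] = got.get(key, 0) + int(e["density"])
        assert got == truth.site_trips

    def test_empty_events_raise(self):
        with pytest.raises(ValueError):
            hn.build_network(make_events("s1", [])[0:0])
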