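"""Proximity-clustered haul-out network and connectivity metrics.

Haul-out locations pooled across seals are grouped into nodes by
transitive ("chain-rule") clustering at a spatial threshold (default
10 km): any two events within the threshold belong to the same node, and
membership propagates through chains even when the endpoints are farther
apart than the threshold.  Nodes are lettered west to east by centroid
longitude.

Edges connect nodes between which at least one seal moved on consecutive
haul-outs.  Each undirected edge carries five metrics:

* ``density``   -- total completed trips between the two nodes;
* ``occupancy`` -- distinct seals making the connection;
* ``weight``    -- trips per seal, ``density / occupancy``;
* ``distance_km`` -- great-circle separation of node centroids (or a
  user-supplied printed distance);
* ``dc_weight`` -- distance-corrected weight, ``weight / distance_km``.

Node metrics are degree and shortest-path betweenness centrality (Brandes,
via networkx) computed on the distance-corrected weights.  The paper-style
convention treats strong connections as short (edge cost = 1/dc_weight) and
normalizes raw betweenness by the number of ordered-into-unordered pairs
(n-1)(n-2)/2; both the cost and the normalization convention are explicit,
logged parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from ._validation import check_coordinates, require_columns

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

COST_CONVENTIONS = ("inverse_dc_weight", "dc_weight")
NORMALIZATIONS = ("pairs", "max")


def haversine(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (WGS84 coordinates, spherical Earth)."""
    check_coordinates(lon1, lat1)
    check_coordinates(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def _letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ..."""
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = chr(ord("A") + r) + s
    return s


class ProximitySiteClusterer:
    """Chain-rule spatial clustering of haul-out locations.

    Two events are linked when their great-circle separation is at most
    ``threshold_km``; clusters are the connected components of that linkage
    graph (single-linkage semantics).  ``fit_predict`` returns a letter
    label per event, assigned A, B, ... by ascending cluster-centroid
    longitude.
    """

    def __init__(self, threshold_km: float = 10.0):
        self.threshold_km = threshold_km

    def get_params(self, deep=True):
        return {"threshold_km": self.threshold_km}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit_predict(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if lon.size == 0:
            raise ValueError("need at least one location")
        check_coordinates(lon, lat)
        n = lon.size
        parent = np.arange(n)

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n - 1):
            d = haversine(lon[i], lat[i], lon[i + 1:], lat[i + 1:])
            for j in np.flatnonzero(np.atleast_1d(d) <= self.threshold_km) + i + 1:
                ra, rb = find(i), find(int(j))
                if ra != rb:
                    parent[rb] = ra
        roots = np.array([find(i) for i in range(n)])
        uniq = np.unique(roots)
        cent_lon = np.array([lon[roots == r].mean() for r in uniq])
        cent_lat = np.array([lat[roots == r].mean() for r in uniq])
        west_to_east = np.argsort(cent_lon, kind="stable")
        name_of_root = {uniq[k]: _letters(rank) for rank, k in enumerate(west_to_east)}
        self.labels_ = np.array([name_of_root[r] for r in roots])
        self.centroids_ = pd.DataFrame({
            "node": [_letters(r) for r in range(len(uniq))],
            "lon": cent_lon[west_to_east], "lat": cent_lat[west_to_east],
        })
        self.n_clusters_ = len(uniq)
        return self.labels_


def cluster_sites(events: pd.DataFrame, threshold_km: float = 10.0) -> pd.DataFrame:
    """Add a ``node`` letter column to events by chain-rule clustering."""
    require_columns(events, ["lon", "lat"], "events")
    clu = ProximitySiteClusterer(threshold_km=threshold_km)
    out = events.copy()
    out["node"] = clu.fit_predict(out["lon"].to_numpy(float), out["lat"].to_numpy(float))
    out.attrs["node_centroids"] = clu.centroids_
    return out


def count_transitions(events: pd.DataFrame) -> pd.DataFrame:
    """Edge density and occupancy from consecutive haul-outs at distinct nodes.

    Each consecutive pair of one seal's time-ordered events at different
    nodes contributes one trip to the unordered node pair; consecutive
    events at the same node are ignored.
    """
    require_columns(events, ["seal_id", "start", "node"], "node-labelled events")
    trips: dict[tuple[str, str], int] = {}
    seals: dict[tuple[str, str], set] = {}
    for sid, grp in events.sort_values("start").groupby("seal_id", sort=False):
        nodes = grp["node"].to_numpy()
        for a, b in zip(nodes[:-1], nodes[1:]):
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            trips[key] = trips.get(key, 0) + 1
            seals.setdefault(key, set()).add(sid)
    rows = [{"node_u": u, "node_v": v, "density": d, "occupancy": len(seals[(u, v)])}
            for (u, v), d in sorted(trips.items())]
    return pd.DataFrame(rows, columns=["node_u", "node_v", "density", "occupancy"])


def edge_weight(density: int, occupancy: int) -> float:
    """Average trips per individual for an edge: density / occupancy."""
    if occupancy < 1:
        raise ValueError("edge occupancy must be at least 1")
    if density < occupancy:
        raise ValueError("edge density cannot be smaller than occupancy")
    return density / occupancy


@dataclass
class HaulOutNetwork:
    """Undirected haul-out connectivity network with the five edge metrics."""

    graph: nx.Graph
    nodes: pd.DataFrame
    edges: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def node_degree(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree").sort_index()

    def betweenness(self, cost: str = "inverse_dc_weight",
                    normalization: str = "pairs") -> pd.Series:
        return betweenness(self.graph, cost=cost, normalization=normalization)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def betweenness(graph: nx.Graph, cost: str = "inverse_dc_weight",
                normalization: str = "pairs") -> pd.Series:
    """Normalized shortest-path betweenness on distance-corrected weights.

    ``cost`` maps an edge's dc_weight to a path cost: ``inverse_dc_weight``
    (default; strong connections act as short) or ``dc_weight``.
    ``normalization`` rescales raw Brandes scores: ``pairs`` divides by
    (n-1)(n-2)/2, ``max`` divides by the maximum raw score.
    """
    if cost not in COST_CONVENTIONS:
        raise ValueError(f"cost must be one of {COST_CONVENTIONS}")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    g = graph.copy()
    for u, v, data in g.edges(data=True):
        dcw = data["dc_weight"]
        if dcw <= 0:
            raise ValueError(f"edge {u}-{v}: non-positive distance-corrected weight")
        data["cost"] = 1.0 / dcw if cost == "inverse_dc_weight" else dcw
    raw = nx.betweenness_centrality(g, weight="cost", normalized=False)
    n = g.number_of_nodes()
    if normalization == "pairs":
        denom = (n - 1) * (n - 2) / 2.0
        scores = {k: (v / denom if denom > 0 else 0.0) for k, v in raw.items()}
    else:
        mx = max(raw.values()) if raw else 0.0
        scores = {k: (v / mx if mx > 0 else 0.0) for k, v in raw.items()}
    return pd.Series(scores, name="betweenness").sort_index()


def _assemble(edges: pd.DataFrame, centroids: pd.DataFrame | None, metadata: dict,
              cost: str, normalization: str) -> HaulOutNetwork:
    edges = edges.copy()
    if "weight" not in edges.columns:
        edges["weight"] = edges["density"] / edges["occupancy"]
    if (edges["occupancy"] < 1).any() or (edges["density"] < edges["occupancy"]).any():
        raise ValueError("every edge needs density >= occupancy >= 1")
    edges["dc_weight"] = edges["weight"] / edges["distance_km"]
    g = nx.Graph()
    for _, r in edges.iterrows():
        if r["node_u"] == r["node_v"]:
            raise ValueError("self-loop edge not allowed")
        g.add_edge(r["node_u"], r["node_v"], distance_km=float(r["distance_km"]),
                   density=int(r["density"]), occupancy=int(r["occupancy"]),
                   weight=float(r["weight"]), dc_weight=float(r["dc_weight"]))
    if centroids is not None:
        for _, r in centroids.iterrows():
            if r["node"] in g:
                g.nodes[r["node"]].update(lon=float(r["lon"]), lat=float(r["lat"]))
            else:
                g.add_node(r["node"], lon=float(r["lon"]), lat=float(r["lat"]))
    deg = pd.Series(dict(g.degree()), name="degree").sort_index()
    btw = betweenness(g, cost=cost, normalization=normalization)
    nodes = pd.DataFrame({"node": deg.index, "degree": deg.to_numpy(),
                          "betweenness": btw.reindex(deg.index).to_numpy()})
    if centroids is not None:
        nodes = nodes.merge(centroids, on="node", how="left")
    metadata = dict(metadata, betweenness_cost=cost, betweenness_normalization=normalization)
    logger.info("network: %d nodes, %d edges (betweenness cost=%s, normalization=%s)",
                g.number_of_nodes(), g.number_of_edges(), cost, normalization)
    return HaulOutNetwork(graph=g, nodes=nodes, edges=edges, metadata=metadata)


def build_network(events: pd.DataFrame, threshold_km: float = 10.0,
                  cost: str = "inverse_dc_weight",
                  normalization: str = "pairs") -> HaulOutNetwork:
    """Cluster events into nodes, count trips, and attach all metrics.

    Edge distances are centroid-to-centroid great-circle distances.
    """
    if len(events) == 0:
        raise ValueError("no events to build a network from")
    labelled = cluster_sites(events, threshold_km=threshold_km)
    centroids = labelled.attrs["node_centroids"]
    trans = count_transitions(labelled)
    cent = centroids.set_index("node")
    if len(trans):
        trans["distance_km"] = [
            haversine(cent.loc[u, "lon"], cent.loc[u, "lat"],
                      cent.loc[v, "lon"], cent.loc[v, "lat"])
            for u, v in zip(trans["node_u"], trans["node_v"])]
    else:
        trans["distance_km"] = pd.Series(dtype=float)
    return _assemble(trans, centroids,
                     {"threshold_km": threshold_km, "distance_source": "centroid_haversine"},
                     cost, normalization)


def network_from_edge_table(edges: pd.DataFrame, cost: str = "inverse_dc_weight",
                            normalization: str = "pairs") -> HaulOutNetwork:
    """Build the network from a pre-computed printed edge table
    (``node_u, node_v, distance_km, occupancy, density[, weight]``);
    the printed distances are authoritative."""
    require_columns(edges, ["node_u", "node_v", "distance_km", "occupancy", "density"],
                    "edge table")
    return _assemble(edges, None, {"distance_source": "edge_table"}, cost, normalization)


def load_printed_edges() -> pd.DataFrame:
    """The published 13-node / 17-edge haul-out network edge table."""
    with resources.files("hauloutnet.data").joinpath("table3_edges.csv").open() as fh:
        return pd.read_csv(fh)


def convention_grid(network: HaulOutNetwork) -> pd.DataFrame:
    """Betweenness of every node under the 2x2 cost x normalization grid."""
    rows = []
    for cost in COST_CONVENTIONS:
        for norm in NORMALIZATIONS:
            sc = betweenness(network.graph, cost=cost, normalization=norm)
            for node, val in sc.items():
                rows.append({"cost": cost, "normalization": norm,
                             "node": node, "betweenness": val})
    return pd.DataFrame(rows)


def select_convention(network: HaulOutNetwork, anchors: dict[str, float]):
    """Pick the grid cell whose scores best match anchor node values.

    ``anchors`` maps node labels to published betweenness scores.  Returns
    ``(cost, normalization, scores, max_abs_err)`` for the cell minimizing
    the maximum absolute deviation from the anchors.
    """
    best = None
    for cost in COST_CONVENTIONS:
        for norm in NORMALIZATIONS:
            sc = betweenness(network.graph, cost=cost, normalization=norm)
            err = max(abs(sc[node] - val) for node, val in anchors.items())
            if best is None or err < best[3]:
                best = (cost, norm, sc, err)
    logger.info("selected betweenness convention cost=%s normalization=%s "
                "(max anchor deviation %.4f)", best[0], best[1], best[3])
    return best
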