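"""Geographical operations on the road network and census polygons.

Distances are planar metres (a projected CRS is assumed upstream; there is
no geodesy here).  Demand points (census-area envelope centroids) and
supply points (candidate ambulance sites) are snapped to their nearest
road-graph node and origin-destination distances are shortest-path lengths
between snap nodes, computed by one single-source Dijkstra per site
(few sites, many areas).  Travel time uses a single scalar road speed,
30 km/h by default, applied network-wide.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .errors import DisconnectedNetworkError, GeometryError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_SPEED_KMH = 30.0

__all__ = [
    "envelope_centroid",
    "count_points_in_polygons",
    "snap_to_node",
    "snap_points_to_nodes",
    "od_matrix",
    "distance_to_time",
]


def envelope_centroid(polygon) -> tuple[float, float]:
    """Centre of a polygon's bounding envelope (NOT the area centroid).

    Accepts a shapely geometry or a sequence of (x, y) vertices.
    """
    if hasattr(polygon, "bounds"):
        if getattr(polygon, "is_empty", False):
            raise GeometryError("empty polygon has no envelope")
        xmin, ymin, xmax, ymax = polygon.bounds
        nvert = len(polygon.exterior.coords) - 1 if isinstance(
            polygon, Polygon) else 3
    else:
        pts = np.asarray(polygon, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError("polygon must be a sequence of (x, y) pairs")
        nvert = len(pts)
        xmin, ymin = pts.min(axis=0)
        xmax, ymax = pts.max(axis=0)
    if nvert < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    if xmax == xmin or ymax == ymin:
        raise GeometryError("degenerate polygon: zero envelope extent")
    return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)


def count_points_in_polygons(
    points, polygons: Mapping[int, Polygon]
) -> tuple[pd.Series, int]:
    """Count points falling in each polygon (point-in-polygon assignment).

    Each point is assigned to at most one polygon; points on a shared
    boundary go to the first polygon in area-id order.  Points covered by
    no polygon land in an "unassigned" bucket (mirroring non-geocodable
    cases in real EMS records).

    Returns ``(counts indexed by area_id, n_unassigned)``.
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(points, dtype=float).reshape(-1, 2)
    ids = sorted(polygons)
    geoms = [polygons[i] for i in ids]
    tree = STRtree(geoms)
    counts = pd.Series(0, index=pd.Index(ids, name="area_id"), name="cases")
    unassigned = 0
    pts = [Point(x, y) for x, y in xy]
    cand_pt, cand_poly = tree.query(pts, predicate="intersects")
    hits: dict[int, int] = {}
    for pi, gi in zip(cand_pt, cand_poly):
        aid = ids[gi]
        if pi not in hits or aid < hits[pi]:
            hits[pi] = aid  # boundary ties: lowest area_id wins
    for pi in range(len(pts)):
        if pi in hits:
            counts[hits[pi]] += 1
        else:
            unassigned += 1
    return counts, unassigned


def _node_arrays(graph: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    ids = np.asarray(sorted(graph.nodes))
    coords = np.asarray(
        [(graph.nodes[i]["x"], graph.nodes[i]["y"]) for i in ids], dtype=float
    )
    return ids, coords


def snap_points_to_nodes(points, graph: nx.Graph,
                         rtol: float = 1e-9) -> np.ndarray:
    """Nearest graph node for each point; distance ties -> lowest node id."""
    if graph.number_of_nodes() == 0:
        raise ParameterError("graph has no nodes")
    xy = np.asarray(points, dtype=float).reshape(-1, 2)
    ids, coords = _node_arrays(graph)
    tree = cKDTree(coords)
    k = min(8, len(ids))
    dist, idx = tree.query(xy, k=k)
    dist = np.atleast_2d(dist.reshape(len(xy), -1))
    idx = np.atleast_2d(idx.reshape(len(xy), -1))
    out = np.empty(len(xy), dtype=ids.dtype)
    for p in range(len(xy)):
        d0 = dist[p, 0]
        tied = idx[p][np.isclose(dist[p], d0, rtol=rtol, atol=0.0)]
        out[p] = ids[tied].min()
    return out


def snap_to_node(point, graph: nx.Graph):
    """Snap a single (x, y) point to its nearest node (ties: lowest id)."""
    return snap_points_to_nodes([point], graph)[0]


def _point_table(points, id_name: str) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.copy()
        if id_name in df.columns:
            df = df.set_index(id_name)
        return df[["x", "y"]]
    xy = np.asarray(points, dtype=float).reshape(-1, 2)
    return pd.DataFrame(xy, columns=["x", "y"])


def od_matrix(graph: nx.Graph, origins, destinations,
              weight: str = "length_m") -> pd.DataFrame:
    """Shortest-path network distances origin x destination, in metres.

    ``origins``/``destinations`` are (x, y) arrays or DataFrames with
    ``x``/``y`` columns (and optionally an ``area_id``/``site_id`` column
    or index used for labelling).  One Dijkstra per destination.  Any
    unreachable pair raises ``DisconnectedNetworkError`` — the planning
    problem is ill-posed on a disconnected instance.
    """
    otab = _point_table(origins, "area_id")
    dtab = _point_table(destinations, "site_id")
    onodes = snap_points_to_nodes(otab.to_numpy(), graph)
    dnodes = snap_points_to_nodes(dtab.to_numpy(), graph)
    snap_err = np.hypot(
        *(otab.to_numpy()
          - np.array([[graph.nodes[n]["x"], graph.nodes[n]["y"]]
                      for n in onodes])).T
    )
    logger.debug("origin snap distance: max %.1f m, mean %.1f m",
                 snap_err.max(initial=0), snap_err.mean() if len(snap_err) else 0)
    D = np.full((len(otab), len(dtab)), np.inf)
    for j, dn in enumerate(dnodes):
        lengths = nx.single_source_dijkstra_path_length(graph, dn,
                                                        weight=weight)
        for i, on in enumerate(onodes):
            d = lengths.get(on)
            if d is not None:
                D[i, j] = d
    if np.isinf(D).any():
        bad = [(otab.index[i], dtab.index[j])
               for i, j in zip(*np.where(np.isinf(D)))]
        raise DisconnectedNetworkError(bad)
    out = pd.DataFrame(D, index=otab.index.copy(), columns=dtab.index.copy())
    out.index.name = "area_id"
    out.columns.name = "site_id"
    return out


def distance_to_time(distance_m, speed_kmh: float = DEFAULT_SPEED_KMH):
    """Convert network distance in metres to travel time in seconds."""
    if speed_kmh <= 0:
        raise ParameterError(f"speed must be positive, got {speed_kmh}")
    return np.multiply(distance_m, 3.6 / speed_kmh)
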