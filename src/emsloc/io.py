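"""Plain-text readers/writers for the pipeline artifacts.

Everything is GeoJSON, CSV or JSON.  Floats are written with Python's
shortest round-tripping repr, so dense OD matrices read back bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic import CensusAreas


def write_areas_geojson(areas: CensusAreas, path) -> None:
    """Census polygons + attribute table as a GeoJSON FeatureCollection."""
    feats = []
    for aid, rec in areas.table.iterrows():
        props = {"area_id": int(aid)}
        for k, v in rec.items():
            props[k] = float(v) if hasattr(v, "item") else v
        feats.append({
            "type": "Feature",
            "geometry": mapping(areas.polygons[aid]),
            "properties": props,
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_areas_geojson(path) -> CensusAreas:
    gj = json.loads(Path(path).read_text())
    rows, polys = [], {}
    for feat in gj["features"]:
        props = dict(feat["properties"])
        aid = int(props.pop("area_id"))
        polys[aid] = shape(feat["geometry"])
        rows.append({"area_id": aid, **props})
    table = pd.DataFrame(rows).set_index("area_id").sort_index()
    return CensusAreas(table=table, polygons=polys)


def write_graph_csv(graph: nx.Graph, nodes_path, edges_path) -> None:
    nodes = pd.DataFrame(
        [(n, graph.nodes[n]["x"], graph.nodes[n]["y"]) for n in sorted(graph)],
        columns=["id", "x", "y"])
    nodes.to_csv(nodes_path, index=False)
    edges = pd.DataFrame(
        [(u, v, d["length_m"]) for u, v, d in graph.edges(data=True)],
        columns=["u", "v", "length_m"])
    edges.to_csv(edges_path, index=False)


def read_graph_csv(nodes_path, edges_path) -> nx.Graph:
    g = nx.Graph()
    for rec in pd.read_csv(nodes_path).itertuples(index=False):
        g.add_node(int(rec.id), x=float(rec.x), y=float(rec.y))
    for rec in pd.read_csv(edges_path).itertuples(index=False):
        g.add_edge(int(rec.u), int(rec.v), length_m=float(rec.length_m))
    xs = nx.get_node_attributes(g, "x")
    ys = nx.get_node_attributes(g, "y")
    g.graph["bbox"] = (min(xs.values()), min(ys.values()),
                       max(xs.values()), max(ys.values()))
    return g


def write_od_long(od: pd.DataFrame, path) -> None:
    """OD matrix as long CSV (area_id, site_id, distance_m)."""
    long = od.stack().rename("distance_m").reset_index()
    long.columns = ["area_id", "site_id", "distance_m"]
    long.to_csv(path, index=False)


def write_od_dense(od: pd.DataFrame, path) -> None:
    od.to_csv(path)


def read_od_dense(path) -> pd.DataFrame:
    od = pd.read_csv(path, index_col=0)
    od.columns = od.columns.astype(int)
    od.index = od.index.astype(int)
    od.index.name = "area_id"
    od.columns.name = "site_id"
    return od


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(v):
    if hasattr(v, "item"):
        return v.item()
    if hasattr(v, "tolist"):
        return v.tolist()
    raise TypeError(f"not JSON serialisable: {type(v)}")
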