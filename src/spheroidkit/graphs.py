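"""Spatial cell graphs: proximity (PCG) and Delaunay (DCG) neighbourhoods.

Vertices are nuclei centroids.  In the PCG two nuclei are neighbours iff
their Euclidean distance is strictly below a threshold (default 40 voxels);
the DCG additionally requires the pair to be an edge of the 3D Delaunay
triangulation, so E_DCG is a subset of E_PCG.  Edge weights are the
Euclidean distances.  The PCG vertex degree counts all cells within the
threshold ball and is read as a local cell density in cells per unit
volume; with the conventional unit volume of 65,450 um^3 it converts to
cells/mm^3.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "CellGraph",
    "build_pcg",
    "build_dcg",
    "density_features",
    "to_cells_per_mm3",
    "UNIT_VOLUME_UM3",
]

#: neighbourhood volume underlying the cells/u.v. density reading (um^3)
UNIT_VOLUME_UM3 = 65_450.0


@dataclasses.dataclass
class CellGraph:
    """An undirected spatial graph over nuclei centroids."""

    kind: str  # "PCG" | "DCG"
    points: np.ndarray
    graph: nx.Graph
    edge_distance_threshold: float

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for i, p in enumerate(self.points):
            g.nodes[i]["z"], g.nodes[i]["y"], g.nodes[i]["x"] = map(float, p)
            g.nodes[i]["degree"] = int(self.graph.degree[i])
        nx.write_graphml(g, path)


def _base_graph(points: np.ndarray) -> tuple[np.ndarray, nx.Graph]:
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    return pts, g


def build_pcg(centroids: np.ndarray, threshold: float = 40.0) -> CellGraph:
    """Proximity cell graph: edge (u,w) iff dist(u,w) < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pts, g = _base_graph(centroids)
    if len(pts) == 0:
        raise ValueError("empty point set")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    for u, w in pairs:
        d = float(np.linalg.norm(pts[u] - pts[w]))
        if d < threshold:  # strict inequality; KDTree query is <=
            g.add_edge(int(u), int(w), weight=d)
    return CellGraph("PCG", pts, g, threshold)


def build_dcg(centroids: np.ndarray, threshold: float = 40.0, _jitter_seed: int = 0) -> CellGraph:
    """Delaunay cell graph: Delaunay edges shorter than the threshold.

    Degenerate (coplanar/collinear) inputs are retried once with a seeded
    jitter of 1e-6 voxels; a persisting failure raises with guidance.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pts, g = _base_graph(centroids)
    if len(pts) < 4:
        raise ValueError("at least 4 points are required for a 3D Delaunay graph")
    try:
        tri = Delaunay(pts)
    except Exception:
        warnings.warn("degenerate point set for Delaunay; retrying with 1e-6 jitter")
        rng = np.random.default_rng(_jitter_seed)
        try:
            tri = Delaunay(pts + rng.normal(scale=1e-6, size=pts.shape))
        except Exception as exc:
            raise ValueError(
                "degenerate point set: jitter the coordinates or add points"
            ) from exc
    edges = set()
    for simplex in tri.simplices:
        for i in range(4):
            for j in range(i + 1, 4):
                edges.add(tuple(sorted((int(simplex[i]), int(simplex[j])))))
    for u, w in edges:
        d = float(np.linalg.norm(pts[u] - pts[w]))
        if d < threshold:
            g.add_edge(u, w, weight=d)
    return CellGraph("DCG", pts, g, threshold)


def density_features(graph: CellGraph, pitch: float | None = None) -> pd.DataFrame:
    """Per-vertex degree and incident-edge-distance statistics.

    Distance statistics are NaN for isolated vertices.  If ``pitch`` is
    given, micrometre columns are added alongside the voxel columns.
    """
    rows = []
    for v in range(graph.n_vertices):
        weights = [graph.graph.edges[v, u]["weight"] for u in graph.graph.neighbors(v)]
        w = np.asarray(weights)
        rows.append({
            "vertex": v,
            "degree": len(weights),
            "neighbor_dist_min": w.min() if len(w) else np.nan,
            "neighbor_dist_max": w.max() if len(w) else np.nan,
            "neighbor_dist_mean": w.mean() if len(w) else np.nan,
            "neighbor_dist_sd": w.std() if len(w) else np.nan,
        })
    df = pd.DataFrame(rows)
    if pitch is not None:
        for col in ["neighbor_dist_min", "neighbor_dist_max", "neighbor_dist_mean", "neighbor_dist_sd"]:
            df[col + "_um"] = df[col] * pitch
    return df


def to_cells_per_mm3(degree: float, unit_volume: float = UNIT_VOLUME_UM3) -> float:
    """Convert a PCG degree (cells/u.v.) to cells/mm^3."""
    if unit_volume <= 0:
        raise ValueError("unit_volume must be positive")
    if degree < 0:
        raise ValueError("degree must be non-negative")
    return degree / unit_volume * 1e9
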