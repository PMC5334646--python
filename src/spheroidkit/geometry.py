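"""Alpha-shape model of a spheroid and depth-from-surface (NDS) computation.

The spheroid body is reconstructed from the nuclei centroids: after a
proximity-based outlier removal (largest connected component of the graph
linking points closer than 20 voxels), the 3D Delaunay tetrahedralization
is filtered by circumradius — tetrahedra with circumradius below ``alpha``
(90 voxels by default) are kept.  The union of kept tetrahedra is the solid
model; faces belonging to exactly one kept tetrahedron form the boundary
triangle mesh.  As alpha grows to infinity the shape converges to the
convex hull; as alpha shrinks to 0 it degenerates to the point set.

Each nucleus's depth is its minimum Euclidean distance to the boundary
mesh; the normalized distance to the surface (NDS) divides by the dataset
maximum, so NDS = 0 on the surface and NDS = 1 at the deepest point.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "SurfaceModel",
    "remove_outliers",
    "build_alpha_shape",
    "depth_from_surface",
    "point_triangle_distance",
]


@dataclasses.dataclass
class SurfaceModel:
    """Alpha-shape tetrahedral complex with its boundary triangle mesh.

    ``points`` are the input coordinates (voxels); ``kept_tetrahedra``
    indexes into ``points`` (rows of 4); ``boundary_triangles`` likewise
    (rows of 3).  ``volume`` is in voxel^3, ``surface_area`` in voxel^2;
    micrometre values follow by multiplying with pitch^3 / pitch^2.
    """

    points: np.ndarray
    kept_tetrahedra: np.ndarray
    boundary_triangles: np.ndarray
    alpha: float
    volume: float
    surface_area: float
    centroid: np.ndarray
    _delaunay: Delaunay = dataclasses.field(repr=False, default=None)
    _kept_mask: np.ndarray = dataclasses.field(repr=False, default=None)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def contains(self, query: np.ndarray) -> np.ndarray:
        """Boolean point-in-shape test (inside any kept tetrahedron)."""
        query = np.asarray(query, dtype=np.float64).reshape(-1, 3)
        simplex = self._delaunay.find_simplex(query)
        inside = simplex >= 0
        inside[inside] = self._kept_mask[simplex[inside]]
        return inside

    def to_json(self, path: str | Path | None = None) -> dict:
        summary = {
            "alpha": self.alpha,
            "n_points": self.n_points,
            "volume_voxels3": self.volume,
            "surface_area_voxels2": self.surface_area,
            "centroid": self.centroid.tolist(),
            "n_tetrahedra": int(len(self.kept_tetrahedra)),
            "n_boundary_triangles": int(len(self.boundary_triangles)),
        }
        if path is not None:
            Path(path).write_text(json.dumps(summary, indent=2))
        return summary

    def write_ply(self, path: str | Path) -> None:
        """Export the boundary mesh as ASCII PLY."""
        verts = self.points
        faces = self.boundary_triangles
        lines = [
            "ply", "format ascii 1.0",
            f"element vertex {len(verts)}",
            "property float x", "property float y", "property float z",
            f"element face {len(faces)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        lines += [f"{p[2]:.6f} {p[1]:.6f} {p[0]:.6f}" for p in verts]
        lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in faces]
        Path(path).write_text("\n".join(lines) + "\n")


def remove_outliers(centroids: np.ndarray, outlier_distance_threshold: float = 20.0) -> np.ndarray:
    """Largest connected component of the proximity graph at the threshold.

    Points further than ``outlier_distance_threshold`` from the main
    aggregate (false-positive detections outside the spheroid) are dropped.
    """
    pts = np.asarray(centroids, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if outlier_distance_threshold <= 0:
        raise ValueError("threshold must be positive")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(outlier_distance_threshold, output_type="ndarray")
    n = len(pts)
    if len(pairs) == 0:
        adj = coo_matrix((n, n))
    else:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    n_comp, comp = connected_components(adj, directed=False)
    largest = np.argmax(np.bincount(comp))
    keep = comp == largest
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"removed {dropped} outlier point(s) outside the main aggregate")
    return pts[keep]


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra (vectorized)."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]] - a
    c = points[simplices[:, 2]] - a
    d = points[simplices[:, 3]] - a
    # circumcentre relative to a solves 2 M x = (|b|^2, |c|^2, |d|^2)
    M = np.stack([b, c, d], axis=1)
    rhs = 0.5 * np.stack(
        [np.sum(b * b, axis=1), np.sum(c * c, axis=1), np.sum(d * d, axis=1)], axis=1
    )
    det = np.linalg.det(M)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        x = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(x, axis=1)
    return radii


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]] - a
    c = points[simplices[:, 2]] - a
    d = points[simplices[:, 3]] - a
    return np.abs(np.einsum("ij,ij->i", b, np.cross(c, d))) / 6.0


def build_alpha_shape(points: np.ndarray, alpha: float = 90.0) -> SurfaceModel:
    """Alpha shape of a 3D point set (circumradius < alpha criterion).

    Returns the solid model with its volume (sum of kept tetra volumes),
    boundary triangle mesh (faces of exactly one kept tetrahedron), surface
    area, and volume-weighted centroid.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("at least 4 points are required for a 3D alpha shape")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # scipy raises QhullError on degenerate input
        raise ValueError(f"degenerate point set (coplanar/collinear): {exc}") from exc

    radii = _circumradii(pts, tri.simplices)
    kept_mask = radii < alpha
    if not kept_mask.any():
        raise ValueError("alpha too small: no tetrahedron kept")
    kept = tri.simplices[kept_mask]

    vols = _tet_volumes(pts, kept)
    volume = float(vols.sum())
    tet_centroids = pts[kept].mean(axis=1)
    centroid = (tet_centroids * vols[:, None]).sum(axis=0) / volume

    # boundary faces: appear in exactly one kept tetrahedron
    faces = kept[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
    faces_sorted = np.sort(faces, axis=1)
    _, idx, counts = np.unique(faces_sorted, axis=0, return_index=True, return_counts=True)
    boundary = faces_sorted[idx[counts == 1]]

    v0, v1, v2 = pts[boundary[:, 0]], pts[boundary[:, 1]], pts[boundary[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)

    return SurfaceModel(
        points=pts,
        kept_tetrahedra=kept,
        boundary_triangles=boundary,
        alpha=float(alpha),
        volume=volume,
        surface_area=float(areas.sum()),
        centroid=centroid,
        _delaunay=tri,
        _kept_mask=kept_mask,
    )


def point_triangle_distance(queries: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each query point to a triangle set.

    ``triangles`` has shape (m, 3, 3).  Uses the standard barycentric
    clamping construction; queries are processed in chunks to bound memory.
    """
    queries = np.asarray(queries, dtype=np.float64).reshape(-1, 3)
    tri = np.asarray(triangles, dtype=np.float64)
    if tri.size == 0:
        raise ValueError("empty triangle set")
    a = tri[:, 0]
    ab = tri[:, 1] - a
    ac = tri[:, 2] - a

    out = np.empty(len(queries))
    chunk = max(1, int(2e6 // max(len(tri), 1)))
    for start in range(0, len(queries), chunk):
        p = queries[start:start + chunk][:, None, :]  # (q,1,3)
        ap = p - a[None]  # (q,m,3)
        d1 = np.einsum("qmi,mi->qm", ap, ab)
        d2 = np.einsum("qmi,mi->qm", ap, ac)
        bp = p - tri[None, :, 1]
        d3 = np.einsum("qmi,mi->qm", bp, ab)
        d4 = np.einsum("qmi,mi->qm", bp, ac)
        cp = p - tri[None, :, 2]
        d5 = np.einsum("qmi,mi->qm", cp, ab)
        d6 = np.einsum("qmi,mi->qm", cp, ac)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(denom != 0, vb / denom, 0.0)
            w = np.where(denom != 0, vc / denom, 0.0)

        # interior case first, then clamp to edges/vertices
        closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

        # vertex A region
        m = (d1 <= 0) & (d2 <= 0)
        closest = np.where(m[..., None], a[None] * np.ones_like(p), closest)
        # vertex B region
        m = (d3 >= 0) & (d4 <= d3)
        closest = np.where(m[..., None], tri[None, :, 1] * np.ones_like(p), closest)
        # vertex C region
        m = (d6 >= 0) & (d5 <= d6)
        closest = np.where(m[..., None], tri[None, :, 2] * np.ones_like(p), closest)
        # edge AB
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        closest = np.where(m[..., None], a[None] + t_ab[..., None] * ab[None], closest)
        # edge AC
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        closest = np.where(m[..., None], a[None] + t_ac[..., None] * ac[None], closest)
        # edge BC
        m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_bc = np.where(
                (d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0
            )
        bc = tri[:, 2] - tri[:, 1]
        closest = np.where(
            m[..., None], tri[None, :, 1] + t_bc[..., None] * bc[None], closest
        )

        out[start:start + chunk] = np.sqrt(
            np.min(np.sum((p - closest) ** 2, axis=2), axis=1)
        )
    return out


def depth_from_surface(
    centroids: np.ndarray, surface: SurfaceModel
) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the boundary mesh and NDS for each centroid.

    Returns ``(distances, nds)``; NDS is the distance divided by the
    dataset maximum (0 = surface, 1 = deepest point).  If all points lie on
    the surface the NDS is all zeros.
    """
    if len(surface.boundary_triangles) == 0:
        raise ValueError("surface model has an empty boundary mesh")
    tri = surface.points[surface.boundary_triangles]
    dist = point_triangle_distance(centroids, tri)
    dmax = dist.max() if len(dist) else 0.0
    nds = dist / dmax if dmax > 0 else np.zeros_like(dist)
    return dist, nds
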