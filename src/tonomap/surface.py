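"""Triangulated flat cortical patches and geodesic machinery.

The synthetic cohort lives on a regular flat grid standing in for a
flattened temporal-plane patch. Geodesic distances are shortest paths on
the mesh edge graph (exact on flat patches up to discretisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

__all__ = ["SurfaceMesh", "make_flat_patch"]


@dataclass
class SurfaceMesh:
    """Triangulated surface patch.

    vertices : (V, 3) float array, mm coordinates
    triangles : (F, 3) int array of vertex indices
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @cached_property
    def vertex_area(self) -> np.ndarray:
        """Per-vertex area: one third of each incident triangle (mm^2)."""
        area = np.zeros(self.n_vertices)
        np.add.at(area, self.triangles.ravel(), np.repeat(self.triangle_areas / 3.0, 3))
        return area

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2) with i < j."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency (CSR)."""
        e = self.edges
        data = np.ones(len(e), dtype=bool)
        a = sp.coo_matrix(
            (data, (e[:, 0], e[:, 1])), shape=(self.n_vertices, self.n_vertices)
        )
        a = a + a.T
        return a.tocsr()

    @cached_property
    def edge_graph(self) -> sp.csr_matrix:
        """Edge graph weighted by Euclidean edge length."""
        e = self.edges
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        g = sp.coo_matrix(
            (w, (e[:, 0], e[:, 1])), shape=(self.n_vertices, self.n_vertices)
        )
        g = g + g.T
        return g.tocsr()

    def geodesic_distances(self, sources=None, limit: float = np.inf) -> np.ndarray:
        """Shortest-path distances from `sources` (default: all vertices)."""
        indices = None if sources is None else np.atleast_1d(sources)
        return dijkstra(self.edge_graph, directed=False, indices=indices, limit=limit)

    def neighbor_smooth(self, values: np.ndarray, steps: int = 1) -> np.ndarray:
        """Nearest-neighbour smoothing: each step averages {v} and neighbours.

        Works on real or complex per-vertex arrays; extra trailing axes are
        smoothed independently.
        """
        a = self.adjacency.astype(float) + sp.identity(self.n_vertices, format="csr")
        norm = np.asarray(a.sum(axis=1)).ravel()
        out = np.asarray(values)
        for _ in range(steps):
            smoothed = a @ out
            out = smoothed / (norm.reshape((-1,) + (1,) * (out.ndim - 1)))
        return out


def make_flat_patch(nx: int, ny: int, spacing_mm: float = 1.0) -> SurfaceMesh:
    """Regular triangulated nx-by-ny grid in the z=0 plane.

    Interior vertex areas equal spacing_mm**2; boundary vertices carry less.
    """
    if nx < 2 or ny < 2:
        raise ValueError("grid must be at least 2x2")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    xs = np.arange(nx) * spacing_mm
    ys = np.arange(ny) * spacing_mm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = i * ny + j + 1
            v10 = (i + 1) * ny + j
            v11 = (i + 1) * ny + j + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return SurfaceMesh(vertices=vertices, triangles=np.asarray(tris))
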