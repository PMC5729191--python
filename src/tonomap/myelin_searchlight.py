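"""Searchlight covariance between R1 (myelin proxy) and map amplitude.

Within a small geodesic disk roved over every vertex, the normalized
spatial covariance (Pearson correlation by default) between the per-vertex
R1 map and a response-amplitude map quantifies whether myelination and
functional selectivity change together locally. The R1 surface gradient
locates myeloarchitectonic borders as ridges of gradient magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .surface import SurfaceMesh

__all__ = [
    "SearchlightResult",
    "geodesic_disks",
    "searchlight_normcov",
    "average_normcov",
    "surface_gradient",
]


@dataclass
class SearchlightResult:
    normcov: np.ndarray  # (V,), NaN where invalid
    valid: np.ndarray  # (V,) bool
    n_in_disk: np.ndarray  # (V,) int
    disk_radius_mm: float


def geodesic_disks(mesh: SurfaceMesh, radius_mm: float = 4.0) -> list[np.ndarray]:
    """Per-vertex sets of vertices within the geodesic radius (incl. self)."""
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(mesh.adjacency, directed=False)
    if n_comp > 1:
        warnings.warn("mesh has disconnected components; disks stay per-component")
    dist = mesh.geodesic_distances(limit=radius_mm)
    return [np.flatnonzero(dist[v] <= radius_mm) for v in range(mesh.n_vertices)]


def searchlight_normcov(
    r1_map: np.ndarray,
    amp_map: np.ndarray,
    disks: list[np.ndarray],
    radius_mm: float = 4.0,
    normalization: str = "pearson",
) -> SearchlightResult:
    """Normalized covariance of (R1, amplitude) within each vertex's disk.

    normalization="pearson" divides the within-disk covariance by both
    within-disk SDs (so |normcov| <= 1); "global" divides by the product of
    the whole-map SDs instead. Disks with fewer than 3 vertices or zero
    variance are flagged invalid (NaN), never propagated.
    """
    r1 = np.asarray(r1_map, dtype=float)
    amp = np.asarray(amp_map, dtype=float)
    if r1.shape != amp.shape or len(r1) != len(disks):
        raise ValueError("maps and disks must share the vertex set")
    if normalization not in ("pearson", "global"):
        raise ValueError("normalization must be 'pearson' or 'global'")
    global_denom = r1.std() * amp.std()

    V = len(disks)
    normcov = np.full(V, np.nan)
    valid = np.zeros(V, dtype=bool)
    n_in = np.array([len(d) for d in disks])
    for v, d in enumerate(disks):
        if len(d) < 3:
            continue
        x, y = r1[d], amp[d]
        sx, sy = x.std(), y.std()
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        if normalization == "pearson":
            if sx <= 0 or sy <= 0:
                continue
            normcov[v] = cov / (sx * sy)
        else:
            if global_denom <= 0:
                continue
            normcov[v] = cov / global_denom
        valid[v] = True
    return SearchlightResult(
        normcov=normcov, valid=valid, n_in_disk=n_in, disk_radius_mm=radius_mm
    )


def average_normcov(results: Sequence[SearchlightResult]) -> np.ndarray:
    """Vertexwise cross-subject mean of normcov maps, ignoring invalid."""
    stack = np.stack([r.normcov for r in results])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(stack, axis=0)


def surface_gradient(values: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Magnitude of the surface gradient of a scalar map (map units per mm).

    The gradient of the linear interpolant is computed per triangle and
    aggregated to vertices by area-weighted vector averaging; degenerate
    triangles are skipped.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != mesh.n_vertices:
        raise ValueError("map does not match the mesh")
    tri = mesh.triangles
    p = mesh.vertices[tri]
    f = values[tri]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    g11 = np.einsum("ij,ij->i", e1, e1)
    g12 = np.einsum("ij,ij->i", e1, e2)
    g22 = np.einsum("ij,ij->i", e2, e2)
    det = g11 * g22 - g12**2
    ok = det > 1e-18
    if not np.all(ok):
        warnings.warn("degenerate triangles skipped in surface gradient")
    df1 = f[:, 1] - f[:, 0]
    df2 = f[:, 2] - f[:, 0]
    c1 = np.where(ok, (g22 * df1 - g12 * df2) / np.where(ok, det, 1.0), 0.0)
    c2 = np.where(ok, (g11 * df2 - g12 * df1) / np.where(ok, det, 1.0), 0.0)
    grad = c1[:, None] * e1 + c2[:, None] * e2  # per-triangle gradient vector

    areas = np.where(ok, mesh.triangle_areas, 0.0)
    acc = np.zeros((mesh.n_vertices, 3))
    wsum = np.zeros(mesh.n_vertices)
    for corner in range(3):
        np.add.at(acc, tri[:, corner], grad * areas[:, None])
        np.add.at(wsum, tri[:, corner], areas)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_grad = acc / wsum[:, None]
    mean_grad[wsum == 0] = 0.0
    return np.linalg.norm(mean_grad, axis=1)
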