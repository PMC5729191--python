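"""Group-level surface statistics.

Concordance maps score vertexwise agreement between two best-band maps
(chance 1/5 for five bands) and are tested across subjects against that
chance level. Familywise error over the surface is controlled by cluster
size: suprathreshold clusters smaller than a minimum area derived from a
null distribution of smoothness-matched random fields are excluded.
Attend-vs-ignore maps contrast each vertex's best (and worst) band
coefficient between the regression in which that band was attended and the
one in which it was ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .glm_mapping import BandBetas, ExtremumMap
from .surface import SurfaceMesh

__all__ = [
    "ClusterNull",
    "ClusterResult",
    "concordance_map",
    "group_ttest_vs_chance",
    "estimate_smooth_steps",
    "cluster_correct",
    "attend_vs_ignore_diff",
    "attend_vs_ignore_group",
]

T_CAP = 1e12


@dataclass
class ClusterNull:
    """Specification of the cluster-size null distribution."""

    vertexwise_alpha: float = 0.01
    n_iter: int = 10000
    corrected_alpha: float = 0.001
    smooth_steps: Optional[int] = None  # None: estimate from the map
    seed: int = 0


@dataclass
class ClusterResult:
    surviving_mask: np.ndarray  # (V,) bool
    clusters: list[dict]  # id, area_mm2, vertices, survives
    min_area_mm2: float
    null_max_areas: np.ndarray
    smooth_steps: int


def concordance_map(wta_a: ExtremumMap, wta_b: ExtremumMap) -> np.ndarray:
    """1 where the two maps assign the same best band, else 0."""
    a, b = wta_a.wta_band, wta_b.wta_band
    if a.shape != b.shape:
        raise ValueError("maps are on different vertex sets")
    return (a == b).astype(float)


def group_ttest_vs_chance(
    subject_maps: Sequence[np.ndarray], chance: float = 0.20
) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t across subjects vs the chance level, one-sided (greater).

    Returns (t map, p map). Zero cross-subject variance yields a capped t
    with the sign of the mean difference.
    """
    maps = np.stack(subject_maps)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    diff = mean - chance
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.sign(diff) * T_CAP, t)
    t = np.clip(t, -T_CAP, T_CAP)
    p = stats.t.sf(t, n - 1)
    return t, p


def _smoothed_null_field(
    mesh: SurfaceMesh, steps: int, rng: np.random.Generator
) -> np.ndarray:
    z = rng.standard_normal(mesh.n_vertices)
    if steps > 0:
        z = mesh.neighbor_smooth(z, steps)
        z = (z - z.mean()) / max(z.std(), 1e-12)
    return z


def _neighbor_correlation(values: np.ndarray, mesh: SurfaceMesh) -> float:
    e = mesh.edges
    a, b = values[e[:, 0]], values[e[:, 1]]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def estimate_smooth_steps(
    values: np.ndarray,
    mesh: SurfaceMesh,
    max_steps: int = 6,
    n_probe: int = 20,
    seed: int = 0,
) -> int:
    """Pick the smoothing-step count whose null fields match the map's
    neighbour correlation; falls back to 0 (with a warning) if the map's
    spatial autocorrelation cannot be estimated."""
    r_obs = _neighbor_correlation(values, mesh)
    if not np.isfinite(r_obs):
        warnings.warn("smoothness estimation failed; using unsmoothed null")
        return 0
    rng = np.random.default_rng(seed)
    best_k, best_err = 0, np.inf
    for k in range(max_steps + 1):
        rs = [
            _neighbor_correlation(_smoothed_null_field(mesh, k, rng), mesh)
            for _ in range(n_probe)
        ]
        err = abs(np.nanmean(rs) - r_obs)
        if err < best_err:
            best_k, best_err = k, err
    return best_k


def _cluster_areas(mask: np.ndarray, mesh: SurfaceMesh):
    """Connected suprathreshold components and their surface areas."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return [], np.array([])
    sub = mesh.adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    areas = np.zeros(n_comp)
    np.add.at(areas, labels, mesh.vertex_area[idx])
    comps = [idx[labels == c] for c in range(n_comp)]
    return comps, areas


def cluster_correct(
    p_map: np.ndarray,
    mesh: SurfaceMesh,
    null: ClusterNull | None = None,
    smoothness_source: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Cluster-size correction by iterative random sampling on the mesh.

    Null fields are white Gaussian maps smoothed by a number of
    nearest-neighbour steps matched to the spatial autocorrelation of
    `smoothness_source` (default: a z transform of the p map itself),
    thresholded at the vertexwise alpha; the maximum suprathreshold cluster
    area is recorded per iteration and the minimum surviving area is the
    (1 - corrected_alpha) quantile of that null.
    """
    null = null or ClusterNull()
    rng = np.random.default_rng(null.seed)
    if null.smooth_steps is not None:
        k = null.smooth_steps
    else:
        src = smoothness_source
        if src is None:
            src = -stats.norm.ppf(np.clip(p_map, 1e-15, 1 - 1e-15))
        k = estimate_smooth_steps(src, mesh, seed=null.seed)

    z_thresh = stats.norm.isf(null.vertexwise_alpha)
    null_max = np.empty(null.n_iter)
    for i in range(null.n_iter):
        z = _smoothed_null_field(mesh, k, rng)
        _, areas = _cluster_areas(z > z_thresh, mesh)
        null_max[i] = areas.max() if len(areas) else 0.0
    # Cluster areas on a mesh are heavily tied (vertex areas are discrete),
    # so an interpolated quantile can land on a tied value and let the whole
    # tie mass through. Use the smallest observed area whose empirical
    # exceedance probability is <= the corrected alpha instead.
    sorted_max = np.sort(null_max)
    tail = null.corrected_alpha * null.n_iter
    candidates = np.unique(sorted_max)
    n_ge = null.n_iter - np.searchsorted(sorted_max, candidates, side="left")
    ok = candidates[n_ge <= tail]
    min_area = float(ok[0]) if len(ok) else float(np.nextafter(sorted_max[-1], np.inf))

    comps, areas = _cluster_areas(p_map < null.vertexwise_alpha, mesh)
    surviving = np.zeros(len(p_map), dtype=bool)
    clusters = []
    for cid, (verts, area) in enumerate(zip(comps, areas)):
        keep = area >= min_area
        if keep:
            surviving[verts] = True
        clusters.append(
            {"id": cid, "area_mm2": float(area), "vertices": verts, "survives": bool(keep)}
        )
    return ClusterResult(
        surviving_mask=surviving,
        clusters=clusters,
        min_area_mm2=min_area,
        null_max_areas=null_max,
        smooth_steps=k,
    )


def attend_vs_ignore_diff(
    attn_betas: BandBetas, wta: ExtremumMap, lta: ExtremumMap
) -> dict[str, np.ndarray]:
    """Per-vertex attended-minus-ignored differences at the best/worst band.

    diff_best = beta_attended(wta band) - beta_ignored(wta band), likewise
    diff_worst at the LTA band; diff_of_diff = diff_best - diff_worst
    separates multiplicative from additive attentional gain (an additive
    gain moves best and worst bands equally).
    """
    if attn_betas.ignored is None:
        raise ValueError("ignored-band betas required (not a tonotopy fit)")
    v = np.arange(len(attn_betas.attended))
    diff_best = attn_betas.attended[v, wta.wta_band] - attn_betas.ignored[v, wta.wta_band]
    diff_worst = attn_betas.attended[v, lta.lta_band] - attn_betas.ignored[v, lta.lta_band]
    return {
        "diff_best": diff_best,
        "diff_worst": diff_worst,
        "diff_of_diff": diff_best - diff_worst,
    }


def attend_vs_ignore_group(
    subject_betas: Sequence[BandBetas],
    subject_wta: Sequence[ExtremumMap],
    subject_lta: Sequence[ExtremumMap],
) -> dict[str, np.ndarray]:
    """Cross-subject attended-vs-ignored t maps (two-sided p).

    Each subject's differences are evaluated at that subject's own best and
    worst bands, then tested against zero across subjects.
    """
    diffs = [
        attend_vs_ignore_diff(b, w, l)
        for b, w, l in zip(subject_betas, subject_wta, subject_lta)
    ]
    out: dict[str, np.ndarray] = {}
    n = len(diffs)
    for key in ("diff_best", "diff_worst", "diff_of_diff"):
        stack = np.stack([d[key] for d in diffs])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.sign(mean) * T_CAP, t)
        out[key] = mean
        out[f"{key}_t"] = np.clip(t, -T_CAP, T_CAP)
        out[f"{key}_p"] = 2 * stats.t.sf(np.abs(out[f"{key}_t"]), n - 1)
    return out
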