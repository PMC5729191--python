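"""ROI quilt: tile the patch with small geodesic ROIs and test, per ROI,
whether the five-band tonotopy response profile predicts the attention
profile, with subject as a random factor.

Each ROI is the set of vertices within a geodesic radius (default 4 mm) of
a lattice of centre vertices. Per ROI, mean band coefficients are computed
for each subject under both conditions, and a mixed model with a random
subject intercept regresses the attention profile on the tonotopy profile;
the partial t of the slope is z-transformed (probit of the t CDF) and
thresholded Bonferroni-corrected over the number of ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm_mapping import BandBetas
from .surface import SurfaceMesh

__all__ = ["ROISet", "make_roi_quilt", "roi_profile_regression"]

Z_CAP = 8.0


@dataclass
class ROISet:
    rois: list[np.ndarray]  # vertex indices per ROI
    centers: np.ndarray  # (n_rois,) center vertex index
    radius_mm: float

    @property
    def n_rois(self) -> int:
        return len(self.rois)


def make_roi_quilt(
    mesh: SurfaceMesh, radius_mm: float = 4.0, spacing_mm: float = 8.0
) -> ROISet:
    """Flood geodesic disks around a near-regular lattice of centre vertices."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    xy = mesh.vertices[:, :2]
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    # inset the lattice by the radius so ROIs stay off the patch edge
    xs = np.arange(lo[0] + radius_mm, hi[0] - radius_mm + 1e-9, spacing_mm)
    ys = np.arange(lo[1] + radius_mm, hi[1] - radius_mm + 1e-9, spacing_mm)
    if len(xs) == 0 or len(ys) == 0:
        xs, ys = [np.mean([lo[0], hi[0]])], [np.mean([lo[1], hi[1]])]
    centers = []
    for x in xs:
        for y in ys:
            d2 = np.sum((xy - [x, y]) ** 2, axis=1)
            centers.append(int(np.argmin(d2)))
    centers = np.unique(centers)

    dist = mesh.geodesic_distances(centers, limit=radius_mm)
    rois = [np.flatnonzero(dist[i] <= radius_mm) for i in range(len(centers))]
    if any(len(r) < 3 for r in rois):
        raise ValueError(
            "ROI radius is too small for the mesh spacing (near-empty ROI)"
        )
    return ROISet(rois=rois, centers=centers, radius_mm=radius_mm)


def _roi_profiles(
    subject_betas: Sequence[BandBetas], roi: np.ndarray
) -> np.ndarray:
    """(n_subjects, 5) mean attended-band coefficients within one ROI."""
    return np.stack([b.attended[roi].mean(axis=0) for b in subject_betas])


def _fit_one_roi(x: np.ndarray, y: np.ndarray, groups: np.ndarray) -> dict:
    """Mixed model y ~ x with a random intercept per subject.

    Returns slope, t, z and a `flagged` marker for singular fits. Perfect
    fits (zero residual) are reported at the z cap rather than flagged.
    """
    n = len(y)
    df = n - 2
    if np.ptp(x) < 1e-12:
        return {"slope": np.nan, "t": np.nan, "z": np.nan, "flagged": True}
    # perfect linear relation: slope recoverable, z at cap
    slope0, icpt0 = np.polyfit(x, y, 1)
    resid0 = y - (slope0 * x + icpt0)
    if np.max(np.abs(resid0)) < 1e-10 * max(1.0, np.max(np.abs(y))):
        return {"slope": float(slope0), "t": np.inf, "z": Z_CAP, "flagged": False}
    try:
        import statsmodels.api as sm

        exog = np.column_stack([np.ones(n), x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
        slope = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(se) or se <= 0:
            raise ValueError("degenerate slope SE")
        t = slope / se
    except Exception:
        return {"slope": np.nan, "t": np.nan, "z": np.nan, "flagged": True}
    z = stats.norm.ppf(np.clip(stats.t.cdf(t, df), 1e-16, 1 - 1e-16))
    return {"slope": slope, "t": float(t), "z": float(np.clip(z, -Z_CAP, Z_CAP)), "flagged": False}


def roi_profile_regression(
    tono: Sequence[BandBetas],
    attn: Sequence[BandBetas],
    rois: ROISet,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI mixed-model fit of attention profiles on tonotopy profiles.

    `tono` and `attn` hold one condition-level BandBetas per subject.
    Returns a table with slope, partial t, z, and a Bonferroni-corrected
    significance flag (one-sided, z above the threshold for n_rois tests);
    singular fits are flagged and excluded from the significant set.
    """
    if len(tono) != len(attn):
        raise ValueError("conditions have different subject counts")
    n_sub = len(tono)
    groups = np.repeat(np.arange(n_sub), 5)
    z_thresh = stats.norm.isf(alpha / rois.n_rois)

    rows = []
    for i, roi in enumerate(rois.rois):
        x = _roi_profiles(tono, roi).ravel()
        y = _roi_profiles(attn, roi).ravel()
        fit = _fit_one_roi(x, y, groups)
        fit["roi"] = i
        fit["n_vertices"] = len(roi)
        fit["significant"] = bool(
            (not fit["flagged"]) and np.isfinite(fit["z"]) and fit["z"] >= z_thresh
        )
        rows.append(fit)
    table = pd.DataFrame(rows)
    table.attrs["z_threshold"] = float(z_thresh)
    table.attrs["alpha"] = alpha
    return table
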