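"""Regression mapping: band regressors, prewhitened GLS, extremum maps.

Each run is modelled with one 12.8 s boxcar per attended frequency band
convolved with the gamma HRF, a verbal-cue regressor and an intercept; for
attention runs the ignored (distractor) bands are modelled in a separate
regression, as in the original analysis. Data and regressors are high-pass
filtered (100 s, discrete-cosine basis) and prewhitened with a per-vertex
AR(1) model. Runs are combined with fixed effects (inverse-variance
weighting); winner- and loser-takes-all maps take the per-vertex argmax /
argmin over the five band coefficients, which are referenced to the silent
baseline via the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hemodynamics import hrf_kernel
from .stimulus_design import BLOCK_DURATION_S, N_BANDS, PROMPT_DURATION_S, RunSchedule
from .synthetic_cohort import VertexSeries

__all__ = [
    "DesignMatrix",
    "BandBetas",
    "ExtremumMap",
    "DesignError",
    "dct_highpass_basis",
    "build_design_matrix",
    "fit_glm_prewhitened",
    "combine_fixed_effects",
    "extremum_maps",
]


class DesignError(ValueError):
    """Raised for rank-deficient or excessively collinear designs."""


@dataclass
class DesignMatrix:
    """Run-level design: attended-band fit, plus a parallel ignored-band fit.

    Columns of each matrix: 5 band regressors, cue, intercept. `ignored`
    is None for the tonotopy condition. Non-constant columns are high-pass
    filtered with the same basis applied to the data.
    """

    attended: np.ndarray
    ignored: Optional[np.ndarray]
    column_names: list[str]
    highpass_basis: np.ndarray
    condition: str


@dataclass
class BandBetas:
    """Per-vertex band coefficients (and variances) for one condition."""

    attended: np.ndarray  # (V, 5)
    attended_var: np.ndarray
    ignored: Optional[np.ndarray]  # (V, 5) or None (tonotopy)
    ignored_var: Optional[np.ndarray]
    condition: str
    n_runs_combined: int = 1


@dataclass
class ExtremumMap:
    wta_band: np.ndarray  # (V,) int
    lta_band: np.ndarray
    wta_value: np.ndarray
    lta_value: np.ndarray
    tie_flag: np.ndarray  # (V,) bool


def dct_highpass_basis(n_timepoints: int, tr_s: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Discrete-cosine drift basis spanning periods longer than `cutoff_s`."""
    order = int(np.floor(2.0 * n_timepoints * tr_s / cutoff_s))
    t = np.arange(n_timepoints)
    k = np.arange(1, order + 1)
    basis = np.cos(np.pi * np.outer(2 * t + 1, k) / (2.0 * n_timepoints))
    # orthonormalise for a stable projection
    q, _ = np.linalg.qr(basis)
    return q


def _residualise(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the span of `basis` from columns/rows-as-time of x (time first)."""
    return x - basis @ (basis.T @ x)


def _regressor_trains(run: RunSchedule, dt: float = 0.1):
    """Fine-grid attended/ignored band boxcars and cue events, retained time."""
    n_fine = int(round(run.retained_duration_s / dt))
    att = np.zeros((N_BANDS, n_fine))
    ign = np.zeros((N_BANDS, n_fine))
    cue = np.zeros(n_fine)
    for blk in run.blocks:
        i0 = int(round(blk.onset_s / dt))
        i1 = int(round((blk.onset_s + BLOCK_DURATION_S) / dt))
        att[blk.band.index, i0:i1] = 1.0
        if blk.distractor_band is not None:
            ign[blk.distractor_band.index, i0:i1] = 1.0
        cue[i0 : int(round((blk.onset_s + PROMPT_DURATION_S) / dt))] = 1.0
    return att, ign, cue


def build_design_matrix(
    run: RunSchedule,
    tr_s: float | None = None,
    hrf_lag_s: float = 6.0,
    hrf_sd_s: float = 3.0,
    highpass_s: float = 100.0,
    dt: float = 0.1,
    max_condition_number: float = 1e6,
) -> DesignMatrix:
    """HRF-convolved, high-pass-filtered design matrices for one run."""
    tr_s = run.tr_s if tr_s is None else tr_s
    n_t = run.n_retained
    att, ign, cue = _regressor_trains(run, dt)
    kernel = hrf_kernel(dt, hrf_lag_s, hrf_sd_s)
    tr_idx = (np.arange(n_t) * tr_s / dt).round().astype(int)

    def convolve_sample(trains: np.ndarray) -> np.ndarray:
        out = np.empty((trains.shape[0], n_t))
        for i, row in enumerate(trains):
            out[i] = np.convolve(row, kernel)[: trains.shape[1]][tr_idx]
        return out

    att_cols = convolve_sample(att).T
    cue_col = convolve_sample(cue[None, :]).T
    basis = dct_highpass_basis(n_t, tr_s, highpass_s)
    const = np.ones((n_t, 1))

    def assemble(cols: np.ndarray) -> np.ndarray:
        filtered = _residualise(np.column_stack([cols, cue_col]), basis)
        X = np.column_stack([filtered, const])
        scale = np.linalg.norm(X, axis=0)
        if np.linalg.cond(X / np.where(scale > 0, scale, 1.0)) > max_condition_number:
            raise DesignError("design matrix is excessively collinear")
        return X

    names = [f"band_{b}" for b in range(N_BANDS)] + ["cue", "const"]
    attended = assemble(att_cols)
    ignored = None
    if run.condition != "tonotopy":
        ignored = assemble(convolve_sample(ign).T)
    return DesignMatrix(
        attended=attended,
        ignored=ignored,
        column_names=names,
        highpass_basis=basis,
        condition=run.condition,
    )


_BIAS_CACHE: dict = {}


def _ar1_bias_inverse(X: np.ndarray, basis: Optional[np.ndarray]):
    key = (X.tobytes(), None if basis is None else basis.tobytes())
    if key not in _BIAS_CACHE:
        if len(_BIAS_CACHE) > 64:
            _BIAS_CACHE.clear()
        _BIAS_CACHE[key] = _ar1_bias_inverse_uncached(X, basis)
    return _BIAS_CACHE[key]


def _ar1_bias_inverse_uncached(X: np.ndarray, basis: Optional[np.ndarray]):
    """Map raw residual lag-1 autocorrelation back to the AR(1) coefficient.

    OLS residuals under-state serial correlation because the (smooth)
    regressors and the drift basis absorb autocorrelated power. For an
    AR(1) process, E[sum r_t r_{t+1}] / E[sum r_t^2] =
    tr(Q' S Q Sigma(rho)) / tr(Q' Q Sigma(rho)) with Q the residual maker
    (including the high-pass projection) and S the symmetrised lag shift.
    Both traces are polynomial in rho via the diagonal sums of Q'SQ and
    Q'Q, so the forward map is evaluated on a grid and inverted by
    monotone interpolation.
    """
    T = X.shape[0]
    M = np.eye(T) - X @ np.linalg.pinv(X)
    Q = M if basis is None else M @ (np.eye(T) - basis @ basis.T)
    QtQ = Q.T @ Q
    S = np.zeros((T, T))
    idx = np.arange(T - 1)
    S[idx, idx + 1] = 0.5
    S[idx + 1, idx] = 0.5
    QtSQ = Q.T @ S @ Q
    c0 = np.array([np.trace(QtQ, offset=k) * (2 if k else 1) for k in range(T)])
    c1 = np.array([np.trace(QtSQ, offset=k) * (2 if k else 1) for k in range(T)])
    grid = np.linspace(-0.95, 0.95, 96)
    powers = grid[None, :] ** np.arange(T)[:, None]
    g = (c1 @ powers) / (c0 @ powers)
    order = np.argsort(g)
    return lambda raw: np.interp(raw, g[order], grid[order])


def _ar1_gls(
    Y: np.ndarray, X: np.ndarray, basis: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-vertex AR(1) GLS.

    Y : (V, T) high-pass-filtered data; X : (T, P) design; basis : the
    orthonormal high-pass basis already projected out of Y (accounted for
    in the autocorrelation bias correction and the residual df).
    Returns betas (V, P), variances (V, P) and the estimated AR(1)
    coefficients (V,). The AR(1) coefficient is estimated from OLS
    residuals with a projection-bias correction, then data and design are
    first-differenced with that coefficient (whitening) and refit via
    batched normal equations.
    """
    V, T = Y.shape
    P = X.shape[1]
    n_basis = 0 if basis is None else basis.shape[1]
    beta_ols, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta_ols).T
    num = np.sum(resid[:, 1:] * resid[:, :-1], axis=1)
    den = np.sum(resid**2, axis=1)
    raw = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    rho = np.clip(_ar1_bias_inverse(X, basis)(raw), -0.95, 0.95)

    X0, X1 = X[:-1], X[1:]
    M00, M11 = X0.T @ X0, X1.T @ X1
    M01 = X1.T @ X0  # X1' X0
    r = rho[:, None, None]
    A = M11[None] - r * (M01 + M01.T)[None] + r**2 * M00[None]

    Y0, Y1 = Y[:, :-1], Y[:, 1:]
    b = (
        Y1 @ X1
        - rho[:, None] * (Y0 @ X1 + Y1 @ X0)
        + (rho**2)[:, None] * (Y0 @ X0)
    )
    betas = np.linalg.solve(A, b[:, :, None])[:, :, 0]

    yty = (
        np.sum(Y1**2, axis=1)
        - 2 * rho * np.sum(Y1 * Y0, axis=1)
        + rho**2 * np.sum(Y0**2, axis=1)
    )
    rss = np.maximum(yty - np.sum(betas * b, axis=1), 0.0)
    dof = (T - 1) - P - n_basis
    sigma2 = rss / dof
    Ainv_diag = np.diagonal(np.linalg.inv(A), axis1=1, axis2=2)
    var = sigma2[:, None] * Ainv_diag
    return betas, var, rho


def fit_glm_prewhitened(ts: VertexSeries, design: DesignMatrix) -> BandBetas:
    """Run-level band coefficients with AR(1) prewhitening.

    The attended and (for attention conditions) ignored band sets are fit
    in separate regressions sharing the high-pass filtering of the data.
    """
    Y = ts.data
    if Y.shape[1] != design.attended.shape[0]:
        raise ValueError("series length does not match the design")
    Yf = _residualise(Y.T, design.highpass_basis).T

    betas_a, var_a, _ = _ar1_gls(Yf, design.attended, design.highpass_basis)
    ignored = ignored_var = None
    if design.ignored is not None:
        betas_i, var_i, _ = _ar1_gls(Yf, design.ignored, design.highpass_basis)
        ignored, ignored_var = betas_i[:, :N_BANDS], var_i[:, :N_BANDS]
    return BandBetas(
        attended=betas_a[:, :N_BANDS],
        attended_var=var_a[:, :N_BANDS],
        ignored=ignored,
        ignored_var=ignored_var,
        condition=design.condition,
        n_runs_combined=1,
    )


def combine_fixed_effects(run_betas: Sequence[BandBetas]) -> BandBetas:
    """Inverse-variance-weighted fixed-effects combination across runs."""
    if not run_betas:
        raise ValueError("nothing to combine")
    has_ignored = {rb.ignored is not None for rb in run_betas}
    if len(has_ignored) != 1:
        raise ValueError("runs have mismatched column structure")

    def combine(bs, vs):
        v = np.stack(vs)
        # Noiseless data yields zero residual variance; floor it so exact
        # fits combine with equal (large) weight instead of dividing by 0.
        pos = v[v > 0]
        floor = (pos.min() * 1e-6) if pos.size else 1.0
        w = 1.0 / np.maximum(v, floor)
        b = np.stack(bs)
        var = 1.0 / w.sum(axis=0)
        return (w * b).sum(axis=0) * var, var

    att, att_var = combine(
        [rb.attended for rb in run_betas], [rb.attended_var for rb in run_betas]
    )
    ign = ign_var = None
    if has_ignored == {True}:
        ign, ign_var = combine(
            [rb.ignored for rb in run_betas], [rb.ignored_var for rb in run_betas]
        )
    conditions = sorted({rb.condition for rb in run_betas})
    return BandBetas(
        attended=att,
        attended_var=att_var,
        ignored=ign,
        ignored_var=ign_var,
        condition="+".join(conditions),
        n_runs_combined=sum(rb.n_runs_combined for rb in run_betas),
    )


def extremum_maps(betas: BandBetas) -> ExtremumMap:
    """Winner- and loser-takes-all maps over the five attended-band betas.

    Ties resolve to the lowest band index and are flagged.
    """
    b = betas.attended
    wta = np.argmax(b, axis=1)
    lta = np.argmin(b, axis=1)
    n_max = np.sum(b == b.max(axis=1, keepdims=True), axis=1)
    n_min = np.sum(b == b.min(axis=1, keepdims=True), axis=1)
    return ExtremumMap(
        wta_band=wta,
        lta_band=lta,
        wta_value=b[np.arange(len(b)), wta],
        lta_value=b[np.arange(len(b)), lta],
        tie_flag=(n_max > 1) | (n_min > 1),
    )
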