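"""Shared hemodynamic response kernel.

A single gamma-density HRF (mean lag 6 s, SD 3 s, i.e. shape 4, scale
1.5 s) is used both by the BOLD simulator and by the GLM design-matrix
builder, so that the analyser's kernel is the simulator's unless a
mis-specification is requested explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["gamma_hrf", "hrf_kernel"]

DEFAULT_LAG_S = 6.0
DEFAULT_SD_S = 3.0
KERNEL_LENGTH_S = 32.0


def gamma_hrf(t: np.ndarray, lag_s: float = DEFAULT_LAG_S, sd_s: float = DEFAULT_SD_S) -> np.ndarray:
    """Gamma-density HRF evaluated at times t (s); mean lag_s, SD sd_s."""
    shape = (lag_s / sd_s) ** 2
    scale = sd_s**2 / lag_s
    return stats.gamma.pdf(t, a=shape, scale=scale)


def hrf_kernel(dt: float, lag_s: float = DEFAULT_LAG_S, sd_s: float = DEFAULT_SD_S) -> np.ndarray:
    """Sampled HRF kernel on a dt grid, scaled so convolution integrates."""
    t = np.arange(0.0, KERNEL_LENGTH_S + dt, dt)
    return gamma_hrf(t, lag_s, sd_s) * dt
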