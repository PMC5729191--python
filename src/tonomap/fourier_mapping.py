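"""Phase-encoded (traveling-wave) Fourier analysis.

A vertex that prefers one position in the stepped stimulus cycle shows a
periodic BOLD signal at the stimulus frequency (8 cycles per stimulation
period); its phase encodes the preferred frequency band. Significance is an
F statistic comparing power at the stimulus frequency with mean power over
the remaining noise frequencies, after excluding very low frequencies and
the second and third stimulus harmonics from both signal and noise.

Runs stepping downward in frequency are time-reversed (equivalently, their
complex signal is conjugate-adjusted) and averaged with upward runs, which
cancels the fixed vertexwise hemodynamic delay. Cross-subject averaging is
performed on the real and imaginary components so that only phase structure
coherent over subjects survives.

Phase convention: the stored complex signal has argument equal to 2*pi times
the cycle fraction at which the response peaks, with fraction 0 at the onset
of the first block of each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .surface import SurfaceMesh
from .synthetic_cohort import VertexSeries

__all__ = [
    "FourierResult",
    "fourier_stats",
    "combine_runs_complex",
    "phase_to_band",
    "phase_to_band_map",
    "group_average_complex",
]

F_CAP = 1e12


@dataclass
class FourierResult:
    """Per-vertex complex signal at the stimulus frequency plus F statistics.

    `complex_signal` is scaled so its modulus is the sinusoid amplitude
    (2|X_k|/T); `phase` = arg(complex_signal) in [0, 2*pi). F/p/df are None
    for group averages, where single-run noise statistics do not apply.
    """

    complex_signal: np.ndarray
    stim_cycles: int
    n_timepoints: int
    F: Optional[np.ndarray] = None
    p: Optional[np.ndarray] = None
    df: Optional[tuple[int, int]] = None
    excluded_bins: Optional[tuple[int, ...]] = None

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_signal)

    @property
    def phase(self) -> np.ndarray:
        return np.mod(np.angle(self.complex_signal), 2 * np.pi)


def _stim_segment(ts: VertexSeries) -> np.ndarray:
    """Crop the silent baselines, leaving the 8-cycle stimulation window.

    Series without a schedule reference are analysed whole.
    """
    if ts.run is None:
        return ts.data
    t0, t1 = ts.run.stim_window_s
    i0 = int(round(t0 / ts.tr_s))
    i1 = int(round(t1 / ts.tr_s))
    return ts.data[:, i0:i1]


def fourier_stats(
    ts: VertexSeries,
    stim_cycles: int = 8,
    n_low_excluded: int = 3,
    harmonics_excluded: Sequence[int] = (2, 3),
) -> FourierResult:
    """Complex signal, amplitude, phase and F statistic at the stimulus bin.

    F = power at the stimulus bin divided by the mean power over noise bins
    (all positive-frequency bins except DC, the `n_low_excluded` lowest
    frequencies, the stimulus bin, its listed harmonics, and Nyquist), with
    df = (2, 2K) for K noise bins.
    """
    x = _stim_segment(ts)
    n_t = x.shape[1]
    if n_t < 2 * stim_cycles:
        raise ValueError("series too short for the requested stimulus frequency")
    X = np.fft.rfft(x, axis=1)
    n_bins = X.shape[1]

    excluded = {0}
    excluded.update(range(1, n_low_excluded + 1))
    excluded.add(stim_cycles)
    excluded.update(h * stim_cycles for h in harmonics_excluded)
    if n_t % 2 == 0:
        excluded.add(n_bins - 1)  # Nyquist bin: real-valued, half the df
    noise_bins = np.array(sorted(set(range(n_bins)) - excluded))
    if len(noise_bins) < 10:
        raise ValueError("exclusions leave fewer than 10 noise bins")

    power = np.abs(X) ** 2
    noise_power = power[:, noise_bins].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = power[:, stim_cycles] / noise_power
    F = np.where(noise_power <= 0, np.where(power[:, stim_cycles] > 0, F_CAP, 0.0), F)
    F = np.minimum(F, F_CAP)
    K = len(noise_bins)
    p = stats.f.sf(F, 2, 2 * K)

    # conj() makes arg() equal the cycle fraction of the response peak
    complex_signal = (2.0 / n_t) * np.conj(X[:, stim_cycles])
    harmonic_bins = tuple(
        sorted(excluded - {0} - set(range(1, n_low_excluded + 1)) - {stim_cycles})
    )
    return FourierResult(
        complex_signal=complex_signal,
        stim_cycles=stim_cycles,
        n_timepoints=n_t,
        F=F,
        p=p,
        df=(2, 2 * K),
        excluded_bins=tuple(sorted(excluded)),
    )


def combine_runs_complex(
    results: Sequence[tuple[FourierResult, str]],
) -> FourierResult:
    """Average runs in the complex domain, time-reversing downward sweeps.

    For a down run the complex signal is conjugated and rotated by one
    sample (exp(-2*pi*i*k/T)), exactly what analysing the time-reversed
    series would give; the vertexwise hemodynamic delay then cancels in the
    complex mean with upward runs.
    """
    if not results:
        raise ValueError("no results to combine")
    n_vertices = {len(r.complex_signal) for r, _ in results}
    if len(n_vertices) != 1:
        raise ValueError("mixed vertex counts")
    adjusted = []
    for res, direction in results:
        c = res.complex_signal
        if direction == "down":
            c = np.conj(c) * np.exp(-2j * np.pi * res.stim_cycles / res.n_timepoints)
        elif direction != "up":
            raise ValueError(f"unknown direction {direction!r}")
        adjusted.append(c)
    ref = results[0][0]
    return FourierResult(
        complex_signal=np.mean(adjusted, axis=0),
        stim_cycles=ref.stim_cycles,
        n_timepoints=ref.n_timepoints,
    )


def phase_to_band(phase: float | np.ndarray, n_bands: int = 5):
    """Map phase (radians in [0, 2*pi)) to band index and cycle fraction.

    Band boundaries sit at cycle fractions k/n_bands; after up/down delay
    cancellation a band-selective vertex lands at its block centre,
    fraction (b + 0.5)/n_bands, comfortably inside bin b.
    """
    fraction = np.mod(np.asarray(phase) / (2 * np.pi), 1.0)
    band = np.floor(fraction * n_bands).astype(int) % n_bands
    if np.isscalar(phase):
        return int(band), float(fraction)
    return band, fraction


def phase_to_band_map(result: FourierResult, n_bands: int = 5) -> np.ndarray:
    band, _ = phase_to_band(result.phase, n_bands)
    return band


def group_average_complex(
    subject_results: Sequence[FourierResult],
    mesh: SurfaceMesh,
    smooth_steps: int = 1,
) -> FourierResult:
    """Cross-subject complex average with per-subject surface smoothing.

    Each subject's complex map receives `smooth_steps` nearest-neighbour
    smoothing steps, then maps are averaged vertexwise; phase-coherent
    structure is preserved while incoherent phases cancel (amplitude falls
    roughly as 1/sqrt(n) for random phases).
    """
    if not subject_results:
        raise ValueError("no subjects")
    ref = subject_results[0]
    for r in subject_results:
        if len(r.complex_signal) != mesh.n_vertices:
            raise ValueError("result does not match the mesh")
    smoothed = [
        mesh.neighbor_smooth(r.complex_signal, smooth_steps) for r in subject_results
    ]
    return FourierResult(
        complex_signal=np.mean(smoothed, axis=0),
        stim_cycles=ref.stim_cycles,
        n_timepoints=ref.n_timepoints,
    )
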