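"""Shared fixtures: small meshes and cached noiseless/noisy runs.

Session-scoped fixtures cache the expensive simulations so unit tests can
share them; every stochastic object is seeded explicitly.
"""

from __future__ import annotations

import numpy as np
import pytest

from tonomap import fourier_mapping as fm
from tonomap import glm_mapping as glm
from tonomap.stimulus_design import build_run_schedule
from tonomap.surface import make_flat_patch
from tonomap.synthetic_cohort import NoiseSpec, plant_ground_truth, simulate_run


@pytest.fixture(scope="session")
def small_mesh():
    return make_flat_patch(16, 10, 1.0)


@pytest.fixture(scope="session")
def mid_mesh():
    return make_flat_patch(24, 16, 1.0)


@pytest.fixture(scope="session")
def quiet():
    return NoiseSpec(sigma=0.0, drift_amp=0.0)


@pytest.fixture(scope="session")
def noiseless_tono_updown(mid_mesh, quiet):
    """Noiseless up+down tonotopy runs on the mid mesh with planted truth."""
    truth = plant_ground_truth(mid_mesh, n_fingers=0, gain=1.0, seed=3)
    out = {}
    for i, direction in enumerate(("up", "down")):
        sched = build_run_schedule("tonotopy", direction, seed=21 + i)
        out[direction] = (
            sched,
            simulate_run(mid_mesh, truth, sched, quiet, seed=50 + i),
        )
    return truth, out


@pytest.fixture(scope="session")
def noiseless_combined_fourier(noiseless_tono_updown):
    truth, runs = noiseless_tono_updown
    results = [(fm.fourier_stats(ts), d) for d, (_, ts) in runs.items()]
    return truth, fm.combine_runs_complex(results)


@pytest.fixture(scope="session")
def noiseless_tono_betas(noiseless_tono_updown):
    truth, runs = noiseless_tono_updown
    fits = []
    for _, (sched, ts) in runs.items():
        design = glm.build_design_matrix(sched, highpass_s=100.0)
        fits.append(glm.fit_glm_prewhitened(ts, design))
    return truth, glm.combine_fixed_effects(fits)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
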