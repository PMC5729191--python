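"""Synthetic cohort: planted-truth invariants, noise statistics, structure."""

import numpy as np
import pytest

from tonomap.stimulus_design import build_run_schedule
from tonomap.surface import make_flat_patch
from tonomap.synthetic_cohort import (
    BOUNDARY_MARGIN,
    EDGE_BAND_MARGIN,
    NoiseSpec,
    R1_RANGE,
    TUNING_SUM,
    _ar1_noise,
    make_cohort,
    plant_ground_truth,
    simulate_run,
)


class TestGroundTruth:
    def test_tuning_invariants(self, mid_mesh):
        truth = plant_ground_truth(mid_mesh, seed=0)
        assert truth.tuning.shape == (mid_mesh.n_vertices, 5)
        assert (truth.tuning >= 0).all()
        assert np.allclose(truth.tuning.sum(axis=1), TUNING_SUM)
        assert (truth.tuning.argmax(axis=1) == truth.best_band).all()
        assert np.allclose(
            truth.selectivity, truth.tuning.max(axis=1) - truth.tuning.mean(axis=1)
        )

    def test_best_band_roughly_uniform(self):
        mesh = make_flat_patch(50, 20)
        truth = plant_ground_truth(mesh, seed=1)
        frac = np.bincount(truth.best_band, minlength=5) / mesh.n_vertices
        assert np.all(np.abs(frac - 0.2) < 0.06)

    def test_coordinates_respect_margins(self, mid_mesh):
        for seed in range(3):
            truth = plant_ground_truth(mid_mesh, n_fingers=2, seed=seed)
            u = truth.band_coordinate
            frac = u - np.floor(u)
            assert frac.min() >= BOUNDARY_MARGIN - 1e-12
            assert frac.max() <= 1 - BOUNDARY_MARGIN + 1e-12
            assert u[np.floor(u) == 4].min() >= 4 + EDGE_BAND_MARGIN - 1e-12
            assert u[np.floor(u) == 0].max() <= 1 - EDGE_BAND_MARGIN + 1e-12

    def test_r1_range_and_coupling_sign(self, mid_mesh):
        coupled = plant_ground_truth(mid_mesh, r1_coupling=1.0, seed=2)
        assert R1_RANGE[0] <= coupled.r1.min() <= coupled.r1.max() <= R1_RANGE[1]
        r = np.corrcoef(coupled.selectivity, coupled.r1)[0, 1]
        assert r > 0.5
        decoupled = plant_ground_truth(mid_mesh, r1_coupling=0.0, seed=2)
        r0 = np.corrcoef(decoupled.selectivity, decoupled.r1)[0, 1]
        assert abs(r0) < 0.3

    def test_fingers_fold_the_map(self):
        mesh = make_flat_patch(60, 10)
        truth = plant_ground_truth(mesh, n_fingers=3, seed=0)
        # along one row, best band must be non-monotone (mirror reversals)
        row = truth.best_band[: 60 * 10 : 10]
        d = np.diff(row.astype(int))
        assert (d > 0).any() and (d < 0).any()

    def test_invalid_args(self, small_mesh):
        with pytest.raises(ValueError):
            plant_ground_truth(small_mesh, gain=0.5)
        with pytest.raises(ValueError):
            plant_ground_truth(small_mesh, n_fingers=-1)
        with pytest.raises(ValueError):
            plant_ground_truth(small_mesh, attention_model="divisive")

    def test_deterministic(self, small_mesh):
        a = plant_ground_truth(small_mesh, seed=7)
        b = plant_ground_truth(small_mesh, seed=7)
        assert np.array_equal(a.tuning, b.tuning)
        assert np.array_equal(a.r1, b.r1)


class TestSimulateRun:
    def test_shapes_and_retained_volumes(self, small_mesh, quiet):
        truth = plant_ground_truth(small_mesh, seed=0)
        run = build_run_schedule("tonotopy", "up", seed=0)
        ts = simulate_run(small_mesh, truth, run, quiet, seed=0)
        assert ts.data.shape == (small_mesh.n_vertices, 576)
        assert ts.tr_s == 1.0

    def test_noiseless_is_deterministic_and_periodic(self, small_mesh, quiet):
        truth = plant_ground_truth(small_mesh, seed=0)
        run = build_run_schedule("tonotopy", "up", seed=4)
        a = simulate_run(small_mesh, truth, run, quiet, seed=1)
        b = simulate_run(small_mesh, truth, run, quiet, seed=2)
        # no noise: seed must not matter
        assert np.array_equal(a.data, b.data)
        # interior cycles repeat almost exactly (HRF transients at the ends)
        x = a.data[:, 32:544]
        c2, c3 = x[:, 64:128], x[:, 128:192]
        assert np.allclose(c2, c3, atol=1e-6 + 0.02 * np.abs(c2).max())

    def test_attention_gain_scales_attended_response(self, small_mesh, quiet):
        run = build_run_schedule("attn_stepped", "up", seed=0)
        lo = plant_ground_truth(small_mesh, gain=1.0, seed=0)
        hi = plant_ground_truth(small_mesh, gain=3.0, seed=0)
        ts_lo = simulate_run(small_mesh, lo, run, quiet, seed=0)
        ts_hi = simulate_run(small_mesh, hi, run, quiet, seed=0)
        assert ts_hi.data.std() > ts_lo.data.std()

    def test_additive_model_differs(self, small_mesh, quiet):
        run = build_run_schedule("attn_stepped", "up", seed=0)
        mult = plant_ground_truth(small_mesh, gain=2.0, seed=0)
        add = plant_ground_truth(small_mesh, gain=2.0, seed=0, attention_model="additive")
        a = simulate_run(small_mesh, mult, run, quiet, seed=0)
        b = simulate_run(small_mesh, add, run, quiet, seed=0)
        assert not np.allclose(a.data, b.data)

    def test_mesh_truth_mismatch_raises(self, small_mesh, mid_mesh, quiet):
        truth = plant_ground_truth(small_mesh, seed=0)
        run = build_run_schedule("tonotopy", "up", seed=0)
        with pytest.raises(ValueError):
            simulate_run(mid_mesh, truth, run, quiet)


class TestNoise:
    def test_ar1_marginal_sd_and_autocorrelation(self):
        rng = np.random.default_rng(0)
        x = _ar1_noise((2000, 576), sigma=1.5, rho=0.4, rng=rng)
        assert x.std() == pytest.approx(1.5, rel=0.02)
        lag1 = np.mean(
            [(row[:-1] * row[1:]).mean() / row.var() for row in x[:200]]
        )
        assert lag1 == pytest.approx(0.4, abs=0.03)

    def test_zero_sigma_is_silent(self):
        rng = np.random.default_rng(0)
        assert np.all(_ar1_noise((4, 100), 0.0, 0.4, rng) == 0)

    def test_invalid_noise_spec(self, small_mesh):
        truth = plant_ground_truth(small_mesh, seed=0)
        run = build_run_schedule("tonotopy", "up", seed=0)
        with pytest.raises(ValueError):
            simulate_run(small_mesh, truth, run, NoiseSpec(sigma=-1.0))
        with pytest.raises(ValueError):
            simulate_run(small_mesh, truth, run, NoiseSpec(ar1_rho=1.0))


class TestCohort:
    def test_structure_and_run_plan(self, small_mesh):
        cohort = make_cohort(
            n_subjects=2, shared_seed=0, mesh=small_mesh,
            noise=NoiseSpec(sigma=0.5),
        )
        assert len(cohort.subjects) == 2
        for subj in cohort.subjects:
            conds = [ts.run.condition for ts in subj.runs]
            assert conds.count("tonotopy") == 4
            assert conds.count("attn_stepped") == 4
            assert conds.count("attn_random") == 4
            dirs = [ts.run.direction for ts in subj.runs]
            assert dirs.count("up") == dirs.count("down") == 6

    def test_subject_maps_jittered_but_close(self, small_mesh):
        cohort = make_cohort(
            n_subjects=3, idiosyncrasy_sd=0.3, shared_seed=1, mesh=small_mesh,
            noise=NoiseSpec(sigma=0.0, drift_amp=0.0),
            run_plan=[("tonotopy", "up")],
        )
        gu = cohort.group_truth.band_coordinate
        for subj in cohort.subjects:
            su = subj.truth.band_coordinate
            assert not np.array_equal(su, gu)
            assert np.mean(np.abs(su - gu)) < 0.5

    def test_identical_subjects_when_sd_zero(self, small_mesh):
        cohort = make_cohort(
            n_subjects=2, idiosyncrasy_sd=0.0, shared_seed=2, mesh=small_mesh,
            noise=NoiseSpec(sigma=0.0, drift_amp=0.0),
            run_plan=[("tonotopy", "up")],
        )
        a, b = cohort.subjects
        assert np.array_equal(
            a.truth.band_coordinate, b.truth.band_coordinate
        )

    def test_cohort_deterministic(self, small_mesh):
        kw = dict(n_subjects=1, shared_seed=5, mesh=small_mesh,
                  noise=NoiseSpec(sigma=0.3), run_plan=[("tonotopy", "up")])
        a = make_cohort(**kw)
        b = make_cohort(**kw)
        assert np.array_equal(a.subjects[0].runs[0].data, b.subjects[0].runs[0].data)
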