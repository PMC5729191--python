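"""End-to-end orchestration: synthesize -> map -> group stats -> report.

A single structured-text (YAML) configuration drives cohort synthesis,
Fourier and GLM mapping, group surface statistics, the ROI quilt and the
R1 searchlight, with every stochastic stage seeded from one master seed.
Outputs are CSV overlays and tables plus a JSON manifest (stage, seed,
checksum per file) and a human-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import fourier_mapping as fm
from . import glm_mapping as glm
from . import myelin_searchlight as msl
from . import roi_quilt as rq
from . import surface_stats as ss
from .stimulus_design import N_BANDS
from .surface import make_flat_patch
from .synthetic_cohort import DEFAULT_GAIN, NoiseSpec, make_cohort

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

log = logging.getLogger("tonomap.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults mirror the study design
    (TR 1 s, 8 cycles, 12.8 s blocks, 100 s high-pass, 4 mm radii)."""

    # cohort
    n_subjects: int = 8
    idiosyncrasy_sd: float = 0.3
    mesh_nx: int = 40
    mesh_ny: int = 32
    mesh_spacing_mm: float = 1.0
    n_fingers: int = 0
    gain: float = DEFAULT_GAIN
    attention_model: str = "multiplicative"
    r1_coupling: float = 1.0
    noise_sigma: float = 1.0
    noise_ar1_rho: float = 0.4
    noise_drift_amp: float = 0.5
    # analysis
    stim_cycles: int = 8
    n_low_excluded: int = 3
    harmonics_excluded: tuple = (2, 3)
    highpass_s: float = 100.0
    smooth_steps: int = 1
    vertexwise_alpha: float = 0.01
    corrected_alpha: float = 0.001
    cluster_iters: int = 2000
    roi_radius_mm: float = 4.0
    roi_spacing_mm: float = 8.0
    roi_alpha: float = 0.05
    searchlight_radius_mm: float = 4.0
    # reproducibility / reporting
    seed: int = 0
    tolerances: dict = field(
        default_factory=lambda: {
            "tonotopy_band_recovery": [0.5, 1.0],
            "concordance_mean": [0.2, 1.0],
            "amplitude_ratio_random_vs_stepped": [0.0, 0.5],
            "mean_normcov_coupled": [0.2, 1.0],
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "harmonics_excluded" in raw:
            cfg.harmonics_excluded = tuple(raw["harmonics_excluded"])
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["harmonics_excluded"] = list(self.harmonics_excluded)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _subject_condition_runs(subject, condition):
    return [r for r in subject.runs if r.run.condition == condition]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    The manifest lists every output file with its stage and checksum, plus
    a summary block (band recovery, concordance, amplitude ratio,
    significant-ROI count, mean searchlight covariance).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    files: list[dict] = []
    stage = "init"

    def record(name: str, st: str):
        files.append({"file": name, "stage": st, "sha256": _sha256(out / name)})

    try:
        stage = "synthesize"
        log.info("stage %s", stage)
        mesh = make_flat_patch(config.mesh_nx, config.mesh_ny, config.mesh_spacing_mm)
        cohort = make_cohort(
            n_subjects=config.n_subjects,
            idiosyncrasy_sd=config.idiosyncrasy_sd,
            shared_seed=config.seed,
            mesh=mesh,
            n_fingers=config.n_fingers,
            gain=config.gain,
            r1_coupling=config.r1_coupling,
            noise=NoiseSpec(
                sigma=config.noise_sigma,
                ar1_rho=config.noise_ar1_rho,
                drift_amp=config.noise_drift_amp,
            ),
            attention_model=config.attention_model,
        )

        stage = "fourier"
        log.info("stage %s", stage)
        fourier_by_cond: dict[str, list[fm.FourierResult]] = {}
        for condition in ("tonotopy", "attn_stepped", "attn_random"):
            per_subject = []
            for subj in cohort.subjects:
                runs = _subject_condition_runs(subj, condition)
                results = [
                    (
                        fm.fourier_stats(
                            r,
                            config.stim_cycles,
                            config.n_low_excluded,
                            config.harmonics_excluded,
                        ),
                        r.run.direction,
                    )
                    for r in runs
                ]
                per_subject.append(fm.combine_runs_complex(results))
            fourier_by_cond[condition] = per_subject

        group_fourier = {
            c: fm.group_average_complex(res, mesh, config.smooth_steps)
            for c, res in fourier_by_cond.items()
        }
        amp_stepped = group_fourier["attn_stepped"].amplitude.mean()
        amp_random = group_fourier["attn_random"].amplitude.mean()
        amplitude_ratio = float(amp_random / amp_stepped)

        fourier_recovery = float(
            np.mean(
                [
                    np.mean(
                        fm.phase_to_band_map(res) == subj.truth.best_band
                    )
                    for res, subj in zip(fourier_by_cond["tonotopy"], cohort.subjects)
                ]
            )
        )

        for cond, res in group_fourier.items():
            df = pd.DataFrame(
                {
                    "amplitude": res.amplitude,
                    "phase": res.phase,
                    "band": fm.phase_to_band_map(res),
                }
            )
            name = f"group_fourier_{cond}.csv"
            _write_csv(out / name, df)
            record(name, "fourier")

        stage = "glm"
        log.info("stage %s", stage)
        tono_betas, attn_betas = [], []
        tono_maps, attn_maps = [], []
        for subj in cohort.subjects:
            per_cond = {}
            for condition in ("tonotopy", "attn_stepped", "attn_random"):
                run_fits = []
                for r in _subject_condition_runs(subj, condition):
                    design = glm.build_design_matrix(r.run, highpass_s=config.highpass_s)
                    run_fits.append(glm.fit_glm_prewhitened(r, design))
                per_cond[condition] = run_fits
            tono = glm.combine_fixed_effects(per_cond["tonotopy"])
            attn = glm.combine_fixed_effects(
                per_cond["attn_stepped"] + per_cond["attn_random"]
            )
            tono_betas.append(tono)
            attn_betas.append(attn)
            tono_maps.append(glm.extremum_maps(tono))
            attn_maps.append(glm.extremum_maps(attn))

        wta_recovery = float(
            np.mean(
                [
                    np.mean(m.wta_band == s.truth.best_band)
                    for m, s in zip(tono_maps, cohort.subjects)
                ]
            )
        )

        stage = "surface_stats"
        log.info("stage %s", stage)
        conc_maps = [
            ss.concordance_map(a, b) for a, b in zip(tono_maps, attn_maps)
        ]
        conc_mean_map = np.mean(conc_maps, axis=0)
        concordance_mean = float(conc_mean_map.mean())
        t_map, p_map = ss.group_ttest_vs_chance(conc_maps, chance=1.0 / N_BANDS)
        clusters = ss.cluster_correct(
            p_map,
            mesh,
            ss.ClusterNull(
                vertexwise_alpha=config.vertexwise_alpha,
                n_iter=config.cluster_iters,
                corrected_alpha=config.corrected_alpha,
                seed=config.seed + 1,
            ),
        )
        attn_contrast = ss.attend_vs_ignore_group(attn_betas, tono_maps, tono_maps)

        df = pd.DataFrame(
            {
                "concordance_mean": conc_mean_map,
                "t": t_map,
                "p": p_map,
                "cluster_survives": clusters.surviving_mask.astype(int),
                "diff_best": attn_contrast["diff_best"],
                "diff_worst": attn_contrast["diff_worst"],
            }
        )
        name = "group_surface_stats.csv"
        _write_csv(out / name, df)
        record(name, "surface_stats")

        cl_rows = [
            {"id": c["id"], "area_mm2": c["area_mm2"], "survives": c["survives"]}
            for c in clusters.clusters
        ]
        name = "clusters.csv"
        _write_csv(out / name, pd.DataFrame(cl_rows, columns=["id", "area_mm2", "survives"]))
        record(name, "surface_stats")

        stage = "roi_quilt"
        log.info("stage %s", stage)
        quilt = rq.make_roi_quilt(mesh, config.roi_radius_mm, config.roi_spacing_mm)
        roi_table = rq.roi_profile_regression(
            tono_betas, attn_betas, quilt, alpha=config.roi_alpha
        )
        name = "roi_quilt.csv"
        _write_csv(out / name, roi_table)
        record(name, "roi_quilt")
        n_sig_rois = int(roi_table["significant"].sum())

        stage = "searchlight"
        log.info("stage %s", stage)
        disks = msl.geodesic_disks(mesh, config.searchlight_radius_mm)
        sl_results = [
            msl.searchlight_normcov(
                subj.truth.r1, res.amplitude, disks, config.searchlight_radius_mm
            )
            for subj, res in zip(cohort.subjects, fourier_by_cond["tonotopy"])
        ]
        normcov_mean_map = msl.average_normcov(sl_results)
        mean_normcov = float(np.nanmean(normcov_mean_map))
        r1_gradient = msl.surface_gradient(cohort.group_truth.r1, mesh)
        name = "searchlight.csv"
        _write_csv(
            out / name,
            pd.DataFrame({"normcov_mean": normcov_mean_map, "r1_gradient_group": r1_gradient}),
        )
        record(name, "searchlight")

        stage = "report"
        summary = {
            "tonotopy_band_recovery": wta_recovery,
            "fourier_band_recovery": fourier_recovery,
            "concordance_mean": concordance_mean,
            "amplitude_ratio_random_vs_stepped": amplitude_ratio,
            "n_significant_rois": n_sig_rois,
            "n_rois": quilt.n_rois,
            "mean_normcov_coupled": mean_normcov,
            "mean_diff_best": float(np.mean(attn_contrast["diff_best"])),
            "mean_diff_worst": float(np.mean(attn_contrast["diff_worst"])),
            "cluster_min_area_mm2": clusters.min_area_mm2,
            "n_surviving_clusters": int(sum(c["survives"] for c in clusters.clusters)),
        }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed with config {asdict(config)}"
        ) from exc

    config.to_yaml(out / "config.yaml")
    record("config.yaml", "init")
    manifest = {
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 2),
        "summary": summary,
        "tolerances": config.tolerances,
        "files": sorted(files, key=lambda f: f["file"]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report = write_report(manifest)
    (out / "report.txt").write_text(report)
    return manifest


def write_report(manifest: dict) -> str:
    """Human-readable summary, a pure function of the manifest."""
    lines = ["tonomap pipeline report", "=" * 24, ""]
    lines.append(f"seed: {manifest.get('seed')}")
    lines.append("")
    summary = manifest.get("summary", {})
    tol = manifest.get("tolerances", {})
    lines.append("summary statistics")
    lines.append("-" * 18)
    if not summary:
        lines.append("  (absent)")
    for key in sorted(summary):
        val = summary[key]
        mark = ""
        if key in tol:
            lo, hi = tol[key]
            mark = "  [pass]" if lo <= val <= hi else "  [FAIL]"
        lines.append(f"  {key}: {val:.4g}{mark}" if isinstance(val, float) else f"  {key}: {val}{mark}")
    lines.append("")
    lines.append("outputs")
    lines.append("-" * 7)
    file_entries = manifest.get("files", [])
    if not file_entries:
        lines.append("  (absent)")
    for f in file_entries:
        lines.append(f"  {f['file']}  [{f['stage']}]  {f['sha256'][:12]}")
    lines.append("")
    return "\n".join(lines)
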