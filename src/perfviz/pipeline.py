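"""End-to-end orchestration of the synthetic perfusion experiment.

``run_experiment`` chains the stages — scene synthesis, reference-normalized
slope cartography, StO2 map, threshold zone classification, registration
overlay, capillary-density phantoms, cohort generation, model fitting,
leave-one-subject-out cross-validation and the supporting statistics — and
returns a serializable report that regenerates bit-identically from the
same configuration and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fcda, fler, io, lactate, registration, synthgen
from .containers import ZONE_LABELS
from .errors import PerfvizError

logger = logging.getLogger("perfviz")

#: Per-zone capillary-density calibration of the phantom scenes (reported
#: per-ROI means: vital 0.26, transition 0.247, ischemic 0.122).
DEFAULT_FCDA_TARGETS = {"vital": 0.26, "transition": 0.247, "ischemic": 0.122}


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the synthetic experiment, with paper-scale defaults."""

    height: int = 96
    width: int = 129
    duration_s: float = 40.0
    fps: float = 25.0
    video_noise_sd: float = 1.0
    reference_intensity: float = 50.0
    attenuation: float = 1.0
    smooth_window: int = 5
    min_delta: float = 0.02
    baseline_frames: int = 5
    t_low: float = 33.0
    t_high: float = 63.0
    mls_alpha: float = 1.0
    fcda_fov_radius: float = 120.0
    fcda_vessel_diameter: float = 6.0
    fcda_targets: dict = field(default_factory=lambda: dict(DEFAULT_FCDA_TARGETS))
    n_subjects: int = 6
    lcl_noise_sd: float | None = None  # None -> per-zone defaults
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _imaging_stage(config: PipelineConfig, out: Path | None) -> dict:
    layout = synthgen.SceneLayout.default(config.height, config.width)
    video, _gt = synthgen.generate_fluorescence_video(
        layout, duration=config.duration_s, fps=config.fps,
        noise_sd=config.video_noise_sd, seed=config.seed,
        reference_intensity=config.reference_intensity,
        attenuation=config.attenuation)
    sto2_map = synthgen.generate_sto2_map(layout, seed=config.seed + 1)

    normalized = fler.normalize_by_reference(video)
    slope_map = fler.compute_slope_map(
        normalized, smooth_window=config.smooth_window,
        min_delta=config.min_delta, baseline_frames=config.baseline_frames)
    rois = fler.classify_zones(sto2_map, (config.t_low, config.t_high))

    # enhanced-reality overlay artifact: deform the StO2 map with a known
    # gentle affine picked from scene corners, then blend onto a video frame
    h, w = config.height, config.width
    src = np.array([[8.0, 8.0], [w - 9.0, 8.0], [8.0, h - 9.0],
                    [w - 9.0, h - 9.0], [w / 2.0, h / 2.0]])
    dst = src * 0.98 + np.array([1.5, -1.0])
    pairs = registration.ControlPointPairs(src, dst)
    warped, warp_field = registration.mls_affine_warp(
        sto2_map.sto2, pairs, alpha=config.mls_alpha)
    mapped = registration.mls_affine_transform(pairs, src, alpha=config.mls_alpha)
    landmark_err = float(np.linalg.norm(mapped - dst, axis=1).max())
    composite = registration.overlay(normalized.frames[-1], warped / 100.0,
                                     opacity=0.5, valid_mask=warp_field.valid_mask)

    if out is not None:
        io.write_video(out / "video.tif", video)
        io.write_mask(out / "reference_mask.tif", layout.reference_card_mask)
        io.write_map(out / "sto2.tif", sto2_map)
        io.write_map(out / "slope.tif", slope_map)
        io.render_pseudocolor(out / "slope.png", slope_map)
        io.render_pseudocolor(out / "sto2.png", sto2_map)
        io.write_roiset(out / "rois.tif", out / "rois.json", rois)
        import imageio.v3 as iio

        lo, hi = composite.min(), composite.max()
        iio.imwrite(out / "overlay.png",
                    np.clip(255 * (composite - lo) / max(hi - lo, 1e-9),
                            0, 255).astype(np.uint8))

    return {
        "sto2_by_zone": fler.zone_summary(sto2_map, rois),
        "slope_by_zone": fler.zone_summary(slope_map, rois),
        "registration": {"landmark_max_error_px": landmark_err,
                         "n_landmarks": len(src)},
    }


def _fcda_stage(config: PipelineConfig, out: Path | None) -> dict:
    frames_by_zone = {}
    for zone in ZONE_LABELS:
        vessels = synthgen.generate_zone_phantom_vessels(
            config.fcda_targets[zone], fov_radius=config.fcda_fov_radius,
            diameter=config.fcda_vessel_diameter)
        frame, _truth = synthgen.generate_confocal_frame(
            vessels, fov_radius=config.fcda_fov_radius, seed=config.seed + 10)
        frames_by_zone[zone] = [frame]
    result = fcda.fcda_zone_contrast(frames_by_zone)
    if out is not None:
        rows = [{"zone": z, **result[z]} for z in ZONE_LABELS]
        pd.DataFrame(rows).to_csv(out / "fcda.csv", index=False)
    return result


def _cohort_stage(config: PipelineConfig, out: Path | None) -> dict:
    params = synthgen.CohortParams(n_subjects=config.n_subjects,
                                   seed=config.seed + 2)
    cohort = synthgen.generate_cohort(params, lcl_noise_sd=config.lcl_noise_sd)
    y = lactate.normalize_lcl(cohort["lcl_mmol_l"],
                              cohort["systemic_lactate_mmol_l"])

    fits, cv_summaries, cv_errors = {}, {}, {}
    for predictor, col in [("sto2", "sto2_pct"), ("fler_slope", "fler_slope")]:
        model = lactate.fit_exponential(cohort[col], y, predictor=predictor)
        fits[predictor] = {"a": model.a, "b": model.b}
        cv = lactate.loo_cv(cohort, predictor=predictor)
        cv = cv.sort_values(["subject_id", "roi_label"]).reset_index(drop=True)
        cv_errors[predictor] = cv
        summary = lactate.error_summary(cv["abs_error"], cv["observed_lcl"])
        cv_summaries[predictor] = dataclasses.asdict(summary)

    w_stat, w_p = lactate.compare_models_wilcoxon(
        cv_errors["sto2"]["abs_error"], cv_errors["fler_slope"]["abs_error"])
    correlations = {}
    for name, (a, b) in {
        "sto2_vs_fler": ("sto2_pct", "fler_slope"),
        "lcl_vs_sto2": ("lcl_mmol_l", "sto2_pct"),
        "lcl_vs_fler": ("lcl_mmol_l", "fler_slope"),
    }.items():
        rho, p = lactate.spearman_correlation(cohort[a], cohort[b])
        correlations[name] = {"rho": rho, "p": p}

    if out is not None:
        io.write_cohort(out / "cohort.csv", cohort)
        for predictor, cv in cv_errors.items():
            cv.to_csv(out / f"cv_errors_{predictor}.csv", index=False)

    return {
        "n_records": int(len(cohort)),
        "n_subjects": int(cohort["subject_id"].nunique()),
        "model_fits": fits,
        "cv_error_summaries": cv_summaries,
        "wilcoxon": {"w_plus": w_stat, "p": w_p},
        "spearman": correlations,
        "cohort_records": cohort.to_dict(orient="records"),
        "sample_size_r078": lactate.sample_size_correlation(0.78, 0.05, 0.90),
    }


def run_experiment(config: PipelineConfig, out_dir=None) -> dict:
    """Run every stage and return (and optionally write) the run report."""
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    report = {"provenance": {"config": dataclasses.asdict(config),
                             "config_hash": config.config_hash(),
                             "seed": config.seed,
                             "version": __version__,
                             "numpy": np.__version__}}
    for name, stage in [("imaging", _imaging_stage), ("fcda", _fcda_stage),
                        ("cohort", _cohort_stage)]:
        logger.info("running stage %s", name)
        try:
            report[name] = stage(config, out)
        except PerfvizError as exc:
            logger.error("stage %s failed: %s", name, exc)
            if out is not None:
                io.write_json(out / "report_partial.json", report)
            raise
    if out is not None:
        io.write_json(out / "report.json", report)
    return report


def render_report(report: dict, out_dir) -> list[str]:
    """Scatter + fit figures and per-zone bar charts from a finished report.

    Missing optional sections are skipped (and noted in the returned list of
    written files as absent).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    cohort_sec = report.get("cohort")
    if cohort_sec and cohort_sec.get("cohort_records"):
        cohort = pd.DataFrame(cohort_sec["cohort_records"])
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, (predictor, col, label) in zip(axes, [
                ("sto2", "sto2_pct", "StO2 (%)"),
                ("fler_slope", "fler_slope", "fluorescence slope (1/s)")]):
            ax.scatter(cohort[col], cohort["lcl_mmol_l"], s=18, alpha=0.7)
            fit = cohort_sec["model_fits"][predictor]
            model = lactate.ExponentialModel(fit["a"], fit["b"], predictor)
            grid = np.linspace(cohort[col].min(), cohort[col].max(), 200)
            mean_sys = cohort["systemic_lactate_mmol_l"].mean()
            ax.plot(grid, lactate.predict_lcl(model, grid, mean_sys), "r-")
            ax.set_xlabel(label)
            ax.set_ylabel("LCL (mmol/L)")
        fig.tight_layout()
        fig.savefig(out / "lactate_fits.png", dpi=120)
        plt.close(fig)
        written.append("lactate_fits.png")
    else:
        written.append("lactate_fits.png: skipped (no cohort section)")

    imaging = report.get("imaging")
    if imaging:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        for ax, key, title in [(axes[0], "sto2_by_zone", "StO2 (%)"),
                               (axes[1], "slope_by_zone", "slope (1/s)")]:
            means = [imaging[key][z]["mean"] for z in ZONE_LABELS]
            sds = [imaging[key][z]["sd"] for z in ZONE_LABELS]
            ax.bar(ZONE_LABELS, means, yerr=sds, color="steelblue")
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out / "zone_summary.png", dpi=120)
        plt.close(fig)
        written.append("zone_summary.png")
    else:
        written.append("zone_summary.png: skipped (no imaging section)")
    return written
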