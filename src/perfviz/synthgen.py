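"""Synthetic scenes, videos, maps, confocal frames and cohorts with known truth.

Everything downstream of acquisition is testable against analytic ground
truth generated here: a three-zone ischemia scene (vital / transition /
ischemic) with zone-dependent dye-inflow kinetics and oxygen-saturation
levels, a constant-intensity calibration card, a global distance-attenuation
factor, bright tubular vessel phantoms inside a circular field of view, and
a cohort whose capillary-lactate values follow the exponential
perfusion-lactate models plus multiplicative log-normal noise.

Defaults emulate the porcine partial pancreatic-ischemia experiment: StO2 of
76.5 +/- 6.0 % (vital), 48.8 +/- 8.1 % (transition), 16.5 +/- 4.76 %
(ischemic); fluorescence slopes 6.79 +/- 4.43, 5.67 +/- 4.93, 0.94 +/- 0.6;
systemic lactate 1.87 +/- 0.869 mmol/L; 40 s of video at 25 fps.

All randomness flows through one ``numpy.random.Generator`` seeded
explicitly; identical parameters and seed give bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ZONE_LABELS,
    ConfocalFrame,
    ConfocalGroundTruth,
    FluorescenceVideo,
    StO2Map,
    VideoGroundTruth,
)
from .errors import InvalidLayoutError, ParameterError
from .lactate import (
    COHORT_COLUMNS,
    FLER_MODEL_COEFFS,
    STO2_MODEL_COEFFS,
    ExponentialModel,
)

__all__ = [
    "ZoneSpec",
    "SceneLayout",
    "CohortParams",
    "DEFAULT_ZONES",
    "generate_fluorescence_video",
    "generate_sto2_map",
    "generate_confocal_frame",
    "generate_zone_phantom_vessels",
    "generate_cohort",
]


@dataclass(frozen=True)
class ZoneSpec:
    """Ground-truth parameters of one perfusion zone.

    ``inflow_delay``/``time_to_peak`` (seconds) and ``peak_intensity``
    (arbitrary units) shape the dye-inflow curve; ``sto2_mean``/``sto2_sd``
    (percent) the oxygen-saturation map; ``fler_mean``/``fler_sd`` the
    per-ROI slope distribution used for cohort draws; ``lcl_noise_sd`` the
    log-scale SD of the multiplicative lactate noise.
    """

    label: str
    sto2_mean: float
    sto2_sd: float
    inflow_delay: float
    time_to_peak: float
    peak_intensity: float
    fler_mean: float
    fler_sd: float
    lcl_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.label not in ZONE_LABELS:
            raise ParameterError(f"unknown zone label {self.label!r}")
        if not 0 <= self.sto2_mean <= 100:
            raise ParameterError("sto2_mean must lie in [0, 100]")
        if self.time_to_peak <= 0:
            raise ParameterError("time_to_peak must be positive")
        if self.time_to_peak <= self.inflow_delay:
            raise ParameterError("time_to_peak must exceed inflow_delay")
        if self.peak_intensity < 0:
            raise ParameterError("peak_intensity must be >= 0")


# Zone StO2 and slope statistics follow the reported per-ROI means/SDs; the
# inflow timing (delay, time-to-peak) has no printed anchor and is set to
# plausible bolus kinetics: fast arrival in vital tissue, slow trickle-in
# through collaterals in the ischemic zone.
DEFAULT_ZONES: tuple[ZoneSpec, ...] = (
    ZoneSpec("vital", 76.5, 6.0, inflow_delay=2.0, time_to_peak=8.0,
             peak_intensity=120.0, fler_mean=6.79, fler_sd=4.43),
    ZoneSpec("transition", 48.8, 8.1, inflow_delay=3.0, time_to_peak=14.0,
             peak_intensity=90.0, fler_mean=5.67, fler_sd=4.93),
    ZoneSpec("ischemic", 16.5, 4.76, inflow_delay=6.0, time_to_peak=30.0,
             peak_intensity=35.0, fler_mean=0.94, fler_sd=0.6),
)


def _check_zone_kinetics(zones) -> None:
    by_label = {z.label: z for z in zones}
    v, i = by_label.get("vital"), by_label.get("ischemic")
    if v is not None and i is not None and i.time_to_peak <= v.time_to_peak:
        raise ParameterError("ischemic time_to_peak must exceed vital time_to_peak")


@dataclass
class SceneLayout:
    """Pixel geometry of a synthetic surgical scene.

    Zone masks are pairwise disjoint and disjoint from the reference card;
    ``fov_mask`` marks valid tissue (the union of the zones by default).
    """

    height: int
    width: int
    zone_masks: dict[str, np.ndarray]
    reference_card_mask: np.ndarray
    fov_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.height, self.width)
        for name, mask in [*self.zone_masks.items(), ("reference", self.reference_card_mask),
                           ("fov", self.fov_mask)]:
            if np.asarray(mask).shape != shape:
                raise InvalidLayoutError(f"mask {name!r} shape differs from layout")
        total = sum(m.astype(int) for m in self.zone_masks.values())
        total = total + self.reference_card_mask.astype(int)
        if total.max() > 1:
            raise InvalidLayoutError("zone/reference masks overlap")

    @classmethod
    def default(cls, height: int = 96, width: int = 129,
                labels=ZONE_LABELS) -> "SceneLayout":
        """Three vertical tissue bands below a background strip with the card."""
        zone_masks = {}
        band_top = height // 6
        edges = np.linspace(0, width, len(labels) + 1).astype(int)
        for label, lo, hi in zip(labels, edges[:-1], edges[1:]):
            m = np.zeros((height, width), dtype=bool)
            m[band_top:, lo:hi] = True
            zone_masks[label] = m
        ref = np.zeros((height, width), dtype=bool)
        ref[2:band_top - 2, 4:20] = True
        fov = np.zeros((height, width), dtype=bool)
        fov[band_top:, :] = True
        return cls(height, width, zone_masks, ref, fov)


def _inflow_fraction(t: np.ndarray, delay: float, ttp: float) -> np.ndarray:
    """Monotone smooth rise: 0 before ``delay``, exactly 1 from ``ttp`` on.

    A logistic rescaled to hit 0 and 1 exactly at the interval endpoints, so
    the analytic time of first maximum is unambiguous (= ``ttp``).
    """
    k = 10.0 / (ttp - delay)
    mid = 0.5 * (delay + ttp)
    sig = 1.0 / (1.0 + np.exp(-k * (t - mid)))
    lo = 1.0 / (1.0 + np.exp(-k * (delay - mid)))
    hi = 1.0 / (1.0 + np.exp(-k * (ttp - mid)))
    frac = (sig - lo) / (hi - lo)
    return np.clip(np.where(t >= ttp, 1.0, np.where(t <= delay, 0.0, frac)), 0.0, 1.0)


def generate_fluorescence_video(
    layout: SceneLayout,
    zones=DEFAULT_ZONES,
    duration: float = 40.0,
    fps: float = 25.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    reference_intensity: float = 50.0,
    attenuation: float = 1.0,
    background_level: float = 2.0,
) -> tuple[FluorescenceVideo, VideoGroundTruth]:
    """Simulate a dye-inflow video over the scene layout.

    Each zone pixel follows a smooth monotone rise from 0 to the zone's
    ``peak_intensity`` between ``inflow_delay`` and ``time_to_peak`` and
    stays at plateau; the reference card is constant across frames; all
    intensities (tissue and card alike) are scaled by one multiplicative
    ``attenuation`` factor, the distance effect that reference
    normalization is designed to cancel. Gaussian noise of ``noise_sd`` is
    added everywhere. Returns the video plus per-pixel analytic truth.
    """
    if fps <= 0:
        raise ParameterError("fps must be positive")
    if attenuation <= 0:
        raise ParameterError("attenuation must be positive")
    n_frames = int(round(duration * fps))
    if n_frames < 2:
        raise ParameterError("duration*fps must give at least 2 frames")
    _check_zone_kinetics(zones)

    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    shape = (layout.height, layout.width)
    frames = np.full((n_frames, *shape), background_level * attenuation)

    gt_ttp = np.full(shape, np.nan)
    gt_peak = np.full(shape, np.nan)
    gt_zone = np.full(shape, "", dtype=object)
    for zone in zones:
        mask = layout.zone_masks[zone.label]
        curve = zone.peak_intensity * _inflow_fraction(t, zone.inflow_delay,
                                                       zone.time_to_peak)
        frames[:, mask] = curve[:, None] * attenuation
        gt_ttp[mask] = zone.time_to_peak
        gt_peak[mask] = zone.peak_intensity * attenuation
        gt_zone[mask] = zone.label

    frames[:, layout.reference_card_mask] = reference_intensity * attenuation
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)

    video = FluorescenceVideo(frames=frames, fps=fps,
                              reference_card_mask=layout.reference_card_mask)
    return video, VideoGroundTruth(gt_ttp, gt_peak, gt_zone)


def generate_sto2_map(layout: SceneLayout, zones=DEFAULT_ZONES,
                      seed: int = 0) -> StO2Map:
    """Draw per-pixel StO2 from each zone's Normal(mean, sd), clipped to [0, 100].

    Pixels outside every zone are flagged invalid (value 0).
    """
    rng = np.random.default_rng(seed)
    sto2 = np.zeros((layout.height, layout.width))
    valid = np.zeros_like(sto2, dtype=bool)
    for zone in zones:
        mask = layout.zone_masks[zone.label]
        n = int(mask.sum())
        draws = zone.sto2_mean + zone.sto2_sd * rng.standard_normal(n)
        sto2[mask] = np.clip(draws, 0.0, 100.0)
        valid |= mask
    return StO2Map(sto2=sto2, valid_mask=valid)


def _distance_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min distance from each (row, col) point to a polyline's segments."""
    best = np.full(len(points), np.inf)
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        if seg_len2 == 0:
            d = np.linalg.norm(points - p0, axis=1)
        else:
            u = np.clip((points - p0) @ seg / seg_len2, 0.0, 1.0)
            proj = p0 + u[:, None] * seg
            d = np.linalg.norm(points - proj, axis=1)
        best = np.minimum(best, d)
    return best


def _polyline_length(polyline: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum())


def generate_confocal_frame(
    vessels: list[tuple[np.ndarray, float]],
    fov_radius: float = 120.0,
    contrast: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background_level: float = 10.0,
) -> tuple[ConfocalFrame, ConfocalGroundTruth]:
    """Render bright vessel tubes on a dark circular field of view.

    ``vessels`` is a list of (centerline polyline as (N, 2) row/col array,
    diameter in px). Every centerline point must stay at least half a
    diameter inside the FOV circle; diameters must be >= 2 px. Ground truth
    records the analytic total centerline length, length-weighted mean
    diameter, analytic FOV area pi*r^2 and the resulting capillary-density
    index, plus the rasterized vessel mask for segmentation scoring.
    """
    size = int(np.ceil(2 * fov_radius)) + 5
    center = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    fov_mask = ((rows - center) ** 2 + (cols - center) ** 2) <= fov_radius**2

    vessel_mask = np.zeros((size, size), dtype=bool)
    total_length = 0.0
    diam_weighted = 0.0
    for polyline, diameter in vessels:
        polyline = np.asarray(polyline, dtype=float) + center
        if diameter < 2:
            raise ParameterError("vessel diameter must be >= 2 px")
        radial = np.linalg.norm(polyline - center, axis=1)
        if np.any(radial > fov_radius - diameter / 2):
            raise ParameterError("vessel centerline extends outside the FOV")
        d = _distance_to_polyline(pts, polyline).reshape(size, size)
        # pixel-footprint rasterization: a width-d band centered on an integer
        # row should occupy d pixel rows, so threshold at (d-1)/2 between
        # pixel centers rather than d/2
        vessel_mask |= d <= (diameter - 1) / 2
        length = _polyline_length(polyline)
        total_length += length
        diam_weighted += diameter * length

    rng = np.random.default_rng(seed)
    intensity = np.full((size, size), background_level)
    intensity[vessel_mask] += contrast
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)

    fov_area = float(np.pi * fov_radius**2)
    mean_diameter = diam_weighted / total_length if total_length > 0 else 0.0
    truth = ConfocalGroundTruth(
        total_length=total_length,
        mean_diameter=mean_diameter,
        fov_area=fov_area,
        fcda=mean_diameter * total_length / fov_area,
        vessel_mask=vessel_mask,
    )
    return ConfocalFrame(intensity=intensity, fov_mask=fov_mask), truth


def generate_zone_phantom_vessels(
    target_fcda: float,
    fov_radius: float = 120.0,
    diameter: float = 6.0,
    spacing: float = 18.0,
) -> list[tuple[np.ndarray, float]]:
    """Horizontal-chord vessel layout whose analytic density index hits a target.

    Chords of the given diameter are stacked every ``spacing`` rows inside
    the FOV circle until the cumulative centerline length reaches
    ``target_fcda * pi * r^2 / diameter``; the last chord is trimmed.
    Deterministic; used to build per-zone phantoms calibrated to reported
    density values.
    """
    if target_fcda < 0:
        raise ParameterError("target_fcda must be >= 0")
    needed = target_fcda * np.pi * fov_radius**2 / diameter
    margin = diameter  # keep the full tube comfortably inside the circle
    vessels: list[tuple[np.ndarray, float]] = []
    got = 0.0
    y = -fov_radius + spacing
    while y < fov_radius - spacing / 2 and got < needed - 1e-9:
        half = np.sqrt(max(fov_radius**2 - y**2, 0.0)) - margin
        if half > 5:
            length = min(2 * half, needed - got)
            if length > 2:
                line = np.array([[y, -length / 2], [y, length / 2]])
                vessels.append((line, diameter))
                got += length
        y += spacing
    if got < needed - 1e-6:
        raise ParameterError("target density too high for the FOV/spacing geometry")
    return vessels


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters for a synthetic animal cohort."""

    n_subjects: int = 6
    systemic_lactate_mean: float = 1.87
    systemic_lactate_sd: float = 0.869
    model_sto2: ExponentialModel = field(
        default_factory=lambda: ExponentialModel(*STO2_MODEL_COEFFS, "sto2"))
    model_fler: ExponentialModel = field(
        default_factory=lambda: ExponentialModel(*FLER_MODEL_COEFFS, "fler_slope"))
    predictor: str = "sto2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("need at least 2 subjects")
        if self.systemic_lactate_mean < 0 or self.systemic_lactate_sd < 0:
            raise ParameterError("lactate mean/sd must be >= 0")
        if self.predictor not in ("sto2", "fler_slope"):
            raise ParameterError("predictor must be 'sto2' or 'fler_slope'")


def generate_cohort(params: CohortParams, zones=DEFAULT_ZONES,
                    lcl_noise_sd: float | None = None) -> pd.DataFrame:
    """Draw a cohort: one systemic lactate per subject, three ROI records each.

    Per ROI the perfusion metrics are drawn from the zone's StO2 and slope
    distributions; the local capillary lactate follows the generating
    exponential model applied to the chosen predictor with multiplicative
    log-normal noise, plus the subject's systemic lactate:

        LCL = exp(-a*x + b) * exp(eps) + systemic,  eps ~ N(0, noise_sd).

    ``lcl_noise_sd`` overrides every zone's noise SD when given (0 = exact
    self-consistent cohort). All lactates are strictly positive by
    construction.
    """
    rng = np.random.default_rng(params.seed)
    model = params.model_sto2 if params.predictor == "sto2" else params.model_fler
    rows = []
    for s in range(params.n_subjects):
        systemic = -1.0
        while systemic <= 0:
            systemic = rng.normal(params.systemic_lactate_mean,
                                  params.systemic_lactate_sd)
        for zone in zones:
            sto2 = float(np.clip(rng.normal(zone.sto2_mean, zone.sto2_sd), 0, 100))
            fler = float(np.clip(rng.normal(zone.fler_mean, zone.fler_sd),
                                 0.01, None))
            x = sto2 if params.predictor == "sto2" else fler
            noise_sd = zone.lcl_noise_sd if lcl_noise_sd is None else lcl_noise_sd
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            lcl = float(model.local_excess(x) * np.exp(eps) + systemic)
            rows.append({
                "subject_id": f"pig{s + 1:02d}",
                "roi_label": zone.label,
                "sto2_pct": sto2,
                "fler_slope": fler,
                "lcl_mmol_l": lcl,
                "systemic_lactate_mmol_l": float(systemic),
            })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
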