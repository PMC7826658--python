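"""Perfusion slope cartography from reference-normalized fluorescence video.

The perfusion surrogate is the per-pixel slope of the dye-inflow curve:
(peak - baseline) normalized intensity divided by the time to reach the
peak. Because absolute fluorescence falls off with camera distance
(inverse-square law), every frame is first divided by the mean signal of a
constant-fluorescence reference card placed in the scene, which cancels any
global illumination or distance factor.

Conventions: baseline is the mean of the first ``baseline_frames``
(unsmoothed) frames; curves are smoothed by a centered moving average with
shrinking edge windows; the peak time is the FIRST frame attaining the
smoothed maximum; pixels whose smoothed rise above baseline stays below
``min_delta`` are invalid, as are pixels peaking in frame 0.
"""
from __future__ import annotations

import numpy as np
from skimage.morphology import remove_small_objects

from .containers import ZONE_LABELS, FluorescenceVideo, PerfusionSlopeMap, ROISet, StO2Map
from .errors import (
    ClassificationError,
    DegenerateReferenceError,
    EmptyROIError,
    ParameterError,
)

__all__ = [
    "normalize_by_reference",
    "time_to_peak",
    "compute_slope_map",
    "roi_mean",
    "classify_zones",
    "zone_summary",
]

DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_DELTA = 0.02
DEFAULT_BASELINE_FRAMES = 5


def normalize_by_reference(video: FluorescenceVideo) -> FluorescenceVideo:
    """Divide each frame by that frame's mean reference-card intensity.

    After normalization the card itself averages 1 in every frame and any
    per-frame multiplicative factor (distance attenuation, illumination
    drift) is removed.
    """
    ref_means = video.frames[:, video.reference_card_mask].mean(axis=1)
    if np.any(ref_means <= 0):
        bad = int(np.argmax(ref_means <= 0))
        raise DegenerateReferenceError(
            f"non-positive reference-card mean in frame {bad}")
    return FluorescenceVideo(
        frames=video.frames / ref_means[:, None, None],
        fps=video.fps,
        reference_card_mask=video.reference_card_mask,
    )


def _moving_average(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with shrinking edge windows.

    Implemented with one cumulative sum so a 1-D series and one lane of a
    3-D stack produce bit-identical values.
    """
    if window <= 1:
        return arr
    n = arr.shape[0]
    half = window // 2
    cs = np.zeros((n + 1, *arr.shape[1:]), dtype=float)
    np.cumsum(arr, axis=0, out=cs[1:])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    counts = (hi - lo).astype(float).reshape((n,) + (1,) * (arr.ndim - 1))
    return (cs[hi] - cs[lo]) / counts


def _peak_stats(curves: np.ndarray, fps: float, smooth_window: int,
                min_delta: float, baseline_frames: int):
    """Shared scalar/map path: (t_peak s, i_peak, baseline, valid) along axis 0."""
    n = curves.shape[0]
    if n < smooth_window:
        raise ParameterError("series shorter than the smoothing window")
    if smooth_window < 1:
        raise ParameterError("smooth_window must be >= 1")
    b = min(baseline_frames, n)
    baseline = curves[:b].mean(axis=0)
    smoothed = _moving_average(curves, smooth_window)
    i_peak = smoothed.max(axis=0)
    # first attainment, with a relative guard so cumulative-sum rounding on a
    # flat plateau cannot push the "first maximum" to a later frame
    tie_eps = 1e-9 * np.maximum(np.abs(i_peak), 1.0)
    peak_frame = np.argmax(smoothed >= i_peak - tie_eps, axis=0)
    valid = (i_peak - baseline) >= min_delta
    valid &= peak_frame > 0
    return peak_frame / fps, i_peak, baseline, valid


def time_to_peak(curve, fps: float, smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                 min_delta: float = DEFAULT_MIN_DELTA,
                 baseline_frames: int = DEFAULT_BASELINE_FRAMES):
    """Peak timing of one intensity series.

    Returns ``(t_peak_seconds, i_peak, i_baseline)`` or ``None`` when the
    curve never rises ``min_delta`` above baseline (or peaks in frame 0).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1:
        raise ParameterError("expected a 1-D intensity series")
    t_peak, i_peak, baseline, valid = _peak_stats(
        curve[:, None], fps, smooth_window, min_delta, baseline_frames)
    if not valid[0]:
        return None
    return float(t_peak[0]), float(i_peak[0]), float(baseline[0])


def compute_slope_map(video: FluorescenceVideo,
                      smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                      min_delta: float = DEFAULT_MIN_DELTA,
                      baseline_frames: int = DEFAULT_BASELINE_FRAMES) -> PerfusionSlopeMap:
    """Per-pixel slope map (peak - baseline) / time_to_peak of a normalized video.

    Vectorized over the full stack; identical to applying :func:`time_to_peak`
    to each pixel independently. Invalid pixels (no rise, or peak in frame 0)
    carry slope 0 and are masked out.
    """
    t_peak, i_peak, baseline, valid = _peak_stats(
        video.frames, video.fps, smooth_window, min_delta, baseline_frames)
    slope = np.zeros_like(i_peak)
    np.divide(i_peak - baseline, t_peak, out=slope, where=valid)
    slope[~valid] = 0.0
    return PerfusionSlopeMap(slope=slope, valid_mask=valid)


def roi_mean(map_: PerfusionSlopeMap | StO2Map, roi: np.ndarray) -> float:
    """Arithmetic mean of the map over the valid pixels of an ROI."""
    roi = np.asarray(roi, dtype=bool)
    values = map_.slope if isinstance(map_, PerfusionSlopeMap) else map_.sto2
    sel = roi & map_.valid_mask
    if not sel.any():
        raise EmptyROIError("ROI contains no valid pixels")
    return float(values[sel].mean())


def classify_zones(sto2_map: StO2Map, thresholds: tuple[float, float] = (33.0, 63.0),
                   min_object_size: int = 16) -> ROISet:
    """Threshold-based replacement for manual zone annotation.

    Ischemic where StO2 < t_low, vital where StO2 >= t_high, transition in
    between; each class is cleaned by small-object removal. Raises
    :class:`ClassificationError` naming the first class left empty.
    """
    t_low, t_high = thresholds
    if not 0 <= t_low < t_high <= 100:
        raise ParameterError("need 0 <= t_low < t_high <= 100")
    valid = sto2_map.valid_mask
    sto2 = sto2_map.sto2
    raw = {
        "ischemic": valid & (sto2 < t_low),
        "vital": valid & (sto2 >= t_high),
        "transition": valid & (sto2 >= t_low) & (sto2 < t_high),
    }
    masks = {}
    for label in ZONE_LABELS:
        cleaned = remove_small_objects(raw[label], max_size=min_object_size - 1)
        if not cleaned.any():
            raise ClassificationError(label)
        masks[label] = cleaned
    return ROISet(masks=masks)


def zone_summary(map_: PerfusionSlopeMap | StO2Map, rois: ROISet) -> dict[str, dict]:
    """Per-zone mean/SD/count of a slope or StO2 map over valid pixels."""
    values = map_.slope if isinstance(map_, PerfusionSlopeMap) else map_.sto2
    out = {}
    for label in ZONE_LABELS:
        sel = rois[label] & map_.valid_mask
        if not sel.any():
            raise EmptyROIError(f"zone {label!r} has no valid pixels")
        v = values[sel]
        out[label] = {"mean": float(v.mean()),
                      "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                      "n_pixels": int(v.size)}
    return out
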