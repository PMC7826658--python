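"""Reading and writing the pipeline's on-disk formats.

Video stacks are multi-page TIFF (one page per frame, 16-bit); masks are
single-page 8-bit TIFF (0/255); scalar maps (StO2, slope) are 32-bit float
TIFF; cohort tables are CSV; ground truth and reports are JSON sidecars.
"""
from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import tifffile

from .containers import FluorescenceVideo, PerfusionSlopeMap, ROISet, StO2Map, ZONE_LABELS
from .errors import ParameterError
from .lactate import COHORT_COLUMNS


def write_video(path, video: FluorescenceVideo) -> None:
    lo, hi = float(video.frames.min()), float(video.frames.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    pages = np.clip((video.frames - lo) * scale, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pages, metadata={"fps": video.fps, "min": lo,
                                            "scale": scale})


def read_video(path, ref_mask_path, fps: float) -> FluorescenceVideo:
    frames = tifffile.imread(path).astype(float)
    ref = read_mask(ref_mask_path)
    return FluorescenceVideo(frames=frames, fps=fps, reference_card_mask=ref)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_map(path, map_) -> None:
    """Scalar map (StO2 or slope) as 32-bit float TIFF; invalid pixels NaN."""
    values = map_.sto2 if isinstance(map_, StO2Map) else map_.slope
    out = np.where(map_.valid_mask, values, np.nan).astype(np.float32)
    tifffile.imwrite(path, out)


def read_sto2_map(path) -> StO2Map:
    arr = tifffile.imread(path).astype(float)
    valid = np.isfinite(arr)
    return StO2Map(sto2=np.where(valid, arr, 0.0), valid_mask=valid)


def read_slope_map(path) -> PerfusionSlopeMap:
    arr = tifffile.imread(path).astype(float)
    valid = np.isfinite(arr)
    return PerfusionSlopeMap(slope=np.where(valid, arr, 0.0), valid_mask=valid)


def render_pseudocolor(path, map_, colormap: str = "jet") -> None:
    """8-bit pseudo-color PNG of a scalar map; invalid pixels black."""
    import imageio.v3 as iio

    values = map_.sto2 if isinstance(map_, StO2Map) else map_.slope
    valid = map_.valid_mask
    lo = values[valid].min() if valid.any() else 0.0
    hi = values[valid].max() if valid.any() else 1.0
    norm = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    rgba = matplotlib.colormaps[colormap](np.clip(norm, 0, 1))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[~valid] = 0
    iio.imwrite(path, rgb)


def write_roiset(path_tiff, path_json, rois: ROISet) -> None:
    """Label TIFF (0 background, 1..3 per zone) plus a JSON legend."""
    labels = np.zeros(rois[ZONE_LABELS[0]].shape, dtype=np.uint8)
    legend = {}
    for i, zone in enumerate(ZONE_LABELS, start=1):
        labels[rois[zone]] = i
        legend[str(i)] = zone
    tifffile.imwrite(path_tiff, labels)
    Path(path_json).write_text(json.dumps(legend, indent=2))


def read_roiset(path_tiff, path_json) -> ROISet:
    labels = tifffile.imread(path_tiff)
    legend = json.loads(Path(path_json).read_text())
    return ROISet(masks={zone: labels == int(i) for i, zone in legend.items()})


def write_cohort(path, cohort: pd.DataFrame) -> None:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ParameterError(f"cohort table missing columns: {sorted(missing)}")
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ParameterError(f"cohort table missing columns: {sorted(missing)}")
    return cohort


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
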