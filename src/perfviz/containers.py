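"""In-memory containers for the imaging data flowing through the pipeline.

All images are numpy arrays in row-major order, 0-based, origin at the
top-left pixel. Masks are boolean arrays of the same height/width as the
image they annotate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ParameterError

ZONE_LABELS = ("vital", "transition", "ischemic")


@dataclass
class FluorescenceVideo:
    """Time-resolved fluorescence stack.

    Parameters
    ----------
    frames : (T, H, W) float array
        Intensity in arbitrary fluorescence units (or dimensionless after
        reference normalization).
    fps : float
        Acquisition frame rate in frames per second.
    reference_card_mask : (H, W) bool array
        Pixels covered by the constant-fluorescence calibration card.
    """

    frames: np.ndarray
    fps: float
    reference_card_mask: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.reference_card_mask = np.asarray(self.reference_card_mask, dtype=bool)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ParameterError("video needs a (T, H, W) stack with at least 2 frames")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if self.reference_card_mask.shape != self.frames.shape[1:]:
            raise DimensionError("reference mask shape does not match frames")
        if not self.reference_card_mask.any():
            raise ParameterError("reference-card mask is empty")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 = injection)."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class PerfusionSlopeMap:
    """Per-pixel perfusion slope: normalized intensity rise per second."""

    slope: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.slope = np.asarray(self.slope, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.slope.shape != self.valid_mask.shape:
            raise DimensionError("slope and valid_mask shapes differ")


@dataclass
class StO2Map:
    """Per-pixel tissue oxygen saturation in percent, [0, 100] on valid pixels."""

    sto2: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.sto2 = np.asarray(self.sto2, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.sto2.shape != self.valid_mask.shape:
            raise DimensionError("sto2 and valid_mask shapes differ")
        vals = self.sto2[self.valid_mask]
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ParameterError("StO2 outside [0, 100] on valid pixels")


@dataclass
class ROISet:
    """Disjoint masks for the vital / transition / ischemic zones."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(ZONE_LABELS) - set(self.masks)
        if missing:
            raise ParameterError(f"missing ROI masks: {sorted(missing)}")
        arrs = [np.asarray(self.masks[z], dtype=bool) for z in ZONE_LABELS]
        self.masks = dict(zip(ZONE_LABELS, arrs))
        total = arrs[0].astype(int) + arrs[1].astype(int) + arrs[2].astype(int)
        if total.max() > 1:
            raise ParameterError("ROI masks overlap")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.masks[label]


@dataclass
class ConfocalFrame:
    """Single confocal-endomicroscopy-like grayscale frame with circular FOV."""

    intensity: np.ndarray
    fov_mask: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
        if self.intensity.shape != self.fov_mask.shape:
            raise DimensionError("intensity and fov_mask shapes differ")
        if not self.fov_mask.any():
            raise ParameterError("field-of-view mask is empty")


@dataclass
class VideoGroundTruth:
    """Analytic per-pixel truth emitted alongside a synthetic video."""

    time_to_peak: np.ndarray  # seconds; NaN outside zones
    peak_intensity: np.ndarray  # raw units, post-attenuation; NaN outside zones
    zone_of_pixel: np.ndarray  # object array of labels, '' outside


@dataclass
class ConfocalGroundTruth:
    """Analytic truth for a synthetic confocal frame."""

    total_length: float  # px, along centerlines
    mean_diameter: float  # px, length-weighted
    fov_area: float  # px^2, analytic pi*r^2
    fcda: float
    vessel_mask: np.ndarray = field(repr=False, default=None)
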