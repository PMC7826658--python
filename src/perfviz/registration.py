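"""Landmark-driven image deformation by moving least squares (MLS).

A static oxygen-saturation map is deformed onto the perfusion cartography
using a handful of manually picked corresponding points. For every
evaluation point v, an affine map A_v minimizing

    sum_i w_i |A_v(p_i) - q_i|^2,   w_i = 1 / |p_i - v|^(2*alpha)

is solved in closed form; as v approaches a control point its weight
diverges, so control points map (essentially) onto their partners while the
deformation stays smooth elsewhere. The dense field is evaluated on a
coarse grid and bilinearly upsampled — exact for any globally affine
deformation, cheap for interactive use.

Coordinates are (x, y) pixel units, 0-based, x = column, y = row.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import map_coordinates

from .errors import DegenerateConfigurationError, DimensionError, ParameterError

__all__ = ["ControlPointPairs", "WarpField", "mls_affine_transform",
           "mls_affine_warp", "overlay"]

_EPS_DIST = 1e-8
_SNAP_RADIUS = 0.5


@dataclass
class ControlPointPairs:
    """Paired landmark coordinates: source points map to target points."""

    source: np.ndarray  # (N, 2) of (x, y)
    target: np.ndarray  # (N, 2) of (x, y)

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise DimensionError("source/target must both be (N, 2)")
        if len(self.source) < 3:
            raise ParameterError("need at least 3 landmark pairs")
        d = np.linalg.norm(self.source[:, None] - self.source[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(self.source), k=1)] < 1e-9):
            raise ParameterError("source points must be pairwise distinct")

    def reversed(self) -> "ControlPointPairs":
        return ControlPointPairs(self.target.copy(), self.source.copy())

    @classmethod
    def from_csv(cls, path) -> "ControlPointPairs":
        """Rows ``x_src,y_src,x_dst,y_dst`` in 0-based pixel units."""
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(arr[:, :2], arr[:, 2:4])


@dataclass
class WarpField:
    """Dense backward map: for each target pixel, its source-space position."""

    source_coords: np.ndarray  # (H, W, 2) of (x, y) positions in the moving image
    valid_mask: np.ndarray  # target pixels that land inside the moving image


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        raise DegenerateConfigurationError(
            "source landmarks are (near-)collinear: affine map underdetermined")


def mls_affine_transform(pairs: ControlPointPairs, points: np.ndarray,
                         alpha: float = 1.0) -> np.ndarray:
    """Evaluate the affine-MLS map at arbitrary points.

    ``points`` is (V, 2) of (x, y); returns the mapped (V, 2) array.
    Evaluation points within 0.5 px of a source landmark inherit that
    landmark's exact displacement (the interpolation limit).
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    p, q = pairs.source, pairs.target
    _check_not_collinear(p)
    v = np.atleast_2d(np.asarray(points, dtype=float))

    d = np.linalg.norm(p[None, :, :] - v[:, None, :], axis=-1)  # (V, N)
    w = 1.0 / np.maximum(d, _EPS_DIST) ** (2 * alpha)
    wsum = w.sum(axis=1, keepdims=True)

    p_star = (w[:, :, None] * p[None]).sum(axis=1) / wsum  # (V, 2)
    q_star = (w[:, :, None] * q[None]).sum(axis=1) / wsum
    p_hat = p[None] - p_star[:, None]  # (V, N, 2)
    q_hat = q[None] - q_star[:, None]

    # 2x2 normal matrices per evaluation point
    A = np.einsum("vn,vni,vnj->vij", w, p_hat, p_hat)
    B = np.einsum("vn,vni,vnj->vij", w, p_hat, q_hat)
    M = np.linalg.solve(A, B)
    out = np.einsum("vi,vij->vj", v - p_star, M) + q_star

    near = d < _SNAP_RADIUS  # snap to the paired displacement near landmarks
    if near.any():
        vi, ni = np.nonzero(near)
        first = np.unique(vi, return_index=True)[1]
        vi, ni = vi[first], ni[first]
        out[vi] = v[vi] + (q[ni] - p[ni])
    return out


def _coarse_axis(n: int, step: int) -> np.ndarray:
    ax = np.arange(0, n, step, dtype=float)
    if ax[-1] != n - 1:
        ax = np.append(ax, n - 1)
    return ax


def mls_affine_warp(image: np.ndarray, pairs: ControlPointPairs,
                    alpha: float = 1.0, grid_step: int = 4,
                    fill_value: float = 0.0) -> tuple[np.ndarray, WarpField]:
    """Deform ``image`` so features at source landmarks move to their targets.

    The backward map (target pixel -> source position) is the MLS transform
    of the reversed pairs, evaluated every ``grid_step`` pixels and
    bilinearly upsampled; resampling is bilinear, and target pixels mapping
    outside the source image are flagged invalid and set to ``fill_value``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DimensionError("expected a single-channel 2-D image")
    h, w = image.shape
    ys, xs = _coarse_axis(h, grid_step), _coarse_axis(w, grid_step)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    coarse_pts = np.column_stack([gx.ravel(), gy.ravel()])
    mapped = mls_affine_transform(pairs.reversed(), coarse_pts, alpha=alpha)
    coarse_field = mapped.reshape(len(ys), len(xs), 2)

    interp = RegularGridInterpolator((ys, xs), coarse_field, method="linear")
    fy, fx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    dense = interp(np.stack([fy, fx], axis=-1))  # (H, W, 2) of source (x, y)

    src_x, src_y = dense[..., 0], dense[..., 1]
    valid = (src_x >= 0) & (src_x <= w - 1) & (src_y >= 0) & (src_y <= h - 1)
    warped = map_coordinates(image, [src_y.ravel(), src_x.ravel()], order=1,
                             mode="constant", cval=fill_value).reshape(h, w)
    warped[~valid] = fill_value
    return warped, WarpField(source_coords=dense, valid_mask=valid)


def overlay(base_frame: np.ndarray, map_image: np.ndarray, opacity: float,
            valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Alpha-blend a pseudo-colored map onto a video frame.

    ``composite = opacity*map + (1-opacity)*base`` on valid pixels, base
    passthrough elsewhere. Images may be grayscale or (H, W, 3).
    """
    base = np.asarray(base_frame, dtype=float)
    top = np.asarray(map_image, dtype=float)
    if base.shape != top.shape:
        raise DimensionError("base and map shapes differ")
    if not 0 <= opacity <= 1:
        raise ParameterError("opacity must lie in [0, 1]")
    blend = opacity * top + (1 - opacity) * base
    if valid_mask is None:
        return blend
    valid = np.asarray(valid_mask, dtype=bool)
    if valid.shape != base.shape[: valid.ndim]:
        raise DimensionError("valid_mask shape incompatible with images")
    out = base.copy()
    out[valid] = blend[valid]
    return out
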