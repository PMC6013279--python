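"""Fluorescence preprocessing: timepoint reduction, ΔF, stacks and ROIs.

Raw acquisition yields eight images per session, taken at 15-min intervals
from 90 to 195 min after maze entry.  Adjacent timepoints are averaged into
four meta-timepoints T1–T4 (90–120, 120–150, 150–180, 180–210 min); the
per-cell activity readout is ΔF = T3 − T1, since IEG-driven fluorescence
peaks 2.5–3 h after behaviour (T3).

Image-stack utilities mirror the original pipeline at reduced scale:
3-D Gaussian smoothing followed by blockwise maximum-intensity projection
collapses 60 z-planes to 12, and circular ROI masks (7 µm radius) yield a
mean grey value per cell and timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RAW_TIMEPOINT_MINUTES",
    "UM_PER_PIXEL",
    "CellTrace",
    "RoiMask",
    "reduce_timepoints",
    "delta_f",
    "reduce_z_stack",
    "extract_roi_means",
    "standardize_timecourse",
]

#: Acquisition times of the 8 raw timepoints, minutes after maze entry.
RAW_TIMEPOINT_MINUTES = (90, 105, 120, 135, 150, 165, 180, 195)

#: Native pixel size: a 400 µm field of view over 1024 pixels.
UM_PER_PIXEL = 400.0 / 1024.0


def reduce_timepoints(raw: Sequence[float]) -> np.ndarray:
    """Average adjacent raw timepoints into the four meta-timepoints.

    ``raw`` must hold exactly 8 finite values; returns
    ``[(r0+r1)/2, (r2+r3)/2, (r4+r5)/2, (r6+r7)/2]``.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.shape[-1] != 8:
        raise ValueError(f"expected 8 raw timepoints, got {arr.shape[-1]}")
    if not np.isfinite(arr).all():
        raise ValueError("raw timepoint values must be finite")
    return arr.reshape(*arr.shape[:-1], 4, 2).mean(axis=-1)


@dataclass(frozen=True)
class CellTrace:
    """One cell's fluorescence across the 8 raw timepoints of a session."""

    cell_id: int
    session_id: str
    raw: tuple

    def __post_init__(self):
        arr = np.asarray(self.raw, dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"raw must hold 8 values, got shape {arr.shape}")
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("raw fluorescence values must be finite and >= 0")
        object.__setattr__(self, "raw", tuple(float(v) for v in arr))

    @property
    def reduced(self) -> np.ndarray:
        """The four meta-timepoint values T1..T4."""
        return reduce_timepoints(self.raw)


def delta_f(trace) -> float:
    """Activity readout ΔF = T3 − T1 (may be negative).

    Accepts a :class:`CellTrace`, the 8 raw values, or the 4 reduced values.
    """
    if isinstance(trace, CellTrace):
        reduced = trace.reduced
    else:
        arr = np.asarray(trace, dtype=float)
        if arr.shape[-1] == 8:
            reduced = reduce_timepoints(arr)
        elif arr.shape[-1] == 4:
            reduced = arr
        else:
            raise ValueError("expected a CellTrace, 8 raw values or 4 reduced values")
    return float(reduced[..., 2] - reduced[..., 0]) if reduced.ndim == 1 else (
        reduced[..., 2] - reduced[..., 0]
    )


@dataclass(frozen=True)
class RoiMask:
    """Circular ROI: centre (x, y) in pixels, 0-based z-plane, radius in px.

    The physical radius is 7 µm; at the native pixel size that is
    7 / (400/1024) ≈ 17.9 px.  Pixel (x, y) belongs to the mask when
    (x − cx)² + (y − cy)² <= r² (inclusive boundary).
    """

    cell_id: int
    center: tuple
    z: int
    radius_px: float = 7.0 / UM_PER_PIXEL

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError(f"radius_px must be positive, got {self.radius_px}")
        if self.z < 0:
            raise ValueError(f"z-plane index must be >= 0, got {self.z}")

    def pixel_indices(self, shape: tuple) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) index arrays of mask pixels inside an image of ``shape``."""
        ny, nx = shape
        cx, cy = self.center
        yy, xx = np.mgrid[0:ny, 0:nx]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius_px**2
        return np.nonzero(inside)


def reduce_z_stack(stack: np.ndarray, sigma: float = 2.0, group: int = 5) -> np.ndarray:
    """Collapse a z-stack by 3-D Gaussian smoothing then blockwise max.

    The stack (z, y, x) is filtered with an isotropic Gaussian (σ = 2 in
    x, y and z) and consecutive groups of ``group`` planes are reduced by
    maximum-intensity projection: 60 planes become 12.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3-D (z, y, x) stack, got ndim={stack.ndim}")
    nz = stack.shape[0]
    if nz % group != 0:
        raise ValueError(f"plane count {nz} is not divisible by group size {group}")
    smoothed = ndimage.gaussian_filter(stack, sigma=sigma, mode="reflect")
    return smoothed.reshape(nz // group, group, *stack.shape[1:]).max(axis=1)


def extract_roi_means(
    planes: np.ndarray,
    masks: Sequence[RoiMask],
    smooth_sigma: float = 2.0,
) -> dict[int, float]:
    """Mean grey value inside each circular ROI on its own z-plane.

    Each plane is first smoothed with a 2-D Gaussian (x, y = 2) as in the
    original measurement pipeline (``smooth_sigma=0`` disables it), then the
    mean over pixels satisfying (x − cx)² + (y − cy)² <= r² is taken.
    """
    planes = np.asarray(planes, dtype=float)
    if planes.ndim != 3:
        raise ValueError(f"expected a 3-D (z, y, x) array of planes, got {planes.ndim}")
    nz = planes.shape[0]
    smoothed: dict[int, np.ndarray] = {}
    out: dict[int, float] = {}
    for mask in masks:
        if mask.z >= nz:
            raise ValueError(f"mask z={mask.z} outside stack with {nz} planes")
        if mask.z not in smoothed:
            plane = planes[mask.z]
            if smooth_sigma > 0:
                plane = ndimage.gaussian_filter(plane, sigma=smooth_sigma, mode="reflect")
            smoothed[mask.z] = plane
        rows, cols = mask.pixel_indices(planes.shape[1:])
        if rows.size == 0:
            raise ValueError(f"mask for cell {mask.cell_id} covers no pixels")
        out[mask.cell_id] = float(smoothed[mask.z][rows, cols].mean())
    return out


def standardize_timecourse(curves: np.ndarray) -> np.ndarray:
    """Standardise per-animal fluorescence time-courses to a common T1 of 0.

    ``curves`` is (n_animals, 4): each animal's mean fluorescence at the
    four meta-timepoints.  Each curve is divided by its own T1 value, then
    the cross-animal mean of the post-division T1 values (identically 1) is
    subtracted from every timepoint, so T1 represents a mean of 0 across
    animals.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if curves.shape[1] != 4:
        raise ValueError(f"expected 4 timepoints per animal, got {curves.shape[1]}")
    t1 = curves[:, 0]
    if (t1 <= 0).any() or not np.isfinite(curves).all():
        raise ValueError("timepoint-1 values must be positive and finite")
    divided = curves / t1[:, None]
    return divided - divided[:, 0].mean()
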