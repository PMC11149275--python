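"""Bone volume fraction (BV/TV) inside a cylindrical region of interest.

A grayscale micro-CT volume is binarized (fixed value or Otsu's two-class
histogram threshold), a cylinder matching the original defect (default
5 mm diameter x 5 mm depth) is rasterized by the voxel-center inclusion
rule, and BV/TV is the bone-voxel count over the total voxel count inside
the mask.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoxelVolume:
    """3-D scalar grid with per-axis voxel spacing (mm) and origin offset."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values)
        object.__setattr__(self, "values", v)
        vs = self.voxel_size_mm
        if np.isscalar(vs):
            vs = (float(vs),) * 3
        vs = tuple(float(s) for s in vs)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if v.ndim != 3 or v.size == 0:
            raise ValidationError(f"volume must be a non-empty 3-D grid, got shape {v.shape}")
        if any(s <= 0 for s in vs):
            raise ValidationError(f"voxel sizes must be positive, got {vs}")


@dataclass(frozen=True)
class CylinderROI:
    """Cylinder along one grid axis; defaults match a 5 x 5 mm defect."""

    axis: int = 0
    center_mm: tuple[float, float] = (0.0, 0.0)
    diameter_mm: float = 5.0
    depth_mm: float = 5.0
    depth_start_mm: float = 0.0

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise ValidationError(f"axis must be 0, 1 or 2, got {self.axis}")
        if self.diameter_mm <= 0 or self.depth_mm <= 0:
            raise ValidationError("cylinder diameter and depth must be > 0")

    @property
    def analytic_volume_mm3(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2 * self.depth_mm


def apply_threshold(volume: VoxelVolume, method: float | str = "otsu"):
    """Binarize a grayscale volume.

    ``method`` is either a fixed threshold value (voxels >= value are bone)
    or ``"otsu"`` for the automatic two-class histogram threshold.  Returns
    ``(binary VoxelVolume, threshold_used)``; the threshold is also logged.
    """
    v = volume.values
    if isinstance(method, str):
        if method != "otsu":
            raise ParameterError(f"unknown threshold method {method!r}")
        if float(np.ptp(v)) == 0.0:
            raise ValidationError("automatic threshold undefined for a constant volume")
        thr = float(threshold_otsu(np.asarray(v, dtype=float)))
    else:
        thr = float(method)
    binary = (v >= thr).astype(np.uint8)
    log.info("threshold applied: %s (method=%s)", thr, method)
    return VoxelVolume(values=binary, voxel_size_mm=volume.voxel_size_mm,
                       origin_mm=volume.origin_mm), thr


def cylinder_mask(shape: tuple[int, int, int],
                  voxel_size_mm, roi: CylinderROI,
                  origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the cylinder."""
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    axes = [0, 1, 2]
    ax = roi.axis
    plane = [a for a in axes if a != ax]
    coords = [(np.arange(shape[a]) + 0.5) * voxel_size_mm[a] + origin_mm[a]
              for a in axes]
    axial = coords[ax]
    in_depth = (axial >= roi.depth_start_mm) & (axial < roi.depth_start_mm + roi.depth_mm)
    c1 = coords[plane[0]] - roi.center_mm[0]
    c2 = coords[plane[1]] - roi.center_mm[1]
    r2 = (roi.diameter_mm / 2.0) ** 2
    in_circle = c1[:, None] ** 2 + c2[None, :] ** 2 <= r2

    mask = np.zeros(shape, dtype=bool)
    shape_ax = [1, 1, 1]
    shape_ax[ax] = shape[ax]
    depth_b = in_depth.reshape(shape_ax)
    circ_shape = [1, 1, 1]
    circ_shape[plane[0]] = shape[plane[0]]
    circ_shape[plane[1]] = shape[plane[1]]
    circle_b = in_circle.reshape(circ_shape)
    mask = depth_b & circle_b
    if not mask.any():
        raise ValidationError("cylinder ROI does not intersect the grid")
    return mask


def bvtv(binary: VoxelVolume, mask: np.ndarray) -> float:
    """Bone voxels over total voxels inside the mask."""
    v = binary.values
    if v.shape != mask.shape:
        raise ValidationError(
            f"volume shape {v.shape} and mask shape {mask.shape} differ")
    total = int(mask.sum())
    if total == 0:
        raise ValidationError("empty ROI mask")
    bone = int(np.count_nonzero(v[mask]))
    return bone / total


def save_volume(volume: VoxelVolume, path) -> None:
    """Multi-page TIFF stack plus a JSON sidecar with spacing/origin."""
    tifffile.imwrite(path, np.asarray(volume.values))
    with open(str(path) + ".json", "w") as fh:
        json.dump({"voxel_size_mm": list(volume.voxel_size_mm),
                   "origin_mm": list(volume.origin_mm)}, fh)


def load_volume(path) -> VoxelVolume:
    values = tifffile.imread(path)
    sidecar = str(path) + ".json"
    meta = {"voxel_size_mm": [1.0, 1.0, 1.0], "origin_mm": [0.0, 0.0, 0.0]}
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta.update(json.load(fh))
    return VoxelVolume(values=values, voxel_size_mm=tuple(meta["voxel_size_mm"]),
                       origin_mm=tuple(meta["origin_mm"]))
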