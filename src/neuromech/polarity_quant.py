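"""Rear-of-soma myosin-activity quantification.

The soma is split along the axis toward the leading process through the
nucleus centroid; myosin II activity is the ratio of the mean
phospho-myosin-light-chain intensity to the mean total-MLC intensity within
the posterior (rear) half.  Means of means are used (not a pixelwise
ratio), so the measure is robust to zero-intensity pixels and invariant to
joint intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, RegionError


@dataclass
class PolarizedSoma:
    """Soma mask plus a polarity frame: nucleus centroid and the unit axis
    pointing toward the leading process (pixel coordinates, x = column,
    y = row)."""

    soma_mask: np.ndarray
    centroid_xy: tuple[float, float]
    axis_xy: tuple[float, float]

    def __post_init__(self) -> None:
        self.soma_mask = np.asarray(self.soma_mask, dtype=bool)
        norm = float(np.hypot(*self.axis_xy))
        if norm == 0:
            raise GeometryError("axis must be non-zero")
        self.axis_xy = (self.axis_xy[0] / norm, self.axis_xy[1] / norm)
        cx, cy = self.centroid_xy
        iy, ix = int(round(cy)), int(round(cx))
        ny, nx = self.soma_mask.shape
        if not (0 <= iy < ny and 0 <= ix < nx) or not self.soma_mask[iy, ix]:
            raise GeometryError("centroid must lie inside the soma mask")


def posterior_half_mask(ps: PolarizedSoma) -> np.ndarray:
    """Soma pixels behind the centroid: (pixel - centroid) . axis < 0."""
    ny, nx = ps.soma_mask.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    proj = (xx - ps.centroid_xy[0]) * ps.axis_xy[0] + (yy - ps.centroid_xy[1]) * ps.axis_xy[1]
    mask = ps.soma_mask & (proj < 0)
    if not mask.any():
        raise GeometryError("geometry-error: posterior half is empty")
    return mask


def anterior_half_mask(ps: PolarizedSoma) -> np.ndarray:
    """Complement of the posterior half within the soma."""
    return ps.soma_mask & ~posterior_half_mask(ps)


def myosin_activity_ratio(
    pmlc_img: np.ndarray, mlc_img: np.ndarray, mask: np.ndarray
) -> float:
    """mean(pMLC over mask) / mean(MLC over mask)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("empty mask")
    pmlc = np.asarray(pmlc_img, dtype=float)
    mlc = np.asarray(mlc_img, dtype=float)
    if pmlc.shape != mlc.shape or pmlc.shape != mask.shape:
        raise RegionError("image and mask shapes differ")
    denom = float(np.mean(mlc[mask]))
    if denom <= 0:
        raise ZeroDivisionError("invalid-denominator: zero MLC signal")
    return float(np.mean(pmlc[mask])) / denom


def rear_myosin_ratio(
    pmlc_img: np.ndarray, mlc_img: np.ndarray, ps: PolarizedSoma
) -> float:
    """Convenience: pMLC/MLC over the posterior half of the soma."""
    return myosin_activity_ratio(pmlc_img, mlc_img, posterior_half_mask(ps))
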