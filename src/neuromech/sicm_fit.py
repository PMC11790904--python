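"""Inverse SICM analysis: reference current, set-point topography,
window-slope line fit, Young's modulus and stiffness-map assembly.

The per-curve analysis follows the hopping-mode recipe: the reference
current is the mean plateau current, the approach stops where the current
falls to the set-point fraction (98% by default), and the slope of the
normalized current between 98.5% and 99% of the reference is obtained with
a least-squares line fit of current versus z.  Young's modulus is

    E = p0 * A / (s_inf / s - 1)

with s the measured slope magnitude on the cell and s_inf its value on the
rigid substrate.

For noisy curves the set-point crossing and the window location are found
on a moving-average smoothed curve, while the line fit itself uses the raw
samples within the selected z range (selection on raw noisy samples would
bias the slope).  Noise-free curves are analyzed without smoothing, so the
round trip through :mod:`neuromech.sicm_sim` is exact to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    FitError,
    InvalidSlopeError,
    NoContactError,
    RegionError,
    WindowTooSparseError,
)
from .sicm_sim import ApproachCurve, PipetteParams, ScanGrid

_RIGID_RTOL = 1e-9


@dataclass
class CurveFitResult:
    i_ref_pa: float
    z_stop_nm: float
    slope_per_nm: float
    modulus_kpa: float  # +inf when rigid, nan when invalid
    n_window_samples: int
    rigid: bool = False
    valid: bool = True


@dataclass
class StiffnessMap:
    modulus_kpa: np.ndarray  # (ny, nx); nan outside valid_mask
    topography_um: np.ndarray
    valid_mask: np.ndarray
    substrate_mask: np.ndarray
    pixel_size_um: float
    s_inf_per_nm: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.modulus_kpa[self.valid_mask])):
            raise FitError("modulus must be finite on valid pixels")


def reference_current(curve: ApproachCurve) -> float:
    """Mean direct current over the pre-approach waiting (plateau) segment."""
    lo, hi = curve.plateau_range
    if hi <= lo:
        raise FitError("no-reference: empty plateau segment")
    return float(np.mean(curve.current_pa[lo:hi]))


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window)
    norm = np.convolve(np.ones_like(values), kernel, mode="same")
    return np.convolve(values, kernel, mode="same") / norm


def _auto_smooth_window(curve: ApproachCurve, i_ref: float) -> int:
    """Pick a smoothing window from the plateau noise level: none for
    (near) noise-free curves, ~2% of the approach length otherwise."""
    lo, hi = curve.plateau_range
    sd = float(np.std(curve.current_pa[lo:hi] / i_ref))
    if sd < 1e-7:
        return 0
    n_approach = curve.z_nm.size - hi
    return max(11, (n_approach // 50) | 1)


def _first_crossing_z(
    z: np.ndarray, norm: np.ndarray, level: float, start: int
) -> float:
    """First z (in approach order, i.e. decreasing z) where ``norm`` falls
    to ``level``, linearly interpolated between bracketing samples."""
    below = np.flatnonzero(norm[start:] <= level)
    if below.size == 0:
        raise NoContactError(f"curve never reaches {level:.4g} of the reference")
    k = start + below[0]
    if k == start or norm[k - 1] <= level:
        return float(z[k])
    frac = (norm[k - 1] - level) / (norm[k - 1] - norm[k])
    return float(z[k - 1] + frac * (z[k] - z[k - 1]))


def setpoint_z(
    curve: ApproachCurve,
    i_ref: float,
    setpoint: float = 0.98,
    smooth: int = 0,
) -> float:
    """z of the set-point crossing (first sample at or below
    ``setpoint * i_ref``, linearly interpolated)."""
    norm = curve.current_pa / i_ref
    norm = _smooth(norm, smooth)
    return _first_crossing_z(curve.z_nm, norm, setpoint, curve.plateau_range[1])


def _window_line(
    curve: ApproachCurve,
    i_ref: float,
    window: tuple[float, float],
    smooth: int,
) -> tuple[float, float, int]:
    """Fit the line ``norm = b*z + a`` over the window samples.

    For noisy curves the samples are selected where the *smoothed*
    normalized current lies inside the window (selecting on raw noisy
    values would correlate noise with inclusion and attenuate the slope);
    the line itself is fitted to the raw values.  Returns ``(b, a, n)``.
    """
    lo, hi = window
    norm = curve.current_pa / i_ref
    start = curve.plateau_range[1]
    basis = _smooth(norm, smooth) if smooth > 1 else norm
    sel = (basis >= lo) & (basis <= hi)
    sel[:start] = False
    n = int(np.count_nonzero(sel))
    if n < 2:
        raise WindowTooSparseError(f"only {n} sample(s) inside the slope window")
    b, a = np.polyfit(curve.z_nm[sel], norm[sel], 1)
    return float(b), float(a), n


def window_slope(
    curve: ApproachCurve,
    i_ref: float,
    window: tuple[float, float] = (0.985, 0.99),
    smooth: int = 0,
) -> tuple[float, int]:
    """Least-squares line-fit slope magnitude of normalized current vs z
    over the samples inside ``window``; returns ``(slope, n_samples)``."""
    b, _, n = _window_line(curve, i_ref, window, smooth)
    return float(abs(b)), n


def youngs_modulus(
    slope_per_nm: float,
    s_inf_per_nm: float,
    p0_kpa: float = 10.0,
    geometry_factor: float = 0.4,
) -> float:
    """E = p0 * A * (s_inf / s - 1)^-1; returns +inf (rigid) when the
    measured slope equals the substrate slope."""
    s = slope_per_nm
    if s <= 0 or s > s_inf_per_nm * (1.0 + _RIGID_RTOL):
        raise InvalidSlopeError(f"slope {s!r} outside (0, s_inf]")
    if s >= s_inf_per_nm * (1.0 - _RIGID_RTOL):
        return np.inf
    return p0_kpa * geometry_factor / (s_inf_per_nm / s - 1.0)


def fit_curve(
    curve: ApproachCurve,
    pipette: PipetteParams,
    smooth: int | str = "auto",
    s_inf_per_nm: float | None = None,
) -> CurveFitResult:
    """Full single-curve analysis chain."""
    i_ref = reference_current(curve)
    if smooth == "auto":
        smooth = _auto_smooth_window(curve, i_ref)
    b, a, n = _window_line(curve, i_ref, pipette.slope_window, smooth)
    # the curve is (locally) linear through the window, so the set-point
    # crossing is read off the fitted line; exact in the noise-free limit
    z_stop = (pipette.setpoint_fraction - a) / b
    s = abs(b)
    s_inf = pipette.substrate_slope_per_nm if s_inf_per_nm is None else s_inf_per_nm
    try:
        e = youngs_modulus(
            s, s_inf, pipette.applied_pressure_kpa, pipette.geometry_factor
        )
    except InvalidSlopeError:
        return CurveFitResult(i_ref, z_stop, s, np.nan, n, valid=False)
    return CurveFitResult(i_ref, z_stop, s, e, n, rigid=np.isinf(e))


def stiffness_map(
    grid: ScanGrid,
    substrate_mask: np.ndarray | None = None,
    s_inf: float | str | None = None,
    smooth: int | str = "auto",
    rigid_margin: float = 0.1,
) -> StiffnessMap:
    """Assemble per-pixel fits into Young's-modulus and topography images.

    s_inf resolution order: an explicit ``s_inf`` value; the median window
    slope over ``substrate_mask`` when that mask is given; ``s_inf="auto"``
    (median of the top-2%-slope pixels, which then also seed the substrate
    mask); otherwise the value carried by the grid's pipette parameters.
    """
    ny, nx = grid.ny, grid.nx
    slopes = np.full((ny, nx), np.nan)
    z_stop = np.full((ny, nx), np.nan)
    fit_ok = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            curve = grid.curve(ix, iy)
            try:
                i_ref = reference_current(curve)
                w = _auto_smooth_window(curve, i_ref) if smooth == "auto" else smooth
                b, a, _ = _window_line(curve, i_ref, grid.pipette.slope_window, w)
                z_stop[iy, ix] = (grid.pipette.setpoint_fraction - a) / b
                slopes[iy, ix] = abs(b)
                fit_ok[iy, ix] = True
            except FitError:
                continue
    if not fit_ok.any():
        raise FitError("empty-map: no pixel produced a valid fit")

    if isinstance(s_inf, str):
        if s_inf != "auto":
            raise FitError(f"unknown s_inf mode {s_inf!r}")
        cutoff = np.nanquantile(slopes, 0.98)
        top = fit_ok & (slopes >= cutoff)
        s_inf_val = float(np.median(slopes[top]))
        substrate_mask = fit_ok & (slopes >= (1.0 - rigid_margin) * s_inf_val)
    elif s_inf is not None:
        s_inf_val = float(s_inf)
    elif substrate_mask is not None:
        sub_ok = fit_ok & np.asarray(substrate_mask, dtype=bool)
        if not sub_ok.any():
            raise RegionError("substrate mask contains no fitted pixel")
        s_inf_val = float(np.median(slopes[sub_ok]))
    else:
        s_inf_val = grid.pipette.substrate_slope_per_nm
    if substrate_mask is None:
        substrate_mask = np.zeros((ny, nx), dtype=bool)
    substrate_mask = np.asarray(substrate_mask, dtype=bool)

    modulus = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            if not fit_ok[iy, ix] or substrate_mask[iy, ix]:
                continue
            try:
                e = youngs_modulus(
                    slopes[iy, ix],
                    s_inf_val,
                    grid.pipette.applied_pressure_kpa,
                    grid.pipette.geometry_factor,
                )
            except InvalidSlopeError:
                continue
            if np.isfinite(e):
                modulus[iy, ix] = e
                valid[iy, ix] = True

    topo = z_stop / 1000.0
    if substrate_mask.any():
        topo = topo - np.nanmedian(topo[substrate_mask])
    return StiffnessMap(
        modulus_kpa=modulus,
        topography_um=topo,
        valid_mask=valid,
        substrate_mask=substrate_mask,
        pixel_size_um=grid.pixel_size_um,
        s_inf_per_nm=s_inf_val,
    )


def roi_mask(
    polygon_um: np.ndarray, shape: tuple[int, int], pixel_size_um: float
) -> np.ndarray:
    """Rasterize an (x, y) polygon in um to a boolean pixel mask."""
    from skimage.draw import polygon2mask

    pts = np.asarray(polygon_um, dtype=float) / pixel_size_um
    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(shape, pts[:, ::-1])


def roi_delta_series(
    maps: list[StiffnessMap],
    roi: np.ndarray,
) -> np.ndarray:
    """Mean modulus within the ROI per time point, referenced to the first
    time point (so the first entry is 0; drop it before correlating).

    ``roi`` is either a boolean mask matching the map shape or an (n, 2)
    polygon in um.
    """
    if len(maps) < 2:
        raise RegionError("need at least two time points")
    shape = maps[0].modulus_kpa.shape
    roi = np.asarray(roi)
    if roi.dtype != bool:
        roi = roi_mask(roi, shape, maps[0].pixel_size_um)
    means = []
    for m in maps:
        sel = roi & m.valid_mask
        if not sel.any():
            raise RegionError("roi-error: ROI misses all valid pixels")
        means.append(float(np.mean(m.modulus_kpa[sel])))
    means = np.asarray(means)
    return means - means[0]


def write_map_outputs(smap: StiffnessMap, outdir) -> None:
    """Write modulus/topography as 32-bit TIFF plus CSV matrices."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "modulus_kpa.tif", smap.modulus_kpa.astype(np.float32))
    tifffile.imwrite(
        outdir / "topography_um.tif", smap.topography_um.astype(np.float32)
    )
    pd.DataFrame(smap.modulus_kpa).to_csv(
        outdir / "modulus_kpa.csv", index=False, header=False
    )
    pd.DataFrame(smap.topography_um).to_csv(
        outdir / "topography_um.csv", index=False, header=False
    )
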