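"""Forward simulation of SICM hopping-mode scans over phantom neurons.

The simulator produces ion-current approach curves whose normalized current
is exactly linear in the probe position below the contact point, with slope
magnitude set by the target Young's modulus.  This makes the inverse
analysis (reference current -> set-point topography -> window-slope fit ->
modulus) well posed and exactly recoverable in the noise-free limit.

Conventions
-----------
* ``z`` is the vertical probe (tip) position in nm, strictly decreasing
  toward the surface within one curve.  The recorded axis is treated as the
  probe position; whether the instrument logs probe or piezo coordinates is
  undocumented upstream, so a single axis is stored.
* Topography is the z of the set-point crossing relative to the substrate
  plane; pixels are row-major with origin top-left and coordinates at pixel
  centers.
* Slopes are magnitudes of d(I/I_ref)/dz in units of 1/nm.
* Current noise is i.i.d. Gaussian with standard deviation
  ``noise_sd * i_ref``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import h5py
import numpy as np

from .errors import ConfigError, GeometryError, InvalidModulusError

# phantom pixel labels
SUBSTRATE = 0
SOMA = 1
PROCESS = 2


@dataclass(frozen=True)
class PipetteParams:
    """Probe parameters of the hopping-mode stiffness measurement.

    ``substrate_slope_per_nm`` is the normalized-current slope magnitude
    measured over the rigid substrate (s_inf).
    """

    applied_pressure_kpa: float = 10.0
    geometry_factor: float = 0.4
    substrate_slope_per_nm: float = 1.0e-3
    setpoint_fraction: float = 0.98
    slope_window: tuple[float, float] = (0.985, 0.99)

    def __post_init__(self) -> None:
        if self.applied_pressure_kpa <= 0:
            raise ConfigError("applied_pressure_kpa must be > 0")
        if self.geometry_factor <= 0:
            raise ConfigError("geometry_factor must be > 0")
        if self.substrate_slope_per_nm <= 0:
            raise ConfigError("substrate_slope_per_nm must be > 0")
        lo, hi = self.slope_window
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("slope_window must satisfy 0 < low < high < 1")
        if not (0.0 < self.setpoint_fraction < lo):
            raise ConfigError("setpoint_fraction must lie below the slope window")


@dataclass
class ApproachCurve:
    """One probe approach: z positions (nm), ion current (pA) and the
    pre-approach plateau segment used for the reference current."""

    z_nm: np.ndarray
    current_pa: np.ndarray
    plateau_range: tuple[int, int]
    pixel_xy_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.z_nm.size == 0:
            raise ConfigError("empty z grid")
        if self.z_nm.shape != self.current_pa.shape:
            raise ConfigError("z and current must have equal length")
        if not np.all(np.diff(self.z_nm) < 0):
            raise ConfigError("z must be strictly monotone decreasing")
        lo, hi = self.plateau_range
        if not (0 <= lo < hi <= self.z_nm.size):
            raise ConfigError("plateau range must be non-empty and in bounds")

    @property
    def plateau_slice(self) -> slice:
        return slice(*self.plateau_range)


def slope_from_modulus(
    modulus_kpa: float, pipette: PipetteParams, rigid: bool = False
) -> float:
    """Normalized approach-curve slope for a surface of given Young's modulus.

    Inverts E = p0 * A * (s_inf / s - 1)^-1 to
    s = s_inf / (1 + p0 * A / E); the rigid limit (E -> inf) gives s_inf.
    """
    s_inf = pipette.substrate_slope_per_nm
    if rigid or np.isinf(modulus_kpa):
        return s_inf
    if not np.isfinite(modulus_kpa) or modulus_kpa <= 0:
        raise InvalidModulusError(f"invalid modulus {modulus_kpa!r} kPa")
    return s_inf / (
        1.0 + pipette.applied_pressure_kpa * pipette.geometry_factor / modulus_kpa
    )


def _default_z_grid(
    slope: float, z_contact_nm: float, pipette: PipetteParams, n_dense: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """Non-uniform z sampling: a coarse plateau, a coarse upper approach,
    a dense band bracketing the slope-fit window, and a coarse tail past
    the set point.  The dense band keeps the window slope estimable under
    per-sample current noise."""
    lo, hi = pipette.slope_window
    pad = 0.0005
    bottom = pipette.setpoint_fraction - 0.005

    def z_of(i_norm: float) -> float:
        return z_contact_nm - (1.0 - i_norm) / slope

    n_plateau = 32
    plateau = np.linspace(z_contact_nm + 400.0, z_contact_nm + 40.0, n_plateau)
    upper = np.linspace(z_contact_nm, z_of(hi + pad), 33)
    dense = np.linspace(z_of(hi + pad), z_of(lo - pad), n_dense + 1)[1:]
    tail = np.linspace(z_of(lo - pad), z_of(bottom), 33)[1:]
    z = np.concatenate([plateau, upper, dense, tail])
    return z, (0, n_plateau)


def synth_approach_curve(
    modulus_kpa: float,
    pipette: PipetteParams,
    z_grid_nm: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    rigid: bool = False,
    surface_z_nm: float = 0.0,
    i_ref_pa: float = 1000.0,
    n_dense: int = 2001,
    rng: np.random.Generator | None = None,
    pixel_xy_um: tuple[float, float] | None = None,
) -> ApproachCurve:
    """Generate one approach curve whose window slope equals
    :func:`slope_from_modulus` and whose set-point crossing sits at
    ``surface_z_nm``."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    s = slope_from_modulus(modulus_kpa, pipette, rigid=rigid)
    # contact point placed so the set-point crossing lands on the surface
    z_contact = surface_z_nm + (1.0 - pipette.setpoint_fraction) / s

    if z_grid_nm is None:
        z, plateau_range = _default_z_grid(s, z_contact, pipette, n_dense)
    else:
        z = np.asarray(z_grid_nm, dtype=float)
        if z.size == 0:
            raise ConfigError("empty z grid")
        n_plateau = int(np.count_nonzero(z >= z_contact))
        if n_plateau == 0:
            raise ConfigError("z grid must start above the contact point")
        plateau_range = (0, n_plateau)

    i_norm = np.minimum(1.0, 1.0 - s * (z_contact - z))
    current = i_norm * i_ref_pa
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        current = current + noise_sd * i_ref_pa * rng.standard_normal(z.size)
    return ApproachCurve(z, current, plateau_range, pixel_xy_um=pixel_xy_um)


@dataclass
class Phantom:
    """Known-truth cell geometry: topography (um), Young's modulus field
    (kPa, +inf on the rigid substrate) and per-pixel labels."""

    topography_um: np.ndarray
    modulus_kpa: np.ndarray
    labels: np.ndarray
    extent_um: float
    process_length_um: float
    process_polyline_um: np.ndarray  # (n, 2) x/y vertices; empty if no process

    def __post_init__(self) -> None:
        shapes = {self.topography_um.shape, self.modulus_kpa.shape, self.labels.shape}
        if len(shapes) != 1:
            raise GeometryError("field shapes differ")
        cell = self.labels != SUBSTRATE
        if np.any(~np.isfinite(self.modulus_kpa[cell])) or np.any(
            self.modulus_kpa[cell] <= 0
        ):
            raise GeometryError("cell pixels must have finite positive modulus")

    @property
    def ny(self) -> int:
        return self.labels.shape[0]

    @property
    def nx(self) -> int:
        return self.labels.shape[1]

    @property
    def pixel_size_um(self) -> float:
        return self.extent_um / self.nx


def make_phantom(
    nx: int,
    ny: int,
    extent_um: float,
    *,
    soma_axes_um: tuple[float, float] = (8.0, 6.0),
    process_length_um: float = 30.0,
    e_soma_kpa: float = 2.0,
    e_process_kpa: float = 3.0,
    e_cell_kpa: float | None = None,
    soma_height_um: float = 0.5,
    process_height_um: float = 0.3,
    soma_center_um: tuple[float, float] | None = None,
    process_halfwidth_um: float | None = None,
) -> Phantom:
    """Build a phantom neuron: an elliptical soma plus a straight leading
    process of the requested arc length, over a rigid flat substrate."""
    if process_length_um < 0:
        raise GeometryError("process length must be >= 0")
    if e_cell_kpa is not None:
        e_soma_kpa = e_process_kpa = e_cell_kpa
    if e_soma_kpa <= 0 or e_process_kpa <= 0:
        raise InvalidModulusError("cell modulus must be positive")

    dx = extent_um / nx
    dy = extent_um / ny
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    xg, yg = np.meshgrid(xs, ys)

    if soma_center_um is None:
        soma_center_um = (0.3 * extent_um, 0.5 * extent_um)
    cx, cy = soma_center_um
    a = soma_axes_um[0] / 2.0
    b = soma_axes_um[1] / 2.0
    if cx - a < 0 or cx + a > extent_um or cy - b < 0 or cy + b > extent_um:
        raise GeometryError("soma does not fit inside the scan area")

    soma = ((xg - cx) / a) ** 2 + ((yg - cy) / b) ** 2 <= 1.0

    labels = np.full((ny, nx), SUBSTRATE, dtype=int)
    labels[soma] = SOMA
    polyline = np.empty((0, 2))
    if process_length_um > 0:
        x0 = cx + a
        x1 = x0 + process_length_um
        if x1 > extent_um:
            raise GeometryError("process extends beyond the scan area")
        hw = process_halfwidth_um if process_halfwidth_um is not None else 0.75 * dy
        proc = (np.abs(yg - cy) <= hw) & (xg >= x0) & (xg <= x1) & ~soma
        labels[proc] = PROCESS
        polyline = np.array([[x0, cy], [x1, cy]])

    topo = np.zeros((ny, nx))
    topo[labels == SOMA] = soma_height_um
    topo[labels == PROCESS] = process_height_um
    modulus = np.full((ny, nx), np.inf)
    modulus[labels == SOMA] = e_soma_kpa
    modulus[labels == PROCESS] = e_process_kpa
    return Phantom(topo, modulus, labels, extent_um, process_length_um, polyline)


@dataclass
class ScanGrid:
    """Hopping-mode grid of approach curves (row-major pixel order)."""

    nx: int
    ny: int
    extent_um: float
    pipette: PipetteParams
    seed: int | None
    noise_sd: float
    z_nm: np.ndarray  # (nx*ny, nsamples)
    current_pa: np.ndarray  # (nx*ny, nsamples)
    plateau_ranges: np.ndarray  # (nx*ny, 2)

    def __post_init__(self) -> None:
        npix = self.nx * self.ny
        if self.z_nm.shape[0] != npix or self.current_pa.shape != self.z_nm.shape:
            raise ConfigError("curve arrays inconsistent with grid size")

    @property
    def n_curves(self) -> int:
        return self.nx * self.ny

    @property
    def pixel_size_um(self) -> float:
        return self.extent_um / self.nx

    def curve(self, ix: int, iy: int) -> ApproachCurve:
        k = iy * self.nx + ix
        return ApproachCurve(
            self.z_nm[k],
            self.current_pa[k],
            tuple(self.plateau_ranges[k]),
            pixel_xy_um=((ix + 0.5) * self.pixel_size_um, (iy + 0.5) * self.pixel_size_um),
        )

    def iter_curves(self) -> Iterator[ApproachCurve]:
        for iy in range(self.ny):
            for ix in range(self.nx):
                yield self.curve(ix, iy)

    # ---- HDF5 container -------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            meta = f.create_group("meta")
            meta.attrs["nx"] = self.nx
            meta.attrs["ny"] = self.ny
            meta.attrs["extent_um"] = self.extent_um
            meta.attrs["seed"] = -1 if self.seed is None else int(self.seed)
            meta.attrs["noise_sd"] = self.noise_sd
            for name in (
                "applied_pressure_kpa",
                "geometry_factor",
                "substrate_slope_per_nm",
                "setpoint_fraction",
            ):
                meta.attrs[name] = getattr(self.pipette, name)
            meta.attrs["slope_window"] = np.asarray(self.pipette.slope_window)
            f.create_dataset("z", data=self.z_nm)
            f.create_dataset("current", data=self.current_pa)
            f.create_dataset("plateau", data=self.plateau_ranges)

    @classmethod
    def from_hdf5(cls, path) -> "ScanGrid":
        with h5py.File(path, "r") as f:
            meta = f["meta"].attrs
            pipette = PipetteParams(
                applied_pressure_kpa=float(meta["applied_pressure_kpa"]),
                geometry_factor=float(meta["geometry_factor"]),
                substrate_slope_per_nm=float(meta["substrate_slope_per_nm"]),
                setpoint_fraction=float(meta["setpoint_fraction"]),
                slope_window=tuple(np.asarray(meta["slope_window"], dtype=float)),
            )
            seed = int(meta["seed"])
            return cls(
                nx=int(meta["nx"]),
                ny=int(meta["ny"]),
                extent_um=float(meta["extent_um"]),
                pipette=pipette,
                seed=None if seed < 0 else seed,
                noise_sd=float(meta["noise_sd"]),
                z_nm=f["z"][...],
                current_pa=f["current"][...],
                plateau_ranges=f["plateau"][...],
            )


def _resample_nearest(fieldarr: np.ndarray, ny: int, nx: int) -> np.ndarray:
    sy = (np.arange(ny) + 0.5) * fieldarr.shape[0] / ny
    sx = (np.arange(nx) + 0.5) * fieldarr.shape[1] / nx
    iy = np.clip(sy.astype(int), 0, fieldarr.shape[0] - 1)
    ix = np.clip(sx.astype(int), 0, fieldarr.shape[1] - 1)
    return fieldarr[np.ix_(iy, ix)]


def simulate_scan(
    phantom: Phantom,
    pipette: PipetteParams,
    nx: int | None = None,
    ny: int | None = None,
    extent_um: float | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    n_dense: int = 2001,
    i_ref_pa: float = 1000.0,
) -> ScanGrid:
    """Simulate a hopping-mode scan of ``phantom`` (one curve per pixel).

    If a grid spec differing from the phantom's is given, the phantom fields
    are resampled by nearest neighbour at the new pixel centers.
    """
    nx = phantom.nx if nx is None else nx
    ny = phantom.ny if ny is None else ny
    extent_um = phantom.extent_um if extent_um is None else extent_um
    if nx < 1 or ny < 1 or extent_um <= 0:
        raise ConfigError("invalid grid spec")

    topo = phantom.topography_um
    modulus = phantom.modulus_kpa
    labels = phantom.labels
    if (ny, nx) != labels.shape:
        topo = _resample_nearest(topo, ny, nx)
        modulus = _resample_nearest(modulus, ny, nx)
        labels = _resample_nearest(labels, ny, nx)

    rng = np.random.default_rng(seed)
    npix = nx * ny
    nsamples = n_dense + 32 + 33 + 32  # plateau + upper + dense + tail
    z_all = np.empty((npix, nsamples))
    cur_all = np.empty((npix, nsamples))
    plat_all = np.empty((npix, 2), dtype=int)
    for iy in range(ny):
        for ix in range(nx):
            k = iy * nx + ix
            rigid = labels[iy, ix] == SUBSTRATE
            curve = synth_approach_curve(
                modulus[iy, ix],
                pipette,
                noise_sd=noise_sd,
                rigid=rigid,
                surface_z_nm=1000.0 * topo[iy, ix],
                i_ref_pa=i_ref_pa,
                n_dense=n_dense,
                rng=rng,
            )
            z_all[k] = curve.z_nm
            cur_all[k] = curve.current_pa
            plat_all[k] = curve.plateau_range
    return ScanGrid(
        nx=nx,
        ny=ny,
        extent_um=extent_um,
        pipette=pipette,
        seed=seed,
        noise_sd=noise_sd,
        z_nm=z_all,
        current_pa=cur_all,
        plateau_ranges=plat_all,
    )
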