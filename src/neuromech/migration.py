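"""Track-level migration metrics for saltatory neuronal migration.

A cell is "in the somal translocation phase" during any 2-min acquisition
interval in which the soma moved; "any distance" is operationalized with a
displacement threshold ``eps_um`` (default 0.2 um, about one camera pixel)
to reject tracking jitter.  The migration speed is the total soma path
length over the total observation time; the translocation speed divides
the path accrued during translocation intervals by the time spent in them
(a ``denominator="total"`` variant is provided because the upstream
definition is ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientTrackError

DEFAULT_EPS_UM = 0.2


@dataclass
class CellTrack:
    """Soma positions (um) and optional leading-process lengths over time."""

    t_min: np.ndarray
    soma_xy_um: np.ndarray  # (n, 2)
    length_um: np.ndarray | None = None
    theta_deg: float | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.soma_xy_um = np.asarray(self.soma_xy_um, dtype=float)
        if self.soma_xy_um.ndim != 2 or self.soma_xy_um.shape[1] != 2:
            raise ConfigError("soma_xy_um must be an (n, 2) array")
        if self.t_min.size != self.soma_xy_um.shape[0]:
            raise ConfigError("time and position lengths differ")
        if self.t_min.size > 1 and not np.all(np.diff(self.t_min) > 0):
            raise ConfigError("timestamps must be strictly increasing")
        if self.length_um is not None:
            self.length_um = np.asarray(self.length_um, dtype=float)
            if np.any(self.length_um < 0):
                raise ConfigError("lengths must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.t_min.size


@dataclass
class MigrationMetrics:
    migration_speed_um_per_min: float
    translocation_speed_um_per_min: float  # NaN when no translocation interval
    translocation_fraction: float
    n_frames: int


def polyline_length(points_um: np.ndarray) -> float:
    """Arc length of a polyline (sum of consecutive Euclidean segments)."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[0] < 1:
        raise ConfigError("need at least one point")
    if pts.shape[0] == 1:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _step_lengths(track: CellTrack) -> np.ndarray:
    if track.n_frames < 2:
        raise InsufficientTrackError("need at least two frames")
    return np.linalg.norm(np.diff(track.soma_xy_um, axis=0), axis=1)


def translocation_phase(track: CellTrack, eps_um: float = DEFAULT_EPS_UM) -> np.ndarray:
    """Boolean per interval: soma displacement strictly above ``eps_um``."""
    return _step_lengths(track) > eps_um


def migration_speed(track: CellTrack) -> float:
    """Total soma path length divided by the observation time (um/min)."""
    steps = _step_lengths(track)
    duration = track.t_min[-1] - track.t_min[0]
    if duration <= 0:
        raise InsufficientTrackError("zero observation time")
    return float(steps.sum() / duration)


def translocation_speed(
    track: CellTrack,
    eps_um: float = DEFAULT_EPS_UM,
    denominator: str = "phase",
) -> float:
    """Soma path during translocation intervals over the time in them
    (``denominator="phase"``) or over the whole track (``"total"``).
    Returns NaN when no interval qualifies."""
    steps = _step_lengths(track)
    flagged = steps > eps_um
    if not flagged.any():
        return np.nan
    dts = np.diff(track.t_min)
    if denominator == "phase":
        return float(steps[flagged].sum() / dts[flagged].sum())
    if denominator == "total":
        return float(steps[flagged].sum() / dts.sum())
    raise ConfigError(f"unknown denominator {denominator!r}")


def migration_metrics(track: CellTrack, eps_um: float = DEFAULT_EPS_UM) -> MigrationMetrics:
    steps = _step_lengths(track)
    flagged = steps > eps_um
    dts = np.diff(track.t_min)
    return MigrationMetrics(
        migration_speed_um_per_min=migration_speed(track),
        translocation_speed_um_per_min=translocation_speed(track, eps_um),
        translocation_fraction=float(dts[flagged].sum() / dts.sum()),
        n_frames=track.n_frames,
    )


def stretch_orientation(theta_deg: float) -> str:
    """Classify the leading-process angle against the stretch direction:
    <=30 deg parallel, >=60 deg perpendicular, otherwise unclassified.
    The angle is first folded into [0, 90] deg."""
    t = abs(float(theta_deg)) % 180.0
    if t > 90.0:
        t = 180.0 - t
    if t <= 30.0:
        return "parallel"
    if t >= 60.0:
        return "perpendicular"
    return "unclassified"


def speed_um_per_h(speed_um_per_min: float) -> float:
    return speed_um_per_min * 60.0


def amplitude_percent_of_length(amplitude_um: float, mean_length_um: float) -> float:
    """Extension/retraction amplitude expressed as a percentage of the mean
    leading-process length."""
    if mean_length_um <= 0:
        raise ConfigError("mean length must be positive")
    return 100.0 * amplitude_um / mean_length_um


def read_track_csv(path) -> CellTrack:
    """CSV with columns ``t_min, x_um, y_um[, length_um][, theta_deg]``."""
    df = pd.read_csv(path)
    theta = float(df["theta_deg"].iloc[0]) if "theta_deg" in df else None
    length = df["length_um"].to_numpy(dtype=float) if "length_um" in df else None
    return CellTrack(
        df["t_min"].to_numpy(),
        df[["x_um", "y_um"]].to_numpy(),
        length_um=length,
        theta_deg=theta,
    )


def write_track_csv(track: CellTrack, path) -> None:
    data = {
        "t_min": track.t_min,
        "x_um": track.soma_xy_um[:, 0],
        "y_um": track.soma_xy_um[:, 1],
    }
    if track.length_um is not None:
        data["length_um"] = track.length_um
    pd.DataFrame(data).to_csv(path, index=False)


def metrics_table(tracks: dict[str, CellTrack], eps_um: float = DEFAULT_EPS_UM) -> pd.DataFrame:
    """One metrics row per named track."""
    rows = []
    for name, track in tracks.items():
        m = migration_metrics(track, eps_um)
        rows.append(
            {
                "cell": name,
                "migration_speed_um_per_min": m.migration_speed_um_per_min,
                "translocation_speed_um_per_min": m.translocation_speed_um_per_min,
                "translocation_fraction": m.translocation_fraction,
                "n_frames": m.n_frames,
                "mean_length_um": (
                    float(np.mean(track.length_um)) if track.length_um is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
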