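"""Ratiometric Ca2+ trace processing and transient detection.

The intracellular Ca2+ level is the ratio of the 525-nm to the 650-nm
emission channel.  The whole-trace mean of the ratio is the baseline F0 and
each frame is normalized to it; an excursion is a transient when
(F - F0) / F0 exceeds 0.40.  Supra-threshold runs separated by less than
the merge window (10 s, i.e. two 5-s frames) are counted as one event.

Note the threshold semantics: the "F/F0 > 40%" rule is implemented as a
40% *increase over baseline* (F/F0 > 1.4).  Reading it literally as a
ratio above 0.4 would flag essentially every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_THRESHOLD = 0.40
DEFAULT_MIN_SEPARATION_S = 10.0
DEFAULT_FRAME_INTERVAL_S = 5.0


@dataclass
class TransientEvent:
    onset_index: int
    peak_index: int
    peak_amplitude: float  # (F - F0) / F0 at the peak

    def __post_init__(self) -> None:
        if self.onset_index > self.peak_index:
            raise ConfigError("onset must not follow the peak")


@dataclass
class CalciumTrace:
    """Two-channel fluorescence series with derived ratio and baseline."""

    t_s: np.ndarray
    f525: np.ndarray
    f650: np.ndarray
    ratio: np.ndarray = field(init=False)
    f0: float = field(init=False)
    norm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f525 = np.asarray(self.f525, dtype=float)
        self.f650 = np.asarray(self.f650, dtype=float)
        if not (self.t_s.size == self.f525.size == self.f650.size):
            raise ConfigError("channel series must have equal length")
        self.ratio = ratio_series(self.f525, self.f650)
        self.f0, self.norm = normalize_f0(self.ratio)

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.t_s))) if self.t_s.size > 1 else np.nan

    @property
    def duration_min(self) -> float:
        return float(self.t_s.size * self.frame_interval_s / 60.0)


def ratio_series(f525: np.ndarray, f650: np.ndarray) -> np.ndarray:
    """Elementwise 525/650 emission ratio."""
    f525 = np.asarray(f525, dtype=float)
    f650 = np.asarray(f650, dtype=float)
    if f525.shape != f650.shape:
        raise ConfigError("channel series must have equal length")
    if np.any(f650 <= 0):
        raise ConfigError("invalid-denominator: F650 must be positive")
    return f525 / f650


def normalize_f0(ratio: np.ndarray) -> tuple[float, np.ndarray]:
    """Whole-trace mean baseline; returns ``(F0, ratio / F0)``.

    The mean is used deliberately even though transients inflate it; a
    percentile baseline is available via :func:`percentile_baseline`.
    """
    ratio = np.asarray(ratio, dtype=float)
    if ratio.size == 0:
        raise ConfigError("invalid-input: empty ratio series")
    f0 = float(np.mean(ratio))
    return f0, ratio / f0


def percentile_baseline(ratio: np.ndarray, q: float = 20.0) -> tuple[float, np.ndarray]:
    """Alternative robust baseline (q-th percentile of the ratio)."""
    ratio = np.asarray(ratio, dtype=float)
    if ratio.size == 0:
        raise ConfigError("invalid-input: empty ratio series")
    f0 = float(np.percentile(ratio, q))
    return f0, ratio / f0


def detect_transients(
    norm: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> list[TransientEvent]:
    """One event per supra-threshold run of the normalized trace.

    Frames with ``norm - 1 > threshold`` (strict) form candidate runs; runs
    whose gap is shorter than ``min_separation_s`` merge into one event.
    """
    norm = np.asarray(norm, dtype=float)
    above = (norm - 1.0) > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    # split into runs, merging short gaps
    events: list[TransientEvent] = []
    run_start = idx[0]
    prev = idx[0]
    run_members = [idx[0]]
    for k in idx[1:]:
        if (k - prev - 1) * frame_interval_s < min_separation_s:
            run_members.append(k)
        else:
            events.append(_finish_run(norm, run_start, run_members))
            run_start = k
            run_members = [k]
        prev = k
    events.append(_finish_run(norm, run_start, run_members))
    return events


def _finish_run(norm: np.ndarray, start: int, members: list[int]) -> TransientEvent:
    members = np.asarray(members)
    peak = int(members[np.argmax(norm[members])])
    return TransientEvent(int(start), peak, float(norm[peak] - 1.0))


def transient_frequency(events: list[TransientEvent], duration_min: float) -> float:
    """Events per minute."""
    if duration_min <= 0:
        raise ConfigError("invalid duration")
    return len(events) / duration_min


BIN_LABELS = ("(-inf,-4)", "[-4,0)", "[0,4)", "[4,inf)")


def frequency_by_length_bin(
    length_um: np.ndarray,
    events: list[TransientEvent],
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    offsets_um: tuple[float, float, float] = (-4.0, 0.0, 4.0),
) -> pd.DataFrame:
    """Transient frequency per leading-process length-deviation bin.

    Each frame is assigned to a half-open bin by its deviation from the
    trace-mean length; an event counts toward the bin of its onset frame.
    Bins with zero occupancy time report NaN frequency (missing, not 0).
    """
    length_um = np.asarray(length_um, dtype=float)
    if length_um.size == 0:
        raise ConfigError("invalid-input: empty length series")
    dev = length_um - np.mean(length_um)
    bin_idx = np.digitize(dev, offsets_um)  # 0..3
    minutes = np.array(
        [np.count_nonzero(bin_idx == b) * frame_interval_s / 60.0 for b in range(4)]
    )
    n_events = np.zeros(4, dtype=int)
    for ev in events:
        if ev.onset_index >= length_um.size:
            raise ConfigError("event onset outside the length series")
        n_events[bin_idx[ev.onset_index]] += 1
    freq = np.where(minutes > 0, n_events / np.where(minutes > 0, minutes, 1.0), np.nan)
    return pd.DataFrame(
        {
            "bin": list(BIN_LABELS),
            "n_events": n_events,
            "minutes": minutes,
            "freq_per_min": freq,
        }
    )


def read_trace_csv(path) -> tuple[CalciumTrace, np.ndarray | None]:
    """CSV with columns ``t_s, f525, f650[, length_um]``."""
    df = pd.read_csv(path)
    trace = CalciumTrace(
        df["t_s"].to_numpy(), df["f525"].to_numpy(), df["f650"].to_numpy()
    )
    length = df["length_um"].to_numpy(dtype=float) if "length_um" in df else None
    return trace, length


def write_events_csv(
    events: list[TransientEvent], path, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
) -> None:
    pd.DataFrame(
        {
            "onset_s": [ev.onset_index * frame_interval_s for ev in events],
            "peak_s": [ev.peak_index * frame_interval_s for ev in events],
            "amplitude": [ev.peak_amplitude for ev in events],
        }
    ).to_csv(path, index=False)
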