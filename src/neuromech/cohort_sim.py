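"""Synthetic cohorts implementing the integrated extension -> tension ->
Ca2+ -> rear myosin -> translocation feedback loop.

Model summary (all functional forms are parameters of :class:`CohortParams`):

* The leading-process length follows a mean-reverting (Ornstein-Uhlenbeck)
  walk toward a per-cell growth target ``baseline + growth_push_um``; the
  stationary spread is half the extension/retraction excursion scale.
* Membrane tension (reported as a lifetime proxy in ns) is affine in the
  instantaneous length.
* Ca2+ transients are an inhomogeneous Bernoulli point process on the 5-s
  frame grid whose rate gates up when the length exceeds the cell baseline
  by ~4 um (logistic gate); a knockdown factor kappa in [0, 1] multiplies
  the rate.
* Each transient opens a refractory/translocation window during which rear
  myosin activity rises and the soma steps toward the process tip; the step
  is subtracted from the process length, producing saltatory anti-phase
  length/translocation dynamics.
* The two emission channels move in opposite directions on Ca2+ binding
  (525 nm up, 650 nm down), so the 525/650 ratio carries the transients.

With the default wild-type parameters the downward step flux balances the
growth push near the cohort-mean length, so per-cell mean lengths center on
``mean_length_um``; knockdown shifts the balance toward longer processes
and fewer, slower somal steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigError
from .polarity_quant import PolarizedSoma

# fluorescence response kernel per transient (5-s frames) and the myosin
# activity kernel over the translocation window
_CA_KERNEL = np.array([1.0, 0.65, 0.35, 0.15])
_MYOSIN_KERNEL = np.array([1.0, 0.8, 0.6, 0.4, 0.25, 0.1])


@dataclass(frozen=True)
class CohortParams:
    n_cells: int = 50
    # length process
    mean_length_um: float = 39.0
    excursion_um: float = 11.3
    cell_sd_um: float = 6.0
    relaxation_min: float = 8.0
    growth_push_um: float = 9.5
    # tension proxy (lifetime, ns)
    tension_base_ns: float = 5.4
    tension_gain_ns_per_um: float = 0.02
    tension_noise_ns: float = 0.05
    # transient rate lambda(L) = kappa * (base + gain * sigmoid((L - baseline - offset)/width))
    rate_base_per_min: float = 0.15
    rate_gain_per_min: float = 1.2
    gate_offset_um: float = 4.0
    gate_width_um: float = 2.0
    knockdown: float = 1.0
    refractory_s: float = 30.0
    # somal steps; knockdown also weakens the per-transient Ca2+/myosin
    # drive, scaling step sizes by 1 - step_kd_coupling * (1 - kappa)
    step_mean_um: float = 4.0
    step_sd_um: float = 1.0
    step_kd_coupling: float = 0.5
    myosin_gain: float = 1.5
    track_jitter_um: float = 0.02
    # imaging grids
    frame_interval_s: float = 5.0
    track_interval_min: float = 2.0
    duration_min: float = 120.0
    # fluorescence emission model
    f525_base: float = 100.0
    f650_base: float = 200.0
    ratio_gain: float = 0.7
    ratio_dip: float = 0.3
    channel_noise: float = 0.01
    amp_lo: float = 0.5
    amp_hi: float = 0.8
    # uniaxial stretch protocol
    stretch_strain: float = 0.20
    stretch_orientation: str | None = None  # None | "parallel" | "perpendicular"
    stretch_onset_min: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "mean_length_um",
            "excursion_um",
            "relaxation_min",
            "frame_interval_s",
            "track_interval_min",
            "duration_min",
            "f525_base",
            "f650_base",
            "gate_width_um",
            "step_mean_um",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.knockdown <= 1.0:
            raise ConfigError("knockdown must be in [0, 1]")
        if self.rate_base_per_min < 0 or self.rate_gain_per_min < 0:
            raise ConfigError("rates must be >= 0")
        if self.stretch_orientation not in (None, "parallel", "perpendicular"):
            raise ConfigError("stretch_orientation must be parallel/perpendicular/None")
        if self.ratio_dip * self.amp_hi >= 1.0:
            raise ConfigError("650-nm channel would go non-positive at peak")


@dataclass
class CellRecord:
    """One simulated cell: 5-s-grid series plus the 2-min soma track."""

    params: CohortParams
    seed: int  # integer seed, or -1 when simulated from a spawned sequence
    variant: str
    baseline_um: float
    t_s: np.ndarray
    length_um: np.ndarray
    tension_ns: np.ndarray
    f525: np.ndarray
    f650: np.ndarray
    rear_myosin: np.ndarray
    true_transient_s: np.ndarray
    track_t_min: np.ndarray
    soma_xy_um: np.ndarray  # (n, 2)
    spawn_index: int = -1  # index into SeedSequence(params.seed).spawn(n_cells)

    @property
    def duration_min(self) -> float:
        return self.params.duration_min

    def true_transient_indices(self) -> np.ndarray:
        return np.round(self.true_transient_s / self.params.frame_interval_s).astype(int)


def _transient_rate_per_min(
    params: CohortParams, length_um: float, baseline_um: float
) -> float:
    gate = expit((length_um - baseline_um - params.gate_offset_um) / params.gate_width_um)
    return params.knockdown * (params.rate_base_per_min + params.rate_gain_per_min * gate)


def simulate_cell(params: CohortParams, seed: int | np.random.SeedSequence) -> CellRecord:
    """Simulate one cell on the 5-s grid; see the module docstring."""
    rng = np.random.default_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1

    dt_min = params.frame_interval_s / 60.0
    n = int(round(params.duration_min * 60.0 / params.frame_interval_s)) + 1
    refr_frames = max(1, int(round(params.refractory_s / params.frame_interval_s)))
    sigma_st = params.excursion_um / 2.0
    sigma_step = sigma_st * np.sqrt(2.0 * dt_min / params.relaxation_min)

    baseline = float(
        np.clip(params.mean_length_um + params.cell_sd_um * rng.standard_normal(), 10.0, None)
    )
    direction = rng.uniform(0.0, 2.0 * np.pi)
    unit = np.array([np.cos(direction), np.sin(direction)])

    # pre-draw per-frame noise so variants with identical dynamics share
    # identical random streams frame for frame
    xi_len = rng.standard_normal(n)
    u_event = rng.random(n)
    xi_tension = rng.standard_normal(n)
    xi_f525 = rng.standard_normal(n)
    xi_f650 = rng.standard_normal(n)
    xi_track = rng.standard_normal((n, 2))

    stretch_on = params.stretch_orientation == "parallel"
    onset_frame = int(round(params.stretch_onset_min * 60.0 / params.frame_interval_s))

    length_dyn = np.empty(n)
    length_obs = np.empty(n)
    transient_frames: list[int] = []
    g = np.zeros(n)  # Ca2+ fluorescence drive
    h = np.zeros(n)  # rear myosin drive
    advance = np.zeros(n)  # soma step per frame (um)

    lvl = baseline
    refr = 0
    step_per_frame = 0.0
    for k in range(n):
        # a parallel stretch scales the geometry once at onset: the process
        # (and the growth target, i.e. the stretched substrate frame)
        # lengthen by 1 + strain, while the membrane rest length -- the
        # tension/gate reference -- stays at the cell baseline
        stretched = stretch_on and k >= onset_frame
        if stretch_on and k == onset_frame:
            lvl *= 1.0 + params.stretch_strain
        length_dyn[k] = lvl
        length_obs[k] = lvl

        if refr > 0:
            refr -= 1
            advance[k] = step_per_frame
        else:
            rate = _transient_rate_per_min(params, length_obs[k], baseline)
            if u_event[k] < min(rate * dt_min, 1.0):
                transient_frames.append(k)
                amp = rng.uniform(params.amp_lo, params.amp_hi)
                m = min(_CA_KERNEL.size, n - k)
                g[k : k + m] += amp * _CA_KERNEL[:m]
                m = min(_MYOSIN_KERNEL.size, n - k)
                h[k : k + m] += _MYOSIN_KERNEL[:m]
                kd_scale = 1.0 - params.step_kd_coupling * (1.0 - params.knockdown)
                step = kd_scale * max(
                    0.5, rng.normal(params.step_mean_um, params.step_sd_um)
                )
                step_per_frame = step / refr_frames
                refr = refr_frames - 1
                advance[k] = step_per_frame
            else:
                step_per_frame = 0.0

        # OU relaxation toward the growth target, minus the somal step
        target = baseline + params.growth_push_um
        if stretched:
            target *= 1.0 + params.stretch_strain
        lvl = (
            lvl
            + (target - lvl) * dt_min / params.relaxation_min
            + sigma_step * xi_len[k]
            - advance[k]
        )
        lvl = max(lvl, 1.0)

    t_s = np.arange(n) * params.frame_interval_s
    tension = (
        params.tension_base_ns
        + params.tension_gain_ns_per_um * (length_obs - params.mean_length_um)
        + params.tension_noise_ns * xi_tension
    )
    f525 = params.f525_base * (1.0 + params.ratio_gain * g) * (
        1.0 + params.channel_noise * xi_f525
    )
    f650 = params.f650_base * (1.0 - params.ratio_dip * g) * (
        1.0 + params.channel_noise * xi_f650
    )
    f525 = np.clip(f525, 1e-3, None)
    f650 = np.clip(f650, 1e-3, None)
    rear_myosin = 1.0 + params.myosin_gain * h

    soma = np.cumsum(advance)[:, None] * unit + params.track_jitter_um * xi_track
    stride = max(1, int(round(params.track_interval_min * 60.0 / params.frame_interval_s)))
    track_idx = np.arange(0, n, stride)

    variant = params.stretch_orientation or ("wt" if params.knockdown == 1.0 else "kd")
    return CellRecord(
        params=params,
        seed=int(seed_int),
        variant=variant,
        baseline_um=baseline,
        t_s=t_s,
        length_um=length_obs,
        tension_ns=tension,
        f525=f525,
        f650=f650,
        rear_myosin=rear_myosin,
        true_transient_s=np.asarray(transient_frames, dtype=float)
        * params.frame_interval_s,
        track_t_min=track_idx * params.frame_interval_s / 60.0,
        soma_xy_um=soma[track_idx],
    )


def simulate_cohort(params: CohortParams) -> list[CellRecord]:
    """Map :func:`simulate_cell` over per-cell seeds spawned from the
    master seed."""
    if params.n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    children = np.random.SeedSequence(params.seed).spawn(params.n_cells)
    records = []
    for k, child in enumerate(children):
        rec = simulate_cell(params, child)
        rec.spawn_index = k  # reproducible from params.seed
        records.append(rec)
    return records


def apply_stretch(
    record: CellRecord,
    strain: float = 0.20,
    orientation: str = "parallel",
    onset_min: float | None = None,
) -> CellRecord:
    """Re-simulate the cell with a uniaxial stretch applied from
    ``onset_min``.  A parallel stretch scales the observed length (and
    therefore the transient rate) by ``1 + strain``; a perpendicular
    stretch leaves the cell statistically unchanged (identical with the
    same seed)."""
    if strain <= 0:
        raise ConfigError("strain must be > 0")
    if orientation not in ("parallel", "perpendicular"):
        raise ConfigError("orientation must be parallel or perpendicular")
    params = replace(
        record.params,
        stretch_strain=strain,
        stretch_orientation=orientation,
        stretch_onset_min=(
            record.params.stretch_onset_min if onset_min is None else onset_min
        ),
    )
    seed = _reseed(record)
    rec = simulate_cell(params, seed)
    rec.spawn_index = record.spawn_index
    return rec


def _reseed(record: CellRecord):
    """Recover the exact seed stream the record was simulated with."""
    if record.spawn_index >= 0:
        children = np.random.SeedSequence(record.params.seed).spawn(
            record.params.n_cells
        )
        return children[record.spawn_index]
    return record.seed


def render_soma_images(
    rear_activity: float,
    shape: tuple[int, int] = (48, 48),
    radius_px: int = 16,
    noise: float = 0.01,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, PolarizedSoma]:
    """Synthetic pMLC/MLC image pair for a soma whose rear-half myosin
    activity is ``rear_activity`` (front half fixed at 1); the leading
    process points along +x."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    soma = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    mlc = 100.0 * (1.0 + noise * rng.standard_normal(shape))
    activity = np.where(xx < cx, rear_activity, 1.0)
    pmlc = 100.0 * activity * (1.0 + noise * rng.standard_normal(shape))
    mlc[~soma] = 0.0
    pmlc[~soma] = 0.0
    ps = PolarizedSoma(soma, (cx, cy), (1.0, 0.0))
    return pmlc, mlc, ps


def mean_rear_activity(record: CellRecord, start_min: float = 0.0) -> float:
    """Time-averaged rear myosin activity from ``start_min`` onward."""
    sel = record.t_s >= start_min * 60.0
    return float(np.mean(record.rear_myosin[sel]))


def write_cell_csvs(record: CellRecord, outdir, name: str) -> None:
    """Write the analysis-module input files for one cell: a 5-s-grid
    trace CSV and a 2-min-grid track CSV."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "t_s": record.t_s,
            "f525": record.f525,
            "f650": record.f650,
            "length_um": record.length_um,
            "tension_ns": record.tension_ns,
        }
    ).to_csv(outdir / f"{name}_trace.csv", index=False)
    stride = max(
        1,
        int(
            round(
                record.params.track_interval_min
                * 60.0
                / record.params.frame_interval_s
            )
        ),
    )
    pd.DataFrame(
        {
            "t_min": record.track_t_min,
            "x_um": record.soma_xy_um[:, 0],
            "y_um": record.soma_xy_um[:, 1],
            "length_um": record.length_um[::stride],
        }
    ).to_csv(outdir / f"{name}_track.csv", index=False)
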