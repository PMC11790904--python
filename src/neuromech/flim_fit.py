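"""Bi-exponential fluorescence-decay fitting (tension-probe FLIM readout).

Decays are modelled as ideal from t = 0 with no instrument-response
deconvolution and no cutoff: every bin enters the least-squares fit.  The
longer of the two fitted lifetimes is the quantity used downstream as the
membrane-tension proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, RegionError


@dataclass
class DecayHistogram:
    """Photon-arrival counts per time bin (edges in ns)."""

    t_edges_ns: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_bins,)

    def __post_init__(self) -> None:
        self.t_edges_ns = np.asarray(self.t_edges_ns, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.t_edges_ns.size != self.counts.size + 1:
            raise FitError("edges must have one more entry than counts")
        if not np.all(np.diff(self.t_edges_ns) > 0):
            raise FitError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise FitError("counts must be non-negative")

    @property
    def t_centers_ns(self) -> np.ndarray:
        return 0.5 * (self.t_edges_ns[:-1] + self.t_edges_ns[1:])


@dataclass
class BiExpFit:
    tau_short_ns: float
    tau_long_ns: float
    a_short: float
    a_long: float
    goodness: float  # reduced chi-square with Poisson weights
    degenerate: bool = False  # lifetimes collapsed within 1%


def simulate_decay(
    tau_long_ns: float,
    tau_short_ns: float | None = None,
    frac_long: float = 1.0,
    n_photons: int = 100_000,
    t_max_ns: float = 40.0,
    n_bins: int = 512,
    seed: int | None = None,
) -> DecayHistogram:
    """Draw a Poissonian photon-arrival histogram from a (bi-)exponential
    decay.  Photons arriving after ``t_max_ns`` are discarded, mimicking a
    finite measurement window."""
    rng = np.random.default_rng(seed)
    if not 0.0 <= frac_long <= 1.0:
        raise FitError("frac_long must be in [0, 1]")
    n_long = rng.binomial(n_photons, frac_long)
    times = rng.exponential(tau_long_ns, size=n_long)
    if tau_short_ns is not None and n_photons - n_long > 0:
        times = np.concatenate(
            [times, rng.exponential(tau_short_ns, size=n_photons - n_long)]
        )
    times = times[times < t_max_ns]
    edges = np.linspace(0.0, t_max_ns, n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    return DecayHistogram(edges, counts)


def _tail_lifetime_guess(t: np.ndarray, counts: np.ndarray) -> float:
    """Log-linear fit of the decay tail as a starting value for tau_long."""
    nz = np.flatnonzero(counts > 0)
    tail = nz[len(nz) // 2 :]
    if tail.size < 2:
        return float(t[-1] / 3.0)
    slope = np.polyfit(t[tail], np.log(counts[tail].astype(float)), 1)[0]
    if slope >= 0:
        return float(t[-1] / 3.0)
    return float(-1.0 / slope)


def biexp_fit(hist: DecayHistogram) -> BiExpFit:
    """Least-squares fit of a1*exp(-t/tau1) + a2*exp(-t/tau2) to the counts
    (all bins used, Poisson-weighted); components sorted so that
    tau_long >= tau_short."""
    counts = np.asarray(hist.counts, dtype=float)
    if np.count_nonzero(counts) < 10:
        raise FitError("fit-error: fewer than 10 non-empty bins")
    t = hist.t_centers_ns

    tau_l0 = _tail_lifetime_guess(t, counts)
    tau_s0 = tau_l0 / 4.0
    a0 = max(counts.max(), 1.0)

    def model(tt, a1, tau1, a2, tau2):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    # unweighted pass, then Poisson weights from the *model* (weighting by
    # observed counts systematically biases the lifetimes low)
    try:
        popt, _ = curve_fit(
            model,
            t,
            counts,
            p0=(0.3 * a0, tau_s0, 0.7 * a0, tau_l0),
            bounds=(1e-12, np.inf),
            maxfev=20000,
        )
        for _ in range(2):
            sigma = np.sqrt(np.clip(model(t, *popt), 1e-9, None))
            popt, _ = curve_fit(
                model,
                t,
                counts,
                p0=popt,
                sigma=sigma,
                absolute_sigma=True,
                bounds=(1e-12, np.inf),
                maxfev=20000,
            )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"fit-error: {exc}") from exc
    a1, tau1, a2, tau2 = popt
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    sigma = np.sqrt(np.clip(model(t, *popt), 1.0, None))
    resid = (model(t, *popt) - counts) / sigma
    dof = max(t.size - 4, 1)
    goodness = float(np.sum(resid**2) / dof)
    degenerate = (tau2 - tau1) / tau2 < 0.01
    return BiExpFit(
        tau_short_ns=float(tau1),
        tau_long_ns=float(tau2),
        a_short=float(a1),
        a_long=float(a2),
        goodness=goodness,
        degenerate=degenerate,
    )


def region_mean_lifetime(lifetime_image_ns: np.ndarray, mask: np.ndarray) -> float:
    """Mean long lifetime over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("region-error: empty mask")
    return float(np.mean(np.asarray(lifetime_image_ns, dtype=float)[mask]))


def fit_image(
    t_edges_ns: np.ndarray,
    counts_stack: np.ndarray,
    mask: np.ndarray | None = None,
    pool_region: bool = False,
) -> np.ndarray | BiExpFit:
    """Fit per-pixel decays of a (ny, nx, n_bins) stack.

    With ``pool_region=True`` the masked decays are summed and a single
    pooled fit is returned instead of a lifetime image.
    """
    counts_stack = np.asarray(counts_stack)
    ny, nx, _ = counts_stack.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    if pool_region:
        pooled = counts_stack[mask].sum(axis=0)
        return biexp_fit(DecayHistogram(t_edges_ns, pooled))
    out = np.full((ny, nx), np.nan)
    for iy in range(ny):
        for ix in range(nx):
            if not mask[iy, ix]:
                continue
            out[iy, ix] = biexp_fit(
                DecayHistogram(t_edges_ns, counts_stack[iy, ix])
            ).tau_long_ns
    return out


def lifetime_length_correlation(
    tau_long_ns: np.ndarray, length_um: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation between per-cell long lifetime and leading
    process length (delegates to :func:`neuromech.stats_glue.spearman`)."""
    from .stats_glue import spearman

    return spearman(tau_long_ns, length_um)


def read_decay_csv(path) -> DecayHistogram:
    """CSV with columns ``bin_start_ns, counts`` (uniform bin width)."""
    df = pd.read_csv(path)
    starts = df["bin_start_ns"].to_numpy(dtype=float)
    width = starts[1] - starts[0] if starts.size > 1 else 1.0
    edges = np.append(starts, starts[-1] + width)
    return DecayHistogram(edges, df["counts"].to_numpy())


def write_decay_csv(hist: DecayHistogram, path) -> None:
    pd.DataFrame(
        {"bin_start_ns": hist.t_edges_ns[:-1], "counts": hist.counts}
    ).to_csv(path, index=False)
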