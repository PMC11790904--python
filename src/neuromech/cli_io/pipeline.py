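"""End-to-end pipeline: simulate cohorts, run every analysis stage and emit
a structured report (CSV tables plus a JSON summary)."""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .. import ca_transients, cohort_sim, migration, polarity_quant, stats_glue
from ..errors import NeuromechError
from .config import RunConfig, cohort_params_from_config

log = logging.getLogger("neuromech.pipeline")

TABLE_NAMES = (
    "tension_length",
    "ca_frequency_bins",
    "stretch_response",
    "migration_metrics",
    "myosin_polarity",
)


def _detect(record: cohort_sim.CellRecord, cfg: dict):
    trace = ca_transients.CalciumTrace(record.t_s, record.f525, record.f650)
    events = ca_transients.detect_transients(
        trace.norm,
        threshold=cfg["threshold"],
        min_separation_s=cfg["min_separation_s"],
        frame_interval_s=record.params.frame_interval_s,
    )
    return trace, events


def _track(record: cohort_sim.CellRecord) -> migration.CellTrack:
    stride = max(
        1,
        int(round(record.params.track_interval_min * 60.0 / record.params.frame_interval_s)),
    )
    return migration.CellTrack(
        record.track_t_min, record.soma_xy_um, length_um=record.length_um[::stride]
    )


def _freq_window(record, cfg, t_lo_s, t_hi_s) -> float:
    sel = (record.t_s >= t_lo_s) & (record.t_s < t_hi_s)
    trace = ca_transients.CalciumTrace(record.t_s[sel], record.f525[sel], record.f650[sel])
    events = ca_transients.detect_transients(
        trace.norm,
        threshold=cfg["threshold"],
        min_separation_s=cfg["min_separation_s"],
        frame_interval_s=record.params.frame_interval_s,
    )
    return ca_transients.transient_frequency(events, (t_hi_s - t_lo_s) / 60.0)


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Simulate WT/knockdown/stretch arms and run all analyses.

    Returns a dict with the five analysis tables and the JSON-ready
    summary; when ``out_dir`` is given everything is also written to disk.
    Any failure aborts with the offending stage name.
    """
    seed = config.data["seed"]
    ca_cfg = config.data["ca"]
    eps_um = config.data["migration"]["eps_um"]
    summary: dict = {"seed": seed}
    tables: dict[str, pd.DataFrame] = {}

    stage = "simulate-cohorts"
    try:
        log.info("simulating cohorts (seed=%s)", seed)
        wt_params = cohort_params_from_config(config, seed=seed)
        kd_params = replace(
            wt_params, knockdown=config.data["pipeline"]["kd_knockdown"], seed=seed + 1
        )
        wt = cohort_sim.simulate_cohort(wt_params)
        kd = cohort_sim.simulate_cohort(kd_params)

        st_cfg = config.data["stretch"]
        base_stretch = replace(
            wt_params,
            n_cells=st_cfg["n_cells"],
            duration_min=st_cfg["duration_min"],
            stretch_onset_min=st_cfg["onset_min"],
            seed=seed + 2,
        )
        unstretched = cohort_sim.simulate_cohort(base_stretch)
        parallel = [
            cohort_sim.apply_stretch(r, st_cfg["strain"], "parallel") for r in unstretched
        ]
        perpendicular = [
            cohort_sim.apply_stretch(r, st_cfg["strain"], "perpendicular")
            for r in unstretched
        ]

        stage = "tension-length"
        n_tension = config.data["pipeline"]["n_tension_cells"]
        tension_cohort = cohort_sim.simulate_cohort(
            replace(wt_params, n_cells=n_tension, seed=seed + 3)
        )
        df = pd.DataFrame(
            [
                {
                    "cell": k,
                    "mean_length_um": float(np.mean(r.length_um)),
                    "mean_tension_ns": float(np.mean(r.tension_ns)),
                }
                for k, r in enumerate(tension_cohort)
            ]
        )
        rho, p = stats_glue.spearman(df["mean_tension_ns"], df["mean_length_um"])
        tables["tension_length"] = df
        summary["tension_length"] = {"spearman_rho": rho, "p": p, "n_cells": n_tension}

        stage = "ca-frequency-bins"
        minutes = np.zeros(4)
        n_events = np.zeros(4, dtype=int)
        for r in wt:
            _, events = _detect(r, ca_cfg)
            binned = ca_transients.frequency_by_length_bin(
                r.length_um, events, frame_interval_s=r.params.frame_interval_s
            )
            minutes += binned["minutes"].to_numpy()
            n_events += binned["n_events"].to_numpy()
        freq = np.where(
            minutes > 0, n_events / np.where(minutes > 0, minutes, 1.0), np.nan
        )
        tables["ca_frequency_bins"] = pd.DataFrame(
            {
                "bin": list(ca_transients.BIN_LABELS),
                "n_events": n_events,
                "minutes": minutes,
                "freq_per_min": freq,
            }
        )
        summary["ca_frequency_bins"] = {
            label: (None if not np.isfinite(f) else float(f))
            for label, f in zip(ca_transients.BIN_LABELS, freq)
        }

        stage = "stretch-response"
        onset_s = st_cfg["onset_min"] * 60.0
        end_s = st_cfg["duration_min"] * 60.0
        rows = []
        stretch_stats = {}
        for label, cells in (("parallel", parallel), ("perpendicular", perpendicular)):
            pre = [_freq_window(r, ca_cfg, 0.0, onset_s) for r in cells]
            post = [_freq_window(r, ca_cfg, onset_s, end_s) for r in cells]
            for k, (f0, f1) in enumerate(zip(pre, post)):
                rows.append(
                    {
                        "orientation": label,
                        "cell": k,
                        "freq_pre_per_min": f0,
                        "freq_post_per_min": f1,
                    }
                )
            res = stats_glue.compare_two(np.asarray(post), np.asarray(pre), paired=True)
            stretch_stats[label] = {
                "test": res.test_name,
                "p": res.p_two_tailed,
                "mean_pre": float(np.mean(pre)),
                "mean_post": float(np.mean(post)),
            }
        tables["stretch_response"] = pd.DataFrame(rows)
        summary["stretch_response"] = stretch_stats

        stage = "migration-metrics"
        rows = []
        for label, cells in (("wt", wt), ("kd", kd)):
            for k, r in enumerate(cells):
                m = migration.migration_metrics(_track(r), eps_um=eps_um)
                rows.append(
                    {
                        "arm": label,
                        "cell": k,
                        "migration_speed_um_per_min": m.migration_speed_um_per_min,
                        "translocation_speed_um_per_min": m.translocation_speed_um_per_min,
                        "translocation_fraction": m.translocation_fraction,
                        "mean_length_um": float(np.mean(r.length_um)),
                    }
                )
        mdf = pd.DataFrame(rows)
        tables["migration_metrics"] = mdf
        mig_stats = {}
        for col in (
            "migration_speed_um_per_min",
            "translocation_speed_um_per_min",
            "mean_length_um",
        ):
            a = mdf.loc[mdf["arm"] == "wt", col].dropna().to_numpy()
            b = mdf.loc[mdf["arm"] == "kd", col].dropna().to_numpy()
            res = stats_glue.compare_two(a, b)
            mig_stats[col] = {
                "test": res.test_name,
                "p": res.p_two_tailed,
                "wt_mean": float(np.mean(a)),
                "kd_mean": float(np.mean(b)),
            }
        summary["migration"] = mig_stats

        stage = "myosin-polarity"
        rows = []
        ratios: dict[str, list[float]] = {"parallel": [], "perpendicular": []}
        for label, cells in (("parallel", parallel), ("perpendicular", perpendicular)):
            for k, r in enumerate(cells):
                activity = cohort_sim.mean_rear_activity(r, start_min=st_cfg["onset_min"])
                pmlc, mlc, ps = cohort_sim.render_soma_images(activity, seed=seed + 100 + k)
                ratio = polarity_quant.rear_myosin_ratio(pmlc, mlc, ps)
                ratios[label].append(ratio)
                rows.append(
                    {"orientation": label, "cell": k, "rear_pmlc_mlc_ratio": ratio}
                )
        tables["myosin_polarity"] = pd.DataFrame(rows)
        res = stats_glue.compare_two(
            np.asarray(ratios["parallel"]), np.asarray(ratios["perpendicular"])
        )
        summary["myosin_polarity"] = {
            "test": res.test_name,
            "p": res.p_two_tailed,
            "parallel_mean": float(np.mean(ratios["parallel"])),
            "perpendicular_mean": float(np.mean(ratios["perpendicular"])),
        }

        if out_dir is not None:
            stage = "write-report"
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name in TABLE_NAMES:
                tables[name].to_csv(
                    out / f"{name}.csv", index=False, float_format="%.8g"
                )
            with open(out / "summary.json", "w") as f:
                json.dump(summary, f, indent=2, sort_keys=True)
    except Exception as exc:
        raise NeuromechError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {"tables": tables, "summary": summary}
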