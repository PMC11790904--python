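# neuromech

Quantitative pipeline for studying how leading-process extension drives
somal translocation in migrating neurons. The package couples a set of
analysis modules — SICM stiffness mapping, FLIM lifetime fitting,
ratiometric Ca²⁺ transient detection, migration-track metrics, and
rear-of-soma myosin quantification — to a synthetic-data generator that
implements the integrated mechanochemical feedback loop
(extension → membrane tension → mechanosensitive Ca²⁺ influx → rear
actomyosin → somal step), so that every analysis stage can be exercised
against known ground truth.

## Modules

| Module | Purpose |
| --- | --- |
| `neuromech.sicm_sim` | Forward simulator of hopping-mode SICM approach curves over phantom neurons with known Young's-modulus fields |
| `neuromech.sicm_fit` | Inverse SICM analysis: reference current, set-point topography, 98.5–99% window-slope fit, Young's modulus `E = p0·A·(s∞/s − 1)⁻¹`, stiffness maps, ROI Δstiffness series |
| `neuromech.flim_fit` | Bi-exponential decay fitting (no cutoff, no IRF); the long lifetime is the membrane-tension proxy |
| `neuromech.ca_transients` | 525/650 ratio, F/F₀ normalization, transient detection at the 40%-over-baseline threshold, length-deviation binning |
| `neuromech.migration` | Leading-process length, somal-translocation phase (2-min intervals, ε = 0.2 µm), migration/translocation speeds, stretch-orientation classes |
| `neuromech.polarity_quant` | Posterior-half soma mask and pMLC/MLC myosin-activity ratio |
| `neuromech.cohort_sim` | Integrated generative model: mean-reverting length dynamics, affine tension, length-gated transient rate (+4 µm gate), transient-triggered somal steps; wild-type, knockdown and 20%-stretch variants |
| `neuromech.stats_glue` | Normality-gated test selection (Student/Welch/Mann–Whitney, paired t/Wilcoxon, ANOVA+Tukey / Kruskal–Wallis+Dunn) and permutation-exact Spearman |
| `neuromech.cli_io` | YAML configuration, end-to-end pipeline, CLI |

## Command line

```bash
neuromech simulate-sicm --config cfg.yaml --out scan.h5
neuromech analyze-sicm scan.h5 --roi roi.yaml --out maps/
neuromech flim-fit decays.csv --out lifetimes.csv
neuromech detect-transients trace.csv --threshold 0.40 --out events.csv
neuromech simulate-cohort --n-cells 50 --seed 1 --out data/
neuromech migration-metrics data/ --eps 0.2 --out metrics.csv
neuromech myosin-ratio pmlc.tif mlc.tif --mask soma.tif --axis 1,0
neuromech stats compare a.csv b.csv [--paired]
neuromech run --config cfg.yaml --out report/
```

`neuromech run` simulates wild-type, knockdown and stretch cohorts and
writes five analysis tables (`tension_length`, `ca_frequency_bins`,
`stretch_response`, `migration_metrics`, `myosin_polarity`) plus a
`summary.json`; identical seeds give byte-identical outputs.

Configuration is YAML with full defaults (empty file ⇒ defaults;
unknown keys are rejected by name). Key defaults: applied pressure
10 kPa, pipette geometry factor A = 0.4, set point 0.98, slope window
(0.985, 0.99), ΔF/F₀ threshold 0.40, translocation ε = 0.2 µm,
stretch strain 0.20.

## File formats

Everything is plain text except the SICM scan container (HDF5:
`/meta`, `/z`, `/current`, `/plateau`) and optional TIFF map/image
outputs. CSV schemas use snake_case headers with unit suffixes
(`_um`, `_ns`, `_min`, `_s`); pixel coordinates are 0-based pixel
centers, row-major with the origin at the top-left.
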