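import numpy as np
import pytest
from dataclasses import replace

from neuromech import ca_transients, migration
from neuromech.cohort_sim import (
    CohortParams,
    apply_stretch,
    simulate_cell,
    simulate_cohort,
)
from neuromech.errors import ConfigError


def _detect(record):
    trace = ca_transients.CalciumTrace(record.t_s, record.f525, record.f650)
    return ca_transients.detect_transients(trace.norm)


def _track(record):
    return migration.CellTrack(record.track_t_min, record.soma_xy_um)


class TestParams:
    def test_defaults_valid(self):
        p = CohortParams()
        assert p.mean_length_um == 39.0
        assert p.excursion_um == 11.3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"knockdown": 1.5},
            {"knockdown": -0.1},
            {"mean_length_um": -1.0},
            {"rate_base_per_min": -0.2},
            {"stretch_orientation": "diagonal"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            CohortParams(**kwargs)


class TestSimulateCell:
    def test_deterministic_same_seed(self):
        p = CohortParams()
        a = simulate_cell(p, 11)
        b = simulate_cell(p, 11)
        np.testing.assert_array_equal(a.length_um, b.length_um)
        np.testing.assert_array_equal(a.f525, b.f525)
        np.testing.assert_array_equal(a.soma_xy_um, b.soma_xy_um)
        np.testing.assert_array_equal(a.true_transient_s, b.true_transient_s)

    def test_full_knockdown(self):
        rec = simulate_cell(CohortParams(knockdown=0.0), 5)
        assert rec.true_transient_s.size == 0
        # no somal steps: net displacement is jitter only
        assert np.linalg.norm(rec.soma_xy_um[-1] - rec.soma_xy_um[0]) < 1.0
        # the process relaxes toward its upper (growth) excursion
        late = rec.length_um[-360:].mean()
        assert late > rec.baseline_um + rec.params.growth_push_um / 2.0

    def test_cohort_mean_length_matches_printed_mean(self):
        records = simulate_cohort(CohortParams(n_cells=50, seed=1))
        means = np.array([r.length_um.mean() for r in records])
        sem = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 39.0) <= 3.0 * sem

    def test_series_time_aligned(self):
        rec = simulate_cell(CohortParams(), 3)
        n = rec.t_s.size
        assert rec.length_um.size == n == rec.tension_ns.size
        assert rec.f525.size == n == rec.f650.size == rec.rear_myosin.size
        assert rec.track_t_min.size == rec.soma_xy_um.shape[0]
        assert rec.t_s[1] - rec.t_s[0] == pytest.approx(5.0)
        assert rec.track_t_min[1] - rec.track_t_min[0] == pytest.approx(2.0)

    def test_true_transients_are_supra_threshold(self):
        rec = simulate_cell(CohortParams(), 21)
        norm = ca_transients.CalciumTrace(rec.t_s, rec.f525, rec.f650).norm
        for idx in rec.true_transient_indices():
            assert norm[idx] - 1.0 > 0.40


class TestSimulateCohort:
    def test_zero_cells_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(CohortParams(n_cells=0))

    def test_master_seed_stability(self):
        p = CohortParams(n_cells=5, seed=9)
        a = simulate_cohort(p)
        b = simulate_cohort(p)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.length_um, rb.length_um)
            np.testing.assert_array_equal(ra.f525, rb.f525)

    def test_knockdown_slows_translocation(self):
        wt = simulate_cohort(CohortParams(n_cells=20, seed=2))
        kd = simulate_cohort(CohortParams(n_cells=20, seed=2, knockdown=0.2))
        wt_speed = np.nanmean(
            [migration.translocation_speed(_track(r)) for r in wt]
        )
        kd_speed = np.nanmean(
            [migration.translocation_speed(_track(r)) for r in kd]
        )
        assert kd_speed < wt_speed
        wt_mig = np.mean([migration.migration_speed(_track(r)) for r in wt])
        kd_mig = np.mean([migration.migration_speed(_track(r)) for r in kd])
        assert kd_mig < wt_mig


class TestApplyStretch:
    def test_parallel_scales_length_at_onset(self):
        p = CohortParams(duration_min=30.0)
        base = simulate_cell(p, 4)
        par = apply_stretch(base, strain=0.2, orientation="parallel", onset_min=15.0)
        onset = int(15.0 * 60 / 5)
        # identical history before onset, x1.2 jump at onset
        np.testing.assert_array_equal(par.length_um[:onset], base.length_um[:onset])
        assert par.length_um[onset] == pytest.approx(1.2 * base.length_um[onset])

    def test_l40_becomes_48(self):
        # strain 0.2 applied to a 40-um process gives 48 um
        p = CohortParams(duration_min=30.0, cell_sd_um=1e-9, excursion_um=1e-6,
                         rate_base_per_min=0.0, rate_gain_per_min=0.0,
                         mean_length_um=40.0, growth_push_um=1e-6)
        base = simulate_cell(p, 1)
        par = apply_stretch(base, 0.2, "parallel", onset_min=15.0)
        onset = int(15.0 * 60 / 5)
        assert base.length_um[onset] == pytest.approx(40.0, abs=1e-3)
        assert par.length_um[onset] == pytest.approx(48.0, abs=1e-3)

    def test_perpendicular_identical_same_seed(self):
        base = simulate_cell(CohortParams(duration_min=30.0), 8)
        perp = apply_stretch(base, 0.2, "perpendicular")
        np.testing.assert_array_equal(perp.length_um, base.length_um)
        np.testing.assert_array_equal(perp.f525, base.f525)

    def test_invalid_strain(self):
        base = simulate_cell(CohortParams(duration_min=30.0), 8)
        with pytest.raises(ConfigError):
            apply_stretch(base, 0.0, "parallel")

    def test_invalid_orientation(self):
        base = simulate_cell(CohortParams(duration_min=30.0), 8)
        with pytest.raises(ConfigError):
            apply_stretch(base, 0.2, "oblique")

    def test_parallel_cohort_paired_frequency_increase(self):
        params = CohortParams(n_cells=12, duration_min=30.0, seed=1)
        base = simulate_cohort(params)

        def freq(rec, lo_min, hi_min):
            sel = (rec.t_s >= lo_min * 60) & (rec.t_s < hi_min * 60)
            trace = ca_transients.CalciumTrace(
                rec.t_s[sel], rec.f525[sel], rec.f650[sel]
            )
            ev = ca_transients.detect_transients(trace.norm)
            return len(ev) / (hi_min - lo_min)

        par = [apply_stretch(r, 0.2, "parallel") for r in base]
        pre = np.array([freq(r, 0, 15) for r in par])
        post = np.array([freq(r, 15, 30) for r in par])
        assert post.mean() > pre.mean()


class TestDetectionLink:
    def test_recall_against_true_transients(self):
        records = simulate_cohort(CohortParams(n_cells=20, seed=1))
        n_true = 0
        n_matched = 0
        for rec in records:
            events = _detect(rec)
            detected = np.array([e.onset_index for e in events])
            for idx in rec.true_transient_indices():
                n_true += 1
                if detected.size and np.min(np.abs(detected - idx)) <= 2:
                    n_matched += 1
        assert n_true > 0
        assert n_matched / n_true >= 0.95

    def test_wt_top_bin_exceeds_bottom_bin(self):
        records = simulate_cohort(CohortParams(n_cells=20, seed=1))
        minutes = np.zeros(4)
        events = np.zeros(4)
        for rec in records:
            table = ca_transients.frequency_by_length_bin(
                rec.length_um, _detect(rec)
            )
            minutes += table["minutes"].to_numpy()
            events += table["n_events"].to_numpy()
        freq = events / minutes
        assert freq[3] > freq[0]

    def test_zero_knockdown_all_bins_empty(self):
        records = simulate_cohort(CohortParams(n_cells=10, seed=1, knockdown=0.0))
        for rec in records:
            table = ca_transients.frequency_by_length_bin(
                rec.length_um, _detect(rec)
            )
            assert table["n_events"].sum() == 0


def test_write_cell_csvs(tmp_path):
    from neuromech.cohort_sim import write_cell_csvs

    rec = simulate_cell(CohortParams(duration_min=10.0), 2)
    write_cell_csvs(rec, tmp_path, "cell000")
    trace, length = ca_transients.read_trace_csv(tmp_path / "cell000_trace.csv")
    assert trace.t_s.size == rec.t_s.size
    track = migration.read_track_csv(tmp_path / "cell000_track.csv")
    assert track.n_frames == rec.track_t_min.size
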