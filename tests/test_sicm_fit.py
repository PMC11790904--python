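import numpy as np
import pytest

from neuromech import sicm_fit, sicm_sim, stats_glue
from neuromech.errors import (
    FitError,
    InvalidSlopeError,
    NoContactError,
    RegionError,
    WindowTooSparseError,
)
from neuromech.sicm_fit import (
    reference_current,
    roi_delta_series,
    setpoint_z,
    stiffness_map,
    window_slope,
    youngs_modulus,
)
from neuromech.sicm_sim import make_phantom, simulate_scan, synth_approach_curve


def _flat_curve(plateau_value=100.0, n=50):
    z = np.linspace(1000.0, 0.0, n)
    current = np.full(n, plateau_value)
    return sicm_sim.ApproachCurve(z, current, (0, 10))


class TestReferenceCurrent:
    def test_constant_plateau(self):
        assert reference_current(_flat_curve(100.0)) == pytest.approx(100.0)

    def test_noisy_plateau_within_3_sigma(self, rng):
        n_plateau = 400
        z = np.linspace(5000.0, 0.0, 1000)
        current = np.full(1000, 250.0)
        noise = 5.0 * rng.standard_normal(1000)
        curve = sicm_sim.ApproachCurve(z, current + noise, (0, n_plateau))
        est = reference_current(curve)
        assert abs(est - 250.0) <= 3.0 * 5.0 / np.sqrt(n_plateau)

    def test_missing_plateau(self):
        curve = _flat_curve()
        curve.plateau_range = (10, 10)  # degrade after construction
        with pytest.raises(FitError):
            reference_current(curve)


class TestSetpointZ:
    def test_generator_ground_truth(self, pipette):
        curve = synth_approach_curve(3.0, pipette, surface_z_nm=500.0)
        i_ref = reference_current(curve)
        assert setpoint_z(curve, i_ref, 0.98) == pytest.approx(500.0, abs=1e-9)

    def test_unique_crossing_on_monotone_curve(self, pipette):
        curve = synth_approach_curve(3.0, pipette)
        i_ref = reference_current(curve)
        z1 = setpoint_z(curve, i_ref, 0.98)
        norm = curve.current_pa / i_ref
        below = curve.z_nm[norm <= 0.98]
        assert np.all(below <= z1 + 1e-9)

    def test_no_contact(self, pipette):
        s = sicm_sim.slope_from_modulus(3.0, pipette)
        z_contact = (1 - pipette.setpoint_fraction) / s
        # truncate well above the set-point crossing
        z = np.linspace(z_contact + 400.0, z_contact + 10.0, 60)
        curve = synth_approach_curve(3.0, pipette, z_grid_nm=z)
        with pytest.raises(NoContactError):
            setpoint_z(curve, reference_current(curve), 0.98)


class TestWindowSlope:
    def test_round_trip_half_slope(self, pipette):
        curve = synth_approach_curve(4.0, pipette)
        i_ref = reference_current(curve)
        s, n = window_slope(curve, i_ref)
        assert n >= 2
        assert s == pytest.approx(pipette.substrate_slope_per_nm / 2, rel=1e-6)

    def test_rigid_curve(self, pipette):
        curve = synth_approach_curve(np.inf, pipette, rigid=True)
        s, _ = window_slope(curve, reference_current(curve))
        assert s == pytest.approx(pipette.substrate_slope_per_nm, rel=1e-9)

    def test_sparse_window_raises(self, pipette):
        s = sicm_sim.slope_from_modulus(4.0, pipette)
        z_contact = (1 - pipette.setpoint_fraction) / s
        z_mid = z_contact - 0.0125 / s  # one sample inside [0.985, 0.99]
        z = np.concatenate(
            [np.linspace(z_contact + 300, z_contact + 50, 10), [z_mid, z_mid - 0.01 / s]]
        )
        curve = synth_approach_curve(4.0, pipette, z_grid_nm=z)
        with pytest.raises(WindowTooSparseError):
            window_slope(curve, reference_current(curve))


class TestYoungsModulus:
    def test_half_slope(self):
        assert youngs_modulus(5e-4, 1e-3) == pytest.approx(4.0)

    def test_quarter_slope(self):
        assert youngs_modulus(2.5e-4, 1e-3) == pytest.approx(4.0 / 3.0)

    def test_rigid_flag(self):
        assert np.isinf(youngs_modulus(1e-3, 1e-3))

    @pytest.mark.parametrize("s", [0.0, -1e-4, 2e-3])
    def test_invalid_slope(self, s):
        with pytest.raises(InvalidSlopeError):
            youngs_modulus(s, 1e-3)

    def test_monotone_in_slope(self):
        slopes = np.linspace(1e-5, 9.9e-4, 50)
        es = [youngs_modulus(s, 1e-3) for s in slopes]
        assert np.all(np.diff(es) > 0)


class TestStiffnessMap:
    def test_noise_free_recovery(self, pipette, small_phantom):
        grid = simulate_scan(small_phantom, pipette, n_dense=301)
        smap = stiffness_map(grid, substrate_mask=small_phantom.labels == 0)
        cell = small_phantom.labels != 0
        np.testing.assert_allclose(
            smap.modulus_kpa[cell], small_phantom.modulus_kpa[cell], rtol=1e-6
        )
        np.testing.assert_allclose(
            smap.topography_um, small_phantom.topography_um, atol=1e-9
        )
        assert smap.valid_mask[cell].all()

    def test_all_substrate_grid(self, pipette):
        ph = make_phantom(8, 8, 10.0, soma_axes_um=(2, 2), process_length_um=0.0)
        ph.labels[:] = 0
        ph.modulus_kpa[:] = np.inf
        ph.topography_um[:] = 0.0
        grid = simulate_scan(ph, pipette, n_dense=101)
        smap = stiffness_map(grid, substrate_mask=np.ones((8, 8), dtype=bool))
        assert not smap.valid_mask.any()
        assert smap.substrate_mask.all()

    def test_map_shape_ny_nx(self, pipette):
        ph = make_phantom(12, 8, 12.0, soma_axes_um=(3, 2.5), process_length_um=2.0,
                          soma_center_um=(4.0, 6.0))
        grid = simulate_scan(ph, pipette, n_dense=101)
        smap = stiffness_map(grid, substrate_mask=ph.labels == 0)
        assert smap.modulus_kpa.shape == (8, 12)

    def test_auto_s_inf(self, pipette, small_phantom):
        grid = simulate_scan(small_phantom, pipette, n_dense=301)
        smap = stiffness_map(grid, s_inf="auto")
        assert smap.s_inf_per_nm == pytest.approx(
            pipette.substrate_slope_per_nm, rel=1e-6
        )


class TestRoiDeltaSeries:
    def _maps(self, pipette, e_values):
        maps = []
        for e in e_values:
            ph = make_phantom(
                12, 12, 6.0, soma_axes_um=(3, 2.5), process_length_um=0.0,
                soma_center_um=(3.0, 3.0), e_cell_kpa=e,
            )
            grid = simulate_scan(ph, pipette, n_dense=101)
            maps.append(stiffness_map(grid, substrate_mask=ph.labels == 0))
        return maps, ph

    def test_identical_maps_zero_deltas(self, pipette):
        maps, _ = self._maps(pipette, [3.0, 3.0, 3.0])
        roi = np.zeros((12, 12), dtype=bool)
        roi[4:8, 4:8] = True
        deltas = roi_delta_series(maps, roi)
        np.testing.assert_allclose(deltas, 0.0, atol=1e-9)

    def test_constructed_increase(self, pipette):
        maps, _ = self._maps(pipette, [3.0, 5.0])
        roi = np.zeros((12, 12), dtype=bool)
        roi[4:8, 4:8] = True
        deltas = roi_delta_series(maps, roi)
        assert deltas[1] == pytest.approx(2.0, rel=1e-6)

    def test_three_timepoints_two_retained(self, pipette):
        maps, _ = self._maps(pipette, [3.0, 4.0, 5.0])
        roi = np.zeros((12, 12), dtype=bool)
        roi[4:8, 4:8] = True
        deltas = roi_delta_series(maps, roi)
        assert deltas.size == 3 and deltas[0] == 0.0
        assert deltas[1:].size == 2  # first time point dropped downstream

    def test_roi_outside_valid(self, pipette):
        maps, _ = self._maps(pipette, [3.0, 3.0])
        roi = np.zeros((12, 12), dtype=bool)
        roi[0, 0] = True  # substrate corner
        with pytest.raises(RegionError):
            roi_delta_series(maps, roi)

    def test_polygon_roi(self, pipette):
        maps, _ = self._maps(pipette, [3.0, 4.0])
        poly = np.array([[2.0, 2.0], [4.0, 2.0], [4.0, 4.0], [2.0, 4.0]])
        deltas = roi_delta_series(maps, poly)
        assert deltas[1] == pytest.approx(1.0, rel=1e-6)


def test_stiffness_length_coupling_positive_spearman(pipette):
    """Per-cell stiffness change correlates with length change when the
    generator couples modulus to process length (two scans per cell)."""
    rng = np.random.default_rng(11)
    n_cells = 20
    d_len = rng.uniform(-8.0, 8.0, n_cells)
    d_stiff = []
    roi = np.zeros((10, 10), dtype=bool)
    roi[3:7, 3:7] = True
    for dl in d_len:
        e0 = 3.0
        e1 = float(np.clip(e0 + 0.25 * dl + 0.1 * rng.standard_normal(), 0.5, None))
        maps = []
        for e in (e0, e1):
            ph = make_phantom(
                10, 10, 5.0, soma_axes_um=(2.5, 2.0), process_length_um=0.0,
                soma_center_um=(2.5, 2.5), e_cell_kpa=e,
            )
            grid = simulate_scan(ph, pipette, n_dense=101)
            maps.append(stiffness_map(grid, substrate_mask=ph.labels == 0))
        d_stiff.append(roi_delta_series(maps, roi)[1])
    rho, p = stats_glue.spearman(np.asarray(d_stiff), d_len)
    assert rho > 0
    assert p < 0.05
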