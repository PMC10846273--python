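"""Serial-transfer frequency dynamics and (alpha, C) calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import privgood as pg
from privgood.dynamics import (
    FrequencyTrajectory,
    assay_transfer_indices,
    binomial_weights,
    calibrate,
)

from conftest import random_interior_params


class TestGenerationsPerTransfer:
    @pytest.mark.parametrize(
        "dilution, expected",
        [(100, math.log2(100)), (2, 1.0), (1024, 10.0)],
    )
    def test_log2_of_dilution(self, dilution, expected):
        assert pg.generations_per_transfer(dilution) == pytest.approx(expected)

    def test_daily_1_in_100_is_about_six_point_seven(self):
        # the canonical '~6.7 generations per day' of a 1:100 regime
        assert pg.generations_per_transfer(100) == pytest.approx(6.7, abs=0.1)

    def test_no_dilution_rejected(self):
        with pytest.raises(ValueError):
            pg.generations_per_transfer(1.0)


class TestTransferRegime:
    def test_derived_quantities(self, regime):
        assert regime.generations_per_transfer == pytest.approx(6.6439, abs=1e-4)
        assert regime.total_generations == pytest.approx(30 * math.log2(100))

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            pg.TransferRegime(dilution_factor=1.0)
        with pytest.raises(ValueError):
            pg.TransferRegime(n_transfers=0)


class TestStepFrequency:
    def test_neutral_composition_is_stationary(self):
        p = pg.ModelParams(alpha=0.0, C=0.0)
        for x in [0.1, 0.5, 0.9]:
            assert pg.step_frequency(p, x, 6.64) == pytest.approx(x, abs=1e-15)

    def test_boundaries_absorbing(self, interior_params):
        assert pg.step_frequency(interior_params, 0.0, 6.64) == 0.0
        assert pg.step_frequency(interior_params, 1.0, 6.64) == 1.0

    def test_invalid_inputs_rejected(self, interior_params):
        with pytest.raises(ValueError):
            pg.step_frequency(interior_params, 1.2, 6.64)
        with pytest.raises(ValueError):
            pg.step_frequency(interior_params, 0.5, 0.0)

    @given(x=st.floats(0.001, 0.999), dt=st.floats(0.1, 20.0))
    def test_log_odds_oracle(self, x, dt):
        """Independent oracle: the log-odds advance by (fco - fch) * dt."""
        p = pg.ModelParams(fmax=1.0, Km=1.0, C=0.1, r=1.0, alpha=0.2)
        x1 = pg.step_frequency(p, x, dt)
        lhs = math.log(x1 / (1 - x1))
        rhs = math.log(x / (1 - x)) + pg.fitness_gap(p, x) * dt
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestSimulate:
    def test_neutral_trajectory_constant(self, regime):
        traj = pg.simulate_serial_transfers(pg.ModelParams(alpha=0.0, C=0.0), regime, 0.5)
        assert np.all(traj.x == 0.5)
        assert traj.generations[0] == 0.0
        assert len(traj.x) == regime.n_transfers + 1

    def test_costless_privatization_sweeps(self, regime):
        traj = pg.simulate_serial_transfers(pg.ModelParams(alpha=0.2, C=0.0), regime, 0.5)
        assert np.all(np.diff(traj.x) > 0)
        assert traj.x[-1] > 0.99

    def test_frequencies_stay_in_unit_interval(self, regime):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_interior_params(rng)
            traj = pg.simulate_serial_transfers(p, regime, float(rng.uniform(0, 1)))
            assert np.all((traj.x >= 0) & (traj.x <= 1))

    def test_converges_to_interior_equilibrium(self, interior_params):
        """The solver's x* is the attracting fixed point of the map."""
        x_star = pg.solve_coexistence(interior_params).x_star
        long_regime = pg.TransferRegime(n_transfers=600)
        for x0 in (0.1, 0.5, 0.9):
            traj = pg.simulate_serial_transfers(interior_params, long_regime, x0)
            # monotone approach from either side
            diffs = np.diff(traj.x)
            assert np.all(diffs >= 0) or np.all(diffs <= 0)
            assert traj.x[-1] == pytest.approx(x_star, abs=1e-6)

    def test_interior_equilibrium_is_fixed_point(self, interior_params):
        x_star = pg.solve_coexistence(interior_params, tol=1e-14).x_star
        stepped = pg.step_frequency(interior_params, x_star, 6.64)
        assert abs(stepped - x_star) < 1e-12

    def test_finite_bottleneck_requires_rng(self, interior_params, regime):
        with pytest.raises(ValueError):
            pg.simulate_serial_transfers(interior_params, regime, 0.5, bottleneck_cells=10000)
        rng = np.random.default_rng(0)
        traj = pg.simulate_serial_transfers(
            interior_params, regime, 0.5, bottleneck_cells=10000, rng=rng
        )
        assert np.all((traj.x >= 0) & (traj.x <= 1))


class TestAssaySchedule:
    def test_includes_start_and_final_assay(self, regime):
        idx = assay_transfer_indices(regime)
        # nominal assays at 0, 50, 100, 150, 200 generations
        np.testing.assert_array_equal(idx, [0, 8, 15, 23, 30])

    def test_assay_generations_near_nominal(self, regime):
        idx = assay_transfer_indices(regime)
        gens = idx * regime.generations_per_transfer
        nominal = np.arange(len(idx)) * 50.0
        assert np.all(np.abs(gens - nominal) <= regime.generations_per_transfer / 2 + 1e-9)


class TestCalibrate:
    def _observe(self, params, regime, x0=0.5):
        traj = pg.simulate_serial_transfers(params, regime, x0)
        idx = assay_transfer_indices(regime)
        return FrequencyTrajectory(traj.generations[idx], traj.x[idx])

    def test_noise_free_joint_recovery(self, regime):
        truth = pg.ModelParams(fmax=1.0, Km=1.0, C=0.08, r=1.0, alpha=0.3)
        fit = calibrate(self._observe(truth, regime), regime)
        assert fit.converged and fit.identifiable
        assert fit.alpha == pytest.approx(0.3, abs=1e-3)
        assert fit.C == pytest.approx(0.08, abs=1e-3)
        assert fit.objective < 1e-12

    def test_flat_trajectory_flagged_non_identifiable(self, regime):
        obs = FrequencyTrajectory(np.array([0.0, 50.0, 100.0]), np.full(3, 0.5))
        fit = calibrate(obs, regime)
        assert not fit.identifiable
        assert not fit.converged

    def test_fixed_cost_recovery(self, regime):
        truth = pg.ModelParams(fmax=1.0, Km=2.0, C=0.08, r=1.0, alpha=0.3)
        fit = calibrate(self._observe(truth, regime), regime, Km=2.0, fix_C=0.08)
        assert fit.C == 0.08
        assert fit.alpha == pytest.approx(0.3, abs=1e-4)

    def test_too_short_trajectory_rejected(self, regime):
        with pytest.raises(ValueError):
            calibrate(FrequencyTrajectory(np.array([0.0]), np.array([0.5])), regime)

    def test_binomial_weights_shape_and_floor(self):
        w = binomial_weights(np.array([0.0, 0.5, 1.0]), 200.0)
        assert w.shape == (3,)
        assert np.all(np.isfinite(w)) and np.all(w > 0)
        # boundary weight capped by the variance floor, not infinite
        assert w[0] == pytest.approx(4 * 200.0**2)


class TestTrajectoryValidation:
    def test_bad_trajectories_rejected(self):
        with pytest.raises(ValueError):
            FrequencyTrajectory(np.array([0.0, 1.0]), np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            FrequencyTrajectory(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            FrequencyTrajectory(np.array([0.0, 0.0]), np.array([0.5, 0.5]))
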