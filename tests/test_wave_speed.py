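"""Speed index functions, the wave-speed solver and its parameter scans."""

import numpy as np
import pytest

import neuralfront as nf
from neuralfront.wave_speed import NoFrontSpeedError

from conftest import (
    phi1_exponential,
    phi21_exponential,
    phi22_exponential,
    wave_speed_exponential_beta0,
)

K_EXP = nf.make_difference_of_exponentials_kernel(1.0, 0.0)
W_EXP = nf.make_single_exponential_kernel(1.0)


class TestSpeedIndexFunctions:
    def test_phi1_single_speed_value(self):
        xi = nf.single_atom_distribution(5.0)
        assert nf.phi1(1.0, K_EXP, 1.0, xi) == pytest.approx(2.5 / 9.0, abs=1e-10)

    def test_phi21_phi22_single_delay_values(self):
        eta = nf.single_atom_distribution(0.1)
        assert nf.phi21(1.0, W_EXP, 1.0, eta) == pytest.approx(
            0.5 * (1 - np.exp(-0.1)), abs=1e-10)
        assert nf.phi22(1.0, W_EXP, 1.0, eta) == pytest.approx(
            np.exp(-0.1) / 4.0, abs=1e-10)

    def test_closed_form_agreement_on_mu_grid(self):
        # quadrature vs antiderivative oracles to 1e-9 over 50 points
        xi = [(5.0, 0.5), (10.0, 0.5)]
        eta = [(0.1, 0.5), (0.2, 0.5)]
        xi_d = nf.make_two_point_distribution(5.0, 10.0)
        eta_d = nf.make_two_point_distribution(0.1, 0.2)
        for mu in np.linspace(0.05, 4.9, 50):
            assert nf.phi1(mu, K_EXP, 1.0, xi_d) == pytest.approx(
                phi1_exponential(mu, 1.0, xi), abs=1e-9)
            assert nf.phi21(mu, W_EXP, 0.1, eta_d) == pytest.approx(
                phi21_exponential(mu, 0.1, eta), abs=1e-9)
            assert nf.phi22(mu, W_EXP, 0.1, eta_d) == pytest.approx(
                phi22_exponential(mu, 0.1, eta), abs=1e-9)

    def test_phi_vanishes_as_mu_to_zero(self, class_a_setup):
        val = nf.phi_total(1e-6, **class_a_setup)
        assert abs(val) < 1e-4

    def test_phi1_limit_at_c0(self):
        # single speed, exponential kernel: phi1 -> alpha/2 as mu -> c0
        xi = nf.single_atom_distribution(5.0)
        val = nf.phi1(5.0 * (1 - 1e-10), K_EXP, 1.0, xi)
        assert val == pytest.approx(phi1_exponential(5.0 * (1 - 1e-10), 1.0,
                                                     [(5.0, 1.0)]), abs=1e-9)
        assert val == pytest.approx(0.5, abs=1e-6)

    def test_mu_outside_domain_rejected(self):
        xi = nf.single_atom_distribution(5.0)
        with pytest.raises(ValueError):
            nf.phi1(5.0, K_EXP, 1.0, xi)
        with pytest.raises(ValueError):
            nf.phi21(-0.1, W_EXP, 1.0, nf.single_atom_distribution(1.0))


class TestWaveSpeedSolver:
    def test_exponential_kernel_closed_form_root(self):
        params = nf.ModelParameters(alpha=1.0, beta=0.0, theta=0.3)
        xi = nf.single_atom_distribution(5.0)
        eta = nf.single_atom_distribution(1.0)
        sol = nf.solve_wave_speed(K_EXP, W_EXP, params, xi, eta)
        assert sol.mu0 == pytest.approx(
            wave_speed_exponential_beta0(1.0, 0.3, 5.0), abs=1e-9)
        assert sol.mu0 == pytest.approx(0.58824, abs=1e-5)
        assert sol.residual < 1e-10
        assert not sol.multiple_roots

    def test_infinite_speed_limit(self):
        # c0 -> inf: mu0 -> (alpha - 2 theta)/(2 theta)
        params = nf.ModelParameters(alpha=1.0, beta=0.0, theta=0.3)
        xi = nf.single_atom_distribution(1e6)
        eta = nf.single_atom_distribution(1.0)
        sol = nf.solve_wave_speed(K_EXP, W_EXP, params, xi, eta)
        assert sol.mu0 == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_speed_vanishes_at_threshold_balance(self):
        # theta -> (alpha+beta)/2: right side of the speed equation -> 0
        params = nf.ModelParameters(alpha=1.0, beta=0.0, theta=0.5 - 1e-7)
        xi = nf.single_atom_distribution(5.0)
        eta = nf.single_atom_distribution(1.0)
        sol = nf.solve_wave_speed(K_EXP, W_EXP, params, xi, eta)
        assert 0.0 < sol.mu0 < 1e-5

    def test_no_front_for_standing_balance(self):
        params = nf.ModelParameters(alpha=1.0, beta=0.0, theta=0.5)
        with pytest.raises(NoFrontSpeedError):
            nf.solve_wave_speed(K_EXP, W_EXP, params,
                                nf.single_atom_distribution(5.0),
                                nf.single_atom_distribution(1.0))

    def test_class_configurations_solve(self, class_a_setup, class_b_setup,
                                         class_c_setup):
        for setup in (class_a_setup, class_b_setup, class_c_setup):
            sol = nf.solve_wave_speed(**setup)
            assert 0.0 < sol.mu0 < setup["xi"].min_support
            assert sol.residual < 1e-10

    def test_local_monotonicity_at_root(self, class_a_setup):
        sol = nf.solve_wave_speed(**class_a_setup)
        h = 1e-6
        up = nf.phi_total(sol.mu0 + h, **class_a_setup)
        dn = nf.phi_total(sol.mu0 - h, **class_a_setup)
        assert (up - dn) / (2 * h) > 0


class TestMonotonicityScan:
    def test_class_a_all_derivatives_positive(self, class_a_setup):
        grid = np.linspace(0.2, 4.5, 25)
        scan = nf.monotonicity_scan(**class_a_setup, mu_grid=grid)
        assert scan.phi1_all_positive
        assert scan.phi2_all_positive
        assert scan.phi1_turning_point is None

    def test_class_c_phi1_derivative_changes_sign_once(self, class_c_setup):
        grid = np.linspace(0.005, 4.5, 80)
        scan = nf.monotonicity_scan(**class_c_setup, mu_grid=grid)
        assert not scan.phi1_all_positive
        assert scan.phi1_turning_point is not None
        # negative then positive: one flip only
        signs = np.sign(scan.dphi1)
        flips = np.nonzero(np.diff(signs) != 0)[0]
        assert len(flips) == 1
        assert signs[0] < 0 and signs[-1] > 0

    def test_phi21_nondecreasing_for_excitatory_feedback(self, class_a_setup):
        W, beta, eta = class_a_setup["W"], 0.1, class_a_setup["eta"]
        grid = np.linspace(0.1, 4.5, 20)
        vals = [nf.phi21(m, W, beta, eta) for m in grid]
        assert np.all(np.diff(vals) >= 0)


class TestSensitivityScans:
    def test_speed_increases_with_transmission_speed(self, class_a_setup):
        curve = nf.speed_sensitivity_scan(
            class_a_setup["K"], class_a_setup["W"], class_a_setup["params"],
            class_a_setup["xi"], class_a_setup["eta"],
            "c0", np.linspace(2.0, 9.0, 8), kappa=2.0)
        assert curve.solvable.all()
        assert np.all(np.diff(curve.mu0) > 0)

    def test_speed_decreases_with_feedback_delay(self, class_a_setup):
        curve = nf.speed_sensitivity_scan(
            class_a_setup["K"], class_a_setup["W"], class_a_setup["params"],
            class_a_setup["xi"], class_a_setup["eta"],
            "tau0", np.linspace(0.05, 1.0, 8), kappa=2.0)
        assert curve.solvable.all()
        assert np.all(np.diff(curve.mu0) < 0)

    def test_unsolvable_points_recorded_not_raised(self):
        params = nf.ModelParameters(alpha=1.0, beta=0.0, theta=0.49)
        curve = nf.speed_sensitivity_scan(
            K_EXP, W_EXP, params, nf.single_atom_distribution(5.0),
            nf.single_atom_distribution(1.0), "c0",
            [0.001, 5.0], kappa=2.0)
        assert curve.solvable[1]
        assert np.isnan(curve.mu0[~curve.solvable]).all()


class TestFeedbackIntracorticalLimit:
    def test_residual_decreases_toward_limit(self):
        r1 = nf.verify_feedback_intracortical_limit(K_EXP, 1.0, 0.5, 1e4, 1e-4)
        r2 = nf.verify_feedback_intracortical_limit(K_EXP, 1.0, 0.5, 1e6, 1e-6)
        assert r1 < 1e-3
        assert r2 < 1e-5
        assert r2 < r1

    def test_common_limit_value(self):
        # both sides tend to weight/2 * mu/(1+mu) for the unit exponential kernel
        mu = 0.5
        xi = nf.single_atom_distribution(1e8)
        limit = mu / (2.0 * (1.0 + mu))
        assert nf.phi1(mu, K_EXP, 1.0, xi) == pytest.approx(limit, rel=1e-6)


def test_speed_curve_csv_round_trip(tmp_path, class_a_setup):
    from neuralfront.wave_speed import write_speed_curve_csv
    curve = nf.speed_sensitivity_scan(
        class_a_setup["K"], class_a_setup["W"], class_a_setup["params"],
        class_a_setup["xi"], class_a_setup["eta"], "c0", [3.0, 6.0], kappa=2.0)
    path = tmp_path / "curve.csv"
    write_speed_curve_csv(curve, path)
    body = np.genfromtxt(path, delimiter=",", skip_header=2)
    np.testing.assert_allclose(body[:, 1], curve.mu0)
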