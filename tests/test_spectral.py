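"""Evans functions, zero counting and the standing-front characteristic equation."""

import numpy as np
import pytest

import neuralfront as nf
from neuralfront import spectral
from neuralfront.spectral import (
    ContourError,
    DegenerateLinearizationError,
    count_evans_zeros,
    essential_spectrum,
    evans,
    evans_derivative_at_zero,
    find_standing_real_root,
    scan_standing_complex_roots,
    standing_auxiliary_f,
    standing_characteristic,
)

from conftest import evans_beta0_exponential, evans_derivative_beta0_exponential

K_EXP = nf.make_difference_of_exponentials_kernel(1.0, 0.0)
W_EXP = nf.make_single_exponential_kernel(1.0)


@pytest.fixture(scope="module")
def beta0_front():
    params = nf.ModelParameters(alpha=1.0, beta=0.0, theta=0.3)
    return nf.solve_traveling_front(K_EXP, W_EXP, params,
                                    nf.single_atom_distribution(5.0),
                                    nf.single_atom_distribution(1.0))


class TestEvansFunction:
    def test_origin_is_always_a_zero(self, class_a_setup, class_b_setup,
                                     class_c_setup):
        # translation invariance: E(0) = 0 for every solved front
        for setup in (class_a_setup, class_b_setup, class_c_setup):
            front = nf.solve_traveling_front(**setup)
            assert abs(evans(0.0, front).E) < 1e-8

    def test_limit_at_large_lambda(self, class_a_front):
        assert evans(1e3, class_a_front).E == pytest.approx(1.0, abs=1e-2)
        ev = evans(complex(800.0, 600.0), class_a_front)
        assert abs(ev.E - 1.0) < 1e-2
        assert abs(ev.E1 - 1.0) < 1e-2 and abs(ev.E2 - 1.0) < 1e-2

    def test_domain_gate_at_essential_spectrum(self, class_a_front):
        with pytest.raises(ValueError):
            evans(complex(-1.0, 2.0), class_a_front)

    def test_beta0_closed_form_relation(self, beta0_front):
        # E(lambda) = 1 - phi1(mu0/(lambda+1))/phi1(mu0), exponential oracle
        for lam in (0.5, 1.0, 3.0):
            expected = evans_beta0_exponential(lam, beta0_front.mu0, 5.0)
            assert evans(lam, beta0_front).E == pytest.approx(expected, abs=1e-8)

    def test_mixed_pathway_speed_index_relation(self, class_a_setup,
                                                class_a_front):
        # E(lambda) = 1 - [phi1(g mu0) + phi22(g mu0; offset mu0)]
        #               / [phi1(mu0) + phi22(mu0)],  g = 1/(lambda+1),
        # with the feedback delay offset pinned at the base front's mu0 tau
        K, W = class_a_setup["K"], class_a_setup["W"]
        xi, eta = class_a_setup["xi"], class_a_setup["eta"]
        mu0 = class_a_front.mu0
        den = (nf.phi1(mu0, K, 1.0, xi) + nf.phi22(mu0, W, 0.1, eta))
        rng = np.random.default_rng(11)
        for lam in rng.uniform(0.05, 6.0, 20):
            g = mu0 / (lam + 1.0)
            num = (nf.phi1(g, K, 1.0, xi)
                   + nf.phi22(g, W, 0.1, eta, offset_speed=mu0))
            expected = 1.0 - num / den
            assert evans(float(lam), class_a_front).E.real == pytest.approx(
                expected, abs=1e-8)

    def test_derivative_at_origin_positive(self, class_a_front):
        assert evans_derivative_at_zero(class_a_front) > 0

    def test_derivative_matches_symbolic_oracle(self, beta0_front):
        expected = evans_derivative_beta0_exponential(beta0_front.mu0, 5.0)
        assert evans_derivative_at_zero(beta0_front) == pytest.approx(
            expected, rel=1e-6)

    def test_derivative_richardson_stable(self, class_a_front):
        d1 = evans_derivative_at_zero(class_a_front, h=1e-4)
        d2 = evans_derivative_at_zero(class_a_front, h=5e-5)
        assert abs(d1 - d2) < 1e-6


class TestZeroCounting:
    def test_right_half_plane_is_zero_free(self, class_a_setup, class_b_setup,
                                           class_c_setup):
        for setup in (class_a_setup, class_b_setup, class_c_setup):
            front = nf.solve_traveling_front(**setup)
            count = count_evans_zeros(front, (0.05, 5.0, -5.0, 5.0))
            assert count.winding_number == 0

    def test_contour_enclosing_origin_counts_one(self, class_a_front):
        count = count_evans_zeros(class_a_front, (-0.05, 5.0, -5.0, 5.0))
        assert count.winding_number == 1

    def test_far_right_rectangle_empty(self, class_a_front):
        count = count_evans_zeros(class_a_front, (50.0, 60.0, -5.0, 5.0))
        assert count.winding_number == 0

    def test_refinement_stability(self, class_a_front):
        a = count_evans_zeros(class_a_front, (-0.05, 5.0, -5.0, 5.0),
                              n_per_edge=16)
        b = count_evans_zeros(class_a_front, (-0.05, 5.0, -5.0, 5.0),
                              n_per_edge=32)
        assert a.winding_number == b.winding_number == 1

    def test_invalid_rectangle_rejected(self, class_a_front):
        with pytest.raises(ValueError):
            count_evans_zeros(class_a_front, (-2.0, 5.0, -5.0, 5.0))


class TestEssentialSpectrum:
    def test_line_location_and_membership(self):
        ess = essential_spectrum()
        assert ess.real_part == -1.0
        assert ess.contains(complex(-1.0, 3.0))
        assert not ess.contains(0.2)


class TestStandingCharacteristic:
    def test_neutral_eigenvalue_is_trivial_root(self):
        eta = nf.make_two_point_distribution(1.3, 2.6)
        ev = standing_characteristic(0.0, 0.5, 0.5, 0.5, 0.5, eta)
        assert abs(ev.value) < 1e-14
        assert ev.sign_factor == 1

    def test_pure_feedback_reduction(self):
        # alpha = 0: the equation reduces to (lambda+1) exp(lambda tau0) = 1
        eta = nf.single_atom_distribution(2.0)
        for lam in (0.3, complex(0.2, 1.0)):
            ev = standing_characteristic(lam, 0.5, 0.5, 0.0, 1.0, eta)
            reduced = lam + 1.0 - np.exp(-lam * 2.0)
            assert ev.value == pytest.approx(reduced, abs=1e-14)

    def test_no_delay_term_without_feedback(self):
        eta = nf.single_atom_distribution(1.0)
        ev = standing_characteristic(0.7, 0.5, 0.5, 1.0, 0.0, eta)
        assert ev.value == pytest.approx(0.7, abs=1e-14)

    def test_degenerate_normalisation_rejected(self):
        eta = nf.single_atom_distribution(1.0)
        with pytest.raises(DegenerateLinearizationError):
            standing_characteristic(0.0, 0.5, -0.5, 1.0, 1.0, eta)

    def test_magnitude_normalisation_flips_sign(self):
        eta = nf.single_atom_distribution(2.0)
        ev = standing_characteristic(0.5, 0.0, -2.5, 0.0, 1.0, eta,
                                     magnitude_normalisation=True)
        assert ev.sign_factor == -1
        assert ev.value == pytest.approx(0.5 + 1.0 + np.exp(-1.0), abs=1e-14)


class TestStandingRoots:
    @pytest.mark.parametrize("tau0", [2.0, 0.5])
    def test_pure_feedback_real_root_is_zero(self, tau0):
        eta = nf.single_atom_distribution(tau0)
        root = find_standing_real_root(0.5, 0.5, 0.0, 1.0, eta)
        assert abs(root) < 1e-12

    def test_mixed_configuration_root_is_zero(self):
        eta = nf.make_two_point_distribution(1.3, 2.6)
        root = find_standing_real_root(0.5, 0.5, 0.5, 0.5, eta)
        assert abs(root) < 1e-12

    def test_auxiliary_function_strictly_increasing(self):
        eta = nf.make_two_point_distribution(1.3, 2.6)
        lams = np.linspace(-0.99, 10.0, 1000)
        vals = [standing_auxiliary_f(l, 0.5, 0.5, 0.5, 0.5, eta) for l in lams]
        assert np.all(np.diff(vals) > 0)

    def test_no_unstable_complex_roots_verbatim(self):
        # modulus bound |lambda+1| > 1 >= |sum w e^{-lambda tau}| on Re > 0
        eta = nf.single_atom_distribution(2.0)
        roots = scan_standing_complex_roots(0.5, 0.5, 0.0, 1.0, eta,
                                            region=(0.0, 3.0, -10.0, 10.0),
                                            grid=(80, 160))
        assert roots == []

    def test_no_unstable_roots_small_delay_negative_branch(self):
        # sign-flipped equation lambda+1 = -e^{-lambda tau}, tau -> 0:
        # roots sit near Re lambda = -2, none in the right half-plane
        eta = nf.single_atom_distribution(0.05)
        roots = scan_standing_complex_roots(0.0, -2.5, 0.0, 1.0, eta,
                                            region=(0.0, 3.0, -10.0, 10.0),
                                            grid=(80, 160),
                                            magnitude_normalisation=True)
        assert roots == []

    def test_left_half_plane_region_rejected(self):
        eta = nf.single_atom_distribution(1.0)
        with pytest.raises(ValueError):
            scan_standing_complex_roots(0.5, 0.5, 0.0, 1.0, eta,
                                        region=(-2.0, 0.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            find_standing_real_root(0.5, 0.5, 0.0, 1.0, eta,
                                    bracket=(-3.0, 1.0))
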