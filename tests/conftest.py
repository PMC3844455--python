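"""Shared fixtures: canonical model configurations and closed-form oracles.

The closed-form expressions below are independent antiderivative-based
oracles for exponential kernels; they are frozen here and never computed
through the package's own quadrature code paths.
"""

import numpy as np
import pytest

import neuralfront as nf


# ---------------------------------------------------------------------------
# canonical configurations
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def class_a_setup():
    """Excitatory kernel pair with two speeds and two delays."""
    return dict(
        K=nf.make_difference_of_exponentials_kernel(1.0, 0.0),
        W=nf.make_single_exponential_kernel(1.0),
        params=nf.ModelParameters(alpha=1.0, beta=0.1, theta=0.2),
        xi=nf.make_two_point_distribution(5.0, 10.0),
        eta=nf.make_two_point_distribution(0.1, 0.2),
    )


@pytest.fixture(scope="session")
def class_b_setup(class_a_setup):
    out = dict(class_a_setup)
    out["K"] = nf.make_difference_of_exponentials_kernel(1.0, 0.4, 0.2)
    return out


@pytest.fixture(scope="session")
def class_c_setup(class_a_setup):
    out = dict(class_a_setup)
    out["K"] = nf.make_difference_of_exponentials_kernel(1.0, 0.4, 3.0)
    return out


@pytest.fixture(scope="session")
def standing_feedback_setup():
    """Inverted-Mexican-hat feedback, no intracortical coupling, delay 2."""
    return dict(
        K=nf.make_single_exponential_kernel(1.0),
        W=nf.make_difference_of_exponentials_kernel(1.0, 0.4, 10.0),
        params=nf.ModelParameters(alpha=0.0, beta=1.0, theta=0.5),
        xi=nf.single_atom_distribution(5.0),
        eta=nf.single_atom_distribution(2.0),
    )


@pytest.fixture(scope="session")
def class_a_front(class_a_setup):
    return nf.solve_traveling_front(**class_a_setup)


# ---------------------------------------------------------------------------
# closed-form oracles for exponential kernels (independent of the package)
# ---------------------------------------------------------------------------

def phi1_exponential(mu, alpha, atoms_weights, sigma=1.0):
    """phi1 for K(x) = e^{-|x|/sigma}/(2 sigma): per atom alpha/(2(sigma*a+1)),
    a = (c-mu)/(c mu)."""
    total = 0.0
    for c, w in atoms_weights:
        a = (c - mu) / (c * mu)
        total += w / (2.0 * (sigma * a + 1.0))
    return alpha * total


def phi21_exponential(mu, beta, atoms_weights, sigma=1.0):
    """phi21 for W = e^{-|x|/sigma}/(2 sigma): per atom beta/2 (1 - e^{-mu tau/sigma})."""
    return beta * sum(w * 0.5 * (1.0 - np.exp(-mu * tau / sigma))
                      for tau, w in atoms_weights)


def phi22_exponential(mu, beta, atoms_weights, sigma=1.0):
    """phi22 for W = e^{-|x|/sigma}/(2 sigma): per atom
    beta mu e^{-mu tau/sigma} / (2 (sigma + mu))."""
    return beta * sum(w * mu * np.exp(-mu * tau / sigma) / (2.0 * (sigma + mu))
                      for tau, w in atoms_weights)


def wave_speed_exponential_beta0(alpha, theta, c):
    """Root of alpha/2 * c mu/(c - mu + c mu) = alpha/2 - theta for
    K = e^{-|x|}/2, single speed atom, beta = 0."""
    rhs = alpha / 2.0 - theta
    # alpha c mu / 2 = rhs (c - mu + c mu)  =>  mu (alpha c / 2 + rhs - rhs c) = rhs c
    return rhs * c / (alpha * c / 2.0 + rhs * (1.0 - c))


def _cum_exp_half(b):
    """int_{-inf}^{b} e^{-|x|}/2 dx."""
    return np.where(b <= 0, np.exp(b) / 2.0, 1.0 - np.exp(-b) / 2.0)


def traveling_profile_exponential(z, mu, alpha, beta, c, tau):
    """Closed-form front profile for K = W = e^{-|x|}/2, single speed c,
    single delay tau (piecewise exponential antiderivatives).

    The intracortical part for z <= 0 is
        alpha e^{c z/(c-mu)} [1/2 - c mu / (2(c - mu + c mu))],
    and for z > 0 the memory integral is split at the origin; the feedback
    part uses A(b) = int_{-inf}^b e^{x/mu} e^{-|x|}/2 dx in
        beta [ Cum(z - mu tau) - e^{tau} e^{-z/mu} A(z - mu tau) ].
    """
    q1 = c * mu / (2.0 * (c - mu + c * mu))      # phi1-type constant
    if z <= 0:
        ic = alpha * np.exp(c * z / (c - mu)) * (0.5 - q1)
    else:
        e_warp = np.exp(-c * z / (c + mu))
        e_mem = np.exp(-z / mu)
        q2 = c * mu / (2.0 * (c + mu - c * mu))  # requires c + mu != c mu
        ic = alpha * (1.0 - e_warp / 2.0 - e_mem * q1 - q2 * (e_warp - e_mem))

    def A(b):
        a0 = mu / (2.0 * (mu + 1.0))
        if b <= 0:
            return a0 * np.exp(b * (1.0 + 1.0 / mu))
        # mu != 1 assumed by callers
        return a0 + (np.exp(b * (1.0 / mu - 1.0)) - 1.0) * mu / (2.0 * (1.0 - mu))

    zs = z - mu * tau
    fb = beta * (float(_cum_exp_half(zs))
                 - np.exp(tau) * np.exp(-z / mu) * A(zs))
    return ic + fb


def evans_beta0_exponential(lam, mu0, c):
    """E(lambda) = 1 - phi1(mu0/(1+lambda))/phi1(mu0) for K=e^{-|x|}/2, beta=0."""
    def f(mu):
        return c * mu / (2.0 * (c - mu + c * mu))
    return 1.0 - f(mu0 / (lam + 1.0)) / f(mu0)


def evans_derivative_beta0_exponential(mu0, c):
    """d/d lambda at 0 of the expression above: c/(c - mu0 + c mu0)."""
    return c / (c - mu0 + c * mu0)
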