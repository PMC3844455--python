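"""Speed index functions and the implicit wave-speed equation.

A traveling front ``u(x,t) = U(x + mu t)`` of the delayed neural field exists
for a unique speed ``mu0`` in ``(0, c0)``, where ``c0`` is the smallest
transmission speed in the support of the speed density.  The speed solves

    phi(mu) = phi1(mu) + phi21(mu) + phi22(mu) = (alpha + beta)/2 - theta,

with the speed index functions

    phi1(mu)  = alpha * sum_i w_i  int_{-inf}^{0}    exp((c_i - mu)/(c_i mu) x) K(x) dx,
    phi21(mu) = beta  * sum_j w_j  int_{-mu tau_j}^0 W(x) dx,
    phi22(mu) = beta  * sum_j w_j  e^{tau_j} int_{-inf}^{-mu tau_j} e^{x/mu} W(x) dx.

For excitatory and Mexican-hat kernels (classes A, B) phi is strictly
increasing, which makes the root unique; inverted-Mexican-hat kernels
(class C) allow an initial decreasing branch and hence possibly several
sign changes, which the solver detects and flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .kernels import (
    AtomicDistribution,
    ModelParameters,
    SpatialKernel,
    make_two_point_distribution,
)

__all__ = [
    "phi1",
    "phi21",
    "phi22",
    "phi2",
    "phi_total",
    "solve_wave_speed",
    "SpeedSolution",
    "NoFrontSpeedError",
    "monotonicity_scan",
    "MonotonicityScan",
    "speed_sensitivity_scan",
    "SpeedCurve",
    "verify_feedback_intracortical_limit",
    "write_speed_curve_csv",
]

_EPSABS = 1e-12
_EPSREL = 1e-10


class NoFrontSpeedError(RuntimeError):
    """The speed equation has no root in (0, c0) for this configuration."""


def _check_mu(mu: float, c0: float) -> None:
    if not (0.0 < mu < c0):
        raise ValueError(f"wave speed mu={mu} must lie in (0, c0={c0})")


def _exp_weighted_left_tail(kernel: SpatialKernel, a: float, upper: float) -> float:
    """``int_{-inf}^{upper} e^{a x} K(x) dx`` with envelope-aware truncation.

    Requires ``a + rho > 0`` so the integrand decays toward ``-inf``.
    """
    rate = a + kernel.decay_rate
    if rate <= 0:
        return np.inf
    lower = min(upper, 0.0) - min(kernel.x_max + abs(upper), 45.0 / rate)
    pts = [0.0] if lower < 0.0 < upper else None
    val, _ = integrate.quad(lambda x: np.exp(a * x) * kernel(x), lower, upper,
                            points=pts, limit=200, epsabs=_EPSABS, epsrel=_EPSREL)
    return val


def phi1(mu: float, K: SpatialKernel, alpha: float, xi: AtomicDistribution) -> float:
    """Intracortical speed index function."""
    _check_mu(mu, xi.min_support)
    total = 0.0
    for c, w in xi.items():
        a = (c - mu) / (c * mu)
        total += w * _exp_weighted_left_tail(K, a, 0.0)
    return alpha * total


def phi21(mu: float, W: SpatialKernel, beta: float, eta: AtomicDistribution) -> float:
    """Short-window part of the feedback speed index function."""
    if mu <= 0:
        raise ValueError(f"wave speed mu={mu} must be positive")
    return beta * sum(w * W.integral(-mu * tau, 0.0) for tau, w in eta.items())


def phi22(mu: float, W: SpatialKernel, beta: float, eta: AtomicDistribution,
          offset_speed: float | None = None) -> float:
    """Exponentially weighted tail part of the feedback speed index function.

    ``offset_speed`` pins the integration limit ``-offset_speed * tau_j``
    independently of the exponential rate ``1/mu``; it defaults to ``mu``
    itself (the plain speed index function).  The pinned variant arises in
    the Evans-function identity, where the delay offset stays at the base
    front's ``mu0 tau`` while the rate is rescaled by ``1/(lambda + 1)``.
    """
    if mu <= 0:
        raise ValueError(f"wave speed mu={mu} must be positive")
    off = mu if offset_speed is None else offset_speed
    total = 0.0
    for tau, w in eta.items():
        total += w * np.exp(tau) * _exp_weighted_left_tail(W, 1.0 / mu, -off * tau)
    return beta * total


def phi2(mu: float, W: SpatialKernel, beta: float, eta: AtomicDistribution) -> float:
    return phi21(mu, W, beta, eta) + phi22(mu, W, beta, eta)


def phi_total(mu: float, K: SpatialKernel, W: SpatialKernel, params: ModelParameters,
              xi: AtomicDistribution, eta: AtomicDistribution) -> float:
    return (phi1(mu, K, params.alpha, xi)
            + phi2(mu, W, params.beta, eta))


@dataclass
class SpeedSolution:
    """Root of the speed equation with solver diagnostics."""

    mu0: float
    residual: float
    bracket: tuple
    iterations: int
    all_roots: tuple = ()
    multiple_roots: bool = False

    def __repr__(self):
        flag = " (multiple roots!)" if self.multiple_roots else ""
        return f"SpeedSolution(mu0={self.mu0:.12g}, residual={self.residual:.2e}{flag})"


def solve_wave_speed(K: SpatialKernel, W: SpatialKernel, params: ModelParameters,
                     xi: AtomicDistribution, eta: AtomicDistribution,
                     n_scan: int = 256) -> SpeedSolution:
    """Solve ``phi(mu) = (alpha+beta)/2 - theta`` for the front speed.

    A pre-scan on ``n_scan`` points over ``(eps, c0 - eps)`` locates every
    sign change of the residual, each of which is polished by a bracketed
    Brent search (tolerance 1e-12 on mu).  For monotone phi (classes A, B)
    there is exactly one root; when several sign changes occur (possible for
    class C kernels) the largest root is returned and the case flagged.
    """
    if not params.admits_traveling_front():
        raise NoFrontSpeedError(
            f"need 0 < 2*theta < alpha+beta, got theta={params.theta}, "
            f"alpha+beta={params.total_weight}")
    c0 = xi.min_support
    target = params.total_weight / 2.0 - params.theta

    def g(mu):
        return phi_total(mu, K, W, params, xi, eta) - target

    # combined geometric + linear pre-scan: the geometric part resolves roots
    # arbitrarily close to 0 (phi -> 0 there), the linear part keeps uniform
    # resolution near c0 where class-C configurations may host several roots
    eps = 1e-9 * c0
    cap = c0 * (1.0 - 1e-6)
    grid = np.unique(np.concatenate([
        np.geomspace(eps, cap, n_scan - n_scan // 3),
        np.linspace(eps, cap, n_scan // 3),
    ]))
    vals = np.array([g(m) for m in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_changes.size == 0:
        raise NoFrontSpeedError(
            f"no sign change of phi(mu) - {target:.6g} on (0, {c0:.6g}); "
            f"phi range [{vals.min() + target:.6g}, {vals.max() + target:.6g}]")

    roots = []
    iters = 0
    for k in sign_changes:
        res = optimize.root_scalar(g, bracket=(grid[k], grid[k + 1]),
                                   method="brentq", xtol=1e-12)
        roots.append(res.root)
        iters += res.iterations
    mu0 = max(roots)
    return SpeedSolution(
        mu0=mu0,
        residual=abs(g(mu0)),
        bracket=(float(grid[sign_changes[-1]]), float(grid[sign_changes[-1] + 1])),
        iterations=iters,
        all_roots=tuple(roots),
        multiple_roots=len(roots) > 1,
    )


@dataclass
class MonotonicityScan:
    """Finite-difference signs of dphi1/dmu and dphi2/dmu on a grid."""

    mu_grid: np.ndarray
    dphi1: np.ndarray
    dphi2: np.ndarray
    phi1_all_positive: bool
    phi2_all_positive: bool
    phi1_turning_point: float | None
    phi2_turning_point: float | None


def _turning_point(grid: np.ndarray, deriv: np.ndarray) -> float | None:
    """First mu where the derivative flips from negative to positive."""
    s = np.sign(deriv)
    flips = np.nonzero((s[:-1] < 0) & (s[1:] > 0))[0]
    if flips.size == 0:
        return None
    k = flips[0]
    # linear interpolation of the zero crossing of the derivative
    d0, d1 = deriv[k], deriv[k + 1]
    return float(grid[k] + (grid[k + 1] - grid[k]) * (-d0) / (d1 - d0))


def monotonicity_scan(K: SpatialKernel, W: SpatialKernel, params: ModelParameters,
                      xi: AtomicDistribution, eta: AtomicDistribution,
                      mu_grid: np.ndarray) -> MonotonicityScan:
    """Centered-difference monotonicity check of the speed index functions.

    For classes (A)/(B) both derivatives are positive throughout ``(0, c0)``;
    for class (C) each flips sign once (negative then positive), and the
    estimated turning points are reported.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    c0 = xi.min_support
    h = min(1e-5 * c0, 0.49 * min(mu_grid.min(), c0 - mu_grid.max()))
    d1 = np.array([(phi1(m + h, K, params.alpha, xi) - phi1(m - h, K, params.alpha, xi))
                   / (2 * h) for m in mu_grid])
    d2 = np.array([(phi2(m + h, W, params.beta, eta) - phi2(m - h, W, params.beta, eta))
                   / (2 * h) for m in mu_grid])
    return MonotonicityScan(
        mu_grid=mu_grid, dphi1=d1, dphi2=d2,
        phi1_all_positive=bool(np.all(d1 > 0)),
        phi2_all_positive=bool(np.all(d2 > 0)),
        phi1_turning_point=_turning_point(mu_grid, d1),
        phi2_turning_point=_turning_point(mu_grid, d2),
    )


@dataclass
class SpeedCurve:
    """Wave speed as a function of the lowest transmission speed or delay."""

    scan_variable: str
    scan_values: np.ndarray
    mu0: np.ndarray
    residual: np.ndarray
    solvable: np.ndarray
    kappa: float
    metadata: dict = field(default_factory=dict)


def speed_sensitivity_scan(K: SpatialKernel, W: SpatialKernel, params: ModelParameters,
                           xi: AtomicDistribution, eta: AtomicDistribution,
                           scan_variable: str, scan_values, kappa: float = 2.0) -> SpeedCurve:
    """Scan mu0 against the lowest transmission speed c0 or lowest delay tau0.

    At each scan point the corresponding two-point distribution is rebuilt as
    atoms ``(v, kappa*v)`` with equal weights, keeping the ratio of the fast
    to the slow pathway fixed.  The other distribution is left untouched.
    For general kernels mu0 increases with c0; for excitatory feedback
    (W >= 0) mu0 decreases with tau0.  Unsolvable points are recorded as NaN
    and the scan continues.
    """
    if scan_variable not in ("c0", "tau0"):
        raise ValueError("scan_variable must be 'c0' or 'tau0'")
    scan_values = np.asarray(scan_values, dtype=float)
    mu0 = np.full_like(scan_values, np.nan)
    residual = np.full_like(scan_values, np.nan)
    solvable = np.zeros(scan_values.shape, dtype=bool)
    for i, v in enumerate(scan_values):
        two_point = make_two_point_distribution(v, kappa * v)
        xi_i = two_point if scan_variable == "c0" else xi
        eta_i = two_point if scan_variable == "tau0" else eta
        try:
            sol = solve_wave_speed(K, W, params, xi_i, eta_i)
        except NoFrontSpeedError:
            continue
        mu0[i] = sol.mu0
        residual[i] = sol.residual
        solvable[i] = True
    return SpeedCurve(scan_variable=scan_variable, scan_values=scan_values,
                      mu0=mu0, residual=residual, solvable=solvable, kappa=kappa,
                      metadata={"alpha": params.alpha, "beta": params.beta,
                                "theta": params.theta})


def verify_feedback_intracortical_limit(kernel: SpatialKernel, weight: float, mu: float,
                                        c_large: float, tau_small: float) -> float:
    """Residual of the fast-transmission / short-feedback-delay identity.

    When the two pathways share the same footprint ``K = W`` (the single
    kernel argument enforces this) and each carries a single atom, the
    intracortical index at speed atom ``c_large`` and the feedback index at
    delay atom ``tau_small`` converge to the same value as ``c_large -> inf``
    and ``tau_small -> 0``: the two couplings become indistinguishable.
    Returns ``|phi1 - phi2|`` at the given atoms; it decreases toward zero as
    the limits are approached.
    """
    from .kernels import single_atom_distribution

    xi = single_atom_distribution(c_large)
    eta = single_atom_distribution(tau_small)
    p1 = phi1(mu, kernel, weight, xi)
    p2 = phi2(mu, kernel, weight, eta)
    return abs(p1 - p2)


def write_speed_curve_csv(curve: SpeedCurve, path) -> None:
    """Write a sensitivity scan as CSV: (scan_value, mu0, residual, solvable)."""
    with open(path, "w") as fh:
        fh.write(f"# scan_variable={curve.scan_variable} kappa={curve.kappa!r} "
                 f"{curve.metadata}\n")
        fh.write("scan_value,mu0,residual,solvable\n")
        for v, m, r, s in zip(curve.scan_values, curve.mu0, curve.residual,
                              curve.solvable):
            fh.write(f"{v:.17g},{m:.17g},{r:.17g},{int(s)}\n")
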