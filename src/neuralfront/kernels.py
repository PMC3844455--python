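"""Spatial connectivity kernels, speed/delay distributions and model assumptions.

The neural field under study couples a population to itself through two
pathways: intracortical connections with distance-dependent transmission
delay ``|x - y|/c`` (kernel ``K``, speed density ``xi``), and re-entrant
feedback fibres of fixed length with distance-independent delay ``tau``
(kernel ``W``, delay density ``eta``).  This module provides the parametric
kernel families used throughout, their classification into excitatory (A),
Mexican-hat (B) and inverted-Mexican-hat (C) interaction classes, discrete
(atomic) speed/delay distributions, and a checker for the standing model
assumptions (normalisation, symmetry, exponential envelope, moment
conditions and the front-existence inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "SpatialKernel",
    "AtomicDistribution",
    "ModelParameters",
    "AssumptionReport",
    "make_difference_of_exponentials_kernel",
    "make_single_exponential_kernel",
    "kernel_from_callable",
    "classify_kernel",
    "make_two_point_distribution",
    "single_atom_distribution",
    "distribution_moment",
    "check_assumptions",
    "truncation_radius",
]

#: default quadrature tolerances used for all kernel integrals
QUAD_EPSABS = 1e-12
QUAD_EPSREL = 1e-10


def truncation_radius(rho_min: float) -> float:
    """Truncation point for improper kernel integrals.

    The exponential envelope makes the tail beyond ``max(50, 40/rho_min)``
    smaller than ~1e-17, i.e. below double precision resolution.
    """
    return max(50.0, 40.0 / rho_min)


class InvalidParameterError(ValueError):
    """Raised when a kernel/distribution parameter violates its precondition."""


@dataclass(frozen=True)
class SpatialKernel:
    """A real-valued synaptic footprint ``K(x)`` on the line.

    Parameters
    ----------
    evaluate : callable
        Vectorisable map from position to synaptic density.
    params : mapping
        Named parameters the kernel was built from.
    decay_rate : float
        Exponent ``rho`` of the exponential envelope ``|K(x)| <= C exp(-rho|x|)``.
    family : str
        Family tag ("difference_of_exponentials", "single_exponential", "custom").
    sign_change_radius : float or None
        Radius ``M`` separating the inner and outer sign regions for
        Mexican-hat type kernels, if known.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    params: Mapping[str, float] = field(default_factory=dict)
    decay_rate: float = 1.0
    family: str = "custom"
    sign_change_radius: float | None = None

    def __call__(self, x):
        return self.evaluate(np.asarray(x, dtype=float))

    @property
    def x_max(self) -> float:
        return truncation_radius(self.decay_rate)

    def integral(self, lower: float, upper: float) -> float:
        """Integral of the kernel over [lower, upper], split at the origin kink."""
        lower = max(lower, -self.x_max)
        upper = min(upper, self.x_max)
        if upper <= lower:
            return 0.0
        pts = [0.0] if lower < 0.0 < upper else None
        val, _ = integrate.quad(
            self.evaluate, lower, upper, points=pts, limit=200,
            epsabs=QUAD_EPSABS, epsrel=QUAD_EPSREL,
        )
        return val

    def cumulative(self, b: float) -> float:
        """``int_{-inf}^{b} K(x) dx`` (truncated at the envelope radius)."""
        return self.integral(-self.x_max, b)

    def mass(self) -> float:
        """Total integral over the line; 1 for the shipped families."""
        return self.integral(-self.x_max, self.x_max)


def make_difference_of_exponentials_kernel(s: float, r: float, rho: float = 1.0) -> SpatialKernel:
    """Kernel ``K(x) = [s e^{-|x|} - r rho e^{-rho|x|}] / (2(s-r))``.

    Normalised to unit mass for every admissible parameter triple.  Depending
    on ``r`` and ``rho`` the kernel is purely excitatory (r = 0), Mexican hat
    (slow negative tail, rho < 1) or inverted Mexican hat (negative core,
    r*rho > s with rho > 1).
    """
    if not (s > r):
        raise InvalidParameterError(f"require s > r, got s={s}, r={r}")
    if rho <= 0:
        raise InvalidParameterError(f"require rho > 0, got rho={rho}")

    norm = 2.0 * (s - r)

    def evaluate(x):
        ax = np.abs(x)
        return (s * np.exp(-ax) - r * rho * np.exp(-rho * ax)) / norm

    return SpatialKernel(
        evaluate=evaluate,
        params={"s": s, "r": r, "rho": rho},
        decay_rate=min(1.0, rho) if r != 0.0 else 1.0,
        family="difference_of_exponentials",
    )


def make_single_exponential_kernel(sigma: float) -> SpatialKernel:
    """Excitatory kernel ``W(x) = e^{-|x|/sigma} / (2 sigma)`` (class A)."""
    if sigma <= 0:
        raise InvalidParameterError(f"require sigma > 0, got sigma={sigma}")

    def evaluate(x):
        return np.exp(-np.abs(x) / sigma) / (2.0 * sigma)

    return SpatialKernel(
        evaluate=evaluate,
        params={"sigma": sigma},
        decay_rate=1.0 / sigma,
        family="single_exponential",
    )


def kernel_from_callable(fn: Callable, decay_rate: float, **params) -> SpatialKernel:
    """Wrap a user-supplied symmetric footprint with a stated envelope exponent."""
    return SpatialKernel(evaluate=lambda x: np.asarray(fn(x), dtype=float),
                         params=dict(params), decay_rate=decay_rate)


def classify_kernel(kernel: SpatialKernel, probe_radius: float = 25.0,
                    n_samples: int = 4001, tol: float = 1e-12):
    """Classify a kernel into interaction classes A, B, C or "other".

    A: nonnegative everywhere (global excitation).
    B: nonnegative on (-M, M), nonpositive outside (local excitation,
       lateral inhibition — Mexican hat).
    C: the reverse sign pattern (local inhibition, lateral excitation).

    Returns ``(label, M)`` where ``M`` is the estimated sign-change radius
    (None for class A / "other").  Values within ``tol`` of zero are treated
    as zero, so kernels touching zero remain classifiable.
    """
    x = np.linspace(-probe_radius, probe_radius, n_samples)
    v = kernel(x)
    sign = np.zeros_like(v)
    sign[v > tol] = 1.0
    sign[v < -tol] = -1.0

    if np.all(sign >= 0):
        return "A", None

    half = np.abs(x)
    r_pos = half[sign > 0]
    r_neg = half[sign < 0]

    def refine(lo: float, hi: float) -> float:
        """Bisect the sign change of the kernel along the positive half-axis."""
        from scipy.optimize import brentq
        f = lambda r: float(kernel(r))
        if f(lo) * f(hi) < 0:
            return float(brentq(f, lo, hi, xtol=1e-10))
        return 0.5 * (lo + hi)

    if r_pos.size == 0:
        # nonpositive everywhere: degenerate class C with M = probe_radius
        return "C", float(probe_radius)
    # B: all positive samples strictly inside all negative samples
    if r_pos.max() <= r_neg.min():
        return "B", refine(r_pos.max(), r_neg.min())
    # C: all negative samples strictly inside all positive samples
    if r_neg.max() <= r_pos.min():
        return "C", refine(r_neg.max(), r_pos.min())
    return "other", None


@dataclass(frozen=True)
class AtomicDistribution:
    """Discrete distribution of transmission speeds or feedback delays.

    Continuous densities are represented by the caller as quadrature atoms;
    every speed-index and Evans integral then reduces to a finite sum.
    """

    atoms: tuple
    weights: tuple

    def __post_init__(self):
        atoms = np.asarray(self.atoms, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if atoms.ndim != 1 or atoms.size == 0:
            raise InvalidParameterError("distribution needs at least one atom")
        if np.any(atoms <= 0):
            raise InvalidParameterError(f"atoms must be strictly positive: {atoms}")
        if np.any(weights < 0):
            raise InvalidParameterError("weights must be nonnegative")
        if not np.isclose(weights.sum(), 1.0, atol=1e-12):
            raise InvalidParameterError(f"weights must sum to 1, got {weights.sum()}")
        object.__setattr__(self, "atoms", tuple(float(a) for a in atoms))
        object.__setattr__(self, "weights", tuple(float(w) for w in weights))

    @property
    def min_support(self) -> float:
        """Smallest atom; for a speed distribution this is c0, the speed floor."""
        return min(self.atoms)

    @property
    def max_support(self) -> float:
        return max(self.atoms)

    @property
    def mean(self) -> float:
        return distribution_moment(self, lambda v: v)

    def items(self):
        return zip(self.atoms, self.weights)


def make_two_point_distribution(v1: float, v2: float) -> AtomicDistribution:
    """Equal-weight two-atom distribution (two speeds or two delays)."""
    if v1 <= 0 or v2 <= 0:
        raise InvalidParameterError(f"atoms must be positive, got {v1}, {v2}")
    return AtomicDistribution(atoms=(v1, v2), weights=(0.5, 0.5))


def single_atom_distribution(v: float) -> AtomicDistribution:
    """Point mass at ``v`` (a single speed or a single delay)."""
    return AtomicDistribution(atoms=(v,), weights=(1.0,))


def distribution_moment(dist: AtomicDistribution, transform: Callable[[float], float]) -> float:
    """``sum_i w_i * transform(atom_i)`` — generalised moment of an atomic density."""
    return float(sum(w * transform(a) for a, w in dist.items()))


@dataclass(frozen=True)
class ModelParameters:
    """Synaptic weights and firing threshold of the scalar field model.

    alpha : weight of intracortical (transmission-delayed) coupling, >= 0
    beta  : weight of re-entrant feedback (fixed-delay) coupling, >= 0
    theta : mean firing threshold of the Heaviside rate function, > 0
    """

    alpha: float
    beta: float
    theta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError("alpha and beta must be nonnegative")
        if self.alpha + self.beta <= 0:
            raise InvalidParameterError("alpha + beta must be positive")
        if self.theta <= 0:
            raise InvalidParameterError("theta must be positive")

    @property
    def total_weight(self) -> float:
        return self.alpha + self.beta

    def admits_traveling_front(self) -> bool:
        return 0.0 < 2.0 * self.theta < self.total_weight

    def admits_standing_front(self, tol: float = 1e-12) -> bool:
        return abs(self.total_weight - 2.0 * self.theta) <= tol


@dataclass
class Clause:
    name: str
    value: float
    passed: bool
    detail: str = ""


@dataclass
class AssumptionReport:
    """Per-clause numeric evaluation of the standing model assumptions."""

    clauses: list

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.clauses)

    def __getitem__(self, name: str) -> Clause:
        for c in self.clauses:
            if c.name == name:
                return c
        raise KeyError(name)

    def summary(self) -> str:
        lines = [f"overall: {'PASS' if self.passed else 'FAIL'}"]
        for c in self.clauses:
            mark = "ok " if c.passed else "FAIL"
            lines.append(f"  [{mark}] {c.name} = {c.value:.6g} {c.detail}")
        return "\n".join(lines)


def _envelope_constant(kernel: SpatialKernel, probe_radius: float = 25.0) -> float:
    x = np.linspace(-probe_radius, probe_radius, 2001)
    return float(np.max(np.abs(kernel(x)) * np.exp(kernel.decay_rate * np.abs(x))))


def check_assumptions(K: SpatialKernel, W: SpatialKernel, params: ModelParameters,
                      xi: AtomicDistribution, eta: AtomicDistribution,
                      quad_tol: float = 1e-8) -> AssumptionReport:
    """Evaluate every clause of the model's standing assumptions.

    Clauses: threshold window 0 < 2*theta < alpha+beta; positive self-coupling
    slope alpha*K(0)+beta*W(0) > 0; unit-mass speed and delay densities;
    finite 1/c and e^tau moments; exponential envelope (informational);
    unit kernel masses and half-mass symmetry; nonnegative first absolute
    half-moments; and the front-existence inequality
    ``int_0^inf [alpha K + beta W] e^{x/c0} dx > (alpha+beta)/2 - theta``.

    A divergent right-tail quadrature in the last clause (kernel decaying
    slower than 1/c0) is reported as a clause failure, not an exception.
    """
    a, b, th = params.alpha, params.beta, params.theta
    clauses: list[Clause] = []

    clauses.append(Clause("threshold_window", 2 * th,
                          0.0 < 2 * th < a + b, f"(require 0 < 2*theta < {a + b})"))
    k0 = float(K(0.0))
    w0 = float(W(0.0))
    slope = a * k0 + b * w0
    clauses.append(Clause("positive_weights", a + b, a + b > 0))
    clauses.append(Clause("self_coupling_slope", slope, slope > 0,
                          f"(alpha*K(0)+beta*W(0), K(0)={k0:.4g}, W(0)={w0:.4g})"))
    clauses.append(Clause("xi_total_mass", sum(xi.weights),
                          np.isclose(sum(xi.weights), 1.0, atol=1e-12)))
    clauses.append(Clause("eta_total_mass", sum(eta.weights),
                          np.isclose(sum(eta.weights), 1.0, atol=1e-12)))
    inv_speed = distribution_moment(xi, lambda c: 1.0 / c)
    clauses.append(Clause("finite_inverse_speed_moment", inv_speed, np.isfinite(inv_speed)))
    exp_delay = distribution_moment(eta, np.exp)
    clauses.append(Clause("finite_exp_delay_moment", exp_delay, np.isfinite(exp_delay)))

    rho = min(K.decay_rate, W.decay_rate)
    c_env = max(_envelope_constant(K), _envelope_constant(W))
    clauses.append(Clause("exponential_envelope", c_env, True,
                          f"(informational: C with rho={rho:.4g})"))

    for name, ker in (("K", K), ("W", W)):
        m = ker.mass()
        clauses.append(Clause(f"{name}_unit_mass", m, abs(m - 1.0) < quad_tol))
        h = ker.cumulative(0.0)
        clauses.append(Clause(f"{name}_half_mass", h, abs(h - 0.5) < quad_tol))
        xm = max(ker.x_max, 0.0)
        absmom, _ = integrate.quad(lambda x: abs(x) * ker(x), -xm, 0.0,
                                   limit=200, epsabs=QUAD_EPSABS, epsrel=QUAD_EPSREL)
        clauses.append(Clause(f"{name}_abs_half_moment", absmom, absmom >= -quad_tol))

    c0 = xi.min_support
    # combined kernel must decay faster than e^{-x/c0} for the integral to exist
    if rho <= 1.0 / c0:
        clauses.append(Clause("front_existence", np.inf, False,
                              "(right tail diverges: decay rate <= 1/c0)"))
    else:
        xm = truncation_radius(rho - 1.0 / c0)
        val, _ = integrate.quad(lambda x: (a * K(x) + b * W(x)) * np.exp(x / c0),
                                0.0, xm, limit=200,
                                epsabs=QUAD_EPSABS, epsrel=QUAD_EPSREL)
        target = (a + b) / 2.0 - th
        clauses.append(Clause("front_existence", val, val > target,
                              f"(require > {target:.6g})"))

    return AssumptionReport(clauses=clauses)
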