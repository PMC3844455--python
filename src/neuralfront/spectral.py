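"""Spectral stability: Evans functions and the standing-front characteristic equation.

For the traveling front the linearised flow has essential spectrum on the
line ``Re lambda = -1`` and point spectrum given by the zeros of the Evans
function

    E(lambda) = E1(lambda) + E2(lambda) - 1,

    E1 = 1 - alpha/(mu0 U'(0)) * sum_i w_i
             int_{-inf}^0 exp( ((lambda+1) c_i - mu0)/(c_i mu0) * x ) K(x) dx,
    E2 = 1 - beta/(mu0 U'(0)) * sum_j w_j e^{tau_j}
             int_{-inf}^{-mu0 tau_j} exp( (lambda+1)/mu0 * x ) W(x) dx,

analytic on ``Re lambda > -1``.  ``E(0) = 0`` always (translation
invariance) and ``E -> 1`` as ``|lambda| -> inf``.  Zeros in the open right
half-plane are counted by the argument principle (winding number of the
contour image by phase accumulation).

For the standing front the eigenvalue problem collapses to the scalar
characteristic equation

    lambda + 1 = aK + aW * sum_j w_j exp(-lambda tau_j),

with ``aK = alpha K(0)/d``, ``aW = beta W(0)/d``, ``d = alpha K(0) + beta W(0)``,
whose real auxiliary function is strictly increasing on ``(-1, inf)`` with
the single root ``lambda = 0``: transmission delays never destabilise the
standing front; only the feedback-delay term can.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .fronts import TravelingFront
from .kernels import AtomicDistribution, SpatialKernel

__all__ = [
    "EvansEvaluation",
    "evans",
    "evans_derivative_at_zero",
    "ZeroCount",
    "count_evans_zeros",
    "ContourError",
    "EssentialSpectrum",
    "essential_spectrum",
    "CharacteristicEvaluation",
    "standing_characteristic",
    "standing_auxiliary_f",
    "find_standing_real_root",
    "scan_standing_complex_roots",
    "DegenerateLinearizationError",
]

_EPSABS = 1e-12
_EPSREL = 1e-10
_DOMAIN_EDGE = -1.0 + 1e-9
_RATE_FLOOR = 1e-3


def _complex_exp_tail(kernel: SpatialKernel, a: complex, upper: float) -> complex:
    """``int_{-inf}^{upper} e^{a x} K(x) dx`` for complex ``a`` with Re a + rho > 0.

    Real and imaginary parts are integrated separately by the adaptive
    scheme; the truncation length follows the lambda-dependent decay rate
    ``Re a + rho`` with a floor of 1e-3.
    """
    rate = max(a.real + kernel.decay_rate, _RATE_FLOOR)
    lower = min(upper, 0.0) - 45.0 / rate
    pts = [0.0] if lower < 0.0 < upper else None

    def f_re(x):
        return np.exp(a.real * x) * np.cos(a.imag * x) * kernel(x)

    def f_im(x):
        return np.exp(a.real * x) * np.sin(a.imag * x) * kernel(x)

    re, _ = integrate.quad(f_re, lower, upper, points=pts, limit=400,
                           epsabs=_EPSABS, epsrel=_EPSREL)
    if a.imag == 0.0:
        return complex(re, 0.0)
    im, _ = integrate.quad(f_im, lower, upper, points=pts, limit=400,
                           epsabs=_EPSABS, epsrel=_EPSREL)
    return complex(re, im)


@dataclass
class EvansEvaluation:
    """Value of the Evans function and its two pathway components."""

    lam: complex
    E1: complex
    E2: complex

    @property
    def E(self) -> complex:
        return self.E1 + self.E2 - 1.0


def _slope_at_threshold(front: TravelingFront) -> float:
    """Cached ``U'(0)`` from the speed-index identity (not finite-differenced)."""
    cached = getattr(front, "_uprime0", None)
    if cached is None:
        cached = front.slope_at_threshold()
        front._uprime0 = cached
    return cached


def evans(lam: complex, front: TravelingFront) -> EvansEvaluation:
    """Evaluate the Evans function at a point of ``Re lambda > -1``."""
    lam = complex(lam)
    if lam.real <= _DOMAIN_EDGE:
        raise ValueError(
            f"lambda={lam} is on or beyond the essential spectrum Re lambda = -1")
    mu0 = front.mu0
    uprime0 = _slope_at_threshold(front)
    if uprime0 <= 0:
        raise ValueError("front slope U'(0) must be positive for the Evans function")
    p = front.params

    s1 = 0.0 + 0.0j
    for c, w in front.xi.items():
        a = ((lam + 1.0) * c - mu0) / (c * mu0)
        s1 += w * _complex_exp_tail(front.K, a, 0.0)
    E1 = 1.0 - p.alpha / (mu0 * uprime0) * s1

    s2 = 0.0 + 0.0j
    for tau, w in front.eta.items():
        a = (lam + 1.0) / mu0
        s2 += w * np.exp(tau) * _complex_exp_tail(front.W, a, -mu0 * tau)
    E2 = 1.0 - p.beta / (mu0 * uprime0) * s2

    return EvansEvaluation(lam=lam, E1=E1, E2=E2)


def evans_derivative_at_zero(front: TravelingFront, h: float = 1e-5) -> float:
    """Centered finite-difference ``E'(0)`` along the real axis.

    Positive for every valid front: the neutral translation eigenvalue at
    the origin is simple.
    """
    ep = evans(+h, front).E.real
    em = evans(-h, front).E.real
    return (ep - em) / (2.0 * h)


class ContourError(RuntimeError):
    """The Evans function vanishes on (or too close to) the requested contour."""


@dataclass
class ZeroCount:
    """Argument-principle zero count inside a rectangular contour."""

    rectangle: tuple  # (re_min, re_max, im_min, im_max)
    winding_number: int
    samples_used: int


def _rectangle_path(rect: tuple, n_per_edge: int) -> np.ndarray:
    re0, re1, im0, im1 = rect
    corners = [complex(re0, im0), complex(re1, im0),
               complex(re1, im1), complex(re0, im1), complex(re0, im0)]
    pts = []
    for a, b in zip(corners[:-1], corners[1:]):
        t = np.linspace(0.0, 1.0, n_per_edge, endpoint=False)
        pts.append(a + (b - a) * t)
    return np.concatenate(pts + [np.array([corners[0]])])


def count_evans_zeros(front: TravelingFront, rect: tuple,
                      n_per_edge: int = 32, max_refine: int = 14,
                      zero_tol: float = 1e-8) -> ZeroCount:
    """Count Evans-function zeros inside a rectangle by phase accumulation.

    The contour image is sampled and segments are bisected until consecutive
    phase steps are below pi/2; the winding number is the accumulated phase
    divided by 2 pi.  If |E| falls below ``zero_tol`` at a sample the
    rectangle is nudged outward (three attempts) before giving up.
    """
    re0, re1, im0, im1 = rect
    if re0 <= -1.0 or re1 <= re0 or im1 <= im0:
        raise ValueError(f"invalid rectangle {rect}: must lie in Re lambda > -1")

    for attempt in range(4):
        pts = list(_rectangle_path(rect, n_per_edge))
        vals = [evans(z, front).E for z in pts]
        if min(abs(v) for v in vals) < zero_tol:
            delta = 10.0 ** (-3 + attempt)
            rect = (max(re0 - delta, -1.0 + 1e-6), re1 + delta,
                    im0 - delta, im1 + delta)
            re0, re1, im0, im1 = rect
            continue
        try:
            total, used = _accumulate_phase(front, pts, vals, max_refine, zero_tol)
        except ContourError:
            delta = 10.0 ** (-3 + attempt)
            rect = (max(re0 - delta, -1.0 + 1e-6), re1 + delta,
                    im0 - delta, im1 + delta)
            re0, re1, im0, im1 = rect
            continue
        winding = int(round(total / (2.0 * np.pi)))
        return ZeroCount(rectangle=rect, winding_number=winding, samples_used=used)
    raise ContourError(f"Evans function vanishes near the contour {rect} "
                       "after 3 nudges")


def _accumulate_phase(front, pts, vals, max_refine, zero_tol):
    """Sum phase steps along the closed polyline, bisecting large steps."""
    total = 0.0
    used = len(pts)
    for k in range(len(pts) - 1):
        total += _phase_step(front, pts[k], pts[k + 1], vals[k], vals[k + 1],
                             max_refine, zero_tol)
    return total, used


def _phase_step(front, za, zb, va, vb, depth, zero_tol):
    step = np.angle(vb / va)
    if abs(step) < np.pi / 2.0:
        return step
    if depth == 0:
        raise ContourError(f"phase step refinement exhausted near {za}")
    zm = 0.5 * (za + zb)
    vm = evans(zm, front).E
    if abs(vm) < zero_tol:
        raise ContourError(f"Evans function vanishes at contour sample {zm}")
    return (_phase_step(front, za, zm, va, vm, depth - 1, zero_tol)
            + _phase_step(front, zm, zb, vm, vb, depth - 1, zero_tol))


@dataclass(frozen=True)
class EssentialSpectrum:
    """The essential spectrum: the vertical line ``Re lambda = -1``."""

    real_part: float = -1.0
    description: str = ("vertical line Re lambda = -1: bounded solutions of "
                        "mu psi' + (lambda+1) psi = 0 exist only there")

    def contains(self, lam: complex, tol: float = 1e-9) -> bool:
        return abs(complex(lam).real - self.real_part) <= tol


def essential_spectrum() -> EssentialSpectrum:
    """Metadata describing the essential spectrum (never destabilising)."""
    return EssentialSpectrum()


class DegenerateLinearizationError(ZeroDivisionError):
    """alpha*K(0) + beta*W(0) = 0: the standing-front linearisation degenerates."""


@dataclass
class CharacteristicEvaluation:
    """Residual of the standing-front characteristic equation at ``lambda``."""

    lam: complex
    value: complex
    sign_factor: int


def _standing_coefficients(K0: float, W0: float, alpha: float, beta: float,
                           magnitude_normalisation: bool):
    d = alpha * K0 + beta * W0
    if d == 0.0:
        raise DegenerateLinearizationError(
            "alpha*K(0) + beta*W(0) = 0; cannot normalise the linearisation")
    sign = 1
    if magnitude_normalisation:
        sign = int(np.sign(d))
        d = abs(d)
    return alpha * K0 / d, beta * W0 / d, sign


def standing_characteristic(lam: complex, K0: float, W0: float, alpha: float,
                            beta: float, eta: AtomicDistribution,
                            magnitude_normalisation: bool = False) -> CharacteristicEvaluation:
    """Residual ``lambda + 1 - aK - aW sum_j w_j exp(-lambda tau_j)``.

    The verbatim linearisation divides by ``d = alpha K(0) + beta W(0)``,
    assumed positive.  With ``magnitude_normalisation=True`` the division is
    by ``|d|`` instead — a documented extension for inverted-Mexican-hat
    feedback where ``d < 0`` — which flips the sign of both coefficients.
    """
    lam = complex(lam)
    aK, aW, sign = _standing_coefficients(K0, W0, alpha, beta, magnitude_normalisation)
    delay_sum = sum(w * np.exp(-lam * tau) for tau, w in eta.items())
    value = lam + 1.0 - aK - aW * delay_sum
    return CharacteristicEvaluation(lam=lam, value=value, sign_factor=sign)


def standing_auxiliary_f(lam: float, K0: float, W0: float, alpha: float, beta: float,
                         eta: AtomicDistribution,
                         magnitude_normalisation: bool = False) -> float:
    """Real auxiliary function whose unique root on ``(-1, inf)`` is 0."""
    return standing_characteristic(lam, K0, W0, alpha, beta, eta,
                                   magnitude_normalisation).value.real


def find_standing_real_root(K0: float, W0: float, alpha: float, beta: float,
                            eta: AtomicDistribution,
                            bracket: tuple = (-1.0 + 1e-6, 10.0),
                            magnitude_normalisation: bool = False) -> float:
    """Bisection root of the auxiliary function on a bracket within ``(-1, inf)``.

    For the verbatim (positive-slope) normalisation the function is strictly
    increasing and the root is exactly 0.
    """
    lo, hi = bracket
    if lo <= -1.0:
        raise ValueError("bracket must lie within (-1, inf)")

    def f(x):
        return standing_auxiliary_f(x, K0, W0, alpha, beta, eta,
                                    magnitude_normalisation)

    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"no sign change of the auxiliary function on {bracket}: "
            f"f({lo})={f(lo):.6g}, f({hi})={f(hi):.6g}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-14))


def scan_standing_complex_roots(K0: float, W0: float, alpha: float, beta: float,
                                eta: AtomicDistribution,
                                region: tuple = (0.0, 3.0, -10.0, 10.0),
                                grid: tuple = (120, 240),
                                magnitude_normalisation: bool = False,
                                newton_tol: float = 1e-10) -> list:
    """Complex roots of the characteristic equation with ``Re lambda > 0``.

    A modulus grid scan over the region locates candidate minima of the
    residual, each refined by a damped two-variable Newton iteration on
    (Re, Im) with central-difference Jacobian.  For the verbatim
    normalisation with positive coefficients the modulus bound
    ``|lambda + 1| > 1 >= |sum w exp(-lambda tau)|`` on ``Re lambda > 0``
    excludes roots, and the scan returns an empty list.
    """
    re0, re1, im0, im1 = region
    if re0 <= -1.0:
        raise ValueError(f"region {region} must lie within Re lambda > -1")

    def residual(x, y):
        v = standing_characteristic(complex(x, y), K0, W0, alpha, beta, eta,
                                    magnitude_normalisation).value
        return np.array([v.real, v.imag])

    xs = np.linspace(re0, re1, grid[0])
    ys = np.linspace(im0, im1, grid[1])
    mod = np.empty((grid[0], grid[1]))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            r = residual(x, y)
            mod[i, j] = np.hypot(r[0], r[1])

    # local minima of the modulus surface (interior, 4-neighbourhood)
    cands = []
    interior = mod[1:-1, 1:-1]
    is_min = ((interior <= mod[:-2, 1:-1]) & (interior <= mod[2:, 1:-1])
              & (interior <= mod[1:-1, :-2]) & (interior <= mod[1:-1, 2:]))
    for i, j in zip(*np.nonzero(is_min)):
        cands.append((xs[i + 1], ys[j + 1]))

    roots = []
    h = 1e-7
    for x0, y0 in cands:
        x, y = x0, y0
        for _ in range(100):
            r = residual(x, y)
            if np.hypot(*r) < newton_tol:
                break
            jac = np.column_stack([
                (residual(x + h, y) - residual(x - h, y)) / (2 * h),
                (residual(x, y + h) - residual(x, y - h)) / (2 * h),
            ])
            try:
                dx, dy = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError:
                break
            x += 0.5 * dx
            y += 0.5 * dy
        else:
            continue
        # strictly positive real part; the neutral root at the origin is
        # always present and is not an instability
        if np.hypot(*residual(x, y)) < newton_tol and x > 1e-6:
            root = complex(x, y)
            if all(abs(root - r0) > 1e-6 for r0 in roots):
                roots.append(root)
    return sorted(roots, key=lambda z: (z.real, z.imag))
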