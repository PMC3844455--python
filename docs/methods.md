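# Methods

This note records the model the package implements, the numerical choices
behind each module, and what the simulations do and do not establish.

## Model and assumptions

The field `u(x,t)` is the mean membrane potential of a rate-coding
population on the line, with Heaviside firing rate `H(u − θ)` using the
half-value convention `H(0) = 1/2`.  Two pathways feed it: intracortical
coupling `K` with distance-dependent transmission delay `|x−y|/c`, and
nonlocal feedback `W` with distance-independent delay `τ`.  Speeds and
delays carry discrete probability distributions; continuous densities are
represented by the user as weighted quadrature atoms, which makes every
speed-index and Evans integral a finite sum of one-dimensional integrals.

Standing assumptions checked by `check_assumptions`:

* threshold window `0 < 2θ < α + β` (traveling) or `α + β = 2θ` (standing);
* positive crossing slope `α K(0) + β W(0) > 0`;
* unit-mass, even-mass-split, exponentially bounded kernels
  (`|K| + |W| ≤ C e^{−ρ|x|}`);
* finite `1/c` moment of the speed density and finite `e^τ` moment of the
  delay density (automatic for atomic distributions);
* the front-existence inequality
  `∫₀^∞ [αK + βW] e^{x/c₀} dx > (α+β)/2 − θ`.

The envelope clause is reported informationally (the constant `C` is
estimated as the sampled maximum of `|K(x)| e^{ρ|x|}`), never fatally.  A
divergent quadrature in the existence clause — a kernel tail decaying no
faster than `e^{−x/c₀}` — is reported as a failed clause rather than an
exception; the shipped Mexican-hat illustration (`r = 0.4`, `ρ = 0.2`,
`c₀ = 5`) is exactly such a case.  The clause
`∫_{−∞}^0 |x| K dx ≥ 0` is trivially true for the shipped families and is
evaluated and reported verbatim.

Kernel classes: A (nonnegative), B (nonnegative core, nonpositive tails —
Mexican hat), C (the reverse).  `classify_kernel` samples 4001 points over
`[−probe_radius, probe_radius]` (default 25), treats `|K| < 1e−12` as zero,
and for B/C refines the sign-change radius `M` by bisection.

## Parameters that matter

| parameter | meaning | default / convention |
|---|---|---|
| `α`, `β` | synaptic weights of the two pathways | model input, `α + β > 0` |
| `θ` | firing threshold | model input, `> 0` |
| `s`, `r`, `ρ` | difference-of-exponentials kernel shape | `ρ = 1` when unused (`r = 0`) |
| `σ` | single-exponential footprint width | model input |
| `c₀` | slowest speed atom; upper bound for `μ₀` | derived from `ξ` |
| `X_max` | improper-integral truncation | `max(50, 40/ρ_min)`; tail `< 1e−17` |
| quadrature | adaptive per smooth piece | `epsrel 1e−10`, `epsabs 1e−12` |

All quantities are dimensionless; time and space units are absorbed by the
scaling of the membrane time constant and kernel range.

## Front construction

The standing front is the cumulative of `αK + βW`; its crossing slope is
`αK(0) + βW(0)`.  For inverted-Mexican-hat feedback this slope is negative:
the closed-form "front" is then not monotone and the threshold-crossing
picture behind it is violated.  We construct the profile verbatim and flag
it (`monotone = False`) rather than guessing a corrected profile; its
dynamics are studied by simulation only.

The traveling front is evaluated from its four-term integral
representation.  The moving-frame warp `c x/(c + s(x) μ)` makes the memory
integrand *discontinuous* at the origin (the prefactor jumps between
`c/(c−μ)` and `c/(c+μ)`), so every quadrature is split at `x = 0`
(`scipy.integrate.quad` with an interior breakpoint).  Exponential memory
weights bound all tails, truncated at 45 e-folds.

`tabulate` provides a fast grid evaluation for simulation initial
conditions: the memory integrals obey the one-step recursion
`I(z + Δ) = e^{−Δ/μ} I(z) + local`, with the local piece by Simpson's rule
per cell and one-sided node values (shift `±1e−9`) around the origin jump;
the warped cumulative accumulates the same way.  Agreement with direct
quadrature is at the 1e−6 level on the default grid (Δ = 0.01), ample for
initial conditions perturbed by noise of amplitude 0.025.  Direct
quadrature remains the reference path and is what the tests assert against.

## Wave-speed solver

`solve_wave_speed` pre-scans the residual `φ(μ) − ((α+β)/2 − θ)` on 256
points of `(ε, c₀(1 − 1e−6))`, combining a geometric subdivision (resolving
roots arbitrarily close to 0, where `φ → 0`) with a linear one (uniform
resolution near `c₀`, where class-C configurations may host several roots),
then polishes every bracketed sign change with Brent's method
(`xtol 1e−12`) — bracketed bisection accelerated by secant/inverse-quadratic
steps.  For monotone `φ` (classes A and B) the root is unique; if several
sign changes appear, all roots are reported, the largest is returned, and
the solution is flagged `multiple_roots`.  A configuration whose residual
never changes sign raises an error carrying the attained `φ` range.

Sensitivity scans rebuild the scanned two-point distribution as atoms
`(v, κv)` with equal weights (fixed fast/slow ratio `κ`, default 2) and
re-solve per point; unsolvable points are recorded as NaN, not raised.
Derivatives with respect to `μ` are centred finite differences — implicit
differentiation of `φ` with respect to distribution parameters is out of
scope.  The class-C turning points of the index functions are estimated by
sign-flip interpolation on the scan grid; no accuracy claim is attached to
them.

## Spectral stability

`U'(0)` entering the Evans normalisation is computed from the speed-index
identity `μ₀ U'(0) = φ₁(μ₀) + φ₂₂(μ₀)`, not finite-differenced — this is
what makes `E(0) = 0` exact up to quadrature error.  Complex integrands are
integrated as separate real and imaginary adaptive quadratures; truncation
follows the λ-dependent decay rate `Re a + ρ` with a floor of `1e−3`.

One identity deserves a caution: the mixed-pathway equivalence
`E(λ) = 1 − [φ₁(γμ₀) + φ₂₂(γμ₀)] / [φ₁(μ₀) + φ₂₂(μ₀)]`, `γ = 1/(λ+1)`,
holds exactly only when the feedback integral's lower limit is pinned at
the *base front's* delay offset `−μ₀τ` while the exponential rate is
rescaled — the plain reparametrised `φ₂₂(γμ₀)` moves the limit too and
deviates at order `β(1−γ)μ₀τ`.  `phi22(..., offset_speed=μ₀)` exposes the
pinned form; the equivalence then holds to ~1e−12 and is asserted in tests.

Zero counting uses phase accumulation along a rectangular contour:
segments are bisected until consecutive phase steps are below `π/2`, and
the winding number is the accumulated phase over `2π`.  If `|E|` drops
below `1e−8` at a sample the rectangle is nudged outward (three attempts)
before a contour error is raised.  Doubling the initial sampling does not
change any count asserted in the tests.

For the standing front the characteristic residual
`λ + 1 − a_K − a_W Σ w_j e^{−λτ_j}` divides by `d = αK(0) + βW(0)`,
assumed positive.  For class-C feedback `d < 0`; as a documented extension
(off by default) `magnitude_normalisation=True` divides by `|d|`, flipping
the sign of both coefficients.  The real root search is bracketed bisection
on `(−1, ∞)` where the auxiliary function is strictly increasing for the
verbatim normalisation (unique root 0).  The complex scan minimises the
residual modulus on a grid and refines candidates by a damped two-variable
Newton iteration (central-difference Jacobian, damping 0.5, tolerance
1e−10); roots with real part below `1e−6` are discarded as the neutral
eigenvalue.  Whether the eigenvalue relation needs complex `γ` with
`|γ| < 1` or only real `γ` is probed numerically: for every tested
configuration the complex grid scan finds no off-axis roots in the right
half-plane, consistent with the real-`γ` argument.

The characteristic-equation machinery does *not* reproduce the oscillatory
instability of the standing front under delayed class-C feedback — for the
inverted-hat case the linearisation's positivity assumption is violated and
both normalisations yield no unstable roots.  That instability is
established here by direct simulation only (below); no
characteristic-equation mechanism is asserted for it.

## Simulation

Euler-forward stepping of the field on a ring of length `L` with
minimal-image distance `d(x,y) = min(|x−y|, L − |x−y|)`; the kernel is
evaluated at ring distance, which differs from a truncated line domain by
`O(e^{−ρL/2})`.  Defaults are `Δt = 0.02`, `L = 60`, 600 intervals.  The
history buffer spans `max_j τ_j + (L/2)/min_i c_i` plus two steps; delayed
reads round to the nearest step (optionally linear in time — the two agree
to a few percent, consistent with the first-order stepper dominating the
error).  The default spatial rule is a deterministic Riemann sum on the
grid; a seeded Monte-Carlo mode redraws uniform grid offsets each step
(adaptive importance sampling is out of scope) and agrees with the Riemann
rule to better than 1% on the measured front speed.

Initial conditions: a step (0 on the left half-ring, 1 on the right,
constant over the pre-history) or the analytic traveling front with uniform
noise of amplitude 0.025 on a pre-history window of length 12; history
beyond the supplied window holds the analytic front.  On a ring the
wrapped front necessarily carries a second, falling interface; since
`θ < (α+β)/2` the quiescent gap is invaded from both sides, so speed
measurements place the front at three-quarters of the ring and fit within
a window before the interfaces collide.  Problem sizes in the tests
(300 cells for speed recovery over `t ≤ 20`, 600 cells for the standing
instability over `t ≤ 60`) are the smallest at which the reported checks
are comfortably converged: halving `Δt` and doubling the grid changes the
measured speed by under 1%, and the sharp feedback core (`e^{−10|x|}`,
width 0.1) needs the `dx = 0.1` grid to be resolved at all — the standing
instability visibly disappears at `dx = 0.2`.

Front tracking interpolates the rising threshold crossing sub-grid,
unwraps it with period `L`, and fits a least-squares slope.  Oscillation
detection linearly detrends a probe trace over a window (default: second
half of the run), requires the dominant rFFT component to complete at
least two cycles, to dominate the remaining spectrum (3x the median
magnitude), and to exceed ten times the noise floor peak-to-peak.  The
probe must sit near the (slowly drifting) interface: the instability is
localised where the field crosses threshold.

What the simulations show — and don't: recovery of the analytic wave speed
to 5% at the stated resolution, monotone speed trends under speed/delay
scans, absence of oscillation in the wake of a stable traveling front, and
oscillatory instability of the standing front under delayed inverted-hat
feedback (single delay 2.0 and two-point delays 1.3/2.6 alike).  They are
idealisations: Heaviside rates, one spatial dimension, a single synaptic
time scale, no biological noise beyond the initial perturbation, and a
periodic domain standing in for an infinite one.

## Known limitations

* Kernels beyond the two shipped exponential families enter as user
  callables with a stated envelope exponent; asymmetric kernels are not
  modelled.
* Traveling pulses, multi-bump states and two-dimensional domains are out
  of scope, as are smooth sigmoid firing rates.
* The analytic instability threshold for delayed class-C feedback is not
  derived; the package reports what simulation and the (inapplicable)
  characteristic equation each say, separately.
* Resolvent-based spectral computations are not implemented; the operator
  spectrum is accessed only through the Evans function it induces.
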