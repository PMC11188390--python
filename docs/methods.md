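# Methods

## Model family

All models are scalar DDEs with one constant delay,

    dx/dt = f(x(t − τ)) − b x(t),        τ > 0,

with decreasing (negative-feedback) production `f`. Kinds:

| kind            | f(x)                | decay | state domain | threshold limit of |
|-----------------|---------------------|-------|--------------|--------------------|
| `sigmoidal`     | −tanh(κx)           | b = 0 | ℝ            | —                  |
| `hill`          | 1/(1 + xᵖ)          | b > 0 | x > 0        | —                  |
| `wazewska`      | a·e^(−cx)           | b > 0 | x > 0        | —                  |
| `threshold`     | 1 if x ≤ 1 else 0   | b > 0 | ℝ            | `hill`, p → ∞      |
| `sign`          | −sign(x)            | b = 0 | ℝ            | `sigmoidal`, κ → ∞ |
| `wright_reduced`| u' = e^(−u(t−τ)) − b₁          | — | ℝ | `hill` near its lower Hopf point |
| `upper_reduced` | u' = −e^(u(t−τ)) − u − b₁      | — | ℝ | `hill` near its upper Hopf point |

The reduced equations are the leading-order strong-feedback descriptions of
the Mackey-Glass dynamics near its two Hopf points. Their variables map back
to the full model through

    lower: x = 1 + (ln p + u)/p,   b = b₁/p
    upper: x = 1 − (ln p)/p + u/p, b = 1 + (ln p + b₁)/p

implemented as exact, mutually inverse lift/project pairs. The sign
convention of the upper reduced equation (and of its steady-state relation
b₁ = −(u + eᵘ)) is fixed by requiring that its linearization yield the Hopf
conditions cos z = −e^(−u), τ = −z/tan z, and that the lifted Hopf point
reproduce the upper-branch approximation below; both checks are enforced in
the test suite.

Parameter positivity is validated at construction; right-hand-side evaluation
only guards the state domain (hot-loop efficiency). The Hill term is
evaluated in log space with the exponent product clamped at ±700, so Hill
exponents of several hundred are evaluated without overflow. Exactly at a
threshold the production is defined to be **on** (a measure-zero convention,
fixed for reproducibility).

## Integration

**Smooth kinds** use the method of steps with classical RK4 on a fixed mesh
of `steps_per_delay` intervals per delay. Because the step divides τ exactly,
the derivative discontinuities that propagate from t = 0 in steps of τ always
land on mesh nodes, preserving fourth-order accuracy between them. The
delayed state at stage midpoints is read from the stored cubic-Hermite dense
output of the previous delay interval (midpoint formula
(x_a + x_b)/2 + h(d_a − d_b)/8, itself O(h⁴)). No adaptive stepping:
reproducibility and exact discontinuity bookkeeping outweigh speed at these
problem sizes. Divergence (|x| ≥ 1e100, or NaN) and domain exit (x ≤ 0 for
the positive-state kinds) raise an error reporting the failure time.

**Threshold/sign kinds** are integrated exactly. Between switching events the
equation is x' = c − bx with constant c, solved as an explicit exponential
(straight line when b = 0). The state's own crossings of the threshold level
are found in closed form within each segment and propagated forward by τ as
switching events, so the only approximation anywhere is the dense interpolant
between recorded nodes; node values are exact. Both integrators agree on
limit-cycle extrema to ~1e−14, and the closed-form cycle quantities are
reproduced to 1e−8 or better.

**History (initial data)**: the model family does not prescribe initial data,
so the default is a constant history at the steady state plus a 1%
perturbation (+0.01 absolute for the kinds oscillating about zero; constant
0.5 for the threshold kind, which has no steady state in its oscillatory
regime b < 1). A perturbed steady state reaches the unique attractor fastest.
Constant, linear, and arbitrary-callable histories are supported.

**Defaults**: `steps_per_delay = 200` (step-halving to 400 changes measured
periods by < 1e−5 relative); horizon 400τ near Hopf points, where critical
slowing down makes transients long, and ~100τ elsewhere;
`transient_fraction = 0.5`.

## Oscillation summary

The post-transient window is characterized by: the time-weighted mean level;
the period as the mean spacing of successive upward crossings of that level,
each crossing refined by root-finding on the dense interpolant; extrema as
the exact extrema of the piecewise cubic (closed-form roots of the quadratic
derivative per interval, which also handles the corner extrema of the
threshold kinds exactly). `converged` requires the last three cycle durations
to agree within 0.1%. A trajectory is reported as **not sustained** when
fewer than three complete cycles survive the transient, or when the
peak-to-peak amplitude of the second half of the window falls below half of
the first half (decaying oscillation) or below an absolute/relative floor
(quiescent trajectory); in that case the period fields are None. Periods are
reported both in absolute time and in units of τ; comparisons of
near-Hopf Mackey-Glass periods are made in units of τ, consistent with
2π/(ωτ) at the computed Hopf point (≈ 3.87 at p = 20, τ = 1.8).

## Hopf analysis

For the Mackey-Glass equation the steady state solves x(1 + xᵖ) = 1/b
(bracketed root-finding on the logarithm, relative tolerance 1e−12; the left
side is strictly increasing so the root is unique). The characteristic
equation λ + A e^(−λτ) + b = 0 with A = p xᵖ⁻¹/(1 + xᵖ)² yields, at λ = iω
and z = ωτ:

    xᵖ = −1/(p cos z + 1)  (> 0 requires cos z < −1/p),
    τ  = −z/(b tan z).

Sweeping z over (arccos(−1/p), π) traces the closed Hopf boundary; τ(z)
diverges at both ends, so at fixed τ above the boundary minimum there are
exactly two roots, found by a 400-subdivision bracketing scan plus bisection
(the scan is needed because τ(z) is not monotone; branch labels: "lower" =
smaller z and b, "upper" = b near 1). Every computed point satisfies the
characteristic residual |iω + A e^(−iωτ) + b| < 1e−8 (measured ~1e−12).

Large-p approximations: lower branch b ≈ π/(2pτ); upper branch parametrically
z₀ solving −z₀/tan z₀ = τ on (π/2, π) (bisection to 1e−12), x₁ = −ln(−cos z₀),
b = 1 + (ln p − x₁ − e^(x₁))/p. These coincide exactly with the reduced
equations' Hopf points (b₁ = π/(2τ) and b₁ = −(u + eᵘ) with u = x₁) lifted
through the parameter maps — an algebraic identity the tests check at random
τ. At p = 20, τ = 1.8 the numeric points are b = 0.0478 and 1.0426; the
approximations give 0.0436 (9% low, an O(1/p) error) and 1.0464 (0.4% high).

## Strong-feedback closed forms

* Sawtooth outer solution: the 4τ-periodic piecewise-linear wave with extrema
  ±τ. Uniform approximation: τ − κ⁻¹ln(2 cosh κ(t−τ)) on (0, 2τ) and its odd
  image, evaluated overflow-free via ln(2 cosh y) = |y| + ln(1 + e^(−2|y|));
  its extrema are ±(τ − κ⁻¹ln 2) and its residual error is O(e^(−κ))
  (measured 5e−4 against simulation at κ = 10, τ = 0.4). The phase convention
  starts the cycle at an upward zero crossing.
* Local Hopf amplitude 2√((τ−τ₀)/τ₀), valid while (τ−τ₀)/τ₀ ≤ 1/κ (the
  validity flag uses exactly this cutoff; the law gives the order relation,
  the constant 1 is a documented choice). **Unit convention**: this is the
  amplitude of the rescaled state y = κx — substituting y and s = κt gives
  the parameter-free form dy/ds = −tanh(y(s − κτ)) to which the law applies;
  divide by κ for the amplitude of x (verified against simulation to 2% at
  (τ−τ₀)/τ₀ = 0.005). Sweep overlays perform this rescaling.
* Threshold cycle: x_min = e^(−bτ), x_max = (1 − 1/b)e^(−bτ) + 1/b, period
  P = −b⁻¹ ln[x_min(1 − b x_max)/(x_max(1 − b x_min))]. The period grouping
  is pinned down by two independent derivations that the tests compare at
  machine precision: the closed form, and the phase-duration sum
  2τ + Δ₁ + Δ₂ with Δ₁ = −b⁻¹ln[(1−b)/(1−b·x_min)] (rise back to the
  threshold) and Δ₂ = b⁻¹ln x_max (decay to the threshold). The segment
  identity (1 − b·x_max) = (1 − b)·x_min holds algebraically and is
  property-tested over random (b, τ). For b ≥ 1 the cycle does not exist
  (the period diverges like −ln(1 − b) as b → 1⁻).

## Sweeps and fixtures

Sweeps integrate each grid point from the perturbed steady state or,
warm-started, from a constant history at the previous point's final state
(the attractor is unique in the regimes studied; warm and cold starts agree
to 1e−4 and the tests check it). Per-point failures are logged and skipped.
Overlays share the numeric grid and the long-format (param, quantity, value,
source) schema; values round-trip bit-identically through CSV (written via
`repr`) and JSON. The synthetic fixture generator produces sine, damped,
sawtooth and square trajectories of known period/extrema (deterministic given
a seed) for validating the summarizer; it emulates clean limit-cycle records
with optional additive Gaussian noise, not the transient approach, drift, or
non-stationarity of real measured time series — passing summarizer tests on
fixtures therefore validates the extraction machinery, not robustness to
arbitrary experimental data.

## Problem sizes used in the tests

Long runs use 400 delay intervals at 200 steps per delay (80k steps, well
under a second each); sweep grids use 2–6 points; the large-delay
demonstration (τ = 100) runs 20 delay intervals at 400 steps per delay. The
strong-feedback convergence study uses p ∈ {200, 400}, where the measured
O(1/p) error (~2.5/p on x_min) makes the rate assertion sharp.

## Known limitations

* One constant delay; no state-dependent or distributed delays, no networks
  of coupled units, no stochastic terms.
* Only the stable 4τ-periodic solution of the sign model is treated; the
  unstable 4τ/(4n+1) family and higher Hopf branches (larger z windows) are
  out of scope, as are Floquet analysis and normal-form coefficients.
* The fixed-step integrator is not stiff-stable: very large b (h·b ≳ 2.8)
  requires more steps per delay, and divergence is detected rather than
  prevented.
* At p = 20 the Heaviside-limit formulas describe the cycle to O(1/p):
  expect ~2% on the period, ~5% on maxima, and an O(ln p/p) ≈ 0.15 absolute
  lift of the minima — the reduced equations exist precisely to capture the
  near-Hopf behavior the limit formulas miss.
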