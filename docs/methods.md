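# Methods

## Model and assumptions

A single species occupies two patches coupled by migration. Patch 1 receives
an impulsive toxicant input: at every time nγ (n = 1, 2, …) the environmental
concentration c_e jumps by b, and between pulses it decays exponentially at
rate h. Organisms in patch 1 accumulate a body burden c_o by uptake (rate f)
and lose it by egestion and metabolism (rates g, m); the burden depresses
their growth rate linearly with coefficient δ. Patch 2 is clean. Emigration
from patch 1 responds to the *environmental* concentration through a
saturating type-III term, d₁₂(t) = d₁₂(1 + ρ c_e²/(1 + α c_e²)): amplification
is negligible at low pollution, grows sigmoidally, and saturates at
d₁₂(1 + ρ/α). Return migration d₂₁ is constant.

Environmental stochasticity enters through the growth rates: each r_i(t) is an
Ornstein–Uhlenbeck process reverting to r_ie at speed μ_i with intensity ξ_i.
The model uses the pathwise OU solution — deterministic transient
r_ie + (r_i0 − r_ie)e^{−μ_i t} plus white noise of amplitude
σ_i(t) = ξ_i/√(2μ_i)·√(1 − e^{−2μ_i t}) — substituted into the population
equations, rather than simulating the rate as an extra state. The two
Brownian motions are independent; there is no demographic noise.

Concentrations are dimensionless fractions, which forces f ≤ g + m and
b ≤ 1 − e^{−hγ}; both bounds are validated at construction (configurable down
to a warning for exploratory use).

## Exact toxicokinetics

The pulsed subsystem is linear, so the package never integrates it
numerically. Between pulses, with post-pulse environmental value c_e(nγ⁺),

    c_e(nγ+s) = c_e(nγ⁺) e^{−hs},
    c_o(nγ+s) = c_o(nγ) e^{−(g+m)s} + f c_e(nγ⁺) (e^{−(g+m)s} − e^{−hs})/(h−g−m).

When |h − (g+m)| < 1e−12 the generic formula is replaced by its analytic
limit, c_o(nγ+s) = (c_o(nγ) + f c_e(nγ⁺)s) e^{−hs}, removing a spurious
singularity. States reported *at* a pulse instant are pre-pulse (left-limit)
values, matching the jump convention Δc_e(t) = c_e(t⁺) − c_e(t).

The γ-periodic orbit is written down in closed form
(c̃_e(0) = b/(1−e^{−hγ}), and c̃_o(0) from the fixed point of the one-period
affine map). Its body-burden extrema are found from the unique stationary
point of A e^{−(g+m)s} + B e^{−hs} on (0, γ) plus the endpoints; a 10⁴-point
grid cross-checks the closed form and would take over only if it ever won by
more than 1e−9 (a safety net, not an expected path). Period averages are
closed forms as well: ⟨c̃_o⟩ = fb/(h(g+m)γ), and the saturating average
η = ln[((1−e^{−hγ})² + αb²)/((1−e^{−hγ})² + αb²e^{−2hγ})]/(2hγα). Both are
verified against adaptive quadrature of the orbit to 1e−8 in the tests.

## Threshold conventions

* Case selection in the extinction / persistence criteria compares the
  effective patch-1 rate with r₂e; an equality tie (tolerance 1e−12) selects
  the symmetric case (i).
* The extinction criterion's case (ii) uses d₁₂* (the migration rate at the
  environmental *maximum*) and case (iii) uses (d₁₂)_*; the persistence
  criterion mirrors the swap. This follows the theorem statements; the
  published worked numbers only reproduce under this reading.
* The permanence criterion's body-burden constant is read as c_o^M — the only
  extremum of that family that makes the condition conservative.
* The p-moment bound constants θᵢ are read as the reversion speeds μᵢ,
  consistent with the σ_i(t) limits.
* All criteria are reported as signed margins (expression minus its noise
  threshold), so downstream checks read only the sign. They are sufficient
  conditions: an all-false report is "inconclusive", not a survival verdict.

## Simulation

The population SDE is integrated by Euler–Maruyama on a uniform grid with the
toxicant forcing evaluated exactly on the grid (post-pulse values used for the
step across a pulse; the grid must contain every pulse instant, enforced as
γ/dt integer to 1e−9). Two positivity strategies are offered:

* **ppt-em** (default): EM step then truncation at a floor (default 1e−10,
  several orders below any density of interest). Simplest and robust.
* **log-em**: EM on (ln x₁, ln x₂) with Itô-corrected drifts,
  d ln x₁ = (r₁(t) − a₁x₁ − d₁₂(t) + d₂₁ x₂/x₁ − σ₁²(t)/2)dt + σ₁(t)dB₁.
  Exactly positive; the density ratios in the drift can be stiff when one
  patch is many orders of magnitude below the other, so ppt-em remains the
  default.

Default step dt = γ/200 = 0.005 for the published pulse period γ = 1. The
strong self-convergence rate measured for ppt-em is ≈ order 1/2 (error ratio
per halving of dt within [1.2, 1.7]), as expected for EM with multiplicative
noise; with ξ = 0 both schemes reduce to first-order deterministic Euler and
are checked against an adaptive RK reference.

Ensembles are vectorised across paths in chunks of 100, but each path p draws
its Gaussian increments from its own stream seeded with `seed + p`, so results
are independent of the chunking, reproducible path-by-path, and an ensemble's
first path is bitwise the single-path run with the same seed. A divergence
guard aborts with the offending step if a state becomes non-finite or the
total density exceeds 1e6 (impossible under the dissipative drift unless the
configuration is broken).

## Finite-horizon surrogates for asymptotic notions

The survival definitions are limits (t → ∞) and cannot be tested directly.
The summaries module uses documented surrogates: a path is flagged *extinct*
when the chosen density stays below a threshold (default 0.01) throughout the
final dwell span (default 20% of the horizon); *persistence in the mean* is a
positive windowed time average (default window: second half of the horizon,
level 0.05); permanence is reported descriptively via 5–95% quantile bands.
The Monte-Carlo experiments use horizon T = 300 with 200 paths (500 for the
moment bound), which keeps the full suite within a few minutes on one core
while leaving the qualitative outcomes far from their decision boundaries
(measured extinction fractions ≈ 0.99 vs the 0.9 criterion; persistent-path
fractions 1.0 vs 0.95).

## Parameter fixtures

Two published parameter sets are built in, each with per-panel noise/pulse/
migration variants. The second set does not restate the toxicokinetic rates;
they carry over from the first (f = 0.5, g = 0.3, m = 0.2, so f = g + m),
which is the only reading that reproduces its printed no-migration average
(−0.0825). Both share the initial state (x₁, x₂, c_o, c_e)(0) =
(0.8, 0.5, 0.2, 0.6). The base `set40` fixture completes the unstated noise
parameters with its first panel's values (μ = 0.1, ξ = 0.4, γ = 1, b = 0.1);
`set41` defaults to the no-migration panel (d₁₂ = d₂₁ = 0). The third panel
variant of the second set (`set41-fig2c`) is provided for completeness, but
its published margins are not reproducible from its stated parameters under
any reading we found, so no test asserts them.

## What the synthetic experiments do and do not show

The generator *is* the model: simulated data share its assumptions (log-normal
multiplicative noise, independent patch noises, exactly periodic pulses,
deterministic toxicokinetics). Passing tests show internal consistency between
the analytic thresholds and the simulated dynamics at the published parameter
sets; they do not validate the model against field data, nor the behaviour
under correlated noises, random pulse schedules, or toxicant uptake in the
clean patch, all of which are out of scope.

## Known limitations

* The threshold criteria are sufficient only; between the extinction and
  persistence margins lies a gap where the package honestly reports
  "inconclusive".
* EM with a floor is asymptotically positive in probability but not pathwise
  exact; use `log-em` where exact positivity matters.
* The migration amplification bound d₁₂(1+ρ/α) can be large for small α;
  stiff configurations may need a smaller dt than the default.
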