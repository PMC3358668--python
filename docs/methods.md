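# Methods

This note records the models, the statistical machinery, the numerical
choices, and the limits of what the bundled benchmarks establish.

## SDE simulation

Models are Itō SDEs `dX = b(t,X) dt + v(t,X) dW` with independent Brownian
components, integrated by the fixed-step Euler–Maruyama scheme
`X_{k+1} = X_k + b(t_k, X_k)·dt + v(t_k, X_k)·ΔŴ_k`. No adaptive or
higher-order (Milstein) stepping is offered: the statistical layer treats
the discrete scheme itself as the model being checked, and a fixed grid
keeps the Girsanov bookkeeping exact per step. Time is dimensionless, as
are the property bounds (e.g. `F[10](…)`).

**Measure perturbation.** A perturbed trajectory uses increments
`ΔŴ_k = ΔW_k + θ·dt` with `ΔW_k ~ Normal(0, dt)` and a constant,
per-trajectory shift θ. Constant shifts satisfy the Novikov condition
trivially and give the exponential-martingale weight in closed form:
`log Z_T = −θ·W_T − ‖θ‖²·T/2`, evaluated on the raw (natural-measure)
draws, which the engine retains precisely so the weight needs no inversion.
The weight is reported per trajectory (`log_weight`, 0 exactly when θ = 0)
but is not used inside the hypothesis test — the test relies on the
fairness bound instead (below).

**Perturbation policy.** Each sample draws θ fresh from the symmetric
uniform box `[−θ_max, +θ_max]^dim_noise`. Symmetry is the constructive
fairness argument: biases toward and away from any event are applied
equally often in the long run, driving the geometric mean of the implied
per-sample Radon–Nikodym derivatives toward 1. The bound η that enters the
test is *asserted* by the user, because the implied derivative of a
path-property event under a drift shift is not computable in closed form.
`check_fairness` verifies the geometric-mean condition only where
derivatives are explicit (the discrete fixture). θ_max has the units of
drift (state per unit time) on the Brownian scale; a useful heuristic is
to match it to `barrier / horizon` for threshold-crossing properties.

**Clamping.** Population models (`clamp_nonnegative=True`) clamp every
state component at 0 after each Euler step; events are counted on the
trajectory record. This is a modeling choice — the Euler scheme can
overshoot into negative populations that the continuous dynamics, whose
coefficients vanish at 0, never reach.

**Reproducibility.** One root seed; chunk j of any sampler draws from
`SeedSequence(root, spawn_key=(j,))` (Philox-backed `default_rng`), so the
outcome stream is a pure function of the root seed, independent of how many
samples the sequential test consumes. Single-trajectory `simulate(…, seed)`
is bit-reproducible in isolation; batch streams use one generator per chunk
and therefore differ from the single-path streams (both are deterministic).

## BLTL monitoring

Traces pair each state with a duration; the simulator emits `Δ_k = dt` with
a trailing 0. Semantics are two-valued on finite traces:

- `σ^k ⊨ x ~ v` compares the state-k value; equality is exact (tolerance
  0) — users who need a tolerance can write a conjunction of `<` and `>`.
- `φ₁ U[t] φ₂` at k needs a witness k+i with `φ₂`, `φ₁` at all strictly
  earlier offsets, and elapsed time `Σ_{0≤l<i} Δ_{k+l} ≤ t`. The sum runs
  over the durations *before* the witness: the time to reach it, not
  including its own duration. A bounded Until with no witness inside the
  trace is false; the CLI warns when a formula's accumulated bound exceeds
  the trace horizon, since such a verdict can be an artifact of truncation.
- `F[t] φ` desugars to `(φ ∨ ¬φ) U[t] φ` and `G[t] φ` to `¬F[t]¬φ` at
  parse time.

The production evaluator computes each subformula as a boolean vector over
all start indices: the Until verdict uses the *earliest* φ₂-witness not
preceded by a φ₁-violation (computed by a reversed running minimum), which
is sufficient because durations are non-negative, so any later witness is
reached no sooner. This makes monitoring O(trace length) per subformula. A
deliberately naive recursive transcription of the five rules
(`brute_force_satisfies`) is kept solely as a test oracle; the randomized
suite checks exact agreement between the two.

Grammar: `!` binds tighter than `&`, which binds tighter than `|`; Until is
non-associative and takes parenthesized operands.

## Sequential test

With a Beta(α, β) prior the Bayes factor for x successes in n trials is
`B = (1 − I)/I`, `I = I_{θ₀}(α + x, β + n − x)` (regularized incomplete
beta; the upper tail is computed through the complement identity
`I_{1−θ₀}(β+n−x, α+x)` so neither tail loses precision). All sequential
arithmetic is on log B; underflow of either tail yields an explicit ±∞
sentinel rather than an exception. Defaults: Beta(1,1) prior (flat,
non-informative), T = 100, η = 1, max_samples = 10⁶.

Two consequences of taking the prior-weighted likelihood ratio literally
(i.e. without dividing out the prior odds) deserve emphasis:

- With the flat prior and θ₀ = 1/2 it coincides with the Jeffreys Bayes
  factor.
- At n = 0 it equals the prior odds `(1 − θ₀)/θ₀`. For small θ₀ this is
  large, so any decision threshold `T < (1 − θ₀)/θ₀` is crossed almost
  immediately on prior mass alone. Rare-event demonstrations must therefore
  use thresholds above the prior odds; the bundled benchmarks and the
  acceptance checks do.

**Non-i.i.d. correction.** An η-fair strategy distorts the n-sample
posterior by at most η^{2n} in either direction, so before the stopping
check the test moves log B toward 0 by `2n·log η`, clamping at 0: the
penalty may neutralize evidence but never manufacture evidence for the
other hypothesis (an uncorrected sign flip would let the correction itself
force a wrong decision). Acceptance uses strict inequalities (adjusted
B > T for H₀, < 1/T for H₁); a tie keeps sampling; the order within one
iteration is *adjust, then test*. The correction is exactly conservative:
|adjusted log B| ≤ |raw log B| with equality iff η = 1 or n = 0.
`eventually_fair(η, b)` implements the termination condition `η⁴ < e^b`
(compared as `4·log η < b` so the boundary case is exact); the
concentration constant b is supplied by the user, never estimated.

**Posterior distortion bound.** The guarantee that a c-bounded change of
measure moves the posterior `P(ρ < θ₀ | X₁…X_n)` by at most c^{2n} is
exercised where the biased likelihood is explicit: the Bernoulli family
`q(u) = min(c·u, 1 − (1−u)/c)`, whose outcome-wise derivatives `q/u` and
`(1−q)/(1−u)` stay within [1/c, c] for every u ∈ [0,1]. Both posteriors
are computed by adaptive quadrature (splitting at the branch point
`u = 1/(c+1)`) and the sandwich `c^{−2n}·P ≤ Q ≤ c^{2n}·P` is checked on
sampled outcome sequences. The discrete two-outcome fixture (`toy_fixture`)
plays the complementary role: explicit per-outcome derivatives for the
geometric-mean fairness check and for hitting-time demonstrations.

## Bundled models

**Lefever–Garay** (one-dimensional):
`dx = [r₀x(1−x/K) − βx²/(1+x²) + x(1−x/K)A₀cos(ωt)] dt + x(1−x/K) dW`.
The trailing noise term is read as the Itō diffusion coefficient. Both
x = 0 and x = K are noise-free; x = 0 is absorbing.

**Immunogenic tumor** (immune x, tumor y, two independent noises):
`dx = (a₁ − a₂x + a₃xy) dt + [b₁₁(x−x₁) + b₁₂(y−y₁)] dW₁`,
`dy = (b₁y(1−b₂y) − xy) dt + [b₂₁(x−x₁) + b₂₂(y−y₁)] dW₂`.
Noise scales with distance to the stochastic equilibrium (x₁, y₁), which
defaults to the interior fixed point of the drift (computed from the
y-nullcline `x = b₁(1−b₂y)` and the x-equation).

**Parameter provenance.** The studies these systems come from calibrate
their coefficients elsewhere; the defaults shipped here (`r0=1, K=10,
β=2, A₀=0.3, ω=1`; `a₁=0.5, a₂=1, a₃=0.2, b₁=2, b₂=0.25`, noise couplings
0.1) are chosen only to give well-behaved, bistable-looking desk-scale
dynamics and are **not** calibrated values. Consequently no specific
sample-count figure for these models is treated as a reproduction target;
they serve as structural presets, and all quantitative validation runs on
the analytic benchmarks. The headline rare-growth properties are bundled
as presets: `lefever_rare` monitors `F[10](x > 1e11)` from x₀ = 10⁹ cells,
`immuno_rare` monitors `F[10](x > 3.3)` from 0.1 units each. Note the
immunogenic property is stated on the *immune* variable x even though the
prose motivation concerns tumor cells (y); the preset follows the stated
formula, and monitoring y instead is a one-line formula override.

**Benchmarks.** `brownian_barrier_model(a, t)` pairs `dX = dW` with
`F[t](x > a)` and the reflection-principle probability `2(1 − Φ(a/√t))` as
ground truth. Discrete monitoring at step dt undercounts crossings
(excursions between grid points are invisible), so Monte-Carlo estimates
converge to the continuous value from below as dt → 0; at dt = 10⁻⁴ the
bias is within the 0.02 band used by the validation suite.

## Problem sizes and numerical tolerances

- Bayes-factor cross-validation: closed form vs adaptive quadrature
  (`epsabs=0, epsrel=1e-12`, integrand rescaled at the beta mode so large-n
  cases stay in range) to 10⁻⁹ relative agreement, over every (x, n) with
  n ≤ 50 plus stride-10 strata up to n = 200, four thresholds, three
  priors (≈ 28,000 points per threshold–prior setting).
- Martingale and measure-shift checks: 10⁵ paths, 4 (resp. 3) standard
  errors; Kolmogorov–Smirnov at α = 10⁻³ for the shifted-law check.
- Barrier recovery: 10⁵ paths at dt = 10⁻⁴, absolute tolerance 0.02.
- Error control: 500 replicates per setting; wrong-decision fraction ≤ 5%.
- Rare-event contrast: barrier a = 3 at dt = 4·10⁻³ (discrete crossing
  probability ≈ 2.4·10⁻³), θ₀ = 2·10⁻⁴, thresholds {3·10³, 3·10⁴, 3·10⁵}
  (above the prior odds of 5·10³ — see the prior-odds remark above — and
  spanning two decades), 50 paired seeded replicates per threshold,
  biased arm θ_max = 3, η = 1.1.

## What the synthetic benchmarks do not show

The analytic benchmarks have constant coefficients and one-dimensional
barrier events; they validate the engine, the monitor, and the sequential
machinery, not the biological realism of the tumor presets (whose
placeholder parameters make their verdicts illustrative only). The η^{2n}
correction is only as good as the asserted η: for SDE sampling the package
cannot verify fairness internally, and a user who asserts η = 1 while
sampling with aggressive biases forfeits the error guarantees. Equality
atoms on floating-point trajectories are almost never true; they exist for
discrete-valued traces. Correlated Brownian components and stochastic PDEs
are out of scope.
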