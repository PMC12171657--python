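# Methods

## Model

The simulator composes three standard stochastic primitives:

1. **Poisson offending.** Offender *j* commits N_i ~ Poisson(λ_i) offenses
   in year *i*, independently across years given the hazard path.
2. **Exponential population.** The year-1 rate λ₁ is Exponential with mean
   μ (expected offenses/year).  The Exponential is maximally skewed among
   simple one-parameter choices: most offenders carry near-zero risk, a
   thin tail carries most of the offending.
3. **Binomial charging.** Each offense is charged independently with
   probability r, so the charged count each year is Binomial(N_i, r); by
   Poisson thinning this is marginally Poisson(r·λ_i).

Desistance enters as a deterministic decay of the hazard path: the annual
odds of reoffending, e^λ − 1, shrink by the factor (1 − d) each year,

    λ_{i+1} = ln(1 + (1 − d)(e^{λ_i} − 1)),

applied unconditionally every year, whether or not the offender offended
that year.  (The empirical source of the 12.3% estimate measured the
decrement per offense-free year; the conditional variant is deliberately
out of scope — see Limitations.)  Years are indexed 1..T and "cumulative
by year t" means through the end of year t.

## Parameters

| Parameter | Meaning | Units | Default |
|---|---|---|---|
| d | annual proportional decrease in reoffending odds | fraction | 0.123 |
| r | probability an offense is charged | fraction | scenario-specific |
| μ | Exponential population mean of λ₁ | offenses/year | calibrated |
| target | observed cumulative charged rate anchor | fraction | 0.185 at year 25 |
| T | horizon | years | 25 |
| checkpoints | reporting years | years | 5, 10, 15, 20, 25 |
| n_iterations | Monte Carlo trials | count | 30,000 |
| seed | RNG seed | integer | 20250122 |

d = 0.123 (odds retention 0.877) and the 18.5% 25-year anchor are the two
empirical constants the model consumes; the sensitivity grid varies
d over {0, 0.05, 0.123, 0.20} and r over {1.00, 0.75, 0.50, 0.35, 0.25,
0.15, 0.05}.  30,000 trials put the standard error of a rate near 50% at
about 0.29 percentage points.  The default seed encodes a date and is
recorded in every output sidecar; any integer works.

## Analytic engine

Conditional on λ₁ the first-event probabilities are closed forms
(1 − exp(−S_t) and 1 − exp(−r·S_t) with S_t the cumulative hazard), so
population rates are one-dimensional integrals against the Exponential
density.  The substitution λ₁ = −μ ln u maps the integral to (0, 1) with
unit weight.  Near u = 0 the integrand behaves like u^(μrt) — a
fractional power for calibrated μ — which plain Gauss–Legendre resolves
only algebraically; the additional cubing substitution u = v³ raises the
endpoint exponent above 2 and restores fast convergence (node-doubling
discrepancies ~1e−15 at order 512).  Every call verifies convergence by
doubling the node count and raises if the discrepancy exceeds 1e−8.  The
d = 0 case bypasses quadrature entirely: the integral is the Laplace
transform of the Exponential, giving charged rate μrt/(1 + μrt) exactly —
this identity doubles as the engine's strongest self-test.

The trajectory S_t(λ₁) is a nonlinear function of λ₁ (the odds recurrence
does not commute with scaling), so the hazard path is recomputed at every
quadrature node; the vectorized recurrence over 1024 nodes × 25 years
costs microseconds and needs no caching.

## Monte Carlo engine

Fully vectorized over trials: one seeded PCG64 generator draws the λ₁
vector, the Poisson count matrix over the hazard paths, and the Binomial
charged-count matrix, then cumulative first-event indicators are reduced
at the checkpoints.  Results are bit-reproducible from the seed.  A
scalar per-offender reference implementation (`simulate_trial`) exists
for transparency and is tested against the vectorized path; it stops
early once both first-event years are known, which cannot change
cumulative first-event proportions — this is also why tracking events
through the full horizon (to serve all checkpoints in one run) is
equivalent to stopping at the first charge.  Standard errors are the
binomial sqrt(p̂(1 − p̂)/n).

## Calibration

μ_r solves charged_rate_T(μ) = target.  The charged rate is strictly
increasing in μ, so Brent's method on the bracket [1e−6, 10]
offenses/year finds the unique root; with the analytic objective the
achieved rate matches the target to 1e−8.  A Monte Carlo objective is
available for protocol fidelity with goal-seek workflows: it re-runs the
same seeded simulation at each candidate μ (common random numbers), which
makes the objective deterministic in μ but stepwise; the solved μ then
carries the sampling error of the trial count (order ±1% at 30,000).
Calibration always anchors on the charged rate, never the actual rate —
that is the model's identification device.  r = 0 is rejected: no
positive target is attainable without charging.

## Design choices

- The hard-coded odds-retention constant 0.877 is generalized to 1 − d so
  the sensitivity grid runs through a single code path; d = 0.123
  reproduces 0.877 exactly as 1 − 0.123.
- The recurrence is evaluated as `log1p((1 − d)·expm1(λ))`; the textbook
  form (1 − e^(−λ))/e^(−λ) loses precision for the tiny hazards typical
  of calibrated populations.
- The per-year trajectory export interprets the annual reoffense
  probability as the *unconditional* population expectation
  E[1 − e^(−λ_i)] over the Exponential draw of λ₁, not the probability
  among offenders with no prior event; the choice is recorded in the
  output metadata.
- Rates are proportions everywhere in the library; percentage formatting
  belongs to the presentation layer.
- Table replications derive a per-scenario child seed from the root seed
  and the (r, d) pair via `SeedSequence`, so adding or reordering
  scenarios does not perturb other rows.

## What the simulations do and do not show

The generator *is* the model: synthetic populations are Exponential in
λ₁, Poisson in counts, Binomial in charging, with geometric odds decay.
Agreement between the Monte Carlo and analytic engines validates the
implementation, and replication of the published tables validates the
parameterization — neither validates the model against real offending
data.  Real populations may have non-Exponential risk mixtures (a Gamma
population is the natural generalization), clustered or cyclical
offending that violates the Poisson assumption, charge probabilities that
vary by offender or offense, and desistance that is neither constant nor
unconditional.  Results are therefore conditional statements: *if* a
population with these mechanics produces the observed 18.5% charged rate,
*then* its actual reoffending is as reported.

## Numerical notes and degenerate inputs

- λ = 0 is a fixed point of the recurrence; μ → 0 sends all rates to 0.
- d = 1 extinguishes the hazard after one year; allowed.
- r = 1 makes charged and actual rates identical (tested bitwise in MC).
- Quadrature non-convergence raises `ArithmeticError` with diagnostics
  (exit code 2 in the CLI); invalid parameters raise `ValueError`
  (exit code 1).
- Problem sizes: test-suite replications default to 30,000 Monte Carlo
  iterations for table replication checks and 2,000 for structural
  checks; the full table 1 + table 2 replication completes in a few
  seconds on one CPU.
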