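# darkfigure

Official recidivism statistics count only the offenses that end in a charge
or conviction.  The gap between offenses that happen and offenses that are
recorded — the *dark figure* — means that observed sexual-recidivism rates
are lower bounds on actual reoffending.  `darkfigure` is a simulator for
quantifying that gap: it models a population of offenders whose offending
decays over time (desistance), calibrates the model so that its *observed*
(charged) recidivism matches an empirical anchor, and then reads off the
*actual* recidivism the same population implies under different charging
assumptions.  It is aimed at quantitative criminologists, forensic
statisticians, and anyone evaluating how sensitive published recidivism
rates are to under-ascertainment.

## The model

Offender *j*'s number of offenses in year *i* is Poisson with mean λᵢ.
The year-1 mean λ₁ is drawn from an Exponential population with mean μ —
most offenders have a low rate, a few a much higher one.  Desistance
shrinks the annual **odds** of reoffending by a fixed fraction *d* each
year.  Writing the annual probability of at least one offense as
p = 1 − e^(−λ) and the odds as p/(1 − p) = e^λ − 1, the yearly update is

    λ_{i+1} = ln(1 + (1 − d)(e^{λ_i} − 1)),

so that odds_{i+1} = (1 − d)·odds_i exactly.  The headline desistance rate
d = 0.123 gives the retention factor 0.877; d = 0 is the constant-hazard
limiting case.

Each offense is independently charged with probability *r* (Binomial
thinning), so charged counts in year *i* are Poisson with mean r·λᵢ.
Conditional on λ₁, the cumulative probabilities of a first event by year
*t* are

    P(≥1 offense by t)  = 1 − exp(−S_t),      S_t = Σ_{i≤t} λ_i,
    P(≥1 charge  by t)  = 1 − exp(−r·S_t).

The population mean μ_r is **calibrated** so that the 25-year cumulative
*charged* rate equals an observed anchor (default 18.5%).  Because the
charged rate is strictly increasing in μ, the root is unique; the package
solves it by Brent's method over a Gauss–Legendre quadrature of the
Exponential population (for d = 0 the integral collapses to the closed
form μrt/(1 + μrt)).  The actual rate at the calibrated μ_r then measures
how much reoffending the observed 18.5% implies once charging is
incomplete (r < 1).

Rates can be estimated two ways, and the two engines cross-check each
other: a vectorized, seeded Monte Carlo engine (default 30,000 trials)
following the generative story above, and the deterministic analytic
engine based on the thinning closed forms.

## Worked example

Calibrate a population in which only 25% of offenses are charged:

```bash
$ darkfigure calibrate --r 0.25 --desistance 0.123
{
  "mu_r": 0.11143826804654172,
  "target_rate": 0.185,
  "achieved_rate": 0.18500000000000025,
  ...
}
```

The solved μ ≈ 0.1114 expected offenses/year is roughly four times the
base-case (r = 1) value of 0.0287 — fewer charges per offense require a
more active population to produce the same observed 18.5%.  Simulate that
scenario:

```bash
$ darkfigure run --r 0.25 --calibrate --iterations 30000 --seed 7
{
  ...
  "estimates": {
    "checkpoints": [5, 10, 15, 20, 25],
    "actual_rate":  [0.3072, 0.4042, 0.4443, 0.4637, 0.4730],
    "charged_rate": [0.0996, 0.1459, 0.1682, 0.1796, 0.1859],
    ...
  }
}
```

The charged rate reaches the 18.5% anchor at year 25 (0.1859, within
Monte Carlo noise), while the actual 25-year reoffending rate is 47.3% —
the dark figure implied by a 25% charge rate.  `darkfigure table1`,
`darkfigure table2`, and `darkfigure trajectories` export the full
charge-rate table, the desistance-sensitivity grid, and the per-year
hazard series as CSV with JSON provenance sidecars.

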