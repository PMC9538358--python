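# Methods

## Model structure and assumptions

The fund is modelled as a single stock (the cumulative balance) with
two annual flows (premium revenue, reimbursement expenditure) on an
annual Euler step; the trajectory invariant `B(T) − B₀ = Σ(R − E)`
holds to floating-point precision and is asserted in the tests.
Sub-annual dynamics are ignored: the published quantities of interest
are yearly balances.

Assumptions baked into the engine:

- 2019 is the base year; the forecast horizon is 2020–2050 (both
  configurable).
- The insured pool is the union of the two SMI schemes, split into
  active urban employees, retired employees and urban-and-rural
  residents; benefits accrue to the severely disabled share of the
  insured pool.
- Premiums are the only revenue — no investment income on the fund.
- Economic development is stable: wages, pensions, incomes and care
  costs each compound at a constant annual rate with no shocks.

Population dynamics default to independent per-group exponential
growth. The exact demographic equations behind the published study are
not available in its main text, so the exponential form is the minimal
model consistent with the stable-growth assumption; two refinements are
available but off by default: a retirement flow mode
(`retirement_flow_rate` moves that fraction of active employees into
the retiree pool each year) and an `employees_override` hook that
drives the employee path from an external urban-employment projection
through the fitted OLS link.

Expected-value accounting is used throughout: person counts are real
numbers and never rounded, since the model is deterministic and
operates at population scale.

## Parameters

| parameter | unit | china_scale default | rationale |
|---|---|---|---|
| insured employees / retirees / residents (2019) | persons | 243 M / 86 M / 1 025 M | 2019-era SMI enrolment magnitudes |
| wage / pension / resident-income base (2019) | yuan/yr | 90 000 / 40 000 / 42 750 | urban wage, average pension, per-capita disposable income; the income base puts the 0.08–0.1% premiums at ¥34.2–42.75/person/yr |
| population growth | /yr | +0.5% / +3% / −0.2% | slow formal-employment growth, fast aging into retirement, slight resident decline |
| wage / pension / income growth | /yr | 6.5% / 5.5% / 6.5% | stable nominal growth |
| care cost (2019) | yuan/yr | 11 400 | reimbursable cost per severely disabled person consistent with the premium scale |
| care-cost growth | /yr | 8% | long-term-care cost inflation outpacing income (Baumol-type cost disease) |
| contribution multipliers | — | individual 1, employer 0, government 0 | pure individual financing; the multipliers model employer/government sharing when set |
| initial balance | yuan | 0 | the fund launches in 2020 |

The 1.5-point gap between care-cost growth and income growth is the
load-bearing calibration choice: it makes the expenditure/revenue ratio
drift upward ≈1.4%/yr, so mid-range schemes show the characteristic
rise–peak–decline balance curve with the inflection in the mid-2040s
(the reference scheme 0.08%/0.3%/80% peaks in 2046). With care cost
tracking income exactly, the ratio is nearly flat and no scheme peaks
inside the horizon. When `care_cost` growth is left unset in a config,
it falls back to the resident-income growth rate.

Everywhere a rate appears it is a fraction (0.0008 = 0.08%); internal
arithmetic is in yuan, and reporting divides by a configurable unit
(default 10⁹ yuan).

## Screening rules

A scheme is *appropriate* iff its balance trajectory (i) never goes
negative, (ii) is not excessive — terminal balance at most ¥3 trillion
by default (`excess_scope="any"` tests every year), (iii) peaks in the
late forecast period — within the final `late_peak_window = 5` years,
with ties in the maximum broken toward the latest year — and (iv) its
reimbursement ratio lies in the recommended 80–90% band, applied as a
final filter after the balance rules. A strictly-interior-maximum
variant (`require_interior_peak`) additionally rejects curves that only
rise through 2050; it is off by default because a monotonically rising
curve that stays below the excess threshold still satisfies the
sustainability reading adopted here. Screening enumerates every
violated rule, and relaxing any single rule can only grow the selected
set (tested as a property).

## Sensitivity and validation procedures

Sensitivity: `n_runs = 200` simulations with the three knobs drawn
independently and uniformly, by default over the scenario level
extremes ([0.08, 0.1]%, [0.25, 0.35]%, [0.7, 0.9]). One seeded
generator draws the parameters in a fixed order (rate, disability rate,
reimbursement) per run, so envelopes are bit-reproducible across
machines. Envelopes report per-year min/max and the 2.5/25/50/75/97.5%
quantiles.

Historical validation back-casts the insured-urban-employee and
resident-income paths over 2011–2019 and computes the *signed*
arithmetic mean of yearly relative errors per series (so systematic
under-prediction is negative; an absolute-value variant sits behind a
flag). The gate passes iff every |mean error| < 10%. Dimensional
consistency is enforced structurally (typed states, unit conventions,
load-time invariant checks) rather than as a runtime test.

## Synthetic data

The generator emulates statistical-yearbook inputs: model back-casts
multiplied by `(1 + ε)`, `ε ~ N(0, noise_sd)` truncated at −0.9 to keep
positive series positive, with `noise_sd = 0.02` as the default
small-noise regime. It reproduces the *statistical shape* the analysis
assumes — smooth exponential trends with small multiplicative
measurement noise — but not features of real yearbook data such as
policy breaks (e.g. enrolment expansions), business-cycle fluctuation,
or revisions; passing tests therefore demonstrate correctness of the
pipeline and recoverability under the model's own assumptions, not
calibration accuracy against actual Chinese series.

## Numerical choices and tolerances

- Conservation is asserted at 1e-9 relative tolerance (observed ~1e-14).
- Band and threshold comparisons carry a 1e-9 relative guard so nominal
  endpoints (ρ = 0.8, 0.9) are inside the band despite float rounding.
- Growth-rate recovery by log-linear OLS on a 9-point window at 2%
  multiplicative noise has a slope standard error ≈ 0.0026; the
  recovery tolerance is set at 0.01 absolute (≈4 SE) across 100 seeds.
- The employment-link OLS is exactly the closed-form solution (tested
  against it); at the short 9-year window the link's *slope* is weakly
  identified under noise because the covariate grows only ~0.5%/yr, so
  noisy-link tests assert prediction quality, and slope recovery is
  asserted on the noiseless path.
- Scheme knobs accept the closed interval [0, 1]: zero is a meaningful
  edge (no premium, no beneficiaries, or no reimbursement) used by the
  zero-flow identity; scenario grids restrict levels to (0, 1).
- Degenerate inputs fail fast with field-named `ConfigError`s: empty
  horizons, non-finite balances, constant regressors, observed values
  ≤ 0, windows overlapping the forecast horizon.

## Known limitations

- Terminal balance is affine in the policy knobs — linear in the
  payment rate and in the product (disability rate × reimbursement) —
  so any two schemes with equal `d·ρ/r` share the same deficit/peak
  behaviour up to scale. Richer published selections that break this
  symmetry imply model structure (e.g. disability concentrated in a
  faster-growing subgroup) beyond the default configuration; the
  `disability_base` option provides a first step in that direction.
- No regional or urban/rural disaggregation, no stochastic demographic
  micro-simulation, no investment income, and no welfare analysis
  beyond the rule-based screen.
- The china_scale preset is a reconstruction anchored to published
  magnitudes, not a fitted calibration; problem sizes used in tests and
  in the acceptance script (31-year horizon, 45-scheme grid, 200
  sensitivity runs, 50–100 validation/recovery seeds) are the package's
  standard study sizes.
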