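# Methods

## Data model

The analysis is annual. A `YearRecord` holds a calendar year's observed
effort in thousands of hooks — the unit in which CPUE is expressed — and
the bycatch counts of the two species. Per-set observer records
(`SetRecord`) keep raw hook counts per set, the gear code (LLHB, LLALB,
LLJAP), and a binary south-of-40°N region flag; conversion between raw
hooks and thousands is always explicit (`aggregate_annual`). The packaged
1999–2012 table ships as a plain CSV inside the package and is the
reference input for the deterministic statistics.

Monthly climate-index files are accepted in the whitespace-delimited form
meteorological agencies distribute (year, month, value) or as CSV, with an
optional header. Duplicate (year, month) pairs and months outside 1–12 are
rejected at parse time rather than downstream.

## CPUE and the interannual chi-square test

Pooled CPUE is total catch over total effort, not the mean of annual
ratios, so high-effort years carry their proper weight. The interannual
test allocates the study-period total to years proportionally to effort,
`E_t = N·h_t/H`, and computes `X² = Σ(O_t−E_t)²/E_t`, `df = n−1`, with the
upper chi-square tail from `scipy.stats.chi2`.

Numerical choices:

* expected counts enter the statistic at full precision; rounding them to
  the 2 d.p. shown in report tables before summing would perturb a
  statistic of this magnitude by more than its printed precision;
* no continuity correction and no small-count pooling — expected counts in
  this design are far above 5;
* the statistic here is so large that its tail probability underflows
  double precision; the result then carries an explicit `p_underflowed`
  flag and is displayed as `< 1e-300` instead of a misleading `0.0`.

The statistic is evaluated directly from its definition rather than
through a library wrapper because the contract admits arbitrary positive
expected values, including ones whose total differs from the observed
total (useful in testing); wrappers that enforce equal totals would
reject those inputs.

## Climate covariate and event coding

The covariate of both models is NAOpy: the unweighted mean of the twelve
calendar-month index values of the year *preceding* the fishing year. The
mean is unweighted because the annual-mean covariate is defined that way
in this analysis tradition; `min_months` defaults to 12 so a partial year
never masquerades as an annual mean (it is configurable for exploratory
use). Lagging requires the index to cover year `t−1` for every target
year `t` and fails loudly, listing uncovered years.

Leatherback years code 1 when at least one animal was caught — a function
of counts only, independent of effort. Loggerhead years code 1 when the
year's pooled CPUE within the LLHB-south-of-40°N stratum strictly exceeds
the mean CPUE over the years with catches (CPUE > 0) in that stratum.
Ties at the threshold code 0: the event is "greater than the mean", and
the conservative resolution of the boundary keeps the event rare rather
than inflating it. Zero-catch years always code 0.

## Logistic regression and favourability

The fit is plain maximum likelihood via Newton/IRLS from a zero start,
converging when the largest absolute coefficient change drops below 1e-8
(at most 100 iterations; a fit that exhausts them is returned flagged
`converged=False`, never silently). With 14 annual observations the MLE
is fragile and (quasi-)separation is a real possibility; the fitter does
not regularise — that would change the model — but flags |slope| > 50 and
emits a `SeparationWarning`. Single-class outcomes and constant
covariates are rejected because the MLE does not exist. The model
chi-square is the likelihood-ratio statistic against the intercept-only
model, df = 1.

Favourability `F = odds(P) / (n1/n0 + odds(P))` is a strictly increasing
bijection of P for fixed prevalence, with F = 0.5 exactly at
P = n1/(n1+n0); the boundary cases extend continuously (F(0) = 0,
F(1) = 1). Because it is strictly increasing, it preserves rank-based
quantities — AUC is invariant under it, exactly, and the tests assert
exact equality rather than approximate.

## Model evaluation

Hosmer–Lemeshow groups are formed by sorting observations by predicted
probability and cutting into `n_groups` equal-count groups, never
splitting a block of tied probabilities. The declared degrees of freedom
are (groups formed) − 2; with n = 14 and ten groups most groups hold one
or two years and df = 8. A group whose expected events (or non-events)
are exactly zero is merged into its neighbour, reducing df, and the
result is flagged; df ≤ 0 marks the test untestable (p = NaN) instead of
fabricating a p-value. The grouping rule is declared, not inferred from
any particular software's default.

AUC uses the tie-corrected Mann–Whitney rank formulation
(`scipy.stats.rankdata`), which equals trapezoidal ROC integration while
keeping a one-line contract, and is checked against brute-force pair
enumeration in the tests.

Classification rates split years by predicted favourability at a
threshold (default F ≥ 0.5 ⇒ predicted event) and report the correct
rate among predicted-favourable years, among predicted-unfavourable
years, and overall; an empty prediction class yields NaN rather than a
silent 0 or 1.

## Synthetic fishery generator

The generator emulates the structure the analysis assumes, not the real
fishery: independent sets, gear assigned by a fixed mix, hooks uniform on
gear-specific ranges, and species counts Poisson with mean

    hooks/1000 × rate[species][gear] × exp(coef[species] × NAOpy(year)).

The climate index is two-level Gaussian: annual means N(0, 0.45) — the
interannual spread of a normalized annual index — and monthly values
scattered N(annual mean, 0.8) within the year, reflecting that monthly
index variability is roughly twice the interannual variability of annual
means. The index covers one extra leading year so every fishing year has
a lagged covariate.

The default configuration is the study-scale preset
(`table1_like_scenario`): 14 years from 1999, 180 sets/year, gear mix
0.6/0.3/0.1 (LLHB/LLALB/LLJAP), hook ranges 1500–4000, 2000–7000, and
600–1200 per set, 70 % of sets south of 40°N, climate coefficients +2
(loggerhead) and −2 (leatherback). Expected totals sit at the observed
study scale: ≈ 7.9 million hooks over 14 years. Baseline rates are set
*below* the target pooled CPUEs (loggerhead 0.17/0.43/0.26 per gear,
leatherback 0.00055 everywhere) because the climate multiplier
`exp(coef × NAOpy)` has mean ≈ 1.6 over the index distribution, and it is
the realized pooled CPUE — ≈ 0.50 loggerhead and ≈ 0.0009 leatherback
per 1000 hooks, with leatherback presence in roughly 4–5 of 14 years —
that should match the observed study, not the NAOpy = 0 intercept. This
calibration is part of the preset's definition and was fixed before the
validation studies were run.

Overdispersion (gamma-Poisson mixing) is available as a config option but
off by default: the analysis pipeline itself assumes nothing about the
count distribution beyond its mean structure, and the Poisson default
keeps the validation studies' operating characteristics interpretable.

All randomness flows from `SimulationConfig.seed`; the climate and
fishery streams are independent children of it, and replicate studies
derive per-replicate child seeds (`spawn_seeds`) so any replicate can be
re-run in isolation.

### What passing the synthetic studies does and does not show

The generator omits set-level clustering, seasonality within gears,
spatial structure beyond the binary region flag, and any real dependence
between effort allocation and climate. Recovery of the climate
coefficient's sign in ≥ 90 % of replicates and a near-nominal type-I
error therefore validate the *pipeline* — coding, lagging, fitting, and
testing behave correctly when the assumed structure holds — not the
ecological claim on real data. On the real 14-year series the published
coefficients depend on external NOAA index values and unpublished
stratified CPUE, which this package deliberately does not bundle.

The likelihood-ratio test's chi-square reference is mildly
anticonservative at n = 14: measured over 2000 null replicates the
rejection rate at nominal 5 % is ≈ 7.6 %. A 200-replicate study of it
carries a Monte-Carlo standard deviation near 2 percentage points.

## Validation study sizes

The packaged studies use 100 replicates per recovery direction and 200
null replicates at 500 sets/year over 14 years — large enough that the
sign-recovery and type-I proportions are stable to a few percentage
points, and small enough to run in seconds.

## Known limitations

* Annual aggregation only; no sub-annual or spatial modelling.
* The loggerhead event depends on an unpublished stratified CPUE series;
  with synthetic or user-supplied set records the event's year universe
  is whatever those records cover, and the caller must ensure it matches
  the covariate's coverage.
* Plain ML logistic regression at n = 14 is fragile by construction; the
  package surfaces separation and non-convergence instead of fixing them,
  and users should treat flagged fits as exploratory.
* The favourability comparison across species is meaningful on the F
  scale only because F removes prevalence; it does not make the two
  models' probabilities commensurable.
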