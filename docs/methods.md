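# Methods

This note documents the models behind `cohortbridge`, the defaults of the
synthetic study generator, and the numerical and design choices that were
genuinely open.

## Cohort construction

A cohort window runs from a census date (5 December 1990 or 5 December
2000) to the earliest of death, emigration, or the administrative end of
follow-up (31 December 2007). Exposure is counted in whole days on the
half-open convention `(census_date, stop]`: the census day contributes no
risk time, the stop day does. The 1990 cohort is censored on 4 December
2000 and the 2000 cohort runs from 5 December 2000, so deaths 1991–2000
belong to the first window and 2001–2007 to the second, and persons present
at both censuses are never double-counted.

Person-time is split exactly at 1 January boundaries and at the birthdays
on which a person crosses an attained-age band boundary (29 February
birthdays fall on 1 March in non-leap years). Age strata therefore use
**attained age**, updated at every birthday, not age at census — required
for a meaningful 85+ series over a 17-year window. Default bands are
0–4, 5–14, …, 75–84, 85+; reporting focuses on 75–84 and 85+. Person-years
are days/365.25. Splitting is conservative by construction: per person the
stratum days always sum to `stop − start` exactly, and the test suite
asserts this on every synthetic cohort it builds.

## Pragmatic allocation of unlinked deaths

Certificates the main linkage could not resolve are allocated in two
steps:

* **step 1**: equal sex, canton and nationality; marital status identical
  or a plausible change; birth dates at most 92 days apart;
* **step 2**: equal sex and major region; birth dates at most 366 days
  apart.

"Three months" and "one year" are implemented as fixed day bounds (92 and
366) so the windows are calendar-safe. The plausible-transition set
contains the four identity pairs plus single→married, married→widowed,
married→divorced, divorced→married and widowed→married — the legally
possible changes between a census and a later death. Sex-specific causes
(breast C50, prostate C61) exclude opposite-sex candidates; since
candidates always share the certificate's sex, a certificate whose own
sex/cause combination is impossible is left unallocated.

Certificates are processed in a fixed order (death date, then certificate
id); when several census persons qualify, one is drawn uniformly with a
seeded generator. A person already carrying a linked death, already
consumed by an earlier allocation, or known to have emigrated before the
certificate's death date is never a candidate, which keeps the allocation
a partial injection from certificates to persons. Processing order matters
because of person-exclusivity, so it is part of the contract; the seed is
recorded in the result.

Summary percentages are printed with the conventions of the summary
tables they echo: shares of the unlinked pool to two decimals, shares of
all deaths to one decimal, and values below 0.1% to two significant
figures.

## Mortality rates and the reference comparison

Rates are deaths per 100,000 person-years per (calendar year, sex,
attained-age band, cause), computed excluding unlinked deaths (persons
behind them remain under observation until the window closes — the bias
mechanism) and including the allocated deaths (which also terminate their
person's exposure at death). Reference rates divide **all** registered
deaths — linked or not — by mid-year population counts, exactly how a
statistical office computes official rates; in the synthetic setting the
mid-year population is the ground-truth count of persons alive and present
on 1 July. The comparison metric is the per-year relative difference
(cohort − reference)/reference, pooled over sexes by summing numerators and
denominators, summarised by mean/min/max over 1991–2007.

The mid-year denominator is itself an approximation to exact person-time;
with annual mortality around 15–18% in the 85+ band the two differ by well
under 1%, which bounds how closely corrected cohort rates can be expected
to track the reference.

## The coding-change model

For one (cause, sex, age group) stratum with annual deaths `D_y` and
person-years `PY_y`:

    D_y ~ Poisson(mu_y),  log mu_y = log PY_y + b0 + f(y) + g * 1{y >= 1995}

`f` is a restricted cubic spline in Harrell's truncated-power
parameterisation — linear term plus k−2 restricted cubic terms, nonlinear
terms scaled by the squared knot range, linear beyond the boundary knots —
with knots exactly at 1990, 1995, 2000 and 2004 (the printed knot
locations are used as given, although they are not equally spaced). The
step indicator is 1{year ≥ 1995}, matching a coding change effective
1 January 1995 applied to annual data. `exp(g)` is the multiplication
factor; its 95% CI is Wald on the log scale; the percent reduction
100·(1−factor) is rounded half away from zero to integer percent. The
adjusted ("as if always new coding") series forces the step term to its
post-change value for all years, with delta-method CIs on the linear
predictor. Each stratum is fitted separately.

Fitting uses iteratively reweighted least squares (statsmodels GLM,
Poisson family, log link, offset), tolerance 1e-10, at most 100
iterations; non-convergence and separation (a regime with all-zero
counts) are flagged, never silently accepted. The test suite checks the
fit against an independent derivative-free maximisation of the
hand-written likelihood (multi-start Nelder–Mead with Powell polish, run
in a centered/scaled parameterisation for conditioning; the comparison
transform is exact linear algebra) to 1e-6 per coefficient.

## Hazard ratios with and without unlinked deaths

Relative mortality for education (reference: secondary), marital status
(reference: married) and nationality (reference: Swiss) is estimated by a
piecewise-exponential model: person-time sliced at calendar-year and
age-band boundaries, Poisson likelihood on the event indicator with a
log person-years offset, adjusted for the other two exposures, region,
religion, urbanization, attained-age group and calendar year. Under
hazards that are constant within (year × age band) cells — which is how
the generator simulates — this is the exact likelihood, and it
approximates Cox proportional-hazards estimates closely in general; it
was chosen over Cox partial likelihood to keep the estimator
self-contained and checkable against the two-group exponential closed
form (which the tests verify to 1e-8). Education models drop person-time
below age 15 and the `not_applicable` education level, since education is
undefined for children. Slices are aggregated to covariate cells before
fitting (sufficient statistics; the likelihood is unchanged).

The robustness comparison fits each model twice: excluding unlinked
deaths (their persons censored administratively at the end of the window)
and including the pragmatically allocated deaths.

## The synthetic study generator

The generator emulates the study conditions the analyses need, with
hidden ground truth for scoring:

* **Census waves.** Wave 1 (default 50,000 persons) at 5 December 1990;
  wave 2 at 5 December 2000 consists of wave-1 survivors plus fresh
  entrants up to the target size. Ages at census are uniform 0–95;
  categorical attributes follow fixed marginals shaped like a
  western-European census (79/21 Swiss/foreign, education 37/46/17 among
  adults, etc.); canton is uniform over the 26 cantons, mapped onto the
  seven major regions. Attributes are sampled independently except that
  children get `not_applicable` education and `single` marital status.
* **Events.** Competing exponential clocks per cause within (calendar
  year × attained-age band) cells, with optional log-linear calendar
  trends and proportional covariate effects (default: tertiary education
  HR 0.9, compulsory HR 1.05, single HR 1.16, non-Swiss HR 0.95, applied
  to all death causes). Baseline hazards are stylised: steep age
  gradients, cardiovascular dominance in old age, sex-specific breast and
  prostate cancer, rare suicide. Simulation draws one exponential waiting
  time per constant-hazard segment, so cause-specific counts have exact
  closed-form expectations that the tests check.
* **Death certificates.** Each death carries its underlying cause plus
  random additional mentions (default: a non-cancer death mentions the
  residual-cancer group with probability 0.05, breast/prostate with 0.03
  where sex-compatible). The pre-1995 coder promotes the highest-priority
  mentioned cause (external causes, then influenza, then cancers); from
  1995 the underlying cause is coded strictly. This induces a genuine
  downward step in official cancer rates at 1995 whose magnitude is
  analytically computable from the hazards and mention probabilities
  (`analytic_step_factor`), giving a known truth for recovery tests.
  Certificate marital status evolves from the census status only along
  plausible transitions (rate 0.02/year); the certificate canton differs
  from the census canton with probability 0.10.
* **Unlinking.** Each certificate fails the main linkage with a
  probability that is an age-band baseline (about 3% in old age, up to
  18% in young adults) times multipliers for nationality (non-Swiss
  ×2.6), marital status (single ×1.5, widowed ×0.8) and sex (male ×1.15),
  calibrated so the default study yields ≈5% unlinked overall with the
  descriptive gradient of linkage studies (≈4.7% Swiss vs ≈12% foreign
  deaths). Unlinked certificates additionally get their identifying
  fields perturbed: birth date exact with probability 0.5, else uniform
  within ±92 days (0.4) or ±366 days (0.1) — chosen to reproduce the
  step-1 vs step-2 contrast in birth-date agreement; canton replaced with
  probability 0.3; marital status moved one plausible step with
  probability 0.15. Ground truth (certificate → person) is returned in a
  separate table that analytic modules never read.

What the generator does **not** emulate: real canton sizes or population
structure, true ICD-8↔ICD-10 code mappings (labels only), births between
censuses, immigration during follow-up (entrants appear only at wave 2),
attribute changes between waves for survivors, and correlations between
census attributes beyond the age rules above. Passing tests therefore
show that the algorithms are correct under the stated mechanism, not that
real Swiss rates are reproduced — the real-data quantities are
access-restricted and out of reach by design.

## Study designs and their sizing

* **Recovery study** (`studies.coding_step_recovery`): 50,000 women aged
  75–90 at the 1990 census, one age band, flat hazards (residual cancer
  0.040/yr, cardiovascular 0.080, other 0.045, breast 0.002, suicide
  0.0005), no emigration, no unlinking, mention probability of the
  residual-cancer group solved in closed form so the true multiplication
  factor is exactly 0.85. With these hazards a replicate yields roughly
  6,000 pre-1995 and 6,000 post-1995 cancer deaths, putting the Wald
  standard error of the factor near 0.03 — sized a priori so that the
  mean absolute error of the estimate stays below 0.03 and the 95% CI
  has nominal coverage over 200 replicates.
* **Correction study** (`studies.rate_correction_study`): the default
  two-wave study at 50,000 persons per wave; all-cause 85+ rates pooled
  over sexes, 1991–2007.
* **Robustness study** (`studies.hr_robustness_study`): a single-wave
  cohort (2000–2007) of 50,000 adults aged 50–95 at census, education
  exposure, all-cause mortality. The differential variant multiplies the
  unlink probability of tertiary-educated decedents by 6, a deliberately
  strong sensitivity difference that separates cleanly from the
  non-differential band.

## Numerical choices and degenerate inputs

* Event days are the ceiling of the simulated continuous time, clipped
  into `(census_date, end_date]`, so death dates always postdate the
  census.
* Tie-breaking at equal stop dates: death beats emigration beats
  administrative censoring.
* An empty mention set, a death on or before its census date, deaths in a
  stratum with zero person-time, a missing mid-year stratum with deaths,
  duplicate certificate ids, and an all-zero count series are errors;
  empty allocation sets and zero-reference-rate years are flagged results.
* Percent reductions round half away from zero; agreement percentages and
  characteristics tables round to one decimal.

## Limitations

* The piecewise-exponential HR estimator equals Cox only under
  piecewise-constant hazards; on real data the two can drift apart when
  hazards vary strongly within years.
* The allocation's truth-recovery rate is reported, not asserted to a
  target: with coarse matching fields most allocations land on the right
  stratum but not necessarily the right person, which is sufficient for
  rates and (under non-differential unlinking) for hazard ratios, and
  exactly insufficient under differential unlinking — which the
  robustness study demonstrates.
* The multiplication factor cannot separate the coding-policy effect from
  any other change occurring at the same date; it quantifies the jump,
  not its cause.
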