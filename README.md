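# cohortbridge

Census-based mortality cohorts ascertain deaths by linking a national death
registry to census records. Two things quietly distort the mortality rates
such a cohort produces:

1. **Unlinked deaths.** A few percent of death certificates cannot be
   matched to any census person. Each one removes a death from the
   numerator *and* leaves a person accruing person-time in the denominator,
   so absolute rates are biased downwards — most visibly in the oldest age
   groups, where mortality is highest.
2. **Cause-of-death coding changes.** When a statistical office switches
   coding policy (for instance from a priority-rule coder that promoted
   mentioned cancers to a strict underlying-cause coder), cause-specific
   rates jump discontinuously at the switch date, confounding real trends.

`cohortbridge` implements, as a tested reusable pipeline on synthetic data,
the methodology for repairing both problems:

* **Pragmatic two-step allocation** of unlinked certificates to census
  persons — step 1 matches sex, canton, nationality, plausible marital
  status and birth date within 92 days; step 2 relaxes to sex, major region
  and birth date within 366 days; ties are broken uniformly at random with
  a seeded generator, impossible matches (e.g. a prostate-cancer death on a
  female record) are excluded, and each person can absorb at most one death.
* **Exact Lexis person-time** split by calendar year, sex and attained-age
  group (conservation to the day), mortality rates per 100,000 person-years
  including vs excluding the unlinked deaths, and reference rates computed
  the way official statistics do (all deaths over mid-year population).
* **A spline-Poisson trend model** for the coding change: for one
  (cause, sex, age group) stratum the annual death counts follow

  log E[D_y] = log PY_y + β₀ + f(y) + γ·1{y ≥ 1995},

  with f a restricted cubic spline (Harrell basis, knots 1990, 1995, 2000,
  2004). exp(γ) is the **multiplication factor**: the number by which
  pre-change rates must be multiplied to be comparable with post-change
  rates (the analogue of a bridge-coding comparability ratio). The model
  also back-casts pre-change rates as if the new coding had always applied.
* **Hazard-ratio robustness checks**: piecewise-exponential (Poisson)
  models for education, marital status and nationality, fitted with and
  without the unlinked deaths, quantifying when relative mortality is and
  is not affected by linkage failure.
* **A synthetic study generator** (census waves 1990/2000, competing-risk
  event simulation, a pre/post-1995 cause-of-death coder, stratified
  unlinking with field perturbation) that retains hidden ground truth, so
  every correction can be scored against a known answer.

## Worked example

```python
from cohortbridge.studies import default_study_config, rate_correction_study
from cohortbridge.trendmodel import percent_reduction_from_factor

r = rate_correction_study(seed=3)
print(r["allocation_summary"]["allocated_of_unlinked_pct"])   # 100.0
print(round(r["uncorrected"]["summary"]["mean_pct"], 1))      # -10.8
print(round(r["corrected"]["summary"]["mean_pct"], 1))        # -0.3
```

On the default synthetic study (two census waves of 50,000 persons, ~5% of
deaths unlinked), every unlinked certificate is allocated; the uncorrected
all-cause rates in the 85+ age group under-estimate the ground-truth
reference rates by 10.8% on average over 1991–2007, and after allocation
the mean relative difference shrinks to −0.3%.

The factor-to-percent conversion used for reporting coding-change effects:

```python
percent_reduction_from_factor(0.843, 0.767, 0.926)   # (16, (7, 23))
```

a multiplication factor of 0.843 (95% CI 0.767–0.926) is a 16% rate
reduction (95% CI 7%–23%) attributable to the coding change.

The numbered scripts under `analysis/` run the same studies as a narrated
sequence (`01_simulate.py` … `05_robustness.py`) and write their tables
under `results/`.

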