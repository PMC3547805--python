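"""Predefined synthetic study designs and their runners.

Three studies exercise the pipeline end to end:

* the **recovery study** — a single-wave elderly cohort whose pre-1995
  coder induces a coding step of known, analytically computable magnitude
  (default factor 0.85) for the residual-cancer group; replicated fits of
  the trend model measure confidence-interval coverage and the absolute
  error of the estimated multiplication factor;
* the **correction study** — the default two-wave population with ~5%
  unlinked deaths; compares cohort rates excluding/including allocated
  deaths against ground-truth reference rates;
* the **robustness study** — a single-wave cohort used to compare hazard
  ratios with and without unlinked deaths, under non-differential and
  education-differential linkage failure.

The design sizes (number of persons, follow-up spans) are part of the
study definitions; the methods note documents the power reasoning behind
them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date

import numpy as np

from .hazards import ExposureSpec, compare_with_without
from .lexis import (
    ALL_CAUSE,
    CohortWindow,
    death_counts,
    follow_up_intervals,
    mortality_rates,
    person_time_table,
)
from .linkage import allocate_unlinked
from .reporting import RunConfig, run_pipeline
from .synthpop import (
    HazardConfig,
    PopulationConfig,
    StudyConfig,
    UnlinkConfig,
    analytic_step_factor,
    calibrate_mention_prob,
    generate_census,
    generate_study,
    simulate_followup,
)
from .trendmodel import (
    TrendModelSpec,
    fit_poisson_trend,
    multiplication_factor,
    stratum_year_data,
)


# ---------------------------------------------------------------------------
# Default two-wave study


def default_study_config(seed: int = 0, n_persons: int = 50_000) -> StudyConfig:
    """The standard synthetic study: two census waves, ~5% unlinked deaths."""
    pop = PopulationConfig(n_persons=n_persons, census_date=date(1990, 12, 5))
    return StudyConfig(population=pop, hazards=HazardConfig(),
                       unlink=UnlinkConfig(), wave2_target=n_persons,
                       seed=seed)


# ---------------------------------------------------------------------------
# Coding-step recovery study

RECOVERY_TARGET_FACTOR = 0.85
RECOVERY_CAUSE = "other_cancer"
_RECOVERY_BANDS = (0,)  # single attained-age band: the whole cohort


def recovery_hazard_config(target_factor: float = RECOVERY_TARGET_FACTOR
                           ) -> HazardConfig:
    """Flat-trend hazards for an elderly female cohort with a known step.

    Only the residual-cancer cause carries a mention probability, so the
    pre-1995 priority coder inflates its official rate by a factor that is
    exactly computable from the hazards; the true multiplication factor is
    the configured target.
    """
    z = (0.0,)
    hz = HazardConfig(
        age_breaks=_RECOVERY_BANDS,
        baseline_hazard={
            "breast": {"female": (0.002,), "male": z},
            "prostate": {"female": z, "male": z},
            "other_cancer": {"female": (0.040,), "male": z},
            "cardiovascular": {"female": (0.080,), "male": z},
            "suicide": {"female": (0.0005,), "male": z},
            "other": {"female": (0.045,), "male": z},
        },
        log_linear_trend={},
        mention_prob={},
        emigration_hazard=(0.0,),
        covariate_log_hr={},
        marital_transition_rate=0.0,
        residence_move_prob=0.0,
    )
    m = calibrate_mention_prob(hz, RECOVERY_CAUSE, "female", 0, target_factor)
    hz.mention_prob = {RECOVERY_CAUSE: m}
    return hz


def recovery_population(seed: int, n_persons: int = 50_000) -> PopulationConfig:
    """Women aged 75-90 at the 1990 census (where the coding step bites)."""
    cfg = PopulationConfig(
        n_persons=n_persons,
        census_date=date(1990, 12, 5),
        birth_date_range=(date(1900, 12, 5), date(1915, 12, 5)),
        seed=seed,
    )
    cfg.marginals = dict(cfg.marginals)
    cfg.marginals["sex"] = {"female": 1.0, "male": 0.0}
    return cfg


def run_recovery_replicate(seed: int, n_persons: int = 50_000,
                           target_factor: float = RECOVERY_TARGET_FACTOR):
    """One replicate: simulate, rebuild rates, fit, return the factor."""
    hz = recovery_hazard_config(target_factor)
    pop = recovery_population(seed, n_persons)
    census = generate_census(pop)
    window = CohortWindow(pop.census_date, date(2007, 12, 31))
    deaths, emig = simulate_followup(census, hz, window.census_date,
                                     window.end_date, seed=seed)
    intervals = follow_up_intervals(
        census, deaths[["person_id", "death_date", "official_cause"]],
        emig, window)
    pt = person_time_table(intervals, _RECOVERY_BANDS)
    counts = death_counts(intervals, _RECOVERY_BANDS)
    rates = mortality_rates(counts, pt)
    data = stratum_year_data(rates, RECOVERY_CAUSE, "female", "0+",
                             years=range(1991, 2008))
    spec = TrendModelSpec(cause=RECOVERY_CAUSE, sex="female", age_group="0+")
    fit = fit_poisson_trend(data, spec)
    return multiplication_factor(fit)


@dataclass
class RecoveryResult:
    true_factor: float
    estimates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    @property
    def coverage(self) -> float:
        return float(np.mean((self.ci_low <= self.true_factor)
                             & (self.true_factor <= self.ci_high)))

    @property
    def mean_abs_error(self) -> float:
        return float(np.mean(np.abs(self.estimates - self.true_factor)))


def coding_step_recovery(n_replicates: int = 200, seed: int = 0,
                         n_persons: int = 50_000,
                         target_factor: float = RECOVERY_TARGET_FACTOR
                         ) -> RecoveryResult:
    """Replicate the recovery study; report CI coverage and absolute error."""
    hz = recovery_hazard_config(target_factor)
    truth = analytic_step_factor(hz, RECOVERY_CAUSE, "female", 0)
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_replicates)
    est, lo, hi = [], [], []
    for s in seeds:
        mf = run_recovery_replicate(int(s), n_persons, target_factor)
        est.append(mf.point)
        lo.append(mf.ci_low)
        hi.append(mf.ci_high)
    return RecoveryResult(true_factor=truth, estimates=np.array(est),
                          ci_low=np.array(lo), ci_high=np.array(hi))


# ---------------------------------------------------------------------------
# Rate-correction study


def rate_correction_study(seed: int = 0, n_persons: int = 50_000,
                          age_group: str = "85+") -> dict:
    """Run the default study and compare rates against the reference.

    Returns the per-year relative differences and summaries for the
    uncorrected (excluding unlinked deaths) and corrected (including
    allocated deaths) all-cause rates in the focus age group, both sexes
    pooled, plus the allocation summary.
    """
    cfg = RunConfig(study=default_study_config(seed, n_persons),
                    focus_age_groups=(age_group,), run_hazards=False)
    bundle = run_pipeline(cfg)
    uncorrected = bundle["rate_comparisons"][(age_group, "excluding")]
    corrected = bundle["rate_comparisons"][(age_group, "including")]
    return {
        "bundle": bundle,
        "uncorrected": uncorrected,
        "corrected": corrected,
        "allocation_summary": bundle["allocation_summary"],
    }


# ---------------------------------------------------------------------------
# Hazard-ratio robustness study


def robustness_study_config(seed: int, n_persons: int = 50_000,
                            differential: bool = False) -> StudyConfig:
    """Single-wave cohort (2000-2007) of adults aged 50-95 at census.

    ``differential=True`` makes linkage failure depend strongly on
    education (tertiary certificates unlink six times as often), the
    mechanism that biases relative mortality.
    """
    pop = PopulationConfig(
        n_persons=n_persons,
        census_date=date(2000, 12, 5),
        birth_date_range=(date(1905, 12, 5), date(1950, 12, 5)),
        seed=seed,
    )
    unlink = UnlinkConfig()
    if differential:
        unlink = replace(unlink, education_multiplier={
            "compulsory": 1.0, "secondary": 1.0, "tertiary": 6.0})
    return StudyConfig(population=pop, hazards=HazardConfig(), unlink=unlink,
                       wave2_target=None, end_date=date(2007, 12, 31),
                       seed=seed)


def hr_robustness_study(seed: int = 0, n_persons: int = 50_000,
                        differential: bool = False,
                        cause: str = ALL_CAUSE) -> dict:
    """Education HRs with vs without unlinked deaths on one synthetic cohort."""
    cfg = robustness_study_config(seed, n_persons, differential)
    data = generate_study(cfg)
    year = cfg.population.census_date.year
    window = CohortWindow(*data.windows[year])
    census = data.censuses[year]
    res = allocate_unlinked(data.registry, census, seed=seed + 1,
                            emigrations=data.emigrations)
    spec = ExposureSpec(variable="education")
    comparison = compare_with_without(
        census, data.registry, res.allocations[["certificate_id", "person_id"]],
        spec, window, cause=cause, emigrations=data.emigrations)
    non_ref = comparison[~comparison["reference"]]
    return {
        "comparison": comparison,
        "max_abs_difference": float(non_ref["abs_difference"].max()),
        "allocation": res,
    }
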