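"""Descriptive tabulation and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from . import __version__
from .hazards import ExposureSpec, compare_with_without
from .lexis import (
    ALL_CAUSE,
    CohortWindow,
    cohort_rates,
    reference_rates,
    relative_difference,
)
from .linkage import (
    DEFAULT_TRANSITIONS,
    agreement_statistics,
    allocate_unlinked,
    allocation_summary,
)
from .synthpop import (
    DEFAULT_AGE_BREAKS,
    StudyConfig,
    StudyData,
    attained_age_band,
    generate_study,
    midyear_population,
    to_ordinal,
    write_study,
)
from .trendmodel import (
    TrendModelSpec,
    adjusted_rate_series,
    fit_poisson_trend,
    multiplication_factor,
    stratum_year_data,
)

# Age grouping used for descriptive tables (age at census, not attained age)
CHARACTERISTICS_AGE_BREAKS = (0, 15, 25, 35, 45, 55, 65, 75, 85, 95)

_CERT_VARS = ("sex", "nationality", "marital_status")
_CENSUS_VARS = ("education", "household", "religion", "urbanization")


def _age_labels(breaks) -> list[str]:
    out = []
    for i, a in enumerate(breaks):
        out.append(f"{a}-{breaks[i + 1] - 1}" if i + 1 < len(breaks) else f"{a}+")
    return out


def tabulate_characteristics(census: pd.DataFrame, registry: pd.DataFrame,
                             census_date: date,
                             allocations: pd.DataFrame | None = None
                             ) -> pd.DataFrame:
    """Descriptive table of all deaths, unlinked deaths and the census.

    Per covariate level: death count and column percent, unlinked count
    and *row* percent (unlinked / all deaths at that level), census count
    and column percent. Certificate variables (sex, age at census,
    nationality, marital status) are tabulated from the registry itself;
    census-only variables (education, household, religion, urbanization)
    from the census records of linked — and, when available, allocated —
    deaths.
    """
    if len(registry) == 0:
        raise ValueError("empty registry")

    rows = []

    def _block(var, death_levels, unlinked_levels, census_levels):
        levels = sorted(set(death_levels.unique()) | set(census_levels.unique()))
        d_tot, c_tot = len(death_levels), len(census_levels)
        for lev in levels:
            n_d = int((death_levels == lev).sum())
            n_u = int((unlinked_levels == lev).sum())
            n_c = int((census_levels == lev).sum())
            rows.append({
                "variable": var, "level": lev,
                "deaths_n": n_d,
                "deaths_col_pct": round(100 * n_d / d_tot, 1) if d_tot else np.nan,
                "unlinked_n": n_u,
                "unlinked_row_pct": round(100 * n_u / n_d, 1) if n_d else np.nan,
                "census_n": n_c,
                "census_col_pct": round(100 * n_c / c_tot, 1) if c_tot else np.nan,
            })

    unlinked = registry[~registry["linked"]]
    for var in _CERT_VARS:
        _block(var, registry[var], unlinked[var], census[var])

    # age at census, grouped as in descriptive demography tables
    def _age_groups(birth):
        ords = birth.to_numpy().astype("M8[D]").astype("int64")
        band = attained_age_band(ords, np.full(len(ords), to_ordinal(census_date)),
                                 CHARACTERISTICS_AGE_BREAKS)
        return pd.Series(np.array(_age_labels(CHARACTERISTICS_AGE_BREAKS),
                                  dtype=object)[band])

    _block("age_at_census", _age_groups(registry["birth_date"]),
           _age_groups(unlinked["birth_date"]), _age_groups(census["birth_date"]))

    # census-only covariates via the person each death resolves to
    resolved = registry.loc[registry["linked"],
                            ["certificate_id", "person_id"]].copy()
    resolved["person_id"] = resolved["person_id"].astype("int64")
    resolved["from_allocation"] = False
    if allocations is not None and len(allocations):
        alloc = allocations[["certificate_id", "person_id"]].copy()
        alloc["from_allocation"] = True
        resolved = pd.concat([resolved, alloc], ignore_index=True)
    merged = resolved.merge(census, on="person_id", how="inner")
    for var in _CENSUS_VARS:
        if var in census.columns:
            _block(var, merged[var],
                   merged.loc[merged["from_allocation"], var], census[var])
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, with seeds recorded."""

    study: StudyConfig
    out_dir: str | None = None
    allocation_seed: int = 12345
    age_breaks: tuple[int, ...] = DEFAULT_AGE_BREAKS
    analysis_years: tuple[int, int] = (1991, 2007)
    focus_age_groups: tuple[str, ...] = ("75-84", "85+")
    trend_strata: tuple = (("prostate", "male", "85+"),
                           ("breast", "female", "85+"),
                           ("other_cancer", "male", "85+"),
                           ("suicide", "male", "85+"))
    hazard_exposure: str = "education"
    run_hazards: bool = True
    run_trends: bool = True


def combine_rate_tables(tables) -> pd.DataFrame:
    """Sum deaths and exposure over cohort windows, then re-derive rates."""
    cat = pd.concat(tables, ignore_index=True)
    g = (cat.groupby(["year", "sex", "age_group", "cause"], as_index=False)
         .agg(deaths=("deaths", "sum"), person_years=("person_years", "sum")))
    g["rate_per_100k"] = g["deaths"] / g["person_years"] * 1e5
    return g


def run_pipeline(config: RunConfig, data: StudyData | None = None) -> dict:
    """Generate -> allocate -> rates -> trend -> hazards, returning a bundle.

    Deterministic for a fixed config: the same seeds give byte-identical
    CSV output. When ``out_dir`` is set all tables plus a JSON manifest
    are written there.
    """
    if data is None:
        data = generate_study(config.study)
    bundle: dict = {"data": data}

    # --- pragmatic allocation, per cohort window
    alloc_frames, unallocated = [], []
    agreements = []
    for year, (start, end) in sorted(data.windows.items()):
        census = data.censuses[year]
        in_window = ((data.registry["death_date"] > pd.Timestamp(start))
                     & (data.registry["death_date"] <= pd.Timestamp(end)))
        reg = data.registry[in_window]
        res = allocate_unlinked(reg, census, DEFAULT_TRANSITIONS,
                                seed=config.allocation_seed + year,
                                emigrations=data.emigrations)
        alloc_frames.append(res.allocations.assign(cohort=year))
        unallocated.extend(res.unallocated)
        agreements.append(agreement_statistics(res, census, reg)
                          .assign(cohort=year))
    allocations = pd.concat(alloc_frames, ignore_index=True)
    bundle["allocations"] = allocations
    bundle["agreement"] = pd.concat(agreements, ignore_index=True)

    n_unlinked = int((~data.registry["linked"]).sum())
    from .linkage import summarize_counts
    bundle["allocation_summary"] = summarize_counts(
        n_unlinked, len(allocations), len(data.registry))

    # --- descriptive characteristics on the most recent wave
    last = max(data.windows)
    start, end = data.windows[last]
    in_last = ((data.registry["death_date"] > pd.Timestamp(start))
               & (data.registry["death_date"] <= pd.Timestamp(end)))
    bundle["characteristics"] = tabulate_characteristics(
        data.censuses[last], data.registry[in_last],
        census_date=start,
        allocations=allocations[allocations["cohort"] == last])

    # --- rates: cohort excluding / including unlinked, and the reference
    excl_tables, incl_tables = [], []
    for year, (start, end) in sorted(data.windows.items()):
        window = CohortWindow(start, end)
        census = data.censuses[year]
        in_window = ((data.registry["death_date"] > pd.Timestamp(start))
                     & (data.registry["death_date"] <= pd.Timestamp(end)))
        reg = data.registry[in_window]
        alloc = allocations[allocations["cohort"] == year]
        excl_tables.append(cohort_rates(census, reg, window,
                                        emigrations=data.emigrations,
                                        age_breaks=config.age_breaks,
                                        include_allocated=False))
        incl_tables.append(cohort_rates(census, reg, window, allocations=alloc,
                                        emigrations=data.emigrations,
                                        age_breaks=config.age_breaks,
                                        include_allocated=True))
    rates_excl = combine_rate_tables(excl_tables)
    rates_incl = combine_rate_tables(incl_tables)
    bundle["rates_excluding"] = rates_excl
    bundle["rates_including"] = rates_incl

    years = range(config.analysis_years[0], config.analysis_years[1] + 1)
    midyear = midyear_population(data.persons, years, config.age_breaks)
    ref = reference_rates(data.registry, midyear, config.age_breaks,
                          years=years)
    bundle["reference_rates"] = ref

    comparisons = {}
    for age_group in config.focus_age_groups:
        for label, table in (("excluding", rates_excl), ("including", rates_incl)):
            per_year, summary = relative_difference(
                table, ref, cause=ALL_CAUSE, age_group=age_group, years=years)
            comparisons[(age_group, label)] = {"per_year": per_year,
                                               "summary": summary}
    bundle["rate_comparisons"] = comparisons

    # --- coding-change trend models on the corrected rates
    trend_rows, trend_series = [], {}
    for cause, sex, age_group in (config.trend_strata if config.run_trends else ()):
        d = stratum_year_data(rates_incl, cause, sex, age_group, years)
        if len(d) == 0 or d["deaths"].sum() == 0:
            continue
        spec = TrendModelSpec(cause=cause, sex=sex, age_group=age_group)
        try:
            fit = fit_poisson_trend(d, spec)
        except ValueError:
            continue
        mf = multiplication_factor(fit)
        trend_rows.append({"cause": cause, "sex": sex, "age_group": age_group,
                           "factor": mf.point, "ci_low": mf.ci_low,
                           "ci_high": mf.ci_high,
                           "percent_reduction": mf.percent_reduction,
                           "converged": fit.converged})
        trend_series[(cause, sex, age_group)] = adjusted_rate_series(fit)
    bundle["multiplication_factors"] = pd.DataFrame(trend_rows)
    bundle["trend_series"] = trend_series

    # --- hazard-ratio robustness on the most recent wave
    if config.run_hazards:
        spec = ExposureSpec(variable=config.hazard_exposure)
        window = CohortWindow(*data.windows[last])
        bundle["hr_comparison"] = compare_with_without(
            data.censuses[last], data.registry[in_last],
            allocations[allocations["cohort"] == last][["certificate_id",
                                                        "person_id"]],
            spec, window, emigrations=data.emigrations,
            age_breaks=config.age_breaks)
    else:
        bundle["hr_comparison"] = None

    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    write_study(bundle["data"], out)
    for name in ("allocations", "agreement", "characteristics",
                 "rates_excluding", "rates_including", "reference_rates",
                 "multiplication_factors", "hr_comparison"):
        obj = bundle.get(name)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(os.path.join(out, f"{name}.csv"), index=False)
    comp_rows = []
    for (age_group, label), c in bundle["rate_comparisons"].items():
        comp_rows.append({"age_group": age_group, "rates": label,
                          **c["summary"]})
    pd.DataFrame(comp_rows).to_csv(os.path.join(out, "rate_comparison_summary.csv"),
                                   index=False)
    manifest = {
        "package_version": __version__,
        "study_seed": config.study.seed,
        "allocation_seed": config.allocation_seed,
        "n_persons_wave1": config.study.population.n_persons,
        "wave2_target": config.study.wave2_target,
        "age_breaks": list(config.age_breaks),
        "analysis_years": list(config.analysis_years),
        "allocation_summary": {k: (None if isinstance(v, float) and np.isnan(v)
                                   else v)
                               for k, v in bundle["allocation_summary"].items()},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
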