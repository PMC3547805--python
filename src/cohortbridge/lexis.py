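"""Person-time at risk and mortality rates on the calendar-year Lexis grid.

Follow-up runs from a census date to the earliest of death, emigration or
the administrative end of the window. Exposure is counted in whole days on
the half-open convention (census_date, stop]: the census day itself
contributes no risk time, the stop day does. Person-time is split exactly
at calendar-year boundaries and at the birthdays on which a person crosses
an attained-age band boundary, so the per-stratum days always sum to the
interval length to the day.

Rates are deaths per 100,000 person-years with person-years = days/365.25.
Reference rates divide all registered deaths by mid-year population counts,
mirroring how national statistical offices compute official rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .synthpop import (
    DEFAULT_AGE_BREAKS,
    SEXES,
    age_band_crossings,
    to_ordinal,
)

ALL_CAUSE = "all"
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CohortWindow:
    census_date: date
    end_date: date

    def __post_init__(self):
        if self.end_date <= self.census_date:
            raise ValueError("end_date must be after census_date")


def age_group_labels(age_breaks=DEFAULT_AGE_BREAKS) -> list[str]:
    labels = []
    for i, a in enumerate(age_breaks):
        if i + 1 < len(age_breaks):
            labels.append(f"{a}-{age_breaks[i + 1] - 1}")
        else:
            labels.append(f"{a}+")
    return labels


def follow_up_interval(census_date, end_date, death_date=None,
                       emigration_date=None):
    """Stop date and terminal event for one person ("whichever came first").

    Ties are resolved death > emigration > administrative censoring.
    """
    census = pd.Timestamp(census_date)
    candidates = [(pd.Timestamp(end_date), "administrative")]
    if emigration_date is not None and not pd.isna(emigration_date):
        candidates.append((pd.Timestamp(emigration_date), "emigration"))
    if death_date is not None and not pd.isna(death_date):
        candidates.append((pd.Timestamp(death_date), "death"))
    for d, kind in candidates[1:]:
        if d <= census:
            raise ValueError(f"{kind} date {d.date()} not after census {census.date()}")
    # stable preference on ties: death beats emigration beats censoring
    order = {"death": 0, "emigration": 1, "administrative": 2}
    stop, kind = min(candidates, key=lambda t: (t[0], order[t[1]]))
    return stop, kind


def follow_up_intervals(census: pd.DataFrame, deaths: pd.DataFrame,
                        emigrations: pd.DataFrame,
                        window: CohortWindow) -> pd.DataFrame:
    """One follow-up interval per census person (vectorised).

    ``deaths`` needs columns person_id, death_date and (optionally) a
    cause column named ``official_cause`` or ``cause``; only deaths and
    emigrations falling inside the window terminate follow-up.
    """
    df = census[["person_id", "sex", "birth_date"]].copy()
    df["start"] = pd.Timestamp(window.census_date)
    end = pd.Timestamp(window.end_date)

    cause_col = None
    if deaths is not None and len(deaths):
        cause_col = ("official_cause" if "official_cause" in deaths.columns
                     else "cause" if "cause" in deaths.columns else None)
        cols = ["person_id", "death_date"] + ([cause_col] if cause_col else [])
        d = deaths[cols].drop_duplicates("person_id")
        df = df.merge(d, on="person_id", how="left")
        if (df["death_date"] <= df["start"]).any():
            raise ValueError("death date on or before census date")
    else:
        df["death_date"] = pd.NaT
    if emigrations is not None and len(emigrations):
        e = emigrations[["person_id", "emigration_date"]].drop_duplicates("person_id")
        df = df.merge(e, on="person_id", how="left")
    else:
        df["emigration_date"] = pd.NaT

    death = df["death_date"].where(df["death_date"] <= end)
    emig = df["emigration_date"].where(df["emigration_date"] <= end)
    stop = pd.concat([death, emig], axis=1).min(axis=1).fillna(end)
    terminal = np.where(death.notna() & (death == stop), "death",
                        np.where(emig.notna() & (emig == stop),
                                 "emigration", "administrative"))
    out = pd.DataFrame({
        "person_id": df["person_id"],
        "sex": df["sex"],
        "birth_date": df["birth_date"],
        "start": df["start"],
        "stop": stop,
        "terminal_event": terminal,
        "cause": (df[cause_col] if cause_col else pd.Series(pd.NA, index=df.index)),
    })
    out.loc[out["terminal_event"] != "death", "cause"] = pd.NA
    return out


def _year_slice_arrays(start_ord, stop_ord, cross, years):
    """Yield (year, person_index, band, slice_start, slice_end) arrays.

    Slices partition each (start, stop] interval at 1 January boundaries
    and age-band birthdays; slice bounds are inclusive day ordinals.
    """
    jan1 = np.array([to_ordinal(date(int(y), 1, 1)) for y in
                     list(years) + [years[-1] + 1]], dtype="int64")
    nb = cross.shape[1]
    big = np.iinfo("int64").max // 2
    for yi, y in enumerate(years):
        o_start = np.maximum(start_ord + 1, jan1[yi])
        o_end = np.minimum(stop_ord, jan1[yi + 1] - 1)
        m = o_end >= o_start
        if not m.any():
            continue
        idx = np.flatnonzero(m)
        os_, oe = o_start[idx], o_end[idx]
        band_s = np.maximum((cross[idx] <= os_[:, None]).sum(axis=1) - 1, 0)
        band_e = np.maximum((cross[idx] <= oe[:, None]).sum(axis=1) - 1, 0)
        for b in range(int(band_s.min()), int(band_e.max()) + 1):
            entry = cross[idx, b] if b > 0 else np.full(len(idx), -big)
            nxt = cross[idx, b + 1] if b + 1 < nb else np.full(len(idx), big)
            lo = np.maximum(os_, entry)
            hi = np.minimum(oe, nxt - 1)
            sel = (hi >= lo) & (band_s <= b) & (b <= band_e)
            if sel.any():
                yield (int(y), idx[sel], b, lo[sel], hi[sel])


def person_time_table(intervals: pd.DataFrame,
                      age_breaks=DEFAULT_AGE_BREAKS,
                      window: CohortWindow | None = None) -> pd.DataFrame:
    """Days of exposure per (calendar year, sex, attained-age group).

    Conservation is exact: summed over strata, the days equal
    sum(stop - start) over the intervals.
    """
    if len(intervals) == 0:
        return pd.DataFrame(columns=["year", "sex", "age_group", "days"])
    iv = intervals.sort_values(["person_id", "start"])
    starts_by_p = iv.groupby("person_id")["start"].shift(-1)
    overlap = (starts_by_p.notna()) & (starts_by_p < iv["stop"])
    if overlap.any():
        raise ValueError("overlapping follow-up intervals for a person")

    start_ord = intervals["start"].to_numpy().astype("M8[D]").astype("int64")
    stop_ord = intervals["stop"].to_numpy().astype("M8[D]").astype("int64")
    if (stop_ord <= start_ord).any():
        raise ValueError("interval stop must be after start")
    birth = intervals["birth_date"].to_numpy().astype("M8[D]").astype("int64")
    sex_idx = (intervals["sex"].to_numpy() == "male").astype(int)
    cross = age_band_crossings(birth, age_breaks)

    y0 = int(pd.Timestamp(intervals["start"].min()).year)
    y1 = int(pd.Timestamp(intervals["stop"].max()).year)
    years = list(range(y0, y1 + 1))
    labels = age_group_labels(age_breaks)

    acc: dict[tuple, int] = {}
    for y, idx, b, lo, hi in _year_slice_arrays(start_ord, stop_ord, cross, years):
        days = hi - lo + 1
        for s in (0, 1):
            total = int(days[sex_idx[idx] == s].sum())
            if total:
                key = (y, SEXES[s], labels[b])
                acc[key] = acc.get(key, 0) + total
    rows = [{"year": y, "sex": s, "age_group": g, "days": d}
            for (y, s, g), d in sorted(acc.items())]
    return pd.DataFrame(rows)


def death_counts(intervals: pd.DataFrame,
                 age_breaks=DEFAULT_AGE_BREAKS) -> pd.DataFrame:
    """Deaths per (year, sex, age group, cause), attained age at death."""
    d = intervals[intervals["terminal_event"] == "death"]
    if len(d) == 0:
        return pd.DataFrame(columns=["year", "sex", "age_group", "cause", "deaths"])
    birth = d["birth_date"].to_numpy().astype("M8[D]").astype("int64")
    at = d["stop"].to_numpy().astype("M8[D]").astype("int64")
    cross = age_band_crossings(birth, age_breaks)
    band = np.maximum((cross <= at[:, None]).sum(axis=1) - 1, 0)
    labels = age_group_labels(age_breaks)
    out = pd.DataFrame({
        "year": d["stop"].dt.year.to_numpy(),
        "sex": d["sex"].to_numpy(),
        "age_group": np.array(labels, dtype=object)[band],
        "cause": d["cause"].to_numpy(),
    })
    counts = (out.value_counts().rename("deaths").reset_index()
              .sort_values(["year", "sex", "age_group", "cause"]))
    return counts.reset_index(drop=True)


def mortality_rates(counts: pd.DataFrame, person_time: pd.DataFrame,
                    per: float = 1e5) -> pd.DataFrame:
    """Rate table: deaths / person-years x 100,000, plus the all-cause row.

    Every stratum with positive person-time appears for every cause present
    in the counts (zero deaths -> rate 0). A stratum with deaths but no
    person-time is an accounting error and raises.
    """
    pt = person_time.copy()
    pt["person_years"] = pt["days"] / DAYS_PER_YEAR

    if len(counts) == 0:
        out = pt[["year", "sex", "age_group", "person_years"]].copy()
        out["cause"] = ALL_CAUSE
        out["deaths"] = 0
        out["rate_per_100k"] = 0.0
        return out.reset_index(drop=True)

    all_cause = (counts.groupby(["year", "sex", "age_group"], as_index=False)
                 ["deaths"].sum().assign(cause=ALL_CAUSE))
    full = pd.concat([counts, all_cause], ignore_index=True)

    causes = sorted(full["cause"].unique())
    grid = pt[["year", "sex", "age_group", "person_years"]].merge(
        pd.DataFrame({"cause": causes}), how="cross")
    rates = grid.merge(full, on=["year", "sex", "age_group", "cause"], how="outer")

    orphan = rates["person_years"].isna() & (rates["deaths"].fillna(0) > 0)
    if orphan.any():
        bad = rates.loc[orphan, ["year", "sex", "age_group"]].drop_duplicates()
        raise ValueError(f"deaths in strata without person-time:\n{bad}")
    rates = rates[rates["person_years"].notna()].copy()
    rates["deaths"] = rates["deaths"].fillna(0).astype(int)
    rates["rate_per_100k"] = rates["deaths"] / rates["person_years"] * per
    return rates.sort_values(["year", "sex", "age_group", "cause"]).reset_index(drop=True)


def cohort_rates(census: pd.DataFrame, registry: pd.DataFrame,
                 window: CohortWindow,
                 allocations: pd.DataFrame | None = None,
                 emigrations: pd.DataFrame | None = None,
                 age_breaks=DEFAULT_AGE_BREAKS,
                 include_allocated: bool = False) -> pd.DataFrame:
    """Cohort-based rates for one window, with or without allocated deaths.

    Excluding unlinked deaths, only certificates the main linkage resolved
    terminate follow-up: the persons behind unlinked certificates keep
    accruing person-time to the end of the window (the mechanism that
    biases rates downward). When ``include_allocated`` is set, allocated
    certificates (certificate -> person from the pragmatic linkage) also
    count as deaths and stop their person's clock.
    """
    linked = registry[registry["linked"]]
    deaths = pd.DataFrame({
        "person_id": linked["person_id"].astype("int64"),
        "death_date": linked["death_date"],
        "official_cause": linked["official_cause"],
    })
    if include_allocated and allocations is not None and len(allocations):
        alloc = allocations.merge(
            registry[["certificate_id", "death_date", "official_cause"]],
            on="certificate_id", how="left")
        deaths = pd.concat([deaths, alloc[["person_id", "death_date",
                                           "official_cause"]]], ignore_index=True)
    deaths = deaths[deaths["person_id"].isin(census["person_id"])]
    intervals = follow_up_intervals(census, deaths, emigrations, window)
    pt = person_time_table(intervals, age_breaks, window)
    counts = death_counts(intervals, age_breaks)
    rates = mortality_rates(counts, pt)
    return rates


def reference_rates(registry: pd.DataFrame, midyear: pd.DataFrame,
                    age_breaks=DEFAULT_AGE_BREAKS,
                    per: float = 1e5,
                    years=None) -> pd.DataFrame:
    """Official-style rates: all registered deaths / mid-year population.

    Uses every certificate (linked or not); strata come from the
    certificate's own sex, birth date (attained age at death) and year of
    death. ``years`` restricts to the analysis window (certificates from
    other years are ignored). Raises if a stratum with deaths is missing
    from the population table or has a zero count.
    """
    if years is not None:
        registry = registry[registry["death_date"].dt.year.isin(list(years))]
    birth = registry["birth_date"].to_numpy().astype("M8[D]").astype("int64")
    at = registry["death_date"].to_numpy().astype("M8[D]").astype("int64")
    cross = age_band_crossings(birth, age_breaks)
    band = np.maximum((cross <= at[:, None]).sum(axis=1) - 1, 0)
    labels = age_group_labels(age_breaks)
    d = pd.DataFrame({
        "year": registry["death_date"].dt.year.to_numpy(),
        "sex": registry["sex"].to_numpy(),
        "age_group": np.array(labels, dtype=object)[band],
        "cause": registry["official_cause"].to_numpy(),
    })
    counts = d.value_counts().rename("deaths").reset_index()
    all_cause = (counts.groupby(["year", "sex", "age_group"], as_index=False)
                 ["deaths"].sum().assign(cause=ALL_CAUSE))
    counts = pd.concat([counts, all_cause], ignore_index=True)

    rates = counts.merge(midyear, on=["year", "sex", "age_group"], how="left")
    bad = rates["midyear_pop"].isna() | (rates["midyear_pop"] <= 0)
    if bad.any():
        missing = rates.loc[bad, ["year", "sex", "age_group"]].drop_duplicates()
        raise ValueError(f"midyear population missing/zero for strata:\n{missing}")
    rates["rate_per_100k"] = rates["deaths"] / rates["midyear_pop"] * per
    return rates.sort_values(["year", "sex", "age_group", "cause"]).reset_index(drop=True)


def relative_difference(cohort_rate_table: pd.DataFrame, ref_rates: pd.DataFrame,
                        cause: str, age_group: str,
                        sex: str | None = None,
                        years=None) -> tuple[pd.DataFrame, dict]:
    """Per-year percentage difference (cohort - reference)/reference, and summary.

    With ``sex=None`` both sexes are pooled by summing numerators and
    denominators before forming each rate. Years where the reference rate
    is zero are flagged undefined and excluded from the summary.
    """
    def _pool(df, denom_col):
        sel = df[(df["cause"] == cause) & (df["age_group"] == age_group)]
        if sex is not None:
            sel = sel[sel["sex"] == sex]
        g = sel.groupby("year", as_index=False).agg(
            deaths=("deaths", "sum"), denom=(denom_col, "sum"))
        return g

    coh = _pool(cohort_rate_table, "person_years")
    coh["cohort_rate"] = coh["deaths"] / coh["denom"] * 1e5
    ref = _pool(ref_rates, "midyear_pop")
    ref["ref_rate"] = ref["deaths"] / ref["denom"] * 1e5

    out = coh[["year", "cohort_rate"]].merge(ref[["year", "ref_rate"]], on="year",
                                          how="inner")
    if years is not None:
        out = out[out["year"].isin(list(years))]
    undefined = (out["ref_rate"] == 0) & (out["cohort_rate"] > 0)
    out = out.copy()
    out["rel_diff_pct"] = np.where(
        out["ref_rate"] > 0,
        (out["cohort_rate"] - out["ref_rate"]) / out["ref_rate"] * 100.0, np.nan)
    out["undefined"] = undefined
    valid = out.loc[~undefined & out["ref_rate"].gt(0), "rel_diff_pct"]
    summary = {
        "mean_pct": float(valid.mean()) if len(valid) else np.nan,
        "min_pct": float(valid.min()) if len(valid) else np.nan,
        "max_pct": float(valid.max()) if len(valid) else np.nan,
        "n_years": int(len(valid)),
        "n_undefined": int(undefined.sum()),
    }
    return out.reset_index(drop=True), summary
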