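"""Synthetic census populations, mortality follow-up and death registry.

This module manufactures the raw material of a census-based mortality
cohort: census waves, cause-specific death and emigration events simulated
with competing exponential clocks (piecewise-constant over calendar years
and attained-age bands), a pre/post-1995 cause-of-death coder, and a death
registry in which a configurable subset of certificates is rendered
"unlinked" by perturbing the identifying fields. Ground truth (which person
each certificate belongs to) is returned in a separate table that downstream
analytic modules must never read; only the evaluation harness may.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from .causes import (
    CAUSES,
    DEFAULT_PRIORITY_CAUSES,
    SEX_RESTRICTED,
    normalize_cause,
)
from .geography import CANTONS, CANTON_TO_REGION

SEXES = ("female", "male")
MARITAL_STATUSES = ("single", "married", "widowed", "divorced")
EDUCATION_LEVELS = ("compulsory", "secondary", "tertiary")
RELIGIONS = ("protestant", "catholic", "none", "other")
URBANIZATIONS = ("urban", "periurban", "rural")
HOUSEHOLDS = ("single", "multi", "institution")

# Plausible marital-status successions between census and death: legal
# transitions only (a widowed or divorced person can never revert to
# never-married).
MARITAL_SUCCESSORS: dict[str, tuple[str, ...]] = {
    "single": ("married",),
    "married": ("widowed", "divorced"),
    "widowed": ("married",),
    "divorced": ("married",),
}

DEFAULT_AGE_BREAKS = (0, 5, 15, 25, 35, 45, 55, 65, 75, 85)

_EPOCH = np.datetime64("1970-01-01", "D")


def to_ordinal(d) -> int:
    """Days since 1970-01-01 for a date / Timestamp / datetime64."""
    return int((np.datetime64(d, "D") - _EPOCH).astype(int))


def ordinals_to_dates(arr) -> np.ndarray:
    return _EPOCH + np.asarray(arr, dtype="int64")


def _add_years(ordinals: np.ndarray, years: int) -> np.ndarray:
    """Birthday arithmetic: same month/day in a later year, 29 Feb -> 1 Mar."""
    idx = pd.DatetimeIndex(ordinals_to_dates(ordinals))
    y = idx.year.to_numpy() + years
    m = idx.month.to_numpy().copy()
    d = idx.day.to_numpy().copy()
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    bad = (m == 2) & (d == 29) & ~leap
    m[bad] = 3
    d[bad] = 1
    out = pd.to_datetime({"year": y, "month": m, "day": d})
    return ((out.to_numpy().astype("M8[D]")) - _EPOCH).astype("int64")


def age_band_crossings(birth_ordinals: np.ndarray,
                       age_breaks=DEFAULT_AGE_BREAKS) -> np.ndarray:
    """Ordinal of the birthday at which each person enters each age band.

    Returns an (n_persons, n_bands) array; column j is the date the person
    attains age ``age_breaks[j]`` (column 0 is the birth date itself when
    the first break is 0).
    """
    birth_ordinals = np.asarray(birth_ordinals, dtype="int64")
    cols = [_add_years(birth_ordinals, a) if a else birth_ordinals.copy()
            for a in age_breaks]
    return np.stack(cols, axis=1)


def attained_age_band(birth_ordinals, at_ordinals, age_breaks=DEFAULT_AGE_BREAKS):
    """Index of the attained-age band at the given dates (vectorised)."""
    cross = age_band_crossings(birth_ordinals, age_breaks)
    at = np.asarray(at_ordinals, dtype="int64")
    return np.maximum((cross <= at[:, None]).sum(axis=1) - 1, 0)


# ---------------------------------------------------------------------------
# Population generation


def _default_marginals() -> dict[str, dict[str, float]]:
    # Loosely shaped like a western-European census population; canton
    # weights are uniform on purpose (no attempt at real canton sizes).
    return {
        "sex": {"female": 0.51, "male": 0.49},
        "canton": {c: 1.0 / 26 for c in CANTONS},
        "nationality": {"Swiss": 0.794, "non-Swiss": 0.206},
        "marital_status": {"single": 0.420, "married": 0.467,
                           "widowed": 0.057, "divorced": 0.056},
        "education": {"compulsory": 0.366, "secondary": 0.464,
                      "tertiary": 0.170},
        "religion": {"protestant": 0.353, "catholic": 0.418,
                     "none": 0.111, "other": 0.118},
        "urbanization": {"urban": 0.285, "periurban": 0.448, "rural": 0.267},
        "household": {"single": 0.154, "multi": 0.806, "institution": 0.040},
    }


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class PopulationConfig:
    """Parameters of one synthetic census wave.

    Ages at census are uniform over the span of ``birth_date_range``
    (default: 0-95 years); categorical attributes are drawn independently
    from the marginal distributions, except that education is forced to
    ``not_applicable`` below age 15 and marital status to ``single`` below
    age 16.
    """

    n_persons: int
    census_date: date = date(1990, 12, 5)
    birth_date_range: tuple[date, date] | None = None
    marginals: dict[str, dict[str, float]] = field(default_factory=_default_marginals)
    canton_to_region: dict[str, str] = field(default_factory=lambda: dict(CANTON_TO_REGION))
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if self.birth_date_range is None:
            c = self.census_date
            self.birth_date_range = (date(c.year - 95, c.month, c.day), c)
        lo, hi = self.birth_date_range
        if lo > hi or hi > self.census_date:
            raise ConfigurationError("birth_date_range must end on/before census_date")
        for name, dist in self.marginals.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"marginal '{name}' sums to {tot}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"marginal '{name}' has negative mass")
        missing = set(self.marginals["canton"]) - set(self.canton_to_region)
        if missing:
            raise ConfigurationError(f"cantons without region: {sorted(missing)}")


def _sample_categorical(rng, dist: dict[str, float], n: int) -> np.ndarray:
    labels = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def generate_census(config: PopulationConfig, id_start: int = 1) -> pd.DataFrame:
    """Draw one census wave; one row per person, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    lo = to_ordinal(config.birth_date_range[0])
    hi = to_ordinal(config.birth_date_range[1])
    birth_ord = rng.integers(lo, hi + 1, size=n)

    df = pd.DataFrame({
        "person_id": np.arange(id_start, id_start + n, dtype="int64"),
        "sex": _sample_categorical(rng, config.marginals["sex"], n),
        "birth_date": ordinals_to_dates(birth_ord).astype("M8[ns]"),
    })
    census_ord = to_ordinal(config.census_date)
    age = (census_ord - birth_ord) / 365.25

    df["canton"] = _sample_categorical(rng, config.marginals["canton"], n)
    df["region"] = df["canton"].map(config.canton_to_region)
    df["nationality"] = _sample_categorical(rng, config.marginals["nationality"], n)
    df["marital_status"] = _sample_categorical(rng, config.marginals["marital_status"], n)
    df.loc[age < 16, "marital_status"] = "single"
    df["education"] = _sample_categorical(rng, config.marginals["education"], n)
    df.loc[age < 15, "education"] = "not_applicable"
    df["religion"] = _sample_categorical(rng, config.marginals["religion"], n)
    df["urbanization"] = _sample_categorical(rng, config.marginals["urbanization"], n)
    df["household"] = _sample_categorical(rng, config.marginals["household"], n)
    return df


# ---------------------------------------------------------------------------
# Hazards and event simulation


def _stylized_baseline() -> dict[str, dict[str, tuple[float, ...]]]:
    """Stylised cause x sex x age-band death hazards (events/person-year).

    Magnitudes are shaped like western-European vital statistics (steep age
    gradient, cardiovascular dominance in old age, sex-specific cancers)
    without reproducing any country's actual rates.
    Bands: 0-4, 5-14, 15-24, 25-34, 35-44, 45-54, 55-64, 65-74, 75-84, 85+.
    """
    z10 = (0.0,) * 10
    return {
        "breast": {
            "female": (0, 0, 1e-6, 1e-5, 1.5e-4, 4e-4, 6e-4, 9e-4, 1.5e-3, 2.5e-3),
            "male": z10,
        },
        "prostate": {
            "female": z10,
            "male": (0, 0, 0, 0, 1e-6, 2e-5, 2e-4, 8e-4, 2.2e-3, 4.5e-3),
        },
        "other_cancer": {
            "female": (2e-5, 2e-5, 3e-5, 5e-5, 1.5e-4, 6e-4, 1.6e-3, 3.5e-3, 6.5e-3, 1.1e-2),
            "male": (2e-5, 2e-5, 4e-5, 6e-5, 1.5e-4, 7e-4, 2.2e-3, 5.5e-3, 1.1e-2, 1.7e-2),
        },
        "cardiovascular": {
            "female": (1e-5, 5e-6, 1e-5, 2e-5, 5e-5, 2e-4, 8e-4, 3.2e-3, 1.6e-2, 7.0e-2),
            "male": (1e-5, 5e-6, 2e-5, 4e-5, 1.2e-4, 5e-4, 1.8e-3, 5.5e-3, 2.0e-2, 7.5e-2),
        },
        "suicide": {
            "female": (0, 0, 5e-5, 6e-5, 8e-5, 1.0e-4, 1.0e-4, 9e-5, 9e-5, 1.0e-4),
            "male": (0, 0, 1.5e-4, 2e-4, 2.2e-4, 2.5e-4, 2.5e-4, 2.5e-4, 3.5e-4, 4.5e-4),
        },
        "other": {
            "female": (1e-3, 1e-4, 1.5e-4, 2e-4, 4e-4, 1e-3, 2.5e-3, 7e-3, 3.0e-2, 9.0e-2),
            "male": (1.2e-3, 1.2e-4, 3e-4, 4e-4, 7e-4, 1.6e-3, 3.5e-3, 9e-3, 3.4e-2, 9.5e-2),
        },
    }


def _default_mention_prob() -> dict[str, float]:
    # Chance that a death with a different underlying cause carries this
    # cause as an additional certificate mention (the raw material of the
    # pre-1995 priority coder).
    return {"breast": 0.03, "prostate": 0.03, "other_cancer": 0.05}


def _default_emigration() -> tuple[float, ...]:
    return (0.010, 0.008, 0.015, 0.015, 0.010, 0.006, 0.004, 0.003, 0.001, 0.0005)


def _default_covariate_log_hr() -> dict[str, dict[str, float]]:
    return {
        "education": {"compulsory": 0.05, "secondary": 0.0, "tertiary": -0.105,
                      "not_applicable": 0.0},
        "marital_status": {"single": 0.15, "married": 0.0,
                           "widowed": 0.05, "divorced": 0.10},
        "nationality": {"Swiss": 0.0, "non-Swiss": -0.05},
    }


@dataclass
class HazardConfig:
    """Event-generating process for follow-up after a census.

    Death hazards are competing exponential clocks per cause, constant
    within (calendar year x attained-age band) cells; ``log_linear_trend``
    multiplies each cause hazard by exp(slope x (year - trend_ref_year)).
    ``covariate_log_hr`` applies proportional multiplicative effects of
    census covariates to every death cause (not to emigration).
    """

    age_breaks: tuple[int, ...] = DEFAULT_AGE_BREAKS
    baseline_hazard: dict[str, dict[str, tuple[float, ...]]] = field(
        default_factory=_stylized_baseline)
    log_linear_trend: dict[str, float] = field(default_factory=lambda: {
        "cardiovascular": -0.02, "other_cancer": -0.005, "suicide": -0.01})
    trend_ref_year: int = 1991
    mention_prob: dict[str, float] = field(default_factory=_default_mention_prob)
    priority_causes: tuple[str, ...] = DEFAULT_PRIORITY_CAUSES
    regime_switch_date: date = date(1995, 1, 1)
    emigration_hazard: tuple[float, ...] = field(default_factory=_default_emigration)
    covariate_log_hr: dict[str, dict[str, float]] = field(
        default_factory=_default_covariate_log_hr)
    marital_transition_rate: float = 0.02
    residence_move_prob: float = 0.10
    seed: int = 0

    def __post_init__(self):
        nb = len(self.age_breaks)
        for cause, by_sex in self.baseline_hazard.items():
            for sex, rates in by_sex.items():
                if len(rates) != nb:
                    raise ConfigurationError(
                        f"{cause}/{sex}: {len(rates)} rates for {nb} age bands")
                if any(r < 0 for r in rates):
                    raise ConfigurationError(f"negative hazard in {cause}/{sex}")
        if len(self.emigration_hazard) != nb:
            raise ConfigurationError("emigration_hazard length mismatch")
        if any(r < 0 for r in self.emigration_hazard):
            raise ConfigurationError("negative emigration hazard")
        for c, p in self.mention_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"mention_prob[{c}] outside [0,1]")
        if not 0.0 <= self.residence_move_prob <= 1.0:
            raise ConfigurationError("residence_move_prob outside [0,1]")

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.baseline_hazard)


def _covariate_multiplier(census: pd.DataFrame, hz: HazardConfig) -> np.ndarray:
    log_hr = np.zeros(len(census))
    for var, effects in hz.covariate_log_hr.items():
        if var in census.columns:
            log_hr += census[var].map(effects).fillna(0.0).to_numpy(dtype=float)
    return np.exp(log_hr)


def simulate_followup(census: pd.DataFrame, hz: HazardConfig,
                      census_date: date, end_date: date,
                      seed: int | None = None):
    """Simulate deaths and emigrations over (census_date, end_date].

    Competing exponential clocks per cause within piecewise-constant
    (calendar year x age band) cells; per person the earliest simulated
    event wins; everyone else is administratively censored at end_date.

    Returns ``(deaths, emigrations)`` data frames. Deaths carry the full
    certificate snapshot (fields as recorded at death, after plausible
    marital transitions and residence moves) plus the mention set and the
    official cause assigned by the regime-appropriate coder.
    """
    if end_date <= census_date:
        raise ConfigurationError("end_date must be after census_date")
    rng = np.random.default_rng(hz.seed if seed is None else seed)

    n = len(census)
    causes = list(hz.causes)
    n_causes = len(causes)
    birth_ord = (census["birth_date"].to_numpy().astype("M8[D]") - _EPOCH).astype("int64")
    sex_idx = (census["sex"].to_numpy() == "male").astype(int)
    start_ord = to_ordinal(census_date)
    end_ord = to_ordinal(end_date)

    # hazard lookup tables: (cause, sex, band)
    base = np.zeros((n_causes, 2, len(hz.age_breaks)))
    for ci, c in enumerate(causes):
        for si, s in enumerate(SEXES):
            base[ci, si, :] = hz.baseline_hazard[c][s]
    emig = np.asarray(hz.emigration_hazard, dtype=float)
    trend = np.array([hz.log_linear_trend.get(c, 0.0) for c in causes])
    cov_mult = _covariate_multiplier(census, hz)

    cross = age_band_crossings(birth_ord, hz.age_breaks)
    years = np.arange(census_date.year, end_date.year + 2)
    jan1 = np.array([to_ordinal(date(int(y), 1, 1)) for y in years], dtype="int64")

    t = np.full(n, float(start_ord))
    alive = np.ones(n, dtype=bool)
    event_kind = np.full(n, -1, dtype=int)   # cause index, or n_causes = emigration
    event_ord = np.zeros(n, dtype="int64")

    while alive.any():
        idx = np.flatnonzero(alive)
        ti = t[idx]
        yi = np.searchsorted(jan1, ti, side="right") - 1
        next_jan1 = jan1[yi + 1]
        band = np.maximum((cross[idx] <= ti[:, None]).sum(axis=1) - 1, 0)
        nb = len(hz.age_breaks)
        next_cross = np.where(band + 1 < nb,
                              cross[idx, np.minimum(band + 1, nb - 1)],
                              np.iinfo("int64").max)
        seg_end = np.minimum(np.minimum(next_jan1, next_cross), end_ord).astype(float)

        year_val = years[yi]
        lam = base[:, sex_idx[idx], band].T  # (m, n_causes)
        lam = lam * np.exp(np.outer(year_val - hz.trend_ref_year, trend))
        lam = lam * cov_mult[idx][:, None]
        lam_e = emig[band]
        lam_tot = lam.sum(axis=1) + lam_e

        with np.errstate(divide="ignore"):
            wait_days = rng.exponential(1.0, size=len(idx)) / lam_tot * 365.25
        t_event = ti + wait_days
        hit = t_event < seg_end

        if hit.any():
            h = idx[hit]
            probs = np.concatenate([lam[hit], lam_e[hit][:, None]], axis=1)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(len(h))
            kind = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            event_kind[h] = kind
            event_ord[h] = np.clip(np.ceil(t_event[hit]).astype("int64"),
                                   start_ord + 1, end_ord)
            alive[h] = False

        cont = idx[~hit]
        t[cont] = seg_end[~hit]
        done = cont[t[cont] >= end_ord]
        alive[done] = False

    emig_mask = event_kind == n_causes
    death_mask = (event_kind >= 0) & ~emig_mask

    emigrations = pd.DataFrame({
        "person_id": census["person_id"].to_numpy()[emig_mask],
        "emigration_date": ordinals_to_dates(event_ord[emig_mask]).astype("M8[ns]"),
    })

    d_idx = np.flatnonzero(death_mask)
    underlying = np.array(causes, dtype=object)[event_kind[d_idx]]
    d_ord = event_ord[d_idx]
    d_band = np.maximum((cross[d_idx] <= d_ord[:, None]).sum(axis=1) - 1, 0)
    d_sex = census["sex"].to_numpy()[d_idx]

    # additional certificate mentions
    mention_matrix = np.zeros((len(d_idx), n_causes), dtype=bool)
    mention_matrix[np.arange(len(d_idx)), event_kind[d_idx]] = True
    for ci, c in enumerate(causes):
        p = hz.mention_prob.get(c, 0.0)
        if p <= 0:
            continue
        eligible = ~mention_matrix[:, ci]
        if c in SEX_RESTRICTED:
            eligible &= d_sex == SEX_RESTRICTED[c]
        draw = rng.random(len(d_idx)) < p
        mention_matrix[:, ci] |= eligible & draw

    official = _official_causes(underlying, mention_matrix, causes, d_ord,
                                to_ordinal(hz.regime_switch_date),
                                hz.priority_causes)

    # certificate snapshot: marital status may have plausibly changed,
    # residence may have moved since census
    cert_marital = census["marital_status"].to_numpy()[d_idx].copy()
    elapsed = (d_ord - start_ord) / 365.25
    changed = rng.random(len(d_idx)) < 1.0 - np.exp(-hz.marital_transition_rate * elapsed)
    pick = rng.random(len(d_idx))
    for i in np.flatnonzero(changed):
        succ = MARITAL_SUCCESSORS[cert_marital[i]]
        cert_marital[i] = succ[int(pick[i] * len(succ))]

    cert_canton = census["canton"].to_numpy()[d_idx].copy()
    moved = rng.random(len(d_idx)) < hz.residence_move_prob
    new_cantons = rng.choice(np.array(CANTONS, dtype=object), size=int(moved.sum()))
    same = new_cantons == cert_canton[moved]  # re-draw collisions deterministically
    if same.any():
        alt = rng.choice(np.array(CANTONS, dtype=object), size=int(same.sum()))
        new_cantons[same] = alt
    cert_canton[moved] = new_cantons
    cert_region = pd.Series(cert_canton).map(CANTON_TO_REGION).to_numpy()

    mentions = [";".join(c for ci, c in enumerate(causes) if mention_matrix[r, ci])
                for r in range(len(d_idx))]

    deaths = pd.DataFrame({
        "person_id": census["person_id"].to_numpy()[d_idx],
        "death_date": ordinals_to_dates(d_ord).astype("M8[ns]"),
        "underlying_cause": underlying,
        "mentions": mentions,
        "official_cause": official,
        "age_band_at_death": d_band,
        "cert_sex": d_sex,
        "cert_birth_date": census["birth_date"].to_numpy()[d_idx],
        "cert_canton": cert_canton,
        "cert_region": cert_region,
        "cert_nationality": census["nationality"].to_numpy()[d_idx],
        "cert_marital_status": cert_marital,
    })
    return deaths.sort_values(["death_date", "person_id"]).reset_index(drop=True), \
        emigrations.sort_values(["emigration_date", "person_id"]).reset_index(drop=True)


def assign_official_cause(underlying_cause: str, mentions, death_date,
                          regime_switch_date: date = date(1995, 1, 1),
                          priority_causes=DEFAULT_PRIORITY_CAUSES) -> str:
    """Official cause under the regime in force at the death date.

    Before the switch the coder gives priority to the listed causes
    (earliest entry = highest priority): if any mentioned cause is on the
    list, the highest-priority one becomes official. From the switch
    onwards the underlying cause is followed strictly.
    """
    mentions = {normalize_cause(m) for m in mentions}
    underlying_cause = normalize_cause(underlying_cause)
    if not mentions:
        raise ValueError("empty mention set")
    if underlying_cause not in mentions:
        raise ValueError("mentions must contain the underlying cause")
    if pd.Timestamp(death_date) >= pd.Timestamp(regime_switch_date):
        return underlying_cause
    ranked = [c for c in priority_causes if c in mentions]
    return ranked[0] if ranked else underlying_cause


def _official_causes(underlying, mention_matrix, causes, death_ords,
                     switch_ord, priority_causes):
    """Vectorised pre/post-switch coder over a death table."""
    rank = np.full(len(causes), np.inf)
    for r, c in enumerate(priority_causes):
        if c in causes:
            rank[causes.index(c)] = r
    ranks = np.where(mention_matrix, rank[None, :], np.inf)
    best = ranks.argmin(axis=1)
    has_priority = np.isfinite(ranks.min(axis=1))
    pre = death_ords < switch_ord
    out = np.array(underlying, dtype=object)
    use = pre & has_priority
    out[use] = np.array(causes, dtype=object)[best[use]]
    return out


# ---------------------------------------------------------------------------
# Analytic coding-step magnitude


def official_cause_probabilities(hz: HazardConfig, sex: str, band: int) -> dict:
    """P(official = c | underlying = d) under the pre-switch coder.

    Enumeration assumes mentions of distinct causes are independent given
    the underlying cause (exactly how the simulator draws them).
    """
    causes = list(hz.causes)
    m = {c: (hz.mention_prob.get(c, 0.0)
             if (c not in SEX_RESTRICTED or SEX_RESTRICTED[c] == sex) else 0.0)
         for c in causes}
    rank = {c: (hz.priority_causes.index(c) if c in hz.priority_causes else np.inf)
            for c in causes}
    out: dict[str, dict[str, float]] = {}
    for d in causes:
        out[d] = {}
        for c in causes:
            p_c = 1.0 if c == d else m[c]
            if p_c == 0.0:
                out[d][c] = 0.0
                continue
            if np.isinf(rank[c]):
                # c only stays official if c == d and nothing on the
                # priority list is mentioned at all
                if c != d:
                    out[d][c] = 0.0
                    continue
                p_none = np.prod([1.0 - m[e] for e in causes
                                  if e != d and np.isfinite(rank[e])])
                out[d][c] = p_none
                continue
            if c != d and np.isfinite(rank[d]) and rank[d] < rank[c]:
                out[d][c] = 0.0
                continue
            p_no_higher = np.prod([1.0 - m[e] for e in causes
                                   if e not in (c, d) and rank[e] < rank[c]])
            out[d][c] = p_c * p_no_higher
    return out


def stratum_hazard(hz: HazardConfig, cause: str, sex: str, band: int,
                   year: int | None = None) -> float:
    lam = hz.baseline_hazard[cause][sex][band]
    if year is not None:
        lam *= np.exp(hz.log_linear_trend.get(cause, 0.0) * (year - hz.trend_ref_year))
    return lam


def analytic_step_factor(hz: HazardConfig, cause: str, sex: str, band: int) -> float:
    """True multiplication factor induced by the coding switch for a stratum.

    Ratio of the post-switch (strict underlying) official rate to the
    pre-switch (priority-coded) official rate, both evaluated at the
    baseline hazards of the stratum. A factor below 1 means the switch
    produces a sudden drop in the official rate of ``cause``.
    """
    probs = official_cause_probabilities(hz, sex, band)
    u = {d: stratum_hazard(hz, d, sex, band) for d in hz.causes}
    pre = sum(u[d] * probs[d][cause] for d in hz.causes)
    post = u[cause]
    if pre <= 0:
        raise ValueError("cause has zero pre-switch official rate in this stratum")
    return post / pre


def calibrate_mention_prob(hz: HazardConfig, cause: str, sex: str, band: int,
                           target_factor: float) -> float:
    """Mention probability for ``cause`` that induces a given step factor.

    Only valid when no other cause has a positive mention probability (the
    configuration used by the recovery studies); then the pre-switch
    surplus is mention_prob x (hazard mass of lower-priority causes) and
    the factor inverts in closed form.
    """
    others = [c for c in hz.causes if c != cause and hz.mention_prob.get(c, 0.0) > 0]
    if others:
        raise ValueError(f"closed form requires zero mention_prob for {others}")
    rank = {c: (hz.priority_causes.index(c) if c in hz.priority_causes else np.inf)
            for c in hz.causes}
    donors = [d for d in hz.causes
              if d != cause and not rank[d] < rank[cause]
              and (d not in SEX_RESTRICTED or SEX_RESTRICTED[d] == sex)]
    surplus_mass = sum(stratum_hazard(hz, d, sex, band) for d in donors)
    u = stratum_hazard(hz, cause, sex, band)
    if surplus_mass <= 0:
        raise ValueError("no donor hazard mass; factor not adjustable")
    m = u * (1.0 / target_factor - 1.0) / surplus_mass
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"required mention_prob {m:.4f} outside [0,1]")
    return m


# ---------------------------------------------------------------------------
# Registry degradation (the unlinked deaths)


def _default_unlink_base() -> dict[int, float]:
    # Baseline unlink probability by age band at death (Swiss, married,
    # female baseline); calibrated so the default population yields ~5%
    # unlinked overall with the highest proportions in the young, as in the
    # descriptive pattern of census-mortality linkage studies.
    return {0: 0.12, 1: 0.12, 2: 0.18, 3: 0.15, 4: 0.09,
            5: 0.058, 6: 0.040, 7: 0.027, 8: 0.030, 9: 0.031}


@dataclass
class UnlinkConfig:
    """Which certificates fail the main linkage, and how their fields err.

    The unlink probability is a product of an age-band baseline and
    multiplicative factors for nationality, marital status and sex,
    clipped to [0, 0.95]. Unlinked certificates additionally get their
    identifying fields perturbed: birth date exact with probability
    ``birth_exact``, otherwise uniform within +/-92 days (probability
    ``birth_small``) or +/-366 days (remainder); canton replaced with
    probability ``canton_move_prob``; marital status moved one plausible
    step with probability ``marital_change_prob``.
    """

    base_prob_by_band: dict[int, float] = field(default_factory=_default_unlink_base)
    nationality_multiplier: dict[str, float] = field(
        default_factory=lambda: {"Swiss": 1.0, "non-Swiss": 2.6})
    marital_multiplier: dict[str, float] = field(
        default_factory=lambda: {"single": 1.5, "married": 1.0,
                                 "widowed": 0.8, "divorced": 1.1})
    sex_multiplier: dict[str, float] = field(
        default_factory=lambda: {"female": 1.0, "male": 1.15})
    birth_exact: float = 0.5
    birth_small: float = 0.4
    birth_small_window: int = 92
    birth_large_window: int = 366
    canton_move_prob: float = 0.3
    marital_change_prob: float = 0.15
    # optional extra multiplier by a census attribute (e.g. education), for
    # studies of exposure-differential linkage failure
    education_multiplier: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        for p in (*self.base_prob_by_band.values(), self.birth_exact,
                  self.birth_small, self.canton_move_prob, self.marital_change_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("unlink probabilities must lie in [0,1]")
        if self.birth_exact + self.birth_small > 1.0:
            raise ConfigurationError("birth-date mixture weights exceed 1")

    def unlink_probability(self, band, nationality, marital, sex) -> np.ndarray:
        band = np.asarray(band)
        base = np.array([self.base_prob_by_band.get(int(b), 0.05) for b in band])
        p = (base
             * pd.Series(nationality).map(self.nationality_multiplier).fillna(1.0).to_numpy()
             * pd.Series(marital).map(self.marital_multiplier).fillna(1.0).to_numpy()
             * pd.Series(sex).map(self.sex_multiplier).fillna(1.0).to_numpy())
        return np.clip(p, 0.0, 1.0)


def zero_unlink_config() -> UnlinkConfig:
    return UnlinkConfig(base_prob_by_band={b: 0.0 for b in range(10)})


def degrade_to_registry(deaths: pd.DataFrame, uc: UnlinkConfig,
                        seed: int | None = None,
                        id_start: int = 1,
                        person_attrs: pd.DataFrame | None = None):
    """Turn death events into registry certificates, unlinking a subset.

    Returns ``(registry, truth)``: the registry exposes ``person_id`` only
    for linked certificates; ``truth`` maps every certificate to the person
    it really belongs to and is reserved for evaluation.
    ``person_attrs`` (person_id + census attributes) is only consulted when
    the config carries an attribute-differential multiplier.
    """
    rng = np.random.default_rng(uc.seed if seed is None else seed)
    d = deaths.sort_values(["death_date", "person_id"]).reset_index(drop=True)
    n = len(d)
    cert_id = np.array([f"C{int(i):07d}" for i in range(id_start, id_start + n)],
                       dtype=object)

    p = uc.unlink_probability(d["age_band_at_death"].to_numpy(),
                              d["cert_nationality"], d["cert_marital_status"],
                              d["cert_sex"])
    if uc.education_multiplier is not None:
        if person_attrs is None or "education" not in person_attrs.columns:
            raise ConfigurationError(
                "education_multiplier requires person_attrs with education")
        edu = d[["person_id"]].merge(person_attrs[["person_id", "education"]],
                                     on="person_id", how="left")["education"]
        p = np.clip(p * edu.map(uc.education_multiplier).fillna(1.0).to_numpy(), 0, 1.0)
    unlinked = rng.random(n) < p

    birth = d["cert_birth_date"].to_numpy().astype("M8[D]").astype("int64")
    canton = d["cert_canton"].to_numpy().copy()
    marital = d["cert_marital_status"].to_numpy().copy()

    u_idx = np.flatnonzero(unlinked)
    if len(u_idx):
        mix = rng.random(len(u_idx))
        small = (mix >= uc.birth_exact) & (mix < uc.birth_exact + uc.birth_small)
        large = mix >= uc.birth_exact + uc.birth_small
        birth[u_idx[small]] += rng.integers(-uc.birth_small_window,
                                            uc.birth_small_window + 1,
                                            size=int(small.sum()))
        birth[u_idx[large]] += rng.integers(-uc.birth_large_window,
                                            uc.birth_large_window + 1,
                                            size=int(large.sum()))
        move = rng.random(len(u_idx)) < uc.canton_move_prob
        canton[u_idx[move]] = rng.choice(np.array(CANTONS, dtype=object),
                                         size=int(move.sum()))
        mchange = rng.random(len(u_idx)) < uc.marital_change_prob
        pick = rng.random(len(u_idx))
        for j in np.flatnonzero(mchange):
            succ = MARITAL_SUCCESSORS[marital[u_idx[j]]]
            marital[u_idx[j]] = succ[int(pick[j] * len(succ))]

    registry = pd.DataFrame({
        "certificate_id": cert_id,
        "sex": d["cert_sex"],
        "birth_date": ordinals_to_dates(birth).astype("M8[ns]"),
        "canton": canton,
        "region": pd.Series(canton).map(CANTON_TO_REGION).to_numpy(),
        "nationality": d["cert_nationality"],
        "marital_status": marital,
        "death_date": d["death_date"],
        "official_cause": d["official_cause"],
        "linked": ~unlinked,
        "person_id": d["person_id"].where(~unlinked).astype("Int64"),
    })
    truth = pd.DataFrame({"certificate_id": cert_id,
                          "truth_person_id": d["person_id"].to_numpy()})
    return registry, truth


# ---------------------------------------------------------------------------
# Whole-study generation (two census waves) and ground-truth bookkeeping


@dataclass
class StudyConfig:
    """A complete synthetic study: census waves, follow-up, registry."""

    population: PopulationConfig
    hazards: HazardConfig = field(default_factory=HazardConfig)
    unlink: UnlinkConfig = field(default_factory=UnlinkConfig)
    wave2_target: int | None = None        # None -> single census wave
    wave1_end: date = date(2000, 12, 4)
    wave2_census: date = date(2000, 12, 5)
    end_date: date = date(2007, 12, 31)
    seed: int = 0


@dataclass
class StudyData:
    censuses: dict[int, pd.DataFrame]
    windows: dict[int, tuple[date, date]]
    deaths: pd.DataFrame            # all death events, column `cohort`
    emigrations: pd.DataFrame
    registry: pd.DataFrame          # person_id only where linked
    truth: pd.DataFrame             # certificate_id -> truth_person_id
    persons: pd.DataFrame           # ground-truth life lines for evaluation


def generate_study(cfg: StudyConfig) -> StudyData:
    """Generate censuses, events and the (partially unlinked) registry."""
    root = np.random.default_rng(cfg.seed)
    s_pop1, s_sim1, s_pop2, s_sim2, s_unlink = root.integers(0, 2**31 - 1, size=5)

    pop1 = replace(cfg.population, seed=int(s_pop1))
    census1 = generate_census(pop1)
    w1_end = cfg.wave1_end if cfg.wave2_target is not None else cfg.end_date
    deaths1, emig1 = simulate_followup(census1, cfg.hazards,
                                       pop1.census_date, w1_end, seed=int(s_sim1))
    deaths1["cohort"] = pop1.census_date.year
    censuses = {pop1.census_date.year: census1}
    windows = {pop1.census_date.year: (pop1.census_date, w1_end)}
    all_deaths, all_emig = [deaths1], [emig1]

    if cfg.wave2_target is not None:
        gone = set(deaths1["person_id"]) | set(emig1["person_id"])
        survivors = census1[~census1["person_id"].isin(gone)].copy()
        n_new = max(cfg.wave2_target - len(survivors), 0)
        if n_new:
            c2 = cfg.wave2_census
            pop2 = replace(cfg.population, n_persons=n_new, census_date=c2,
                           birth_date_range=(date(c2.year - 95, c2.month, c2.day), c2),
                           seed=int(s_pop2))
            entrants = generate_census(pop2, id_start=int(census1["person_id"].max()) + 1)
            census2 = pd.concat([survivors, entrants], ignore_index=True)
        else:
            census2 = survivors.reset_index(drop=True)
        deaths2, emig2 = simulate_followup(census2, cfg.hazards,
                                           cfg.wave2_census, cfg.end_date,
                                           seed=int(s_sim2))
        deaths2["cohort"] = cfg.wave2_census.year
        censuses[cfg.wave2_census.year] = census2
        windows[cfg.wave2_census.year] = (cfg.wave2_census, cfg.end_date)
        all_deaths.append(deaths2)
        all_emig.append(emig2)

    deaths = pd.concat(all_deaths, ignore_index=True)
    emigrations = pd.concat(all_emig, ignore_index=True)
    attrs = pd.concat([c[["person_id", "education"]] for c in censuses.values()],
                      ignore_index=True).drop_duplicates("person_id")
    registry, truth = degrade_to_registry(deaths, cfg.unlink, seed=int(s_unlink),
                                          person_attrs=attrs)

    persons = _truth_persons(censuses, windows, deaths, emigrations)
    return StudyData(censuses=censuses, windows=windows, deaths=deaths,
                     emigrations=emigrations, registry=registry, truth=truth,
                     persons=persons)


def _truth_persons(censuses, windows, deaths, emigrations) -> pd.DataFrame:
    frames = []
    for year in sorted(censuses):
        f = censuses[year][["person_id", "sex", "birth_date"]].copy()
        f["entry_date"] = pd.Timestamp(windows[year][0])
        frames.append(f)
    persons = (pd.concat(frames, ignore_index=True)
               .sort_values("entry_date").drop_duplicates("person_id", keep="first"))
    persons = persons.merge(deaths[["person_id", "death_date"]], on="person_id",
                            how="left")
    persons = persons.merge(emigrations[["person_id", "emigration_date"]],
                            on="person_id", how="left")
    return persons.reset_index(drop=True)


def midyear_population(persons: pd.DataFrame, years,
                       age_breaks=DEFAULT_AGE_BREAKS) -> pd.DataFrame:
    """Ground-truth mid-year population counts by year, sex and age band.

    A person is counted on 1 July of a year when they have entered the
    study universe before that date and have neither died nor emigrated
    strictly before it. Age is attained age on 1 July.
    """
    from .lexis import age_group_labels  # local import avoids a cycle

    birth = persons["birth_date"].to_numpy().astype("M8[D]").astype("int64")
    entry = persons["entry_date"].to_numpy().astype("M8[D]").astype("int64")

    def _exit_ord(col):
        raw = persons[col].to_numpy().astype("M8[D]")
        out = raw.astype("int64").astype("float64")
        out[np.isnat(raw)] = np.inf  # censored: never exits
        return out

    death = _exit_ord("death_date")
    emig = _exit_ord("emigration_date")
    sex = persons["sex"].to_numpy()
    labels = age_group_labels(age_breaks)

    rows = []
    for y in years:
        jul1 = to_ordinal(date(int(y), 7, 1))
        # NaN exit dates compare False, so ~(exit < jul1) keeps the censored
        present = (entry < jul1) & ~(death < jul1) & ~(emig < jul1)
        idx = np.flatnonzero(present)
        band = attained_age_band(birth[idx], np.full(len(idx), jul1), age_breaks)
        for si, s in enumerate(SEXES):
            for bi, lab in enumerate(labels):
                cnt = int(((sex[idx] == s) & (band == bi)).sum())
                rows.append({"year": int(y), "sex": s, "age_group": lab,
                             "midyear_pop": cnt})
    return pd.DataFrame(rows)


def write_study(data: StudyData, out_dir) -> dict[str, str]:
    """Write the study tables as UTF-8 CSV with ISO-8601 dates."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _w(name, df):
        path = os.path.join(out_dir, name)
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        paths[name] = path

    for year, census in data.censuses.items():
        _w(f"census_{year}.csv", census)
    _w("deaths.csv", data.deaths)
    _w("emigration.csv", data.emigrations)
    _w("registry.csv", data.registry)
    _w("truth.csv", data.truth)
    return paths
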