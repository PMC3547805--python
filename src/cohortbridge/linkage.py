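"""Two-step pragmatic allocation of unlinked death certificates.

Certificates that the main census-mortality linkage could not resolve are
allocated to census persons with coarse rule-based matching:

* step 1 - same sex, canton, nationality, plausible marital status
  (identical or a legally possible change such as married -> widowed) and
  birth date within 92 days;
* step 2 - same sex and major region, birth date within 366 days.

Impossible matches (a sex-specific cause of death on the wrong sex) are
excluded up front. When several census persons qualify, one is chosen
uniformly at random with a seeded generator; a person can receive at most
one death, and persons already carrying a linked death or having emigrated
before the certificate's death date are never candidates. Certificates are
processed in a fixed order (death date, then certificate id) so a seed
fully determines the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causes import SEX_RESTRICTED, normalize_cause
from .synthpop import MARITAL_STATUSES, MARITAL_SUCCESSORS

STEP1_BIRTH_TOLERANCE_DAYS = 92    # "maximally 3 months apart"
STEP2_BIRTH_TOLERANCE_DAYS = 366   # "birth date within one year"


def _default_allowed_pairs() -> frozenset[tuple[str, str]]:
    pairs = {(s, s) for s in MARITAL_STATUSES}
    for a, succs in MARITAL_SUCCESSORS.items():
        pairs.update((a, b) for b in succs)
    return frozenset(pairs)


@dataclass(frozen=True)
class MaritalTransitionTable:
    """Census-status -> certificate-status pairs considered plausible."""

    allowed_pairs: frozenset = field(default_factory=_default_allowed_pairs)

    def __post_init__(self):
        missing = {(s, s) for s in MARITAL_STATUSES} - self.allowed_pairs
        if missing:
            raise ValueError(f"identity pairs missing: {sorted(missing)}")


DEFAULT_TRANSITIONS = MaritalTransitionTable()


@dataclass(frozen=True)
class MatchCriteria:
    step: int
    birth_date_tolerance: int
    geography_level: str  # "canton" or "region"


STEP1 = MatchCriteria(1, STEP1_BIRTH_TOLERANCE_DAYS, "canton")
STEP2 = MatchCriteria(2, STEP2_BIRTH_TOLERANCE_DAYS, "region")


def plausible_marital_transition(census_status: str, certificate_status: str,
                                 table: MaritalTransitionTable = DEFAULT_TRANSITIONS
                                 ) -> bool:
    for s in (census_status, certificate_status):
        if s not in MARITAL_STATUSES:
            raise ValueError(f"unknown marital status {s!r}")
    return (census_status, certificate_status) in table.allowed_pairs


def sex_cause_compatible(sex: str, official_cause: str) -> bool:
    """False only for a sex-specific cause on the wrong sex."""
    cause = normalize_cause(official_cause)
    required = SEX_RESTRICTED.get(cause)
    return required is None or required == sex


class _CensusIndex:
    """Search structure over census persons with a live availability mask."""

    def __init__(self, census: pd.DataFrame):
        self.person_id = census["person_id"].to_numpy()
        self.birth = census["birth_date"].to_numpy().astype("M8[D]").astype("int64")
        self.sex = census["sex"].to_numpy()
        self.marital = census["marital_status"].to_numpy()
        self.available = np.ones(len(census), dtype=bool)
        self._groups_step1: dict = {}
        self._groups_step2: dict = {}
        canton = census["canton"].to_numpy()
        region = census["region"].to_numpy()
        nat = census["nationality"].to_numpy()
        key1 = pd.Series(list(zip(self.sex, canton, nat)))
        for k, grp in key1.groupby(key1).groups.items():
            self._groups_step1[k] = np.asarray(grp)
        key2 = pd.Series(list(zip(self.sex, region)))
        for k, grp in key2.groupby(key2).groups.items():
            self._groups_step2[k] = np.asarray(grp)
        self._pos = {pid: i for i, pid in enumerate(self.person_id)}

    def consume(self, person_id):
        self.available[self._pos[person_id]] = False

    def exclude(self, person_ids):
        for pid in person_ids:
            if pid in self._pos:
                self.available[self._pos[pid]] = False


def find_candidates(cert, index: _CensusIndex, criteria: MatchCriteria,
                    transitions: MaritalTransitionTable = DEFAULT_TRANSITIONS,
                    emigration_ord: dict | None = None) -> np.ndarray:
    """Person ids satisfying the step's criteria for one certificate.

    ``cert`` is a mapping/row with sex, canton, region, nationality,
    marital_status, birth_date (ordinal as ``birth_ord``) and death date
    ordinal (``death_ord``). The result is an order-independent set
    (returned sorted by person id).
    """
    if criteria.step == 1:
        group = index._groups_step1.get((cert["sex"], cert["canton"],
                                         cert["nationality"]))
    else:
        group = index._groups_step2.get((cert["sex"], cert["region"]))
    if group is None:
        return np.empty(0, dtype=index.person_id.dtype)
    g = group[index.available[group]]
    if len(g) == 0:
        return g
    ok = np.abs(index.birth[g] - cert["birth_ord"]) <= criteria.birth_date_tolerance
    g = g[ok]
    if criteria.step == 1 and len(g):
        cert_status = cert["marital_status"]
        allowed = np.array([(s, cert_status) in transitions.allowed_pairs
                            for s in index.marital[g]])
        g = g[allowed]
    if emigration_ord and len(g):
        keep = np.array([emigration_ord.get(index.person_id[i], np.inf)
                         >= cert["death_ord"] for i in g])
        g = g[keep]
    return np.sort(index.person_id[g])


@dataclass
class AllocationResult:
    allocations: pd.DataFrame      # certificate_id, person_id, step_used, n_candidates
    unallocated: list
    seed: int
    n_unlinked: int


def allocate_unlinked(registry: pd.DataFrame, census: pd.DataFrame,
                      transitions: MaritalTransitionTable = DEFAULT_TRANSITIONS,
                      seed: int = 0,
                      emigrations: pd.DataFrame | None = None) -> AllocationResult:
    """Allocate every unlinked certificate, or record it as unallocated.

    Step 1 is tried first; only when it yields no candidate does step 2
    run. A person consumed by an earlier allocation (certificates
    processed by death date, then certificate id) is unavailable to later
    ones, as is any person already carrying a linked death.
    """
    if registry["certificate_id"].duplicated().any():
        raise ValueError("duplicate certificate ids in registry")

    rng = np.random.default_rng(seed)
    index = _CensusIndex(census)
    linked_persons = registry.loc[registry["linked"], "person_id"].dropna()
    index.exclude(linked_persons.astype("int64").tolist())

    emigration_ord = None
    if emigrations is not None and len(emigrations):
        e = emigrations.drop_duplicates("person_id")
        emigration_ord = dict(zip(
            e["person_id"],
            e["emigration_date"].to_numpy().astype("M8[D]").astype("int64")))

    unlinked = registry[~registry["linked"].astype(bool)].copy()
    unlinked["birth_ord"] = unlinked["birth_date"].to_numpy().astype("M8[D]").astype("int64")
    unlinked["death_ord"] = unlinked["death_date"].to_numpy().astype("M8[D]").astype("int64")
    unlinked = unlinked.sort_values(["death_date", "certificate_id"])

    rows, unallocated = [], []
    for cert in unlinked.to_dict("records"):
        if not sex_cause_compatible(cert["sex"], cert["official_cause"]):
            # impossible-match rule: candidates always share the
            # certificate's sex, so a sex-incompatible cause leaves no
            # legal census person to receive the death
            unallocated.append(cert["certificate_id"])
            continue
        chosen = None
        for criteria in (STEP1, STEP2):
            cands = find_candidates(cert, index, criteria, transitions,
                                    emigration_ord)
            if len(cands):
                chosen = cands[int(rng.integers(len(cands)))] if len(cands) > 1 \
                    else cands[0]
                rows.append({"certificate_id": cert["certificate_id"],
                             "person_id": int(chosen),
                             "step_used": criteria.step,
                             "n_candidates": int(len(cands))})
                index.consume(chosen)
                break
        if chosen is None:
            unallocated.append(cert["certificate_id"])

    allocations = pd.DataFrame(rows, columns=["certificate_id", "person_id",
                                              "step_used", "n_candidates"])
    return AllocationResult(allocations=allocations, unallocated=unallocated,
                            seed=seed, n_unlinked=len(unlinked))


# ---------------------------------------------------------------------------
# Agreement reporting (census record vs death certificate)

_AGREEMENT_VARS = ("sex", "birth_date", "marital_status", "nationality",
                   "place_of_residence")


def agreement_statistics(result: AllocationResult | None,
                         census: pd.DataFrame,
                         registry: pd.DataFrame,
                         transitions: MaritalTransitionTable = DEFAULT_TRANSITIONS
                         ) -> pd.DataFrame:
    """Percent agreement between census and certificate, by linkage source.

    Sources are the main linkage ("main") and the pragmatic steps
    ("step1", "step2"). For marital status the percentage of identical or
    plausible changes is also reported; for birth dates the quartiles of
    the signed difference in days (certificate - census). Empty strata are
    reported with NaN entries and n = 0, never raised.
    """
    pairs = []
    linked = registry[registry["linked"]].copy()
    if len(linked):
        linked["person_id"] = linked["person_id"].astype("int64")
        pairs.append(linked.assign(source="main"))
    if result is not None and len(result.allocations):
        alloc = result.allocations.merge(registry.drop(columns=["person_id"]),
                                         on="certificate_id", how="left")
        pairs.append(alloc[alloc["step_used"] == 1].assign(source="step1"))
        pairs.append(alloc[alloc["step_used"] == 2].assign(source="step2"))

    rows = []
    cen = census.set_index("person_id")
    for frame in pairs:
        src = frame["source"].iloc[0] if len(frame) else None
        if src is None or len(frame) == 0:
            continue
        c = cen.loc[frame["person_id"]]
        n = len(frame)
        diff_days = (frame["birth_date"].to_numpy().astype("M8[D]").astype("int64")
                     - c["birth_date"].to_numpy().astype("M8[D]").astype("int64"))
        ident_marital = frame["marital_status"].to_numpy() == c["marital_status"].to_numpy()
        plaus = np.array([(a, b) in transitions.allowed_pairs for a, b in
                          zip(c["marital_status"], frame["marital_status"])])
        q25, q50, q75 = np.percentile(diff_days, [25, 50, 75])
        rows.append({
            "source": src, "n": n,
            "sex_pct": float((frame["sex"].to_numpy() == c["sex"].to_numpy()).mean() * 100),
            "birth_date_pct": float((diff_days == 0).mean() * 100),
            "birth_diff_q25": float(q25),
            "birth_diff_median": float(q50),
            "birth_diff_q75": float(q75),
            "marital_pct": float(ident_marital.mean() * 100),
            "marital_plausible_pct": float(plaus.mean() * 100),
            "nationality_pct": float((frame["nationality"].to_numpy()
                                      == c["nationality"].to_numpy()).mean() * 100),
            "residence_pct": float((frame["canton"].to_numpy()
                                    == c["canton"].to_numpy()).mean() * 100),
        })
    for src in ("main", "step1", "step2"):
        if not any(r["source"] == src for r in rows):
            rows.append({"source": src, "n": 0,
                         **{k: np.nan for k in
                            ("sex_pct", "birth_date_pct", "birth_diff_q25",
                             "birth_diff_median", "birth_diff_q75", "marital_pct",
                             "marital_plausible_pct", "nationality_pct",
                             "residence_pct")}})
    order = {"main": 0, "step1": 1, "step2": 2}
    return (pd.DataFrame(rows).sort_values("source", key=lambda s: s.map(order))
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Headline percentages


def _print_pct(value: float, of_unlinked: bool) -> float:
    """Display rounding: two decimals for shares of the unlinked pool, one
    decimal for shares of all deaths, two significant figures below 0.1%."""
    if value == 0:
        return 0.0
    if value < 0.1:
        from math import floor, log10
        digits = 1 - int(floor(log10(value)))
        return round(value, digits)
    return round(value, 2 if of_unlinked else 1)


def summarize_counts(n_unlinked: int, n_allocated: int, total_deaths: int) -> dict:
    """Headline allocation percentages from raw counts (display-rounded)."""
    if total_deaths <= 0:
        raise ValueError("total_deaths must be positive")
    if n_allocated > n_unlinked or n_unlinked > total_deaths:
        raise ValueError("inconsistent counts")
    n_unallocated = n_unlinked - n_allocated
    out = {
        "n_unlinked": n_unlinked,
        "n_allocated": n_allocated,
        "n_unallocated": n_unallocated,
        "total_deaths": total_deaths,
        "degenerate": n_unlinked == 0,
    }
    if n_unlinked == 0:
        out.update({"unlinked_of_total_pct": 0.0, "allocated_of_unlinked_pct": np.nan,
                    "unallocated_of_unlinked_pct": np.nan,
                    "unallocated_of_total_pct": 0.0})
        return out
    out["unlinked_of_total_pct"] = _print_pct(100 * n_unlinked / total_deaths, False)
    out["allocated_of_unlinked_pct"] = _print_pct(100 * n_allocated / n_unlinked, True)
    out["unallocated_of_unlinked_pct"] = _print_pct(100 * n_unallocated / n_unlinked, True)
    out["unallocated_of_total_pct"] = _print_pct(100 * n_unallocated / total_deaths, False)
    return out


def allocation_summary(result: AllocationResult, total_deaths: int) -> dict:
    """Counts and percentages of the allocation run (see summarize_counts)."""
    if total_deaths < result.n_unlinked:
        raise ValueError("total_deaths smaller than the number of unlinked deaths")
    return summarize_counts(result.n_unlinked, len(result.allocations), total_deaths)
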