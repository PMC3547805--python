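"""Poisson trend model with a coding-change step and spline calendar trend.

The annual death counts of one (cause, sex, age group) stratum are modelled
as Poisson with a log link, the log person-years as fixed offset, a
restricted cubic spline in calendar year for the smooth trend, and an
indicator 1{year >= step_year} for the change in cause-of-death coding
policy. The exponentiated step coefficient is the multiplication factor:
the number by which rates under the old coding must be multiplied to be
comparable with rates under the new coding. A factor of 0.85 means the new
coding produces 15% lower rates for that cause, all else equal.

The spline uses Harrell's restricted truncated-power basis: linear tails
beyond the boundary knots, k-1 design columns for k knots, nonlinear terms
scaled by the squared knot range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_KNOTS = (1990.0, 1995.0, 2000.0, 2004.0)


@dataclass(frozen=True)
class KnotVector:
    knots: tuple[float, ...] = DEFAULT_KNOTS

    def __post_init__(self):
        k = self.knots
        if len(k) < 3:
            raise ValueError("at least 3 knots required")
        if any(b <= a for a, b in zip(k, k[1:])):
            raise ValueError("knots must be strictly increasing")


def rcs_basis(years, knots: KnotVector = KnotVector()) -> np.ndarray:
    """Restricted cubic spline design columns at the given calendar positions.

    Returns an (n, k-1) array: the linear term followed by k-2 restricted
    truncated-power terms that vanish at and below the first knot and are
    constrained to overall linearity beyond the boundary knots.
    """
    x = np.asarray(years, dtype=float)
    t = np.asarray(knots.knots if isinstance(knots, KnotVector) else knots,
                   dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("at least 3 knots required")
    scale = (t[-1] - t[0]) ** 2

    def cub(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (cub(x - t[j])
                - cub(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + cub(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass
class TrendModelSpec:
    cause: str = "all"
    sex: str | None = None
    age_group: str | None = None
    step_year: int = 1995
    knots: KnotVector = field(default_factory=KnotVector)


@dataclass
class PoissonFit:
    params: np.ndarray            # intercept, spline coefficients, step gamma
    cov: np.ndarray
    llf: float
    converged: bool
    n_obs: int
    years: np.ndarray
    step_year: int
    knots: KnotVector
    separation_flag: bool = False

    @property
    def gamma(self) -> float:
        return float(self.params[-1])

    @property
    def gamma_se(self) -> float:
        return float(np.sqrt(self.cov[-1, -1]))

    def design(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        X = np.column_stack([np.ones(len(years)), rcs_basis(years, self.knots),
                             (years >= self.step_year).astype(float)])
        return X


def build_design(years, step_year: int, knots: KnotVector) -> np.ndarray:
    years = np.asarray(years, dtype=float)
    return np.column_stack([np.ones(len(years)), rcs_basis(years, knots),
                            (years >= step_year).astype(float)])


def fit_poisson_trend(data: pd.DataFrame, spec: TrendModelSpec) -> PoissonFit:
    """Maximum-likelihood fit of the step-plus-spline Poisson model.

    ``data`` needs one row per calendar year with columns ``year``,
    ``deaths`` and ``person_years`` (already restricted to the stratum of
    interest, or pass the stratified rate table and set ``spec.cause``/
    ``sex``/``age_group``). Rows with zero person-years are dropped; the
    fit requires observations on both sides of the step.
    """
    d = data
    for col, val in (("cause", spec.cause), ("sex", spec.sex),
                     ("age_group", spec.age_group)):
        if val is not None and col in d.columns:
            d = d[d[col] == val]
    d = (d.groupby("year", as_index=False)[["deaths", "person_years"]].sum()
         if d["year"].duplicated().any() else d)
    d = d[d["person_years"] > 0].sort_values("year")
    if len(d) == 0:
        raise ValueError("no strata with positive person-time")
    years = d["year"].to_numpy(dtype=float)
    deaths = d["deaths"].to_numpy(dtype=float)
    py = d["person_years"].to_numpy(dtype=float)

    if deaths.sum() == 0:
        raise ValueError("all counts are zero: the step factor is unidentifiable")
    pre = years < spec.step_year
    if not pre.any() or pre.all():
        raise ValueError("years must span both coding regimes")
    separation = deaths[pre].sum() == 0 or deaths[~pre].sum() == 0

    X = build_design(years, spec.step_year, spec.knots)
    model = sm.GLM(deaths, X, family=sm.families.Poisson(), offset=np.log(py))
    res = model.fit(maxiter=100, tol=1e-10)
    return PoissonFit(params=np.asarray(res.params),
                      cov=np.asarray(res.cov_params()),
                      llf=float(res.llf),
                      converged=bool(res.converged) and not separation,
                      n_obs=len(d),
                      years=years,
                      step_year=spec.step_year,
                      knots=spec.knots,
                      separation_flag=bool(separation))


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass
class MultiplicationFactor:
    point: float
    ci_low: float
    ci_high: float
    percent_reduction: int
    percent_reduction_ci: tuple[int, int]


def percent_reduction_from_factor(point: float, ci_low: float | None = None,
                                  ci_high: float | None = None):
    """Convert a multiplication factor (and CI) to integer percent reduction.

    Reduction = 100 x (1 - factor), rounded half away from zero; the CI of
    the reduction swaps bounds (a smaller factor is a larger reduction).
    """
    red = _round_half_away(100.0 * (1.0 - point))
    if ci_low is None or ci_high is None:
        return red
    return red, (_round_half_away(100.0 * (1.0 - ci_high)),
                 _round_half_away(100.0 * (1.0 - ci_low)))


def multiplication_factor(fit: PoissonFit, z: float = 1.96) -> MultiplicationFactor:
    """exp(step coefficient) with a Wald 95% CI on the log scale."""
    if not fit.converged and not fit.separation_flag:
        raise ValueError("fit did not converge")
    g, se = fit.gamma, fit.gamma_se
    point = float(np.exp(g))
    lo, hi = float(np.exp(g - z * se)), float(np.exp(g + z * se))
    red, red_ci = percent_reduction_from_factor(point, lo, hi)
    return MultiplicationFactor(point=point, ci_low=lo, ci_high=hi,
                                percent_reduction=red, percent_reduction_ci=red_ci)


def adjusted_rate_series(fit: PoissonFit, years=None, z: float = 1.96,
                         per: float = 1e5) -> pd.DataFrame:
    """Fitted and coding-adjusted annual rates with delta-method 95% CIs.

    The adjusted series forces the step term to its post-change value for
    every year: pre-step years are shown as if the new coding policy had
    applied; at and after the step year the two series coincide.
    """
    years = fit.years if years is None else np.asarray(years, dtype=float)
    X_fit = fit.design(years)
    X_adj = X_fit.copy()
    X_adj[:, -1] = 1.0

    out = {"year": years.astype(int)}
    for name, X in (("fitted", X_fit), ("adjusted", X_adj)):
        eta = X @ fit.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
        out[f"{name}_rate"] = np.exp(eta) * per
        out[f"{name}_lo"] = np.exp(eta - z * se) * per
        out[f"{name}_hi"] = np.exp(eta + z * se) * per
    return pd.DataFrame(out)


def stratum_year_data(rates: pd.DataFrame, cause: str, sex: str,
                      age_group: str, years=None) -> pd.DataFrame:
    """Pull one stratum's (year, deaths, person_years) rows from a rate table."""
    d = rates[(rates["cause"] == cause) & (rates["sex"] == sex)
              & (rates["age_group"] == age_group)]
    if years is not None:
        d = d[d["year"].isin(list(years))]
    return (d[["year", "deaths", "person_years"]]
            .sort_values("year").reset_index(drop=True))
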