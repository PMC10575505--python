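"""Prescribing rates, percentage differences and Poisson trend regression.

Rates are prescriptions per 1000 cohort population (crude, or directly
age-standardized against a configurable reference age distribution).
Temporal trends come from a log-linear Poisson model of annual category
counts with the log annual cohort population as offset and calendar year
as a categorical factor; the reported rate ratio compares the final study
year against the reference (first) year with a 95% Wald interval on the
log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ConfigError, DataError
from .linkage import suppress_small_cells

MISSING = "NA"

# ATC level-3/4 groupings used for the class breakdowns
_ATC_CLASSES = [
    ("J01FA", "macrolides"),
    ("J01M", "quinolones"),
    ("J01AA", "tetracyclines"),
    ("J01C", "beta_lactams_other"),
    ("J01D", "beta_lactams_other"),
]


def atc_major_class(atc_code: str) -> str:
    code = str(atc_code)
    for prefix, label in _ATC_CLASSES:
        if code.startswith(prefix):
            return label
    return "other"


def rate_per_1000(count, population, age_weights: dict | None = None):
    """Prescribing rate per 1000 population.

    Crude: ``1000 * count / population``. With ``age_weights`` (band ->
    weight summing to 1), ``count`` and ``population`` are mappings per age
    band and the rate is the weighted sum of band rates (direct
    standardization).
    """
    if age_weights is None:
        population = float(population)
        if population <= 0:
            raise DataError("rate_per_1000: population must be positive")
        return 1000.0 * float(count) / population
    total_w = sum(age_weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ConfigError("age_weights must sum to 1")
    rate = 0.0
    for band, w in age_weights.items():
        pop = float(population[band])
        n = float(count.get(band, 0.0)) if hasattr(count, "get") else float(count[band])
        if pop <= 0:
            if n > 0:
                raise DataError(f"rate_per_1000: zero population in band {band!r} "
                                "with nonzero count")
            continue
        rate += w * 1000.0 * n / pop
    return rate


def pct_difference(rate_start: float, rate_end: float, ndigits: int = 2):
    """Relative change (end - start) / start, rounded to 2 decimals.

    A zero starting rate has no defined percentage difference and yields
    the missing marker.
    """
    if rate_start == 0:
        return MISSING
    return round((rate_end - rate_start) / rate_start, ndigits)


@dataclass
class TrendResult:
    """Rate ratio of the comparison year against the reference year."""

    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    reference_year: int
    comparison_year: int
    continuity_corrected: bool = False


class PoissonTrendModel:
    """Log-linear Poisson model of annual counts with a population offset.

    log E[count_y] = alpha + sum_y beta_y 1[year = y] + log(population_y),
    year categorical with the reference (default: first) year as baseline.
    Fitting is iteratively reweighted least squares (canonical log link)
    to relative tolerance 1e-8.

    Parameters
    ----------
    counts : DataFrame with columns ``year``, ``count``, ``population``.
    reference_year : baseline year; defaults to the earliest.
    zero_count_strategy : ``"error"`` (default) or ``"add_half"`` — a zero
        count in any year makes the categorical MLE degenerate, so the
        add-half option adds 0.5 to every count and flags the result.
    """

    def __init__(self, counts: pd.DataFrame, reference_year: int | None = None,
                 zero_count_strategy: str = "error", linear_year: bool = False):
        counts = counts[["year", "count", "population"]].copy()
        counts["year"] = counts["year"].astype(int)
        counts = counts.sort_values("year").reset_index(drop=True)
        if counts["year"].duplicated().any():
            raise DataError("poisson_trend: one row per year is required")
        if len(counts) < 2:
            raise DataError("poisson_trend: at least 2 years of data are required")
        if (counts["population"] <= 0).any():
            raise DataError("poisson_trend: populations must be positive")
        self.continuity_corrected = False
        if (counts["count"] == 0).any():
            if zero_count_strategy == "add_half":
                counts["count"] = counts["count"] + 0.5
                self.continuity_corrected = True
            else:
                raise DataError(
                    "poisson_trend: zero count in some year; "
                    "use zero_count_strategy='add_half'"
                )
        self.counts = counts
        self.reference_year = int(reference_year if reference_year is not None
                                  else counts["year"].min())
        if self.reference_year not in set(counts["year"]):
            raise DataError(f"reference_year {self.reference_year} not in data")
        self.linear_year = linear_year

    def fit(self) -> "PoissonTrendResults":
        df = self.counts
        years = df["year"].to_numpy()
        if self.linear_year:
            X = sm.add_constant(pd.DataFrame({"year": years - self.reference_year}))
            param_names = ["year"]
        else:
            non_ref = [y for y in years if y != self.reference_year]
            X = pd.DataFrame(
                {f"year_{y}": (years == y).astype(float) for y in non_ref}
            )
            X = sm.add_constant(X)
            param_names = [f"year_{y}" for y in non_ref]
        model = sm.GLM(
            df["count"].to_numpy(dtype=float),
            X,
            family=sm.families.Poisson(),
            offset=np.log(df["population"].to_numpy(dtype=float)),
        )
        # the categorical-year model is saturated (one observation per
        # year), so statsmodels warns about zero residual df; the MLE and
        # Wald covariance are still exact.
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fitted = model.fit(tol=1e-8, maxiter=200)
        return PoissonTrendResults(self, fitted, param_names)


class PoissonTrendResults:
    """Fitted trend model; exposes rate ratios against the reference year."""

    def __init__(self, model: PoissonTrendModel, fitted, param_names: list[str]):
        self.model = model
        self._fitted = fitted
        self._param_names = param_names

    def rate_ratio(self, comparison_year: int | None = None,
                   alpha: float = 0.05) -> TrendResult:
        m = self.model
        if comparison_year is None:
            comparison_year = int(m.counts["year"].max())
        if m.linear_year:
            name = "year"
            scale = comparison_year - m.reference_year
        else:
            name = f"year_{comparison_year}"
            scale = 1.0
            if name not in self._param_names:
                raise DataError(f"comparison year {comparison_year} not in model")
        beta = float(self._fitted.params[name]) * scale
        se = float(self._fitted.bse[name]) * abs(scale)
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        p = 2 * (1 - norm.cdf(abs(beta / se))) if se > 0 else 1.0
        return TrendResult(
            rate_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_value=float(p),
            reference_year=m.reference_year,
            comparison_year=int(comparison_year),
            continuity_corrected=m.continuity_corrected,
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self._param_names:
            year = int(name.split("_")[1]) if not self.model.linear_year else None
            res = self.rate_ratio(year if year is not None
                                  else int(self.model.counts["year"].max()))
            rows.append(
                {
                    "comparison_year": res.comparison_year,
                    "reference_year": res.reference_year,
                    "rate_ratio": res.rate_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                }
            )
        return pd.DataFrame(rows)


def poisson_trend(
    counts: pd.DataFrame,
    reference_year: int | None = None,
    comparison_year: int | None = None,
    zero_count_strategy: str = "error",
) -> TrendResult:
    """Rate ratio of the comparison (default: last) year vs the reference
    (default: first) year from the categorical-year Poisson model."""
    model = PoissonTrendModel(counts, reference_year=reference_year,
                              zero_count_strategy=zero_count_strategy)
    return model.fit().rate_ratio(comparison_year)


def duration_frequency(
    linked: pd.DataFrame,
    first_line_agents: set[str] | None = None,
    first_line_only: bool = True,
    strata: list[str] | None = None,
    min_n: int | None = None,
) -> pd.DataFrame:
    """Counts and proportions of dispensed days supply.

    Restricted to first-line agents by default (the duration question only
    applies where the guideline states a duration); optional strata columns
    (e.g. province, age band) and small-cell suppression.
    """
    df = linked.loc[linked["prescribed"].astype(bool)].copy()
    if first_line_only:
        agents = first_line_agents or {"amoxicillin", "amoxicillin-clavulanate",
                                       "doxycycline"}
        df = df.loc[df["agent"].isin(agents)]
    keys = (strata or []) + ["duration_days"]
    out = df.groupby(keys, dropna=False).size().rename("n").reset_index()
    group = strata or []
    if group:
        out["proportion"] = out["n"] / out.groupby(group)["n"].transform("sum")
    else:
        out["proportion"] = out["n"] / out["n"].sum()
    out = out.sort_values(keys).reset_index(drop=True)
    if min_n is not None:
        out = suppress_small_cells(out, min_n=min_n, count_columns=["n"],
                                   derived_columns=["proportion"])
    return out


def atc_class_breakdown(
    classified: pd.DataFrame,
    categories: set[str] = frozenset({"clinically_appropriate", "not_recommended"}),
    strata: list[str] | None = None,
    min_n: int | None = None,
) -> pd.DataFrame:
    """Proportion of prescriptions per major ATC class, by quality category.

    Unmappable ATC codes fall into ``other``. Proportions sum to 1 within
    each (stratum, category) cell before suppression.
    """
    df = classified.loc[classified["category"].isin(categories)].copy()
    df["atc_class"] = df["atc_code"].map(atc_major_class)
    keys = (strata or []) + ["category", "atc_class"]
    out = df.groupby(keys, dropna=False).size().rename("n").reset_index()
    group = (strata or []) + ["category"]
    out["proportion"] = out["n"] / out.groupby(group)["n"].transform("sum")
    out = out.sort_values(keys).reset_index(drop=True)
    if min_n is not None:
        out = suppress_small_cells(out, min_n=min_n, count_columns=["n"],
                                   derived_columns=["proportion"])
    return out


def annual_category_counts(
    classified: pd.DataFrame,
    populations: pd.DataFrame,
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """Annual prescription counts per category joined to cohort denominators.

    ``populations`` has columns ``province``, ``year``, ``population``; the
    classified table must carry ``province`` and ``year`` columns.
    """
    keys = ["province", "year", "category"] + (strata or [])
    counts = classified.groupby(keys, dropna=False).size().rename("count").reset_index()
    out = counts.merge(populations, on=["province", "year"], how="left")
    if out["population"].isna().any():
        raise DataError("annual_category_counts: missing population for some "
                        "province-year")
    out["rate_per_1000"] = 1000.0 * out["count"] / out["population"]
    return out
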