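"""The regression-based life expectancy gap and its moving-window trend.

Per period and sex, area life expectancies are regressed on the metric
deprivation index (which ranges from 0, least deprived, to 1, most
deprived).  Because the regressor spans [0, 1], the slope of the ordinary
least-squares fit measures by how many years life expectancy differs between
the least and most deprived areas — the slope-index-of-inequality logic.
The fitted values at index 0 and 1 are the endpoint life expectancies whose
divergence over time explains a widening or narrowing gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .age import AgeSchema
from .deprivation import DeprivationIndexer
from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .lifetable import DEFAULT_RADIX, life_expectancy_surface, period_label

logger = logging.getLogger(__name__)


class SlopeIndexOfInequality(RegressorMixin, BaseEstimator):
    """OLS of a health outcome on a [0, 1] deprivation index.

    With the index as the single regressor, ``-coef_[0]`` is the outcome
    difference between the least (index 0) and most (index 1) deprived
    areas; ``intercept_`` and ``intercept_ + coef_[0]`` are the fitted
    endpoint values.

    Parameters
    ----------
    weighted:
        If True, ``fit`` requires ``sample_weight`` (e.g. area populations)
        and solves the weighted least-squares problem.  Default False:
        every area counts equally.
    """

    def __init__(self, weighted: bool = False):
        self.weighted = weighted

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("expected a single deprivation-index column")
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("X and y have inconsistent lengths")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValidationError("non-finite values in regression inputs")
        n = X.shape[0]
        if n < 3:
            raise InsufficientDataError(f"need at least 3 areas to fit the gap, got {n}")
        x = X[:, 0]
        if np.ptp(x) == 0:
            raise DegenerateInputError("deprivation index is constant across areas")
        if self.weighted:
            if sample_weight is None:
                raise ValueError("weighted=True requires sample_weight")
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
                raise ValidationError("sample_weight must be non-negative with positive sum")
        else:
            w = np.ones(n)
        sw = np.sqrt(w)
        design = np.column_stack([x, np.ones(n)])
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        slope, intercept = float(beta[0]), float(beta[1])

        fitted = intercept + slope * x
        resid = y - fitted
        ybar = np.average(y, weights=w)
        ss_res = float(np.sum(w * resid**2))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))

        self.coef_ = np.array([slope])
        self.intercept_ = intercept
        self.slope_ = slope
        self.gap_ = -slope
        self.e0_least_deprived_ = intercept
        self.e0_most_deprived_ = intercept + slope
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_areas_ = n
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X[:, 0] * self.coef_[0]


@dataclass(frozen=True)
class GapEstimate:
    """Gap regression result for one period x sex.

    ``gap = e0_least_deprived - e0_most_deprived = -slope``; reported
    positive when deprived areas fare worse.
    """

    period: tuple[int, int]
    sex: str
    intercept: float
    slope: float
    gap: float
    e0_least_deprived: float
    e0_most_deprived: float
    n_areas: int
    r_squared: float

    @property
    def period_label(self) -> str:
        return period_label(self.period)


def fit_gap(
    e0_values: pd.DataFrame,
    index: pd.DataFrame,
    period: tuple[int, int] | None = None,
    sex: str | None = None,
    weighted: bool = False,
    weights: pd.Series | Mapping | None = None,
) -> GapEstimate:
    """Fit the life-expectancy gap for one period and sex.

    ``e0_values`` needs columns (area_id, e0); ``index`` columns
    (area_id, gisd).  Areas are matched by identifier; areas missing either
    value are dropped (and logged).
    """
    merged = e0_values[["area_id", "e0"]].merge(
        index[["area_id", "gisd"]], on="area_id", how="inner"
    )
    dropped = set(e0_values["area_id"]) ^ set(index["area_id"])
    if dropped:
        logger.warning(
            "fit_gap %s/%s: %d area(s) missing e0 or index dropped: %s",
            period, sex, len(dropped), sorted(dropped)[:5],
        )
    if (merged["gisd"] < -1e-12).any() or (merged["gisd"] > 1 + 1e-12).any():
        raise ValidationError("deprivation index values must lie in [0, 1]")
    sw = None
    if weighted:
        if weights is None:
            raise ValueError("weighted fit requires per-area weights")
        w = pd.Series(weights)
        sw = merged["area_id"].map(w).to_numpy(dtype=float)
        if np.any(~np.isfinite(sw)):
            raise ValidationError("missing weight for one or more areas")
    sii = SlopeIndexOfInequality(weighted=weighted).fit(
        merged[["gisd"]].to_numpy(), merged["e0"].to_numpy(), sample_weight=sw
    )
    return GapEstimate(
        period=tuple(period) if period is not None else (0, 0),
        sex=sex or "all",
        intercept=sii.intercept_,
        slope=sii.slope_,
        gap=sii.gap_,
        e0_least_deprived=sii.e0_least_deprived_,
        e0_most_deprived=sii.e0_most_deprived_,
        n_areas=sii.n_areas_,
        r_squared=sii.r_squared_,
    )


@dataclass(frozen=True)
class TrendSeries:
    """Ordered gap estimates across moving periods, both sexes."""

    estimates: tuple[GapEstimate, ...]

    def for_sex(self, sex: str) -> tuple[GapEstimate, ...]:
        return tuple(e for e in self.estimates if e.sex == sex)

    @property
    def sexes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.estimates:
            if e.sex not in seen:
                seen.append(e.sex)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "period_label": e.period_label,
                    "sex": e.sex,
                    "gap_years": e.gap,
                    "e0_least_deprived": e.e0_least_deprived,
                    "e0_most_deprived": e.e0_most_deprived,
                    "slope": e.slope,
                    "intercept": e.intercept,
                    "n_areas": e.n_areas,
                    "r_squared": e.r_squared,
                }
                for e in self.estimates
            ]
        )


def endpoint_trajectories(series: TrendSeries) -> pd.DataFrame:
    """Fitted endpoint life expectancies (index 0 and 1) per period and sex.

    The element-wise difference of the two columns equals the gap series.
    """
    if not series.estimates:
        raise ValidationError("empty trend series")
    return series.to_frame()[
        ["period_label", "sex", "e0_least_deprived", "e0_most_deprived"]
    ]


def moving_periods(first_year: int, last_year: int, window: int = 3) -> list[tuple[int, int]]:
    """Overlapping calendar windows: (2003,2005), (2004,2006), ... stepping 1 year."""
    if window < 1:
        raise ValidationError("window length must be >= 1")
    if last_year - first_year + 1 < window:
        raise ValidationError("year range shorter than the window")
    return [(y, y + window - 1) for y in range(first_year, last_year - window + 2)]


def _index_for_period(
    indicators: pd.DataFrame | Mapping[int, pd.DataFrame],
    period: tuple[int, int],
    indexer_factory,
) -> pd.DataFrame:
    """Deprivation index for one window, from the middle year's indicator table."""
    if isinstance(indicators, Mapping):
        mid = (period[0] + period[1]) // 2
        if mid not in indicators:
            raise ValidationError(
                f"no indicator table for the middle year {mid} of period {period_label(period)}"
            )
        table = indicators[mid]
    else:
        table = indicators
    return indexer_factory().fit_transform(table)


def run_trend(
    records: pd.DataFrame,
    indicators: pd.DataFrame | Mapping[int, pd.DataFrame],
    schema: AgeSchema,
    years: tuple[int, int],
    window: int = 3,
    sexes: Sequence[str] = ("female", "male"),
    weighted: bool = False,
    radix: float = DEFAULT_RADIX,
    orientation=None,
    weighting: str = "squared",
    on_error: str = "raise",
) -> TrendSeries:
    """Full moving-window analysis: index, life tables, gap per window and sex.

    For every window the deprivation index is built from the middle year's
    indicator table (a single static table is reused for all windows), one
    e0 is computed per area and sex from the pooled window rates, and the
    gap regression is fitted.  A 20-year range with the default 3-year
    window yields 18 estimates per sex.
    """
    periods = moving_periods(years[0], years[1], window)
    surface, failures = life_expectancy_surface(
        records, schema, periods, sexes=list(sexes), radix=radix, on_error=on_error
    )
    for f in failures.itertuples():
        logger.warning("window %s failed: %s", f.period_label, f.reason)

    factory = lambda: DeprivationIndexer(orientation=orientation, weighting=weighting)
    pop_by_area = None
    if weighted:
        pop_by_area = records.groupby("area_id")["person_years"].sum()

    estimates: list[GapEstimate] = []
    for sex in sexes:
        for period in periods:
            label = period_label(period)
            cell = surface[(surface["sex"] == sex) & (surface["period_label"] == label)]
            if cell.empty:
                continue
            index = _index_for_period(indicators, period, factory)
            est = fit_gap(
                cell, index, period=period, sex=sex,
                weighted=weighted, weights=pop_by_area,
            )
            logger.info(
                "window %s %s: %d areas used, gap %.2f years",
                label, sex, est.n_areas, est.gap,
            )
            estimates.append(est)
    return TrendSeries(tuple(estimates))


def scatter_table(
    e0_surface: pd.DataFrame,
    index: pd.DataFrame,
    period: tuple[int, int],
) -> pd.DataFrame:
    """Per-area (gisd, e0) pairs for one period — the scatter behind the fit."""
    label = period_label(period)
    sel = e0_surface[e0_surface["period_label"] == label]
    return sel.merge(index[["area_id", "gisd"]], on="area_id", how="inner")[
        ["area_id", "sex", "period_label", "gisd", "e0"]
    ]
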