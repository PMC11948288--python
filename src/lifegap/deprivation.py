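"""Composite area deprivation index from nine indicators in three dimensions.

Construction: indicators are z-standardised across areas; within each of the
three dimensions (education, employment, income) the first principal
component of its three indicators is extracted and the indicators are
weighted by their squared loadings (explained-variance shares, normalised to
sum to 1); each dimension's score is oriented so that higher means more
deprived, using a declared anchor indicator; the three dimension scores are
averaged with equal weight; and the resulting raw score is min-max
normalised over the supplied area set so the least deprived area is exactly
0 and the most deprived exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ValidationError

DIMENSIONS = ("education", "employment", "income")

_INDICATOR_COLUMNS = ["area_id", "dimension", "indicator_name", "value"]

#: Default orientation anchors matching the synthetic indicator names:
#: (anchor indicator, direction), direction +1 when a higher anchor value
#: means more deprivation, -1 when it means less (e.g. income).
DEFAULT_ORIENTATION: Mapping[str, tuple[str, int]] = {
    "education": ("school_dropout_rate", 1),
    "employment": ("unemployment_rate", 1),
    "income": ("household_income", -1),
}


@dataclass(frozen=True)
class IndicatorWeight:
    """Weight and orientation of one indicator within its dimension."""

    indicator: str
    weight: float
    sign: int


def validate_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of an indicator table.

    Exactly the three known dimensions, exactly three indicators per
    dimension, every area with a value for all nine indicators, no missing
    values.  Returns the table unchanged when valid.
    """
    missing_cols = [c for c in _INDICATOR_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"indicator table missing columns {missing_cols}")
    unknown = sorted(set(table["dimension"]) - set(DIMENSIONS))
    if unknown:
        raise ValidationError(f"unknown dimension label(s) {unknown}; expected {DIMENSIONS}")
    per_dim = table.groupby("dimension")["indicator_name"].nunique()
    bad_dims = {d: int(per_dim.get(d, 0)) for d in DIMENSIONS if per_dim.get(d, 0) != 3}
    if bad_dims:
        raise ValidationError(
            f"each dimension needs exactly 3 indicators; got {bad_dims}"
        )
    dim_of = table[["indicator_name", "dimension"]].drop_duplicates()
    dup = dim_of["indicator_name"].duplicated()
    if dup.any():
        raise ValidationError(
            f"indicator(s) assigned to multiple dimensions: "
            f"{sorted(dim_of['indicator_name'][dup])}"
        )
    if table["value"].isna().any():
        rows = table[table["value"].isna()][["area_id", "indicator_name"]].to_dict("records")
        raise ValidationError(f"missing indicator values: {rows[:5]}")
    counts = table.pivot_table(
        index="area_id", columns="indicator_name", values="value", aggfunc="count"
    )
    cells = counts.reindex(columns=sorted(dim_of["indicator_name"])).fillna(0)
    missing_cells = [
        {"area_id": area, "indicator_name": ind}
        for area, row in cells.iterrows()
        for ind, k in row.items()
        if k != 1
    ]
    if missing_cells:
        raise ValidationError(
            f"{len(missing_cells)} missing/duplicated area-indicator cell(s): {missing_cells[:5]}"
        )
    return table


def _to_wide(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Pivot to areas x indicators; return (wide frame, dimension -> indicators)."""
    wide = table.pivot(index="area_id", columns="indicator_name", values="value")
    wide = wide.sort_index()
    dims = {
        dim: sorted(table.loc[table["dimension"] == dim, "indicator_name"].unique())
        for dim in DIMENSIONS
    }
    return wide, dims


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """z-score every indicator across areas (population sd, ddof=0).

    Raises :class:`DegenerateInputError` for a constant indicator.
    """
    validate_indicators(table)
    out = table.copy()
    grp = out.groupby("indicator_name")["value"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda s: s.std(ddof=0))
    constant = sd <= 1e-12 * (mean.abs() + 1.0)
    if constant.any():
        names = sorted(out.loc[constant, "indicator_name"].unique())
        raise DegenerateInputError(f"zero-variance indicator(s): {names}")
    out["value"] = (out["value"] - mean) / sd
    return out


class DeprivationIndexer(TransformerMixin, BaseEstimator):
    """Transformer from an indicator table to the [0, 1] deprivation index.

    Parameters
    ----------
    orientation:
        Mapping ``dimension -> (anchor_indicator, direction)`` declaring, per
        dimension, which indicator defines the direction of deprivation
        (direction +1: higher anchor value = more deprived).  Defaults to the
        synthetic indicator set's anchors.
    weighting:
        ``"squared"`` (default) weights indicators by squared first-PC
        loadings (explained-variance shares); ``"raw"`` by normalised
        absolute loadings.

    Attributes
    ----------
    weights_:
        ``dimension -> tuple[IndicatorWeight, ...]`` fitted per-dimension
        weights (non-negative, summing to 1) and orientation signs.
    means_, sds_:
        Standardisation statistics per indicator, learned at fit.
    areas_:
        Area identifiers seen at fit; transform requires the same set.
    """

    def __init__(self, orientation: Mapping[str, tuple[str, int]] | None = None,
                 weighting: str = "squared"):
        self.orientation = orientation
        self.weighting = weighting

    # -- fitting ---------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        if self.weighting not in ("squared", "raw"):
            raise ValueError("weighting must be 'squared' or 'raw'")
        table = validate_indicators(X)
        wide, dims = _to_wide(table)
        means = wide.mean(axis=0)
        sds = wide.std(axis=0, ddof=0)
        constant = sds <= 1e-12 * (means.abs() + 1.0)
        if constant.any():
            raise DegenerateInputError(
                f"zero-variance indicator(s): {sorted(sds.index[constant])}"
            )
        zs = (wide - means) / sds

        orientation = dict(self.orientation or DEFAULT_ORIENTATION)
        weights: dict[str, tuple[IndicatorWeight, ...]] = {}
        for dim in DIMENSIONS:
            cols = dims[dim]
            block = zs[cols].to_numpy()
            if np.allclose(block.std(axis=0), 0):
                raise DegenerateInputError(f"dimension {dim!r}: rank-0 indicator block")
            pca = PCA(n_components=1)
            pca.fit(block)
            loadings = pca.components_[0]
            anchor, direction = orientation.get(dim, (None, 1))
            if anchor is not None:
                if anchor not in cols:
                    raise ValidationError(
                        f"orientation anchor {anchor!r} is not an indicator of dimension {dim!r}"
                    )
                score = block @ loadings
                anchor_col = direction * zs[anchor].to_numpy()
                corr = float(np.dot(score - score.mean(), anchor_col - anchor_col.mean()))
                if corr < 0:
                    loadings = -loadings
            if self.weighting == "squared":
                w = loadings**2
            else:
                w = np.abs(loadings)
            w = w / w.sum()
            signs = np.where(loadings >= 0, 1, -1)
            weights[dim] = tuple(
                IndicatorWeight(indicator=c, weight=float(wj), sign=int(sj))
                for c, wj, sj in zip(cols, w, signs)
            )

        self.weights_ = weights
        self.means_ = means
        self.sds_ = sds
        self.areas_ = wide.index
        self.dimensions_ = dims
        self.n_features_in_ = wide.shape[1]
        raw = self._raw_scores(zs)
        self.raw_scores_ = raw
        return self

    def _raw_scores(self, zs: pd.DataFrame) -> pd.Series:
        dim_scores = []
        for dim in DIMENSIONS:
            ws = self.weights_[dim]
            score = sum(w.weight * w.sign * zs[w.indicator] for w in ws)
            dim_scores.append(score)
        return sum(dim_scores) / len(dim_scores)

    # -- transforming ----------------------------------------------------
    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Raw and min-max normalised index per area.

        The min-max normalisation runs over the supplied area set, which must
        equal the set seen at fit (the index is a relative, cross-sectional
        measure; mixing fits across area sets is a consistency error).
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "weights_")
        table = validate_indicators(X)
        wide, _ = _to_wide(table)
        if set(wide.columns) != set(self.means_.index):
            raise ValidationError("indicator set does not match the fitted weights")
        if not wide.index.equals(self.areas_):
            raise ValidationError(
                "area set does not match the set the weights were fitted on"
            )
        zs = (wide[self.means_.index] - self.means_) / self.sds_
        raw = self._raw_scores(zs)
        lo, hi = raw.min(), raw.max()
        if hi == lo:
            raise DegenerateInputError("all areas have identical raw deprivation scores")
        gisd = (raw - lo) / (hi - lo)
        return pd.DataFrame({"area_id": raw.index, "raw_score": raw.to_numpy(),
                             "gisd": gisd.to_numpy()}).reset_index(drop=True)


def fit_dimension_weights(
    table: pd.DataFrame,
    orientation: Mapping[str, tuple[str, int]] | None = None,
    weighting: str = "squared",
) -> dict[str, tuple[IndicatorWeight, ...]]:
    """Per-dimension first-PC indicator weights (thin wrapper over the estimator)."""
    return DeprivationIndexer(orientation=orientation, weighting=weighting).fit(table).weights_


def compose_index(
    table: pd.DataFrame, weights: Mapping[str, tuple[IndicatorWeight, ...]]
) -> pd.DataFrame:
    """Compose the [0, 1] index from an indicator table and fitted weights.

    Raw score = equal-weight mean over dimensions of the weighted, signed,
    standardised indicator values; then min-max normalised over the areas in
    ``table``.
    """
    std = standardize(table)
    wide, dims = _to_wide(std)
    fitted = sorted(w.indicator for ws in weights.values() for w in ws)
    if fitted != sorted(wide.columns):
        raise ValidationError(
            "weights were fitted on a different indicator set than the table"
        )
    dim_scores = []
    for dim in DIMENSIONS:
        ws = weights[dim]
        dim_scores.append(sum(w.weight * w.sign * wide[w.indicator] for w in ws))
    raw = sum(dim_scores) / len(dim_scores)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise DegenerateInputError("all areas have identical raw deprivation scores")
    gisd = (raw - lo) / (hi - lo)
    return pd.DataFrame(
        {"area_id": raw.index, "raw_score": raw.to_numpy(), "gisd": gisd.to_numpy()}
    ).reset_index(drop=True)
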