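"""Abridged period life tables from death counts and person-years.

The construction is the standard abridged one: central death rates ``m`` are
pooled over a multi-year window (deaths and person-years summed separately),
converted to death probabilities with Chiang's formula
``q = n*m / (1 + (n - a)*m)``, and chained into the survivorship column from
a radix.  The open-ended terminal band is closed with the constant-hazard
rule ``L = l/m``.  Life expectancy at birth ``e0`` is radix-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .age import AgeSchema
from .errors import CompletenessError, DegenerateInputError, ValidationError

DEFAULT_RADIX = 100_000.0


def rate_to_probability(m, width, a):
    """Chiang conversion of a central rate to a death probability (closed band).

    q = width * m / (1 + (width - a) * m), capped at 1; m = 0 gives q = 0.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValidationError("central death rate must be >= 0")
    q = width * m / (1.0 + (width - a) * m)
    return np.minimum(q, 1.0)


def period_label(period: tuple[int, int]) -> str:
    return f"{period[0]}-{period[1]}"


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["area_id", "sex", "year", "age_lower", "age_width", "deaths", "person_years"]


def pool_period(records: pd.DataFrame, period: tuple[int, int],
                schema: AgeSchema | None = None) -> pd.DataFrame:
    """Pool mortality records over one calendar period.

    Deaths and person-years are summed per (area_id, sex, band) across all
    years of the period; the central rate is ``m = D / PY``.  Every
    (area, sex) cell must contribute all years of the period, and, when a
    schema is given, exactly its bands.

    Returns a tidy frame with columns area_id, sex, age_lower, age_width,
    deaths, person_years, m; the period is stored in ``.attrs["period"]``.
    """
    missing = [c for c in _RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"mortality records missing columns {missing}")
    y0, y1 = period
    sel = records[(records["year"] >= y0) & (records["year"] <= y1)]
    if sel.empty:
        raise CompletenessError(f"no mortality records in period {period_label(period)}")

    want_years = set(range(y0, y1 + 1))
    got_years = sel.groupby(["area_id", "sex"])["year"].agg(lambda s: set(s))
    gaps = {
        cell: sorted(want_years - yrs)
        for cell, yrs in got_years.items()
        if want_years - yrs
    }
    if gaps:
        detail = "; ".join(f"{a}/{s}: missing years {m}" for (a, s), m in list(gaps.items())[:5])
        raise CompletenessError(
            f"period {period_label(period)} incomplete for {len(gaps)} cell(s): {detail}"
        )

    pooled = (
        sel.groupby(["area_id", "sex", "age_lower", "age_width"], as_index=False)[
            ["deaths", "person_years"]
        ]
        .sum()
        .sort_values(["area_id", "sex", "age_lower"], ignore_index=True)
    )
    if schema is not None:
        want_bands = set(zip(schema.lowers, schema.width_codes()))
        for (area, sex), grp in pooled.groupby(["area_id", "sex"]):
            got = set(zip(grp["age_lower"], grp["age_width"]))
            if got != want_bands:
                raise CompletenessError(
                    f"{area}/{sex}: age bands {sorted(got)} do not match schema "
                    f"{schema.name} in period {period_label(period)}"
                )
    bad = pooled[(pooled["person_years"] == 0) & (pooled["deaths"] > 0)]
    if not bad.empty:
        rows = bad[["area_id", "sex", "age_lower"]].to_dict("records")
        raise ValidationError(f"deaths with zero exposure: {rows[:5]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(
            pooled["person_years"] > 0,
            pooled["deaths"] / pooled["person_years"].where(pooled["person_years"] > 0, 1.0),
            0.0,
        )
    pooled["m"] = m
    pooled.attrs["period"] = tuple(period)
    return pooled


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Full abridged life-table column set for one area x sex x period."""

    schema: AgeSchema
    radix: float
    m: np.ndarray
    q: np.ndarray
    a: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray

    @property
    def e0(self) -> float:
        """Life expectancy at birth, T(0)/radix."""
        return float(self.T[0] / self.radix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_lower": self.schema.lowers,
                "age_width": self.schema.width_codes(),
                "m": self.m,
                "q": self.q,
                "a": self.a,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )


def _columns_from_rates(M: np.ndarray, schema: AgeSchema, radix: float):
    """Vectorised abridged construction for a stack of rate vectors.

    M has shape (k, n_bands); returns dict of column arrays of the same shape.
    """
    if np.any(M < 0) or not np.all(np.isfinite(M)):
        raise ValidationError("central death rates must be finite and >= 0")
    k, nb = M.shape
    widths = schema.widths
    ax = schema.axs
    q = np.empty_like(M)
    q[:, :-1] = np.minimum(
        widths[:-1] * M[:, :-1] / (1.0 + (widths[:-1] - ax[:-1]) * M[:, :-1]), 1.0
    )
    q[:, -1] = 1.0

    l = np.empty((k, nb))
    l[:, 0] = radix
    for j in range(nb - 1):
        l[:, j + 1] = l[:, j] * (1.0 - q[:, j])
    d = l * q

    L = np.empty_like(M)
    if nb > 1:
        L[:, :-1] = widths[:-1] * l[:, 1:] + ax[:-1] * d[:, :-1]
    m_open = M[:, -1]
    l_open = l[:, -1]
    degenerate = (m_open == 0) & (l_open > 0)
    if np.any(degenerate):
        raise DegenerateInputError(
            "open-interval rate is 0 with survivors present: life expectancy undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        L[:, -1] = np.where(l_open > 0, l_open / np.where(m_open > 0, m_open, 1.0), 0.0)

    T = np.cumsum(L[:, ::-1], axis=1)[:, ::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), np.nan)
    return {"m": M, "q": q, "l": l, "d": d, "L": L, "T": T, "e": e}


def build_life_table(rates, schema: AgeSchema, radix: float = DEFAULT_RADIX) -> LifeTable:
    """Build one abridged life table from per-band central death rates.

    ``rates`` is either an array of m values aligned with ``schema`` bands or
    a pooled-rates frame for a single (area, sex) cell (column ``m``, rows
    sorted by age).
    """
    if isinstance(rates, pd.DataFrame):
        if rates[["area_id", "sex"]].drop_duplicates().shape[0] > 1:
            raise ValidationError(
                "build_life_table expects a single area/sex cell; use life_expectancy_surface"
            )
        rates = rates.sort_values("age_lower")["m"].to_numpy()
    M = np.asarray(rates, dtype=float).reshape(1, -1)
    if M.shape[1] != schema.n_bands:
        raise ValidationError(
            f"expected {schema.n_bands} band rates for schema {schema.name}, got {M.shape[1]}"
        )
    cols = _columns_from_rates(M, schema, radix)
    return LifeTable(
        schema=schema,
        radix=radix,
        a=schema.axs,
        **{key: val[0] for key, val in cols.items()},
    )


class SurfaceResult(NamedTuple):
    """e0 per (area, sex, period) plus the cells that could not be computed."""

    e0: pd.DataFrame
    failures: pd.DataFrame


def life_expectancy_surface(
    records: pd.DataFrame,
    schema: AgeSchema,
    periods: list[tuple[int, int]],
    areas: list[str] | None = None,
    sexes: list[str] | None = None,
    radix: float = DEFAULT_RADIX,
    on_error: str = "raise",
) -> SurfaceResult:
    """Life expectancy at birth for every area x sex x period.

    Batch wrapper over :func:`pool_period` + the abridged construction,
    vectorised over cells.  With ``on_error="report"`` a failed period is
    recorded in ``failures`` (period, sex, area, reason) instead of raising.
    """
    if areas is not None:
        records = records[records["area_id"].isin(areas)]
    if sexes is not None:
        records = records[records["sex"].isin(sexes)]
    e0_rows: list[pd.DataFrame] = []
    failures: list[dict] = []
    for period in periods:
        label = period_label(period)
        try:
            pooled = pool_period(records, period, schema=schema)
            pivot = pooled.pivot_table(
                index=["area_id", "sex"], columns="age_lower", values="m", sort=True
            ).sort_index(axis=1)
            M = pivot.to_numpy()
            cols = _columns_from_rates(M, schema, radix)
            e0 = cols["T"][:, 0] / radix
            frame = pivot.index.to_frame(index=False)
            frame["period_label"] = label
            frame["e0"] = e0
            e0_rows.append(frame)
        except Exception as exc:  # noqa: BLE001 - failures are reported, not dropped
            if on_error != "report":
                raise
            failures.append({"period_label": label, "reason": f"{type(exc).__name__}: {exc}"})
    e0_df = (
        pd.concat(e0_rows, ignore_index=True)[["area_id", "sex", "period_label", "e0"]]
        if e0_rows
        else pd.DataFrame(columns=["area_id", "sex", "period_label", "e0"])
    )
    return SurfaceResult(e0_df, pd.DataFrame(failures, columns=["period_label", "reason"]))
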