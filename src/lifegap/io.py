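"""CSV/YAML input and output with strict, line-numbered validation.

All writers emit plain comma-separated files with fixed headers and ``\n``
line endings; all readers verify the header, types and value ranges and cite
1-based line numbers (header = line 1) for malformed rows.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deprivation import IndicatorWeight, validate_indicators
from .errors import ParseError
from .synthetic import GompertzMakeham, ScenarioConfig

MORTALITY_COLUMNS = ["area_id", "sex", "year", "age_lower", "age_width", "deaths", "person_years"]
INDICATOR_COLUMNS = ["area_id", "dimension", "indicator_name", "value"]
E0_COLUMNS = ["area_id", "sex", "period_label", "e0"]
INDEX_COLUMNS = ["area_id", "period_label", "gisd_value"]


def _read_csv(path, expected_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != expected_columns:
        raise ParseError(
            f"{path}: header mismatch; expected {expected_columns}, got {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, column: str, path, integer: bool = False,
             minimum: float | None = None) -> pd.Series:
    raw = df[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() | (raw.str.strip() == "")
    if integer:
        bad |= values.notna() & (values % 1 != 0)
    if minimum is not None:
        bad |= values < minimum
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ParseError(
            f"{path}: invalid {column!r} at line(s) {lines[:10]}"
            + (f" (+{len(lines) - 10} more)" if len(lines) > 10 else "")
        )
    return values.astype(np.int64) if integer else values.astype(float)


def read_mortality_csv(path) -> pd.DataFrame:
    """Typed mortality records; rejects malformed rows with line numbers."""
    df = _read_csv(path, MORTALITY_COLUMNS)
    out = pd.DataFrame(
        {
            "area_id": df["area_id"],
            "sex": df["sex"],
            "year": _numeric(df, "year", path, integer=True),
            "age_lower": _numeric(df, "age_lower", path, minimum=0),
            "age_width": _numeric(df, "age_width", path),
            "deaths": _numeric(df, "deaths", path, integer=True, minimum=0),
            "person_years": _numeric(df, "person_years", path, minimum=0),
        }
    )
    bad_width = ~((out["age_width"] > 0) | (out["age_width"] == -1))
    if bad_width.any():
        lines = (out.index[bad_width] + 2).tolist()
        raise ParseError(f"{path}: age_width must be > 0 or -1 (open band) at line(s) {lines[:10]}")
    return out


def write_mortality_csv(records: pd.DataFrame, path) -> None:
    records[MORTALITY_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_indicator_csv(path) -> pd.DataFrame:
    """Typed indicator table; delegates structure checks to validate_indicators."""
    df = _read_csv(path, INDICATOR_COLUMNS)
    out = pd.DataFrame(
        {
            "area_id": df["area_id"],
            "dimension": df["dimension"],
            "indicator_name": df["indicator_name"],
            "value": _numeric(df, "value", path),
        }
    )
    return validate_indicators(out)


def write_indicator_csv(table: pd.DataFrame, path) -> None:
    table[INDICATOR_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def write_e0_csv(surface: pd.DataFrame, path) -> None:
    surface[E0_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def write_index_csv(index: pd.DataFrame, path, label: str = "") -> None:
    out = pd.DataFrame(
        {
            "area_id": index["area_id"],
            "period_label": label,
            "gisd_value": index["gisd"],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def write_trend_csv(trend_frame: pd.DataFrame, path) -> None:
    trend_frame.to_csv(path, index=False, lineterminator="\n")


def write_scatter_csv(scatter: pd.DataFrame, path) -> None:
    scatter.to_csv(path, index=False, lineterminator="\n")


def write_weights_yaml(weights: Mapping[str, tuple[IndicatorWeight, ...]], path) -> None:
    payload = {
        dim: [
            {"indicator": w.indicator, "weight": float(w.weight), "sign": int(w.sign)}
            for w in ws
        ]
        for dim, ws in weights.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def write_manifest(path, **entries) -> None:
    """Run manifest: config echo, versions, seed, row counts."""
    from . import __version__

    payload = {"lifegap_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Scenario / pipeline configuration files
# ---------------------------------------------------------------------------

def scenario_from_dict(data: Mapping) -> ScenarioConfig:
    """Build a ScenarioConfig from a plain (YAML-loaded) mapping."""
    data = dict(data)
    if "hazard_params" in data and isinstance(data["hazard_params"], Mapping):
        hp = data["hazard_params"]
        if "makeham_c" in hp:  # single schedule for both sexes
            data["hazard_params"] = GompertzMakeham(**hp)
        else:
            data["hazard_params"] = {sex: GompertzMakeham(**p) for sex, p in hp.items()}
    for key in ("years", "indicator_loadings"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return ScenarioConfig(**data)


def load_scenario_yaml(path) -> ScenarioConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return scenario_from_dict(data)


def load_orientation_yaml(path) -> dict[str, tuple[str, int]]:
    """Orientation file: dimension -> {indicator: ..., direction: +/-1}."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    out = {}
    for dim, entry in data.items():
        out[dim] = (entry["indicator"], int(entry.get("direction", 1)))
    return out
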