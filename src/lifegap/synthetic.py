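"""Synthetic area-level mortality and deprivation-indicator generator.

Emulates the data environment of a national small-area mortality analysis:
~400 areas of heterogeneous (log-normal) population size, each carrying a
latent standardised deprivation score ``z``; age-specific mortality follows a
Gompertz–Makeham hazard scaled proportionally by ``exp(gamma * z)`` so that
life expectancy declines smoothly with deprivation; death counts are Poisson
draws against stationary-population person-years; and nine area-level
indicator variables (three per dimension: education, employment, income) are
noisy linear functions of ``z`` with mixed signs.

Because the hazard is known in closed form, every downstream stage has an
analytic oracle: :func:`analytic_e0` integrates the survival function
numerically and provides the ground-truth life expectancy for any area.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .age import OPEN_WIDTH, AgeSchema, get_schema
from .errors import ConfigurationError

SEXES = ("female", "male")

#: Upper integration limit (years) for survival-function quadrature; the
#: Gompertz term makes survival beyond this age numerically zero.
_MAX_AGE = 130.0
_GRID_STEP = 0.05


@dataclass(frozen=True)
class GompertzMakeham:
    """Gompertz–Makeham hazard h(x) = makeham_c + gompertz_a * exp(gompertz_b * x).

    ``makeham_c`` is the age-independent background rate (1/year),
    ``gompertz_a`` the senescent level at age 0 (1/year) and ``gompertz_b``
    the senescence slope (1/year of age).
    """

    makeham_c: float
    gompertz_a: float
    gompertz_b: float

    def rate(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("hazard undefined for negative age")
        return self.makeham_c + self.gompertz_a * np.exp(self.gompertz_b * age)

    def cumulative(self, age):
        """Integrated hazard from 0 to ``age`` (closed form)."""
        age = np.asarray(age, dtype=float)
        return self.makeham_c * age + self.gompertz_a / self.gompertz_b * np.expm1(
            self.gompertz_b * age
        )


#: Baselines giving e0 ~ 83 (female) and ~ 78 (male) at z = 0.
DEFAULT_HAZARDS: Mapping[str, GompertzMakeham] = {
    "female": GompertzMakeham(1e-4, 6.4e-6, 0.11),
    "male": GompertzMakeham(2e-4, 3.0e-5, 0.095),
}

#: Indicator design: (dimension, indicator_name, default signed loading).
#: Income-like indicators load negatively on deprivation; each dimension also
#: carries one protective (negative) education/employment indicator so the
#: index construction must handle mixed signs.
INDICATOR_DESIGN: tuple[tuple[str, str, float], ...] = (
    ("education", "school_dropout_rate", 0.8),
    ("education", "no_vocational_training_rate", 0.7),
    ("education", "higher_education_rate", -0.6),
    ("employment", "unemployment_rate", 0.9),
    ("employment", "marginal_employment_rate", 0.7),
    ("employment", "employment_rate", -0.6),
    ("income", "household_income", -0.85),
    ("income", "median_wage", -0.7),
    ("income", "tax_revenue_per_capita", -0.6),
)

DEFAULT_LOADINGS = tuple(loading for _, _, loading in INDICATOR_DESIGN)


def _per_sex(value, name: str) -> dict[str, float]:
    """Broadcast a scalar or validate a per-sex mapping."""
    if isinstance(value, Mapping):
        missing = set(SEXES) - set(value)
        if missing:
            raise ConfigurationError(f"{name}: missing sexes {sorted(missing)}")
        return {s: float(value[s]) for s in SEXES}
    return {s: float(value) for s in SEXES}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic scenario.

    The seed determines every random draw; identical configs produce
    byte-identical output files.

    Parameters
    ----------
    n_areas:
        Number of areas (districts).
    years:
        Inclusive calendar-year range ``(first, last)``.
    age_schema_id:
        Name of the age banding used for aggregation.
    pop_scale:
        Mean area population (persons); person-years per calendar year equal
        the mid-year population.
    pop_dispersion:
        Log-normal sigma of area size; 0 makes all areas exactly pop_scale.
    hazard_params:
        Per-sex Gompertz–Makeham baselines (a single schedule is broadcast).
    gradient_gamma:
        Log-hazard increment per unit latent deprivation; scalar or per-sex.
    drift_per_year:
        Annual multiplicative hazard change (1.0 = no secular trend);
        scalar or per-sex.
    drift_gradient:
        Deprivation dependence of the drift: the hazard multiplier is
        ``exp(gamma*z + drift_gradient*z*t) * drift_per_year**t`` with
        ``t = year - first year``.  Positive values make deprived areas
        benefit less from an improving trend (a widening gap).
    indicator_loadings:
        Nine signed loadings, in :data:`INDICATOR_DESIGN` order.
    indicator_noise_sd:
        Per-indicator Gaussian noise scale (scalar or length 9).
    seed:
        Root RNG seed.
    """

    n_areas: int = 400
    years: tuple[int, int] = (2003, 2022)
    age_schema_id: str = "abridged_5y_85"
    pop_scale: float = 200_000.0
    pop_dispersion: float = 0.8
    hazard_params: Mapping[str, GompertzMakeham] | GompertzMakeham = field(
        default_factory=lambda: dict(DEFAULT_HAZARDS)
    )
    gradient_gamma: float | Mapping[str, float] = 0.148
    drift_per_year: float | Mapping[str, float] = 1.0
    drift_gradient: float | Mapping[str, float] = 0.0
    indicator_loadings: tuple[float, ...] = DEFAULT_LOADINGS
    indicator_noise_sd: float | tuple[float, ...] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_areas) != self.n_areas or self.n_areas < 2:
            raise ConfigurationError("n_areas: must be an integer >= 2")
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError("years: last year precedes first year")
        if not self.pop_scale > 0:
            raise ConfigurationError("pop_scale: must be > 0")
        if self.pop_dispersion < 0:
            raise ConfigurationError("pop_dispersion: must be >= 0")
        for sex, hp in self.hazards().items():
            if hp.gompertz_b <= 0:
                raise ConfigurationError(f"hazard_params[{sex}]: gompertz_b must be > 0")
            if hp.gompertz_a <= 0 or hp.makeham_c < 0:
                raise ConfigurationError(
                    f"hazard_params[{sex}]: gompertz_a must be > 0 and makeham_c >= 0"
                )
        if len(self.indicator_loadings) != len(INDICATOR_DESIGN):
            raise ConfigurationError(
                f"indicator_loadings: expected {len(INDICATOR_DESIGN)} values, "
                f"got {len(self.indicator_loadings)}"
            )
        noise = self.noise_sds()
        if np.any(noise < 0):
            raise ConfigurationError("indicator_noise_sd: must be >= 0")
        for name in ("gradient_gamma", "drift_per_year", "drift_gradient"):
            _per_sex(getattr(self, name), name)  # validates mappings
        drift = _per_sex(self.drift_per_year, "drift_per_year")
        if any(v <= 0 for v in drift.values()):
            raise ConfigurationError("drift_per_year: must be > 0")

    # -- resolved accessors ----------------------------------------------
    def hazards(self) -> dict[str, GompertzMakeham]:
        hp = self.hazard_params
        if isinstance(hp, GompertzMakeham):
            return {s: hp for s in SEXES}
        missing = set(SEXES) - set(hp)
        if missing:
            raise ConfigurationError(f"hazard_params: missing sexes {sorted(missing)}")
        return dict(hp)

    def gamma_for(self, sex: str) -> float:
        return _per_sex(self.gradient_gamma, "gradient_gamma")[sex]

    def drift_for(self, sex: str) -> float:
        return _per_sex(self.drift_per_year, "drift_per_year")[sex]

    def drift_gradient_for(self, sex: str) -> float:
        return _per_sex(self.drift_gradient, "drift_gradient")[sex]

    def noise_sds(self) -> np.ndarray:
        sd = self.indicator_noise_sd
        if np.isscalar(sd):
            return np.full(len(INDICATOR_DESIGN), float(sd))
        sd = np.asarray(sd, dtype=float)
        if sd.shape != (len(INDICATOR_DESIGN),):
            raise ConfigurationError("indicator_noise_sd: scalar or length-9 sequence")
        return sd

    def schema(self) -> AgeSchema:
        return get_schema(self.age_schema_id)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------

_STREAM_AREAS = 101
_STREAM_INDICATORS = 202
_STREAM_DEATHS = 303


def _rng(config: ScenarioConfig, *key: int) -> np.random.Generator:
    """Deterministic child stream keyed off the root seed.

    One stream per (area, sex, year) for death counts, so regenerating a
    subset of years or areas reproduces the same draws.
    """
    return np.random.default_rng([int(config.seed), *map(int, key)])


# ---------------------------------------------------------------------------
# Areas and hazards
# ---------------------------------------------------------------------------

def generate_areas(config: ScenarioConfig) -> pd.DataFrame:
    """Draw the area frame: identifier, latent deprivation ``z``, population.

    Populations are log-normal with mean ``pop_scale`` (sigma-corrected so
    the expectation is exact); latent scores are a single standard-normal
    vector drawn in fixed area order and then standardised exactly to mean 0,
    sd 1, so planted "z = ±2 sigma" areas are well defined.
    """
    n = int(config.n_areas)
    width = max(3, len(str(n)))
    area_ids = [f"A{i + 1:0{width}d}" for i in range(n)]
    rng = _rng(config, _STREAM_AREAS)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std()
    sigma = float(config.pop_dispersion)
    if sigma == 0:
        pop = np.full(n, float(config.pop_scale))
    else:
        mu = np.log(config.pop_scale) - sigma**2 / 2.0
        pop = np.exp(rng.normal(mu, sigma, size=n))
    return pd.DataFrame({"area_id": area_ids, "z": z, "population": pop})


def _multiplier(config: ScenarioConfig, sex: str, year: int, z) -> np.ndarray:
    t = float(year - config.years[0])
    z = np.asarray(z, dtype=float)
    gamma = config.gamma_for(sex)
    dg = config.drift_gradient_for(sex)
    drift = config.drift_for(sex)
    return np.exp(gamma * z + dg * z * t) * drift**t


def hazard_at_age(age, sex: str, year: int, z, config: ScenarioConfig):
    """Mortality hazard (1/year) at exact age for an area with latent score z.

    ``(makeham_c + gompertz_a * exp(gompertz_b * age))`` scaled by
    ``exp(gamma*z + drift_gradient*z*t) * drift_per_year**t``.
    """
    base = config.hazards()[sex].rate(age)
    return base * _multiplier(config, sex, year, z)


def _survival_grid(config: ScenarioConfig, sex: str, year: int, z) -> tuple[np.ndarray, np.ndarray]:
    """Survival S(x) on a fine age grid for each requested z (rows)."""
    grid = np.arange(0.0, _MAX_AGE + _GRID_STEP / 2, _GRID_STEP)
    H0 = config.hazards()[sex].cumulative(grid)
    mult = _multiplier(config, sex, year, z)
    S = np.exp(-np.outer(mult, H0))
    return grid, S


def analytic_e0(config: ScenarioConfig, sex: str, z, year: int | None = None):
    """Ground-truth life expectancy at birth by quadrature of exp(-H(x)).

    This is the generator-side oracle the life-table pipeline is checked
    against; it never touches the life-table code path.
    """
    year = config.years[0] if year is None else year
    scalar = np.isscalar(z)
    grid, S = _survival_grid(config, sex, year, np.atleast_1d(z))
    e0 = np.trapezoid(S, grid, axis=1)
    return float(e0[0]) if scalar else e0


def planted_endpoint_gap(config: ScenarioConfig, sex: str, year: int | None = None,
                         sigma: float = 2.0) -> float:
    """Analytic e0 difference between areas at z = -sigma and z = +sigma."""
    lo, hi = analytic_e0(config, sex, [-sigma, sigma], year)
    return float(lo - hi)


# ---------------------------------------------------------------------------
# Mortality simulation
# ---------------------------------------------------------------------------

def _band_structure(config: ScenarioConfig, sex: str, year: int, z: np.ndarray,
                    schema: AgeSchema) -> tuple[np.ndarray, np.ndarray]:
    """Stationary-population structure per area.

    Returns ``(py_share, m)`` with shape (n_areas, n_bands): the fraction of
    total person-years spent in each band under the area's hazard, and the
    exact stationary central death rate of the band,
    m = (S(lo) - S(hi)) / integral of S over the band.
    """
    grid, S = _survival_grid(config, sex, year, z)
    integral = cumulative_trapezoid(S, grid, axis=1, initial=0.0)
    edges = np.append(schema.lowers, _MAX_AGE)
    idx = np.searchsorted(grid, edges)
    if not np.allclose(grid[idx], edges):
        raise ConfigurationError("age schema edges must align with the quadrature grid")
    S_e = S[:, idx]
    I_e = integral[:, idx]
    deaths_share = S_e[:, :-1] - S_e[:, 1:]
    py = I_e[:, 1:] - I_e[:, :-1]
    py_share = py / I_e[:, -1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(py > 0, deaths_share / np.where(py > 0, py, 1.0), 0.0)
    return py_share, m


def simulate_mortality(areas: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Poisson death counts and person-years per area x sex x year x band.

    Person-years in a band are the area population times its stationary-
    population share of the band (so bands sum to the population each year);
    deaths are Poisson with mean (central rate x person-years), drawn from a
    child stream per (area, sex, year).
    """
    schema = config.schema()
    y0, y1 = config.years
    z = areas["z"].to_numpy()
    pop = areas["population"].to_numpy()
    n_bands = schema.n_bands
    width_codes = schema.width_codes()
    static = all(
        config.drift_for(s) == 1.0 and config.drift_gradient_for(s) == 0.0 for s in SEXES
    )

    frames = []
    for s_idx, sex in enumerate(SEXES):
        structure = None
        for year in range(y0, y1 + 1):
            if structure is None or not static:
                py_share, m = _band_structure(config, sex, year, z, schema)
            structure = True
            person_years = pop[:, None] * py_share
            mean_deaths = m * person_years
            deaths = np.empty_like(mean_deaths, dtype=np.int64)
            for a_idx in range(len(areas)):
                rng = _rng(config, _STREAM_DEATHS, a_idx, s_idx, year)
                deaths[a_idx] = rng.poisson(mean_deaths[a_idx])
            frames.append(
                pd.DataFrame(
                    {
                        "area_id": np.repeat(areas["area_id"].to_numpy(), n_bands),
                        "sex": sex,
                        "year": year,
                        "age_lower": np.tile(schema.lowers, len(areas)),
                        "age_width": np.tile(width_codes, len(areas)),
                        "deaths": deaths.ravel(),
                        "person_years": person_years.ravel(),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["age_lower"] = out["age_lower"].astype(float)
    out["age_width"] = out["age_width"].astype(float)
    return out


# ---------------------------------------------------------------------------
# Indicator simulation
# ---------------------------------------------------------------------------

def simulate_indicators(areas: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Nine noisy indicator columns, long format (area_id, dimension, name, value).

    indicator_j = loading_j * z + noise_j, with the mixed-sign loadings of
    :data:`INDICATOR_DESIGN` (income-like indicators load negatively on
    deprivation).
    """
    z = areas["z"].to_numpy()
    loadings = np.asarray(config.indicator_loadings, dtype=float)
    noise_sd = config.noise_sds()
    rng = _rng(config, _STREAM_INDICATORS)
    noise = rng.standard_normal((len(areas), len(loadings))) * noise_sd
    values = z[:, None] * loadings + noise
    rows = []
    for j, (dimension, name, _) in enumerate(INDICATOR_DESIGN):
        rows.append(
            pd.DataFrame(
                {
                    "area_id": areas["area_id"],
                    "dimension": dimension,
                    "indicator_name": name,
                    "value": values[:, j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["area_id", "dimension", "indicator_name"], ignore_index=True
    )
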