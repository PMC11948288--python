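import numpy as np
import pandas as pd
import pytest

import lifegap as lg


@pytest.fixture(scope="session")
def toy_schema():
    """Three bands: 0-4, 5-9, 10+ with midpoint separation fractions."""
    return lg.AgeSchema("toy", (0.0, 5.0, 10.0), (5.0, 5.0, np.inf), (2.5, 2.5, np.nan))


@pytest.fixture(scope="session")
def small_config():
    """A fast scenario: 60 areas, one 3-year window."""
    return lg.ScenarioConfig(n_areas=60, years=(2020, 2022), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    areas = lg.generate_areas(small_config)
    records = lg.simulate_mortality(areas, small_config)
    indicators = lg.simulate_indicators(areas, small_config)
    return areas, records, indicators


def make_indicator_table(values: np.ndarray, area_ids=None) -> pd.DataFrame:
    """Long indicator table from an (n_areas, 9) array in INDICATOR_DESIGN order."""
    from lifegap.synthetic import INDICATOR_DESIGN

    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if area_ids is None:
        area_ids = [f"A{i + 1:03d}" for i in range(n)]
    rows = []
    for j, (dim, name, _) in enumerate(INDICATOR_DESIGN):
        for i, area in enumerate(area_ids):
            rows.append((area, dim, name, values[i, j]))
    return pd.DataFrame(rows, columns=["area_id", "dimension", "indicator_name", "value"])
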