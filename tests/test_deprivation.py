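"""Deprivation index: validation, standardisation, PCA weights, composition."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.base import clone

import lifegap as lg
from lifegap.deprivation import DIMENSIONS, DeprivationIndexer
from lifegap.errors import DegenerateInputError, ValidationError

from conftest import make_indicator_table


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(42)
    return make_indicator_table(rng.normal(size=(25, 9)))


class TestValidate:
    def test_complete_table_returned_unchanged(self, random_table):
        out = lg.validate_indicators(random_table)
        pd.testing.assert_frame_equal(out, random_table)

    def test_missing_cell_names_area_and_indicator(self, random_table):
        broken = random_table.drop(
            random_table[
                (random_table["area_id"] == "A003")
                & (random_table["indicator_name"] == "household_income")
            ].index
        )
        with pytest.raises(ValidationError) as err:
            lg.validate_indicators(broken)
        assert "A003" in str(err.value) and "household_income" in str(err.value)

    def test_four_indicators_in_one_dimension_is_structural_error(self, random_table):
        extra = random_table[random_table["indicator_name"] == "median_wage"].copy()
        extra["indicator_name"] = "extra_income_indicator"
        with pytest.raises(ValidationError, match="exactly 3"):
            lg.validate_indicators(pd.concat([random_table, extra], ignore_index=True))

    def test_unknown_dimension_label_named(self, random_table):
        broken = random_table.copy()
        broken.loc[broken.index[:5], "dimension"] = "housing"
        with pytest.raises(ValidationError, match="housing"):
            lg.validate_indicators(broken)


class TestStandardize:
    def test_columns_mean_zero_sd_one(self, random_table):
        std = lg.standardize(random_table)
        grp = std.groupby("indicator_name")["value"]
        assert np.allclose(grp.mean(), 0.0, atol=1e-12)
        assert np.allclose(grp.std(ddof=0), 1.0, atol=1e-12)

    def test_constant_column_rejected(self, random_table):
        broken = random_table.copy()
        broken.loc[broken["indicator_name"] == "median_wage", "value"] = 3.7
        with pytest.raises(DegenerateInputError, match="median_wage"):
            lg.standardize(broken)

    def test_two_areas_standardize_to_plus_minus_one(self):
        table = make_indicator_table(np.array([[1.0] * 9, [3.0] * 9]))
        std = lg.standardize(table)
        wide = std.pivot(index="area_id", columns="indicator_name", values="value")
        np.testing.assert_allclose(np.sort(wide.to_numpy(), axis=0),
                                   np.vstack([-np.ones(9), np.ones(9)]), atol=1e-12)


class TestDimensionWeights:
    def test_identical_indicators_get_equal_thirds(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=40)
        values = np.column_stack([g, g, g] + [rng.normal(size=40) for _ in range(6)])
        weights = lg.fit_dimension_weights(make_indicator_table(values))
        for w in weights["education"]:
            assert w.weight == pytest.approx(1 / 3, abs=1e-9)

    def test_pure_noise_indicator_gets_zero_weight(self):
        """Two identical indicators plus one exactly orthogonal: the 3x3
        correlation matrix is [[1,1,0],[1,1,0],[0,0,1]], whose leading
        eigenvector (1,1,0)/sqrt(2) gives squared-loading weights
        (1/2, 1/2, 0) — computed by hand from the eigen-decomposition."""
        g = np.array([2.0, 1.0, -1.0, -2.0])
        e = np.array([1.0, -2.0, 2.0, -1.0])  # orthogonal to g, both zero-mean
        assert g @ e == 0
        rng = np.random.default_rng(1)
        values = np.column_stack([g, g, e] + [rng.normal(size=4) for _ in range(6)])
        weights = lg.fit_dimension_weights(make_indicator_table(values))
        by_name = {w.indicator: w.weight for w in weights["education"]}
        # education columns in INDICATOR_DESIGN order: dropout=g, no_voc=g, higher_ed=e
        assert by_name["school_dropout_rate"] == pytest.approx(0.5, abs=1e-9)
        assert by_name["no_vocational_training_rate"] == pytest.approx(0.5, abs=1e-9)
        assert by_name["higher_education_rate"] == pytest.approx(0.0, abs=1e-9)

    def test_negating_a_column_flips_sign_only(self, random_table):
        weights = lg.fit_dimension_weights(random_table)
        flipped_table = random_table.copy()
        mask = flipped_table["indicator_name"] == "median_wage"  # not an anchor
        flipped_table.loc[mask, "value"] *= -1
        flipped = lg.fit_dimension_weights(flipped_table)
        for dim in DIMENSIONS:
            for w0, w1 in zip(weights[dim], flipped[dim]):
                assert w0.indicator == w1.indicator
                assert w1.weight == pytest.approx(w0.weight, abs=1e-10)
                expected_sign = -w0.sign if w0.indicator == "median_wage" else w0.sign
                assert w1.sign == expected_sign

    def test_weights_nonnegative_and_sum_to_one(self, random_table):
        weights = lg.fit_dimension_weights(random_table)
        for dim in DIMENSIONS:
            ws = [w.weight for w in weights[dim]]
            assert all(w >= 0 for w in ws)
            assert sum(ws) == pytest.approx(1.0, abs=1e-12)

    def test_raw_weighting_uses_absolute_loadings(self, random_table):
        sq = lg.fit_dimension_weights(random_table, weighting="squared")
        raw = lg.fit_dimension_weights(random_table, weighting="raw")
        for dim in DIMENSIONS:
            wsq = np.array([w.weight for w in sq[dim]])
            wraw = np.array([w.weight for w in raw[dim]])
            # same ordering of importance, different functional form
            assert np.array_equal(np.argsort(wsq), np.argsort(wraw))
            np.testing.assert_allclose(wraw**2 / (wraw**2).sum(), wsq, atol=1e-10)


class TestComposeIndex:
    def test_extremes_map_to_zero_and_one(self, random_table):
        index = DeprivationIndexer().fit_transform(random_table)
        assert index["gisd"].min() == 0.0
        assert index["gisd"].max() == 1.0
        assert index.loc[index["gisd"].idxmin(), "raw_score"] == index["raw_score"].min()
        assert index.loc[index["gisd"].idxmax(), "raw_score"] == index["raw_score"].max()
        # exactly one area at each extreme when raw scores are distinct
        assert (index["gisd"] == 0.0).sum() == 1
        assert (index["gisd"] == 1.0).sum() == 1

    def test_affine_transform_of_indicators_leaves_index_unchanged(self, random_table):
        index = DeprivationIndexer().fit_transform(random_table)
        shifted = random_table.copy()
        scale = shifted["indicator_name"].map(
            {n: s for n, s in zip(shifted["indicator_name"].unique(), range(2, 12))}
        )
        shifted["value"] = shifted["value"] * scale + 100.0
        index2 = DeprivationIndexer().fit_transform(shifted)
        np.testing.assert_allclose(index["gisd"], index2["gisd"], atol=1e-10)

    def test_permuting_rows_leaves_each_area_index_unchanged(self, random_table):
        index = DeprivationIndexer().fit_transform(random_table).set_index("area_id")
        shuffled = random_table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        index2 = DeprivationIndexer().fit_transform(shuffled).set_index("area_id")
        np.testing.assert_allclose(
            index["gisd"], index2.loc[index.index, "gisd"], atol=1e-12
        )

    def test_noiseless_synthetic_index_is_monotone_in_z(self):
        cfg = lg.ScenarioConfig(n_areas=50, indicator_noise_sd=0.0, seed=4)
        areas = lg.generate_areas(cfg)
        indicators = lg.simulate_indicators(areas, cfg)
        index = DeprivationIndexer().fit_transform(indicators).set_index("area_id")
        z = areas.set_index("area_id")["z"]
        gisd = index.loc[z.index, "gisd"].to_numpy()
        # strictly increasing in z: identical rank orderings, Spearman rho = 1
        assert np.array_equal(np.argsort(gisd), np.argsort(z.to_numpy()))
        rho, _ = spearmanr(gisd, z)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_default_noise_recovery_spearman_above_0_9(self):
        cfg = lg.ScenarioConfig(n_areas=400, seed=12)
        areas = lg.generate_areas(cfg)
        indicators = lg.simulate_indicators(areas, cfg)
        index = DeprivationIndexer().fit_transform(indicators).set_index("area_id")
        z = areas.set_index("area_id")["z"]
        rho, _ = spearmanr(index.loc[z.index, "gisd"], z)
        assert rho >= 0.9

    def test_compose_with_prefit_weights_matches_estimator(self, random_table):
        indexer = DeprivationIndexer().fit(random_table)
        via_estimator = indexer.transform(random_table)
        via_function = lg.compose_index(random_table, indexer.weights_)
        np.testing.assert_allclose(via_estimator["gisd"], via_function["gisd"], atol=1e-12)

    def test_area_set_mismatch_is_consistency_error(self, random_table):
        indexer = DeprivationIndexer().fit(random_table)
        subset = random_table[random_table["area_id"] != "A001"]
        with pytest.raises(ValidationError, match="area set"):
            indexer.transform(subset)


class TestEstimatorContract:
    def test_get_params_round_trip_and_clone(self):
        est = DeprivationIndexer(weighting="raw")
        params = est.get_params()
        assert params["weighting"] == "raw"
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_unfitted_transform_raises(self, random_table):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            DeprivationIndexer().transform(random_table)
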