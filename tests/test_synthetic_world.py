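"""The synthetic study region: determinism, truth surfaces, biased sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from channelfauna.errors import ConfigurationError, DegenerateInputError
from channelfauna.grids import GridSpec, RasterLayer
from channelfauna.records import SEASON_MONTHS
from channelfauna.synthetic_world import (
    StrandingParams,
    TruthModel,
    WorldConfig,
    make_bias_field,
    make_truth_surface,
    make_world,
    sample_sightings,
    sample_strandings,
)


class TestMakeWorld:
    def test_same_seed_is_bitwise_identical(self, small_world):
        (monthly, bathy, land), cfg = small_world
        monthly2, bathy2, land2 = make_world(cfg, seed=7)
        for key in monthly:
            np.testing.assert_array_equal(
                monthly[key].values, monthly2[key].values
            )
        np.testing.assert_array_equal(bathy.values, bathy2.values)
        np.testing.assert_array_equal(land.values, land2.values)

    def test_layer_count_is_variables_times_months(self, small_world):
        (monthly, _, _), cfg = small_world
        assert len(monthly) == len(cfg.variables) * 12

    def test_bathymetry_crosses_both_isobaths(self, small_world):
        (_, bathy, _), _ = small_world
        depths = bathy.values[bathy.mask]
        assert depths.min() < 30 < depths.max()
        assert depths.min() < 200 < depths.max()

    def test_land_region_exists_and_is_contiguous(self, small_world):
        (_, _, land), _ = small_world
        from scipy.ndimage import label

        lab, n = label(land.values == 1)
        assert n == 1

    def test_planar_bathymetry_is_monotone_down_rows(self):
        cfg = WorldConfig(n_rows=14, n_cols=14, planar_bathymetry=True)
        _, bathy, land = make_world(cfg, seed=0)
        sea_cols = np.where((land.values == 0).all(axis=0))[0]
        col = sea_cols[0] if sea_cols.size else 7
        depths = bathy.values[:, col]
        depths = depths[~np.isnan(depths)]
        assert (np.diff(depths) > 0).all()

    def test_rejects_small_grid(self):
        with pytest.raises(ConfigurationError):
            WorldConfig(n_rows=5, n_cols=5)


class TestTruthSurface:
    def _flat_layers(self, spec, values_by_var):
        return {
            v: RasterLayer(spec=spec, name=v, values=vals)
            for v, vals in values_by_var.items()
        }

    def test_zero_coefficients_rejected_but_tiny_allowed(self):
        with pytest.raises(ConfigurationError):
            TruthModel(coefficients={"a": 0.0}, bias_center=(0, 0), bias_spread=1)

    def test_uniform_when_feature_constant(self, tiny_spec):
        layers = self._flat_layers(tiny_spec, {"a": np.ones(tiny_spec.shape)})
        truth = TruthModel({"a": 2.0}, (5, 5), 3.0)
        surf = make_truth_surface(truth, layers)
        n = tiny_spec.n_rows * tiny_spec.n_cols
        np.testing.assert_allclose(surf.values, 1.0 / n, atol=1e-12)

    def test_three_cell_closed_form(self):
        # 3 sea cells with feature (0, 0.5, 1), coefficient 1:
        # probabilities proportional to (1, e^0.5, e)
        spec = GridSpec(n_rows=3, n_cols=3, cell_size=1.0, origin_y=3.0)
        vals = np.full((3, 3), np.nan)
        vals[0, 0], vals[1, 1], vals[2, 2] = 0.0, 0.5, 1.0
        truth = TruthModel({"a": 1.0}, (1, 1), 1.0)
        surf = make_truth_surface(
            truth, {"a": RasterLayer(spec=spec, name="a", values=vals)}
        )
        raw = np.array([1.0, np.exp(0.5), np.exp(1.0)])
        expected = raw / raw.sum()
        got = np.array([surf.values[0, 0], surf.values[1, 1], surf.values[2, 2]])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_probability_sums_to_one_and_land_is_nodata(self, small_world):
        (monthly, bathy, _), _ = small_world
        truth = TruthModel({"sst": 0.3}, (10, 10), 5.0)
        surf = make_truth_surface(truth, {"sst": monthly[("sst", 6)]})
        assert abs(np.nansum(surf.values) - 1.0) < 1e-9
        assert np.isnan(surf.values[~monthly[("sst", 6)].mask]).all()

    def test_monotone_in_positive_coefficient_variable(self, tiny_spec):
        rng = np.random.default_rng(3)
        vals = rng.random(tiny_spec.shape)
        truth = TruthModel({"a": 1.5}, (1, 1), 1.0)
        surf = make_truth_surface(
            truth, {"a": RasterLayer(spec=tiny_spec, name="a", values=vals)}
        )
        order = np.argsort(vals.ravel())
        assert (np.diff(surf.values.ravel()[order]) > 0).all()

    def test_unknown_variable_is_configuration_error(self, flat_sea):
        truth = TruthModel({"missing": 1.0}, (1, 1), 1.0)
        with pytest.raises(ConfigurationError):
            make_truth_surface(truth, {"a": flat_sea})


class TestSampleSightings:
    def _setup(self, tiny_spec, coef=1.0, seed=3):
        rng = np.random.default_rng(seed)
        vals = rng.random(tiny_spec.shape)
        truth = TruthModel({"a": coef}, (5.0, 5.0), 4.0)
        surf = make_truth_surface(
            truth, {"a": RasterLayer(spec=tiny_spec, name="a", values=vals)}
        )
        flat_bias = RasterLayer(
            spec=tiny_spec, name="bias", values=np.ones(tiny_spec.shape)
        )
        return truth, surf, flat_bias

    def test_exact_count_on_sea_cells_in_season(self, tiny_spec):
        _, surf, bias = self._setup(tiny_spec)
        df = sample_sightings(surf, bias, 50, "cetaceans", "spring", seed=1)
        assert len(df) == 50
        months = pd.to_datetime(df["date"]).dt.month
        assert set(months).issubset(set(SEASON_MONTHS["spring"]))
        for x, y in zip(df["x"], df["y"]):
            assert tiny_spec.contains(x, y)

    def test_frequencies_match_truth_chi_square(self, tiny_spec):
        # 20,000 unbiased draws should be consistent with the truth surface
        _, surf, bias = self._setup(tiny_spec)
        n = 20_000
        df = sample_sightings(surf, bias, n, "cetaceans", "summer", seed=2)
        counts = np.zeros(tiny_spec.shape)
        for x, y in zip(df["x"], df["y"]):
            r, c = tiny_spec.cell_of(x, y)
            counts[r, c] += 1
        expected = surf.values * n
        obs, exp = counts.ravel(), expected.ravel()
        # pool low-expectation cells so the chi-square approximation holds
        big = exp >= 5
        obs_b, exp_b = obs[big], exp[big]
        if (~big).any():
            obs_b = np.append(obs_b, obs[~big].sum())
            exp_b = np.append(exp_b, exp[~big].sum())
        stat, p = chisquare(obs_b, exp_b * obs_b.sum() / exp_b.sum())
        assert p > 0.01

    def test_bias_pulls_samples_into_one_half(self, tiny_spec):
        flat = RasterLayer(
            spec=tiny_spec, name="flat",
            values=np.full(tiny_spec.shape, 1.0 / tiny_spec.n_rows / tiny_spec.n_cols),
        )
        truth = TruthModel({"a": 1.0}, (2.5, 5.0), 2.0)
        bias = make_bias_field(truth, tiny_spec)
        df = sample_sightings(flat, bias, 500, "cetaceans", "autumn", seed=4)
        left = (df["x"] < 5.0).mean()
        assert left > 0.5

    def test_all_zero_probability_is_degenerate(self, tiny_spec):
        zero = RasterLayer(
            spec=tiny_spec, name="z", values=np.zeros(tiny_spec.shape)
        )
        bias = RasterLayer(
            spec=tiny_spec, name="b", values=np.ones(tiny_spec.shape)
        )
        with pytest.raises(DegenerateInputError):
            sample_sightings(zero, bias, 10, "cetaceans", "spring", seed=0)

    def test_same_seed_reproduces_records(self, tiny_spec):
        _, surf, bias = self._setup(tiny_spec)
        a = sample_sightings(surf, bias, 30, "pinnipeds", "winter", seed=9)
        b = sample_sightings(surf, bias, 30, "pinnipeds", "winter", seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSampleStrandings:
    def test_degenerate_cause_distribution(self, small_world):
        (_, _, land), _ = small_world
        params = StrandingParams(n=25, cause_probs={"bycatch": 1.0})
        df = sample_strandings(params, land, seed=1)
        assert (df["cause"] == "bycatch").all()
        assert (df["record_type"] == "stranding").all()

    def test_years_within_range_and_conditions_valid(self, small_world):
        (_, _, land), _ = small_world
        params = StrandingParams(n=200, year_range=(1990, 2010))
        df = sample_strandings(params, land, seed=2)
        years = pd.to_datetime(df["date"]).dt.year
        assert years.between(1990, 2010).all()
        assert set(df["condition"]).issubset({"alive", "dead"})

    def test_anthropogenic_fraction_within_binomial_interval(self, small_world):
        from channelfauna.summaries import classify_cause

        (_, _, land), _ = small_world
        probs = {"bycatch": 0.33, "disease": 0.27, "undetermined": 0.40}
        params = StrandingParams(n=200, cause_probs=probs)
        df = sample_strandings(params, land, seed=3)
        frac = (df["cause"].map(classify_cause) == "anthropogenic").mean()
        # binomial 99% interval around 0.33 at n=200
        half = 2.576 * np.sqrt(0.33 * 0.67 / 200)
        assert 0.33 - half <= frac <= 0.33 + half

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            StrandingParams(cause_probs={"bycatch": 0.5, "disease": 0.4})
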