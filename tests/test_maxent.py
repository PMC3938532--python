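"""The maxent fitter: features, moment matching, oracle equivalence, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from channelfauna import maxent
from channelfauna.maxent import (
    FeatureBuilder,
    build_features,
    cross_validate,
    default_feature_classes,
    fit,
    predict_logistic,
    predict_raw,
    training_gain,
)


def _instance(seed, n_bg=20, n_feat=3, n_pres=8):
    """A random small instance in feature space (features already in [0,1])."""
    rng = np.random.default_rng(seed)
    f_bg = rng.random((n_bg, n_feat))
    f_pres = f_bg[rng.integers(0, n_bg, size=n_pres)]
    return f_pres, f_bg


def _smooth_objective(f_pres, f_bg):
    pmean = f_pres.mean(axis=0)

    def obj(lam):
        s = f_bg @ lam
        mx = s.max()
        return pmean @ lam - (mx + np.log(np.exp(s - mx).sum()))

    return obj


class TestFeatures:
    def test_linear_scaling_endpoints(self):
        bg = pd.DataFrame({"v": [2.0, 4.0, 6.0]})
        mat, builder = build_features(bg, ("linear",))
        np.testing.assert_allclose(mat[:, 0], [0.0, 0.5, 1.0])

    def test_quadratic_is_square_of_scaled(self):
        bg = pd.DataFrame({"v": [0.0, 1.0, 2.0]})
        mat, _ = build_features(bg, ("linear", "quadratic"))
        assert mat[1, 1] == pytest.approx(0.25)

    def test_hinge_endpoints(self):
        bg = pd.DataFrame({"v": np.linspace(0, 1, 101)})
        _, builder = build_features(bg, ("linear", "hinge"), n_knots=3)
        hinges = [s for s in builder.specs if s.feature_class == "hinge"]
        fwd = next(s for s in hinges if s.direction == "forward")
        vals = builder.transform(pd.DataFrame({"v": [fwd.knot, 1.0]}))
        j = builder.specs.index(fwd)
        assert vals[0, j] == pytest.approx(0.0, abs=1e-12)
        assert vals[1, j] == pytest.approx(1.0)

    def test_product_of_scaled_pairs(self):
        bg = pd.DataFrame({"a": [0.0, 2.0], "b": [0.0, 4.0]})
        _, builder = build_features(bg, ("linear", "product"))
        prod = next(s for s in builder.specs if s.feature_class == "product")
        j = builder.specs.index(prod)
        vals = builder.transform(pd.DataFrame({"a": [1.0], "b": [2.0]}))
        assert vals[0, j] == pytest.approx(0.25)

    def test_constant_variable_excluded_with_warning(self):
        bg = pd.DataFrame({"v": np.arange(5.0), "const": np.ones(5)})
        with pytest.warns(UserWarning, match="constant"):
            _, builder = build_features(bg, ("linear",))
        assert all("const" not in s.variables for s in builder.specs)

    def test_class_ladder_by_sample_size(self):
        assert default_feature_classes(5) == ("linear",)
        assert "quadratic" in default_feature_classes(10)
        assert "hinge" in default_feature_classes(15)
        assert "product" in default_feature_classes(80)
        assert "product" not in default_feature_classes(79)


class TestFit:
    @pytest.mark.parametrize("seed", range(10))
    def test_moment_matching_at_beta_zero(self, seed):
        """The defining constraint: model feature expectations equal the
        presence-sample means when unregularized."""
        f_pres, f_bg = _instance(seed)
        model = fit(f_pres, f_bg, beta=0.0)
        w = np.exp(f_bg @ model.lam - model.log_z)
        np.testing.assert_allclose(
            w @ f_bg, f_pres.mean(axis=0), atol=1e-5
        )

    def test_no_signal_gives_near_uniform_model(self):
        rng = np.random.default_rng(11)
        f_bg = rng.random((200, 3))
        f_pres = f_bg[rng.integers(0, 200, size=100)]  # presence == background
        model = fit(f_pres, f_bg)
        gain = training_gain(model, f_pres)
        assert gain < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_generic_optimizer(self, seed):
        """Coordinate descent reaches the same optimum as an independent
        generic maximizer of the identical smooth objective."""
        f_pres, f_bg = _instance(seed, n_bg=30, n_feat=2, n_pres=10)
        model = fit(f_pres, f_bg, beta=0.0)
        obj = _smooth_objective(f_pres, f_bg)
        cd_val = obj(model.lam)
        # dense grid seeds a Nelder-Mead polish of the same objective
        grid = np.linspace(-5, 5, 41)
        best = max(
            (np.array([a, b]) for a in grid for b in grid),
            key=lambda lam: obj(lam),
        )
        res = minimize(lambda l: -obj(l), best, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        assert cd_val == pytest.approx(-res.fun, abs=1e-4)

    def test_fit_trace_gains_are_positive_and_sum_to_objective_rise(self):
        f_pres, f_bg = _instance(3)
        builder = FeatureBuilder(
            [maxent.FeatureSpec("linear", (f"v{j}",), ((0.0, 1.0),))
             for j in range(3)]
        )
        model = fit(f_pres, f_bg, builder=builder, beta=0.0)
        gains = [g for _, g in model.trace]
        assert all(g > 0 for g in gains)
        obj = _smooth_objective(f_pres, f_bg)
        n = f_bg.shape[0]
        assert sum(gains) == pytest.approx(obj(model.lam) - obj(np.zeros(3)),
                                           abs=1e-8)

    def test_input_validation(self):
        f_pres, f_bg = _instance(0)
        with pytest.raises(ValueError):
            fit(f_pres[:1], f_bg)
        with pytest.raises(ValueError):
            fit(f_pres, f_bg[:5])
        bad = f_bg.copy()
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            fit(f_pres, bad)


class TestPredict:
    def test_raw_sums_to_one_over_background(self):
        f_pres, f_bg = _instance(1)
        model = fit(f_pres, f_bg)
        assert predict_raw(model, f_bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_model_closed_form(self):
        """All-zero coefficients: raw = 1/N, H = log N, logistic = 0.5."""
        _, f_bg = _instance(2, n_bg=25)
        n = f_bg.shape[0]
        model = fit(f_bg[:5] * 0 + 0.5, f_bg * 0 + 0.5, beta=0.0)
        # constant features force the uniform optimum
        raw = predict_raw(model, f_bg * 0 + 0.5)
        np.testing.assert_allclose(raw, 1.0 / n, atol=1e-9)
        assert model.entropy == pytest.approx(np.log(n), abs=1e-9)
        logistic = predict_logistic(model, f_bg * 0 + 0.5)
        np.testing.assert_allclose(logistic, 0.5, atol=1e-9)

    def test_logistic_strictly_increasing_in_raw(self):
        f_pres, f_bg = _instance(4)
        model = fit(f_pres, f_bg)
        raw = predict_raw(model, f_bg)
        logi = predict_logistic(model, f_bg)
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= -1e-15).all()

    def test_logistic_invariant_to_background_reordering(self):
        f_pres, f_bg = _instance(5, n_bg=40)
        rng = np.random.default_rng(0)
        perm = rng.permutation(40)
        m1 = fit(f_pres, f_bg, beta=0.0)
        m2 = fit(f_pres, f_bg[perm], beta=0.0)
        np.testing.assert_allclose(
            predict_logistic(m1, f_pres), predict_logistic(m2, f_pres),
            atol=1e-6,
        )

    def test_dimension_mismatch_rejected(self):
        f_pres, f_bg = _instance(6)
        model = fit(f_pres, f_bg)
        with pytest.raises(ValueError):
            predict_raw(model, f_bg[:, :2])


class TestTrainingGain:
    def test_uniform_model_has_zero_gain(self):
        _, f_bg = _instance(7, n_bg=30)
        const = np.full((12, 3), 0.5)
        model = fit(const, f_bg * 0 + 0.5, beta=0.0)
        assert training_gain(model, const) == pytest.approx(0.0, abs=1e-9)

    def test_fitted_gain_nonnegative_at_beta_zero(self):
        for seed in range(5):
            f_pres, f_bg = _instance(seed)
            model = fit(f_pres, f_bg, beta=0.0)
            assert training_gain(model, f_pres) >= -1e-10

    def test_two_cell_worked_example(self):
        """Presences in a cell with raw 0.8 over a 2-cell background:
        gain = ln(0.8) + ln 2 = ln 1.6."""
        # engineer λ so that raw = (0.8, 0.2) on features (1, 0)
        f_bg = np.array([[1.0], [0.0]])
        lam = np.array([np.log(4.0)])  # exp(λ)/(exp(λ)+1) = 0.8
        model = maxent.MaxentModel(
            builder=FeatureBuilder([]), lam=lam,
            log_z=float(np.log(np.exp(lam[0]) + 1.0)),
            entropy=0.0, beta=np.zeros(1), n_background=2,
        )
        raw = predict_raw(model, f_bg)
        np.testing.assert_allclose(raw, [0.8, 0.2], atol=1e-12)
        f_pres = np.array([[1.0], [1.0], [1.0]])
        assert training_gain(model, f_pres) == pytest.approx(np.log(1.6),
                                                             abs=1e-12)


class TestCrossValidate:
    def _tables(self, seed, m=25, n_bg=200):
        rng = np.random.default_rng(seed)
        bg = pd.DataFrame({"a": rng.random(n_bg), "b": rng.random(n_bg)})
        pres = bg.iloc[rng.integers(0, n_bg, size=m)].reset_index(drop=True)
        return pres, bg

    def test_25_presences_25_folds_are_singletons(self):
        pres, bg = self._tables(0, m=25)
        cv = cross_validate(pres, bg, None, k=25, seed=1)
        assert len(cv.folds) == 25
        assert all(len(f.test_idx) == 1 for f in cv.folds)

    def test_fold_sizes_balanced(self):
        pres, bg = self._tables(1, m=10)
        cv = cross_validate(pres, bg, None, k=3, seed=2)
        sizes = sorted(len(f.test_idx) for f in cv.folds)
        assert sizes == [3, 3, 4]

    def test_folds_partition_presences(self):
        pres, bg = self._tables(2, m=17)
        cv = cross_validate(pres, bg, None, k=4, seed=3)
        all_test = np.concatenate([f.test_idx for f in cv.folds])
        assert sorted(all_test.tolist()) == list(range(17))

    def test_k_larger_than_presences_is_lowered(self):
        pres, bg = self._tables(3, m=6)
        with pytest.warns(UserWarning, match="lowered"):
            cv = cross_validate(pres, bg, None, k=25, seed=4)
        assert len(cv.folds) == 6

    def test_k_below_two_rejected(self):
        pres, bg = self._tables(4)
        with pytest.raises(ValueError):
            cross_validate(pres, bg, None, k=1, seed=5)
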