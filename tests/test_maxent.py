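"""Maxent features, optimizer, prediction, validation, and importances."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import nichekit as nk
from conftest import sample_groups, small_stack


def _env(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows)


class TestFeatures:
    def test_linear_scaling_maps_extremes_to_unit_interval(self):
        fm = nk.build_features(_env({"x": [2.0, 10.0]}), _env({"x": [4.0, 6.0]}),
                               {"x": "continuous"}, classes=("linear",))
        assert fm.presence[0, 0] == 0.0 and fm.presence[1, 0] == 1.0
        assert fm.background[0, 0] == pytest.approx(0.25)

    def test_quadratic_is_square_of_scaled_value(self):
        fm = nk.build_features(_env({"x": [0.0, 0.5, 1.0]}), _env({"x": [0.0, 1.0]}),
                               {"x": "continuous"}, classes=("linear", "quadratic"))
        assert fm.presence[1, 1] == pytest.approx(0.25)

    def test_categorical_one_hot(self):
        fm = nk.build_features(_env({"lc": [0.0, 1.0, 2.0]}),
                               _env({"lc": [0.0, 1.0, 2.0]}),
                               {"lc": "categorical"})
        assert fm.presence.shape[1] == 3
        assert np.allclose(fm.presence.sum(axis=1), 1.0)

    def test_single_class_categorical_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="single class"):
            fm = nk.build_features(_env({"lc": [1.0, 1.0]}), _env({"lc": [1.0]}),
                                   {"lc": "categorical"})
        assert fm.presence.shape[1] == 0

    def test_hinge_features_span_presence_quantiles(self):
        rng = np.random.default_rng(0)
        fm = nk.build_features(_env({"x": rng.uniform(0, 1, 100)}),
                               _env({"x": rng.uniform(0, 1, 100)}),
                               {"x": "continuous"},
                               classes=("linear", "hinge"), n_hinge_knots=3)
        hinge = [f for f in fm.features if f.kind == "hinge"]
        assert len(hinge) == 6  # forward + reverse per knot
        assert fm.presence.min() >= 0 and fm.presence.max() <= 1


def _oracle_gain(Xp, Xb, beta_j):
    """Independent optimum of the penalized gain via a generic convex solver
    (L-BFGS-B on the positive/negative split of the L1 problem)."""
    J = Xp.shape[1]
    b = Xp.mean(axis=0)

    def neg(theta):
        lam = theta[:J] - theta[J:]
        return -(lam @ b - logsumexp(Xb @ lam) - beta_j @ (theta[:J] + theta[J:]))

    res = minimize(neg, np.zeros(2 * J), method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * J,
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    return -res.fun


class TestFit:
    def test_single_binary_feature_closed_form(self):
        env_p = _env({"x": np.r_[np.ones(80), np.zeros(20)]})
        env_b = _env({"x": np.r_[np.ones(50), np.zeros(50)]})
        res = nk.Maxent(env_p, env_b, {"x": "continuous"},
                        feature_classes=("linear",)).fit(beta=0.0, tol=1e-14,
                                                         max_iter=2000)
        assert res.params.iloc[0] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_heavy_regularization_zeroes_model(self):
        rng = np.random.default_rng(1)
        env_p = _env({"x": rng.uniform(0, 1, 30), "y": rng.uniform(0, 1, 30)})
        env_b = _env({"x": rng.uniform(0, 1, 100), "y": rng.uniform(0, 1, 100)})
        res = nk.Maxent(env_p, env_b, {"x": "continuous", "y": "continuous"}
                        ).fit(beta=500.0)
        assert np.allclose(res.params.to_numpy(), 0.0)
        raw = res.predict_raw(env_b)
        assert np.allclose(raw, 1.0 / len(env_b))

    @pytest.mark.parametrize("beta", [0.0, 1.0])
    def test_objective_matches_convex_solver_oracle(self, beta):
        rng = np.random.default_rng(42 + int(beta))
        for _ in range(6):
            m, n = int(rng.integers(10, 40)), int(rng.integers(10, 50))
            env_p = _env({"x": rng.uniform(0, 1, m), "y": rng.uniform(0, 1, m)})
            env_b = _env({"x": rng.uniform(0, 1, n), "y": rng.uniform(0, 1, n)})
            model = nk.Maxent(env_p, env_b,
                              {"x": "continuous", "y": "continuous"},
                              feature_classes=("linear",))
            res = model.fit(beta=beta, tol=1e-12, max_iter=5000)
            oracle = _oracle_gain(model.features.presence,
                                  model.features.background,
                                  res.beta_j.to_numpy())
            assert res.objective == pytest.approx(oracle, abs=1e-6)

    def test_gain_trace_is_nondecreasing(self):
        rng = np.random.default_rng(5)
        env_p = _env({"x": rng.beta(5, 2, 60), "y": rng.uniform(0, 1, 60)})
        env_b = _env({"x": rng.uniform(0, 1, 200), "y": rng.uniform(0, 1, 200)})
        res = nk.Maxent(env_p, env_b, {"x": "continuous", "y": "continuous"}
                        ).fit(beta=1.0)
        assert all(delta >= 0 for _, delta in res.trace)
        assert res.converged

    def test_negative_beta_rejected(self):
        env = _env({"x": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError, match="beta"):
            nk.Maxent(env, env, {"x": "continuous"}).fit(beta=-1.0)


class TestPredict:
    def test_raw_sums_to_one_over_background(self, divergent_data, stack40):
        occ_a, _, background = divergent_data
        model = nk.Maxent.from_stack(stack40, occ_a, background)
        res = model.fit()
        raw = res.predict_raw(model.features.env_background)
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cloglog_preserves_raw_ranking(self, divergent_data, stack40):
        occ_a, _, background = divergent_data
        res = nk.Maxent.from_stack(stack40, occ_a, background).fit()
        raw = res.predict_grid(stack40, output="raw").values.ravel()
        clog = res.predict_grid(stack40, output="cloglog").values.ravel()
        assert np.array_equal(np.argsort(raw, kind="stable"),
                              np.argsort(clog, kind="stable"))

    def test_missing_layer_named(self, divergent_data, stack40):
        occ_a, _, background = divergent_data
        res = nk.Maxent.from_stack(stack40, occ_a, background).fit()
        partial = nk.RasterStack(stack40.grid, stack40.layers[:1],
                                 stack40.nodata_mask)
        with pytest.raises(ValueError, match="env2"):
            res.predict_grid(partial)


class TestAuc:
    def test_hand_enumerated_cases(self):
        assert nk.evaluate_auc([0.9, 0.8], [0.2, 0.1]) == 1.0
        assert nk.evaluate_auc([0.5, 0.5], [0.5, 0.5]) == 0.5
        assert nk.evaluate_auc([0.8, 0.3], [0.5, 0.1]) == pytest.approx(0.75)

    def test_tie_handling_is_mid_rank(self):
        # pairs: (0.5>0.2)=1, (0.5=0.5)=0.5 -> AUC = 1.5/2
        assert nk.evaluate_auc([0.5], [0.2, 0.5]) == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self, rng):
        sp, sb = rng.uniform(0, 1, 50), rng.uniform(0, 1, 80)
        before = nk.evaluate_auc(sp, sb)
        after = nk.evaluate_auc(np.exp(3 * sp), np.exp(3 * sb))
        assert before == pytest.approx(after, abs=1e-12)


class TestCrossvalidate:
    def test_informative_niche_beats_reliability_bar(self, divergent_data, stack40):
        occ_a, _, background = divergent_data
        env_p = nk.extract_env(stack40, occ_a).values
        env_b = nk.extract_env(stack40, background).values
        cv = nk.crossvalidate(env_p, env_b, stack40.kinds, n_replicates=10,
                              test_fraction=0.2, seed=0)
        assert len(cv.aucs) == 10
        assert cv.mean > 0.9

    def test_uninformative_presence_is_random(self, stack40):
        flat_p = sample_groups(stack40, 0.0, seed=77, n_points=150)[2]
        flat_b = sample_groups(stack40, 0.0, seed=78, n_points=150,
                               n_background=300)[2]
        env_p = nk.extract_env(stack40, flat_p).values
        env_b = nk.extract_env(stack40, flat_b).values
        cv = nk.crossvalidate(env_p, env_b, stack40.kinds, seed=1)
        assert abs(cv.mean - 0.5) < 0.1

    def test_deterministic_under_seed(self, divergent_data, stack40):
        occ_a, _, background = divergent_data
        env_p = nk.extract_env(stack40, occ_a).values
        env_b = nk.extract_env(stack40, background).values
        a = nk.crossvalidate(env_p, env_b, stack40.kinds, n_replicates=3, seed=4)
        b = nk.crossvalidate(env_p, env_b, stack40.kinds, n_replicates=3, seed=4)
        assert a.aucs == b.aucs


def _informative_fit(seed, n=150):
    """Model where only env1 generates the niche; env2 is noise."""
    stack = small_stack(40, seed=seed)
    scenario = nk.NicheScenario(
        groups=["A"], optima={"A": {"env1": 0.0, "env2": 0.0}},
        breadths={"A": {"env1": 0.5, "env2": 1e6}})
    suit = nk.gaussian_niche_suitability(scenario, "A", stack)
    occ = nk.sample_occurrences(suit, n, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    bg = pd.DataFrame({"id": [f"b{i}" for i in range(300)],
                       "longitude": rng.uniform(0, 40, 300),
                       "latitude": rng.uniform(0, 40, 300)})
    env_p = nk.extract_env(stack, occ).values
    env_b = nk.extract_env(stack, bg).values
    return nk.Maxent(env_p, env_b, stack.kinds).fit()


class TestImportance:
    def test_single_variable_model_gets_full_contribution(self):
        rng = np.random.default_rng(3)
        env_p = _env({"x": rng.beta(6, 2, 80)})
        env_b = _env({"x": rng.uniform(0, 1, 200)})
        res = nk.Maxent(env_p, env_b, {"x": "continuous"}).fit()
        contrib = res.percent_contribution()
        assert contrib["x"] == pytest.approx(100.0, abs=0.01)

    def test_contributions_sum_to_100(self):
        res = _informative_fit(60)
        assert res.percent_contribution().sum() == pytest.approx(100.0, abs=0.01)
        assert res.permutation_importance(seed=0).sum() == pytest.approx(100.0, abs=0.01)

    def test_generative_variable_dominates_contribution(self):
        wins = sum(
            _informative_fit(100 + 7 * k).percent_contribution().idxmax() == "env1"
            for k in range(20))
        assert wins >= 18

    def test_absent_variable_has_zero_permutation_importance(self):
        rng = np.random.default_rng(9)
        # y is pure noise and heavily penalized out of the model
        env_p = _env({"x": rng.beta(6, 2, 80), "y": rng.uniform(0, 1, 80)})
        env_b = _env({"x": rng.uniform(0, 1, 200), "y": rng.uniform(0, 1, 200)})
        res = nk.Maxent(env_p, env_b, {"x": "continuous", "y": "continuous"}).fit()
        y_feats = [i for i, f in enumerate(res.features.features) if "y" in f.sources]
        if all(res.params.iloc[i] == 0 for i in y_feats):
            imp = res.permutation_importance(seed=1)
            assert imp["y"] == 0.0

    def test_all_zero_model_warns_and_reports_zero(self):
        rng = np.random.default_rng(2)
        env = _env({"x": rng.uniform(0, 1, 50)})
        res = nk.Maxent(env, env, {"x": "continuous"}).fit(beta=100.0)
        with pytest.warns(UserWarning, match="empty training trace"):
            contrib = res.percent_contribution()
        assert (contrib == 0).all()


class TestResponseCurve:
    def test_positive_linear_model_gives_increasing_curve(self):
        rng = np.random.default_rng(4)
        env_p = _env({"x": rng.beta(8, 2, 100)})
        env_b = _env({"x": rng.uniform(0, 1, 300)})
        res = nk.Maxent(env_p, env_b, {"x": "continuous"},
                        feature_classes=("linear",)).fit()
        assert res.params.iloc[0] > 0
        curve = nk.response_curve(res, "x", n_grid=100)
        assert len(curve.grid) == 100
        assert np.all(np.diff(curve.mean) > 0)

    def test_replicate_band_and_categorical_classes(self, stack40):
        rng = np.random.default_rng(6)
        from nichekit.grids import Layer
        lc = Layer("lc", "categorical", np.round(rng.uniform(0, 2, (40, 40))))
        stack = nk.RasterStack(stack40.grid, stack40.layers + [lc],
                               stack40.nodata_mask)
        # occurrences ignore lc; the layer still enters the model as one-hot
        occ_a, _, background = sample_groups(stack40, 4.0, seed=8, n_points=120)
        env_p = nk.extract_env(stack, occ_a).values
        env_b = nk.extract_env(stack, background).values
        reps = []
        for s in range(3):
            sub = env_p.sample(frac=0.8, random_state=s)
            reps.append(nk.Maxent(sub, env_b, stack.kinds).fit())
        curve = nk.response_curve(reps, "env1", n_grid=50)
        assert np.all(curve.lower <= curve.mean) and np.all(curve.mean <= curve.upper)
        cat = nk.response_curve(reps, "lc")
        assert cat.categorical
        assert set(cat.grid) == {0.0, 1.0, 2.0}

    def test_unknown_variable_rejected(self):
        rng = np.random.default_rng(4)
        env = _env({"x": rng.uniform(0, 1, 30)})
        res = nk.Maxent(env, env, {"x": "continuous"}).fit()
        with pytest.raises(ValueError, match="nope"):
            nk.response_curve(res, "nope")
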