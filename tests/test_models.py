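import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from rapespec.labeling import DEFAULT_THRESHOLDS
from rapespec.models import (PLSRModel, classify_plsr, fit_logit, fit_plsr,
                             fit_rf, fit_svc, l1_selection_path, lasso_select)


def affine_fixture(rng, n=60, p=6):
    x = rng.uniform(0, 10, (n, p))
    coef = rng.normal(0, 3, (3, p))
    intercept = np.array([190.0, 140.0, 60.0])
    y = x @ coef.T + intercept
    return x, y, coef, intercept


class TestPLSR:
    def test_full_component_fit_recovers_affine_map(self, rng):
        x, y, coef, intercept = affine_fixture(rng)
        model = fit_plsr(x, y)
        np.testing.assert_allclose(model.coef, coef, atol=1e-8)
        np.testing.assert_allclose(model.intercept, intercept, atol=1e-7)

    def test_full_component_fit_equals_least_squares_oracle(self, rng):
        x = rng.uniform(0, 5, (40, 6))
        y = x @ rng.normal(size=6) + rng.normal(size=40)  # noisy single target
        model = fit_plsr(x, y)
        ones = np.column_stack([x, np.ones(40)])
        beta, *_ = np.linalg.lstsq(ones, y, rcond=None)
        pred_ols = ones @ beta
        np.testing.assert_allclose(model.predict(x).ravel(), pred_ols, atol=1e-8)

    def test_single_component_suffices_for_rank_one_signal(self, rng):
        t = rng.normal(size=50)
        v = rng.uniform(0.5, 2.0, 6)
        x = np.outer(t, v) + 3.0
        y = 100 + 12.0 * t
        model = fit_plsr(x, y, n_components=1)
        np.testing.assert_allclose(model.predict(x).ravel(), y, atol=1e-8)

    def test_components_beyond_rank_rejected(self, rng):
        t = rng.normal(size=50)
        x = np.outer(t, rng.uniform(0.5, 2.0, 6))
        with pytest.raises(ValueError, match="rank"):
            fit_plsr(x, x @ np.ones(6))

    def test_constant_target_gives_zero_coefficients(self, rng):
        x = rng.uniform(0, 5, (30, 6))
        model = fit_plsr(x, np.full(30, 63.0))
        np.testing.assert_array_equal(model.coef, np.zeros((1, 6)))
        assert model.intercept[0] == 63.0

    def test_classify_inside_box_labels_yellow(self):
        model = PLSRModel(["f0"], ["R", "G", "B"], 1,
                          coef=np.zeros((3, 1)),
                          intercept=np.array([200.0, 130.0, 60.0]))
        assert classify_plsr(model, np.zeros((4, 1))).tolist() == [1, 1, 1, 1]

    def test_reference_inversion_coefficients_run_end_to_end(self, rng):
        # The published six-feature inversion for the red channel, used here
        # only as a smoke fixture: any feature matrix must classify cleanly.
        names = ["SDb", "Srb", "NBDb", "RSI_705_910", "DSI_418_610", "NDSI_646_995"]
        coef = np.array([[6.64, -29.05, 10.63, 75.79, 126.53, -130.96],
                         [33.79, 13.69, 23.13, -90.19, 104.84, 148.18],
                         [-1.69, 0.41, 0.09, 4.65, -11.79, 7.04]])
        intercept = np.array([192.76, 171.39, 45.53])
        model = PLSRModel(names, ["R", "G", "B"], 6, coef, intercept)
        feats = pd.DataFrame(rng.uniform(0, 0.5, (10, 6)), columns=names)
        labels = classify_plsr(model, feats)
        assert set(labels) <= {0, 1}

    def test_feature_mismatch_rejected(self):
        model = PLSRModel(["a", "b"], ["R"], 1, np.ones((1, 2)), np.zeros(1))
        with pytest.raises(ValueError, match="feature mismatch"):
            model.predict(pd.DataFrame({"a": [1.0], "c": [2.0]}))

    def test_json_round_trip(self, tmp_path, rng):
        x, y, *_ = affine_fixture(rng)
        model = fit_plsr(x, y, target_names=["R", "G", "B"])
        back = PLSRModel.from_json(model.to_json(tmp_path / "m.json"))
        np.testing.assert_allclose(back.coef, model.coef)


def separable_toy(rng, n=60):
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(0, 0.5, (n, 2)) + np.where(y[:, None] == 1, 2.0, -2.0)
    return x, y.astype(float)


class TestLogit:
    def test_zero_weights_give_half_probability(self):
        from rapespec.models import LogitModel
        model = LogitModel(np.zeros(3), 0.0, ["a", "b", "c"],
                           np.zeros(3), np.ones(3))
        np.testing.assert_array_equal(model.predict_prob(np.random.rand(5, 3)), 0.5)

    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        x, y = separable_toy(rng)
        model = fit_logit(x, y)  # stated defaults: l2 0.2, lr 0.01, 300 iters
        assert (model.classify(x) == y).all()

    def test_label_flip_negates_weights(self, rng):
        x, y = separable_toy(rng)
        a = fit_logit(x, y)
        b = fit_logit(x, 1 - y)
        np.testing.assert_allclose(a.weights, -b.weights, atol=1e-12)
        assert a.intercept == pytest.approx(-b.intercept, abs=1e-12)

    def test_penalized_loss_decreases_monotonically(self, rng):
        x, y = separable_toy(rng)
        model = fit_logit(x, y)
        first50 = model.loss_path[:50]
        assert np.all(np.diff(first50) <= 1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_logit(rng.normal(size=(10, 2)), np.zeros(10))

    def test_agrees_with_reference_solver_on_easy_data(self, rng):
        # Independent cross-check: on well-separated data the gradient-descent
        # fit and sklearn's penalized solver make identical decisions.
        x, y = separable_toy(rng, n=100)
        ours = fit_logit(x, y)
        xs = (x - x.mean(0)) / x.std(0)
        ref = LogisticRegression(C=1 / (0.2 * len(y))).fit(xs, y)
        np.testing.assert_array_equal(ours.classify(x), ref.predict(xs))

    def test_no_intercept_mode(self, rng):
        x, y = separable_toy(rng)
        model = fit_logit(x, y, fit_intercept=False)
        assert model.intercept == 0.0

    def test_json_serialization(self, tmp_path, rng):
        x, y = separable_toy(rng)
        model = fit_logit(x, y)
        out = model.to_json(tmp_path / "logit.json")
        import json
        d = json.loads(out.read_text())
        assert d["hyperparameters"]["l2_coefficient"] == 0.2
        assert d["hyperparameters"]["max_iterations"] == 300


def planted_pool(rng, n=200, p=80, signal_cols=("sig_a", "sig_b", "sig_c")):
    y = rng.permutation(np.repeat([0.0, 1.0], n // 2))
    data = {}
    for k, name in enumerate(signal_cols):
        data[name] = 2.0 * y + rng.normal(0, 0.4, n) + k
    for k in range(p - len(signal_cols)):
        data[f"noise_{k:03d}"] = rng.normal(size=n)
    return pd.DataFrame(data), y


class TestLassoSelection:
    def test_planted_signals_recovered(self, rng):
        pool, y = planted_pool(rng)
        sel = lasso_select(pool, y, seed=0)
        assert {"sig_a", "sig_b", "sig_c"} <= set(sel.selected_names)
        assert sel.lam > 0

    def test_huge_penalty_selects_nothing(self, rng):
        pool, y = planted_pool(rng)
        sets = l1_selection_path(pool, y, Cs=[1e-4])
        assert sets[0] == []

    def test_path_is_nested_on_planted_fixture(self, rng):
        pool, y = planted_pool(rng)
        sets = l1_selection_path(pool, y, Cs=[1e-3, 1e-2, 1e-1, 1.0])
        for small, big in zip(sets, sets[1:]):
            assert set(small) <= set(big)

    def test_single_class_rejected(self, rng):
        pool, _ = planted_pool(rng)
        with pytest.raises(ValueError, match="both classes"):
            lasso_select(pool, np.ones(len(pool)))

    def test_minority_class_smaller_than_folds_rejected(self, rng):
        pool, y = planted_pool(rng, n=200)
        y = np.zeros(200)
        y[:5] = 1.0
        with pytest.raises(ValueError, match="stratify"):
            lasso_select(pool, y, cv_folds=10)


class TestRFandSVC:
    def test_training_accuracy_on_separable_toy(self, rng):
        x, y = separable_toy(rng, n=80)
        feats = pd.DataFrame(x, columns=["f1", "f2"])
        rf = fit_rf(feats, y, seed=0)
        svc = fit_svc(feats, y, seed=0)
        assert (rf.predict(feats) == y).mean() == 1.0
        assert (svc.predict(feats) == y).mean() >= 0.95

    def test_determinism_under_seed(self, rng):
        x, y = separable_toy(rng, n=80)
        x += rng.normal(0, 2.0, x.shape)  # make the problem non-trivial
        feats = pd.DataFrame(x, columns=["f1", "f2"])
        test = pd.DataFrame(rng.normal(size=(30, 2)), columns=["f1", "f2"])
        a = fit_rf(feats, y, seed=7).predict(test)
        b = fit_rf(feats, y, seed=7).predict(test)
        np.testing.assert_array_equal(a, b)

    def test_permuted_labels_score_near_class_prior(self, rng):
        n = 300
        x = rng.normal(size=(n, 4))
        y = np.zeros(n)
        y[:int(0.7 * n)] = 0.0
        y[int(0.7 * n):] = 1.0
        y = rng.permutation(y)
        feats = pd.DataFrame(x, columns=[f"f{i}" for i in range(4)])
        rf = fit_rf(feats[:200], y[:200], seed=1)
        acc = (rf.predict(feats[200:]) == y[200:]).mean()
        prior = max(np.mean(y[200:]), 1 - np.mean(y[200:]))
        assert abs(acc - prior) < 0.15

    def test_empty_feature_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty feature set"):
            fit_rf(pd.DataFrame(index=range(10)), np.repeat([0.0, 1.0], 5), seed=0)
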