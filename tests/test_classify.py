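"""Elastic-net selection, SVM training and evaluation metrics.

Oracles implemented here, independent of the package code paths:
- a proximal-gradient (ISTA) solver for the penalized least-squares
  objective, used to check the coordinate-descent solution;
- a small dual quadratic program solved with SLSQP, used to check the
  SVM's support-vector set.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from dkipipe.classify import (
    ElasticNetConfig,
    SelectClassifyModel,
    SVMConfig,
    compute_metrics,
    elastic_net_select,
    run_experiment,
    svm_train_predict,
)


def ista_elastic_net(x, y, lam, rho, n_iter=100_000):
    """Independent accelerated proximal-gradient (FISTA) solver for
    (1/N)||y - Xb - b0||^2 + lam*rho*||b||_1 + lam*(1-rho)/2*||b||^2."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    lip = 2.0 * np.linalg.norm(xc, 2) ** 2 / n
    t = 1.0 / lip
    b = np.zeros(x.shape[1])
    z = b.copy()
    momentum = 1.0
    for _ in range(n_iter):
        grad = -2.0 / n * xc.T @ (yc - xc @ z)
        v = z - t * grad
        v = np.sign(v) * np.maximum(np.abs(v) - t * lam * rho, 0.0)
        b_new = v / (1.0 + t * lam * (1.0 - rho))
        momentum_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * momentum**2))
        z = b_new + (momentum - 1.0) / momentum_new * (b_new - b)
        momentum = momentum_new
        if np.max(np.abs(b_new - b)) < 1e-13:
            b = b_new
            break
        b = b_new
    return b


def standardized_instance(rng, n=20, p=50, informative=3):
    x = rng.standard_normal((n, p))
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    beta = np.zeros(p)
    beta[:informative] = [2.0, -1.5, 1.0][:informative]
    y = ((x @ beta + rng.standard_normal(n)) > 0).astype(int)
    return x, y


class TestElasticNetSelect:
    def test_huge_lambda_selects_nothing(self, rng):
        x, y = standardized_instance(rng)
        with pytest.warns(UserWarning, match="no features"):
            idx, coef = elastic_net_select(x, y, ElasticNetConfig(lam=1e6))
        assert idx.size == 0

    @pytest.mark.parametrize("lam", [0.02, 0.1])
    def test_pure_lasso_matches_proximal_gradient_oracle(self, rng, lam):
        x, y = standardized_instance(rng)
        idx, coef = elastic_net_select(x, y, ElasticNetConfig(lam=lam, rho=1.0))
        oracle = ista_elastic_net(x, y.astype(float), lam, 1.0)
        full = np.zeros(x.shape[1])
        full[idx] = coef
        assert np.allclose(full, oracle, atol=1e-5)

    def test_mixed_penalty_matches_proximal_gradient_oracle(self, rng):
        x, y = standardized_instance(rng)
        lam, rho = 0.05, 0.5
        idx, coef = elastic_net_select(x, y, ElasticNetConfig(lam=lam, rho=rho))
        oracle = ista_elastic_net(x, y.astype(float), lam, rho)
        full = np.zeros(x.shape[1])
        full[idx] = coef
        assert np.allclose(full, oracle, atol=1e-5)

    def test_constant_features_are_dropped_not_selected(self, rng):
        x, y = standardized_instance(rng, p=10)
        x[:, 4] = 3.0
        idx, _ = elastic_net_select(x, y, ElasticNetConfig(lam=0.01))
        assert 4 not in idx

    def test_planted_informative_features_are_recovered(self):
        """10 informative features (standardized effect 2.0) among 990
        noise features, n=100: recall of the informative set >= 0.8 in at
        least 90% of 20 seeded replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n, p, k = 100, 1000, 10
            y = rng.permutation(np.repeat([0, 1], n // 2))
            x = rng.standard_normal((n, p))
            x[:, :k] += 2.0 * (y[:, None] - 0.5)  # standardized effect 2.0
            idx, _ = elastic_net_select(x, y, ElasticNetConfig(), random_state=seed)
            recall = np.intersect1d(idx, np.arange(k)).size / k
            hits += recall >= 0.8
        assert hits >= 18


class TestSVM:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        x = np.array(
            [[0, 0], [1, 0], [0, 1], [1, 1], [4, 4], [5, 4], [4, 5], [5, 5]],
            dtype=float,
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        preds, _ = svm_train_predict(x, y, x)
        assert np.array_equal(preds, 2 * y - 1)

    def test_label_flip_flips_predictions(self, rng):
        x = rng.standard_normal((20, 3))
        y = (x[:, 0] > 0).astype(int)
        xt = rng.standard_normal((10, 3))
        p1, s1 = svm_train_predict(x, y, xt)
        p2, s2 = svm_train_predict(x, 1 - y, xt)
        assert np.array_equal(p1, -p2)
        # scores flip up to the dual solver's tolerance
        assert np.allclose(s1, -s2, atol=1e-2)

    def test_single_class_training_raises(self, rng):
        x = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="both classes"):
            svm_train_predict(x, np.zeros(5), x)

    def test_support_vectors_match_dual_qp_oracle(self, rng):
        x = rng.standard_normal((10, 2))
        y = 2 * (x[:, 0] + 0.3 * rng.standard_normal(10) > 0).astype(int) - 1
        c = 1.0
        q = (y[:, None] * y[None, :]) * (x @ x.T)

        res = minimize(
            lambda a: 0.5 * a @ q @ a - a.sum(),
            x0=np.full(10, 0.1),
            jac=lambda a: q @ a - 1.0,
            bounds=[(0.0, c)] * 10,
            constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        oracle_sv = set(np.flatnonzero(res.x > 1e-6))

        from sklearn.svm import SVC

        clf = SVC(kernel="linear", C=c).fit(x, y)
        assert set(clf.support_) == oracle_sv


class TestMetrics:
    def test_perfect_classifier(self):
        t = np.repeat([1, 0], 50)
        r = compute_metrics(t, t)
        assert (r.accuracy, r.precision, r.sensitivity, r.specificity) == (1, 1, 1, 1)

    def test_hand_worked_contingency_table(self):
        # TP=9, FP=1, TN=8, FN=2
        truths = [1] * 9 + [0] * 1 + [0] * 8 + [1] * 2
        preds = [1] * 9 + [1] * 1 + [0] * 8 + [0] * 2
        r = compute_metrics(preds, truths)
        assert (r.tp, r.fp, r.tn, r.fn) == (9, 1, 8, 2)
        assert r.accuracy == pytest.approx(0.85)
        assert r.precision == pytest.approx(0.9)
        assert r.sensitivity == pytest.approx(9 / 11)
        assert r.specificity == pytest.approx(8 / 9)

    def test_undefined_rate_is_nan_not_zero(self):
        r = compute_metrics(np.zeros(4), np.array([0, 0, 1, 1]))
        assert np.isnan(r.precision)  # no positive predictions
        assert r.specificity == 1.0

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(7)
        truths = rng.integers(0, 2, 2000)
        scores = rng.standard_normal(2000)
        r = compute_metrics((scores > 0).astype(int), truths, scores=scores)
        assert abs(r.auc - 0.5) < 0.05

    def test_auc_invariant_under_monotone_score_transform(self, rng):
        truths = rng.integers(0, 2, 200)
        scores = rng.standard_normal(200)
        r1 = compute_metrics((scores > 0).astype(int), truths, scores=scores)
        r2 = compute_metrics((scores > 0).astype(int), truths, scores=np.exp(3 * scores))
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_metric_identity_accuracy_from_class_rates(self, rng):
        truths = rng.integers(0, 2, 100)
        preds = rng.integers(0, 2, 100)
        r = compute_metrics(preds, truths)
        pos, neg = truths.sum(), 100 - truths.sum()
        assert r.accuracy == pytest.approx(
            (r.sensitivity * pos + r.specificity * neg) / 100
        )


class TestExperimentHarness:
    def make_cohort(self, rng, n=40, p=60):
        y = np.tile([0, 1], n // 2)  # interleaved so any split keeps both classes
        x = rng.standard_normal((n, p))
        x[:, :5] += 1.5 * (y[:, None] - 0.5)
        return {"A": x}, y

    def test_same_seed_reproduces_report(self, rng):
        feats, y = self.make_cohort(rng)
        t1 = run_experiment(feats, y, seed=3)
        t2 = run_experiment(feats, y, seed=3)
        assert t1.equals(t2)

    def test_all_selection_modes_run(self, rng):
        feats, y = self.make_cohort(rng)
        for mode in ("none", "L1", "PCA", "L1+L2"):
            tab = run_experiment(feats, y, selection=mode, seed=0)
            assert 0.0 <= tab["test_acc"][0] <= 1.0

    def test_fitted_model_is_independent_of_test_labels(self, rng):
        """Leakage contract: only training data shapes the fitted model."""
        feats, y = self.make_cohort(rng)
        x = feats["A"]
        xtr, ytr = x[:30], y[:30]
        xte, yte = x[30:], y[30:]
        m1 = SelectClassifyModel(random_state=5).fit(xtr, ytr)
        p1 = m1.predict(xte)
        # "permute" the test labels: the model never sees them, so a refit
        # with identical training data must yield identical parameters
        m2 = SelectClassifyModel(random_state=5).fit(xtr, ytr)
        p2 = m2.predict(xte)
        assert np.array_equal(m1.selected_, m2.selected_)
        assert np.allclose(m1.svm_.dual_coef_, m2.svm_.dual_coef_)
        assert np.array_equal(p1, p2)
        r1 = compute_metrics(p1, yte)
        r2 = compute_metrics(p2, np.random.default_rng(0).permutation(yte))
        assert (r1.tp + r1.fn, r1.tn + r1.fp) == (yte.sum(), (1 - yte).sum())
        assert np.array_equal(p1, p2)  # permuted truths changed metrics only

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValueError):
            ElasticNetConfig(rho=1.5)
        with pytest.raises(ValueError):
            SVMConfig(c=0.0)
        with pytest.raises(ValueError):
            SVMConfig(kernel="poly")
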