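"""Classifier families: distance arithmetic, KNN vs brute-force oracle,
ridge logistic optimality, forest voting, SVM kernels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpnoise import (
    KNNClassifier,
    RandomForestModel,
    RidgeLogistic,
    SVMModel,
    default_grid,
    euclidean_distance,
    make_model,
)
from snpnoise.classifiers import WEIGHTINGS, knn_score


class TestEuclideanDistance:
    def test_arithmetic(self):
        assert euclidean_distance([1, 2], [1, 2]) == 0.0
        assert euclidean_distance([0, 0], [2, 1]) == pytest.approx(np.sqrt(5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([0, 1], [0, 1, 2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=30))
    def test_scaled_identity_and_range(self, pairs):
        x0 = np.array([a for a, _ in pairs])
        xi = np.array([b for _, b in pairs])
        d = euclidean_distance(x0, xi, scaled=True)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(euclidean_distance(x0, xi) / (2 * np.sqrt(len(x0))))


def _knn_oracle(train_X, train_y, x0, k, weighting):
    """Full distance matrix + explicit (distance, index) sort + literal vote."""
    m = train_X.shape[1]
    d = np.array(
        [euclidean_distance(x0 / 2.0, xi / 2.0) / np.sqrt(m) for xi in train_X]
    )
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
    dd = d[order]
    yy = train_y[np.array(order)]
    if weighting == "uniform":
        w = np.ones(k)
    elif weighting == "inv":
        w = np.clip(1 - dd, 0, None)
    else:
        if (dd == 0).any():
            w = (dd == 0).astype(float)
        else:
            w = 1.0 / dd
    return float((w * yy).sum() / w.sum()) if w.sum() > 0 else float(yy.mean())


class TestKNN:
    def test_exact_match_dominates(self):
        X = np.array([[0, 0], [2, 2]])
        y = np.array([0, 1])
        assert knn_score(X, y, [0, 0], k=1) == 0.0
        # under reciprocal weighting a zero-distance neighbour outweighs everything
        assert knn_score(X, y, [0, 0], k=2, weighting="recip") == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(5, 15))
            m = int(rng.integers(2, 8))
            X = rng.integers(0, 3, size=(n, m)).astype(float)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            x0 = rng.integers(0, 3, size=m).astype(float)
            k = int(rng.integers(1, n + 1))
            for w in WEIGHTINGS:
                got = knn_score(X, y, x0, k=k, weighting=w)
                assert got == pytest.approx(_knn_oracle(X, y, x0, k, w), abs=1e-12)

    def test_tie_at_half_predicts_positive(self):
        X = np.array([[0, 0], [2, 2]])
        y = np.array([0, 1])
        model = KNNClassifier(k=2, weighting="uniform").fit(X, y)
        assert model.predict(np.array([[1, 1]]))[0] == 1

    def test_grid_contents(self):
        grid = default_grid("knn")
        assert {g["k"] for g in grid} == {1, 3, 5, 7}
        assert {g["weighting"] for g in grid} == set(WEIGHTINGS)
        assert len(grid) == 12

    def test_k_larger_than_training_set_rejected(self):
        with pytest.raises(ValueError):
            KNNClassifier(k=5).fit(np.zeros((3, 2)), np.array([0, 1, 0]))


class TestRidgeLogistic:
    def test_huge_penalty_shrinks_to_class_rate(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(40, 6)).astype(float)
        y = np.array([1] * 30 + [0] * 10)
        model = RidgeLogistic(lam=1e8).fit(X, y)
        assert np.abs(model.coef_).max() < 1e-4
        assert np.allclose(model.decision_scores(X), 0.75, atol=0.01)

    def test_separable_toy_reaches_zero_training_error(self):
        X = np.array([[0, 0], [0, 1], [2, 2], [2, 1]], dtype=float)
        y = np.array([0, 0, 1, 1])
        model = RidgeLogistic(lam=0.01).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_optimum_beats_dense_grid_oracle(self):
        """Penalized log-likelihood at the IRLS solution is not exceeded on a
        dense grid over (intercept, coef1, coef2)."""
        X = np.array([[0, 1], [1, 0], [2, 2], [0, 2], [2, 0], [1, 2]], dtype=float)
        y = np.array([0, 0, 1, 0, 1, 1])
        lam = 1.0
        model = RidgeLogistic(lam=lam).fit(X, y)
        best = model.penalized_loglik(X, y)
        for mu in np.linspace(-3, 3, 13):
            for b1 in np.linspace(-2, 2, 21):
                for b2 in np.linspace(-2, 2, 21):
                    eta = mu + X @ np.array([b1, b2])
                    ll = (y * eta - np.logaddexp(0, eta)).sum() - lam / 2 * (b1**2 + b2**2)
                    assert ll <= best + 1e-8

    def test_optimum_not_beaten_on_finite_difference_grid(self, Xy):
        X, y = Xy
        model = RidgeLogistic(lam=10.0).fit(X, y)
        best = model.penalized_loglik(X, y)
        rng = np.random.default_rng(0)
        theta = np.concatenate(([model.intercept_], model.coef_))
        for _ in range(40):
            delta = rng.normal(size=len(theta)) * 1e-3
            cand = theta + delta
            eta = cand[0] + X @ cand[1:]
            ll = (y * eta - np.logaddexp(0, eta)).sum() - 5.0 * (cand[1:] ** 2).sum()
            assert ll <= best + 1e-6

    def test_coefficient_norm_shrinks_with_penalty(self, Xy):
        X, y = Xy
        norms = [
            np.linalg.norm(RidgeLogistic(lam=lam).fit(X, y).coef_)
            for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_nonconvergence_warns_and_flags(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([0, 1])
        with pytest.warns(UserWarning):
            model = RidgeLogistic(lam=1e-9, max_iter=5).fit(X, y)
        assert not model.converged_


class TestRandomForest:
    def test_scores_are_vote_fractions(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(30, 10)).astype(float)
        y = rng.integers(0, 2, size=30)
        B = 10
        model = RandomForestModel(n_trees=B, m_features=3, seed=0).fit(X, y)
        s = model.decision_scores(X)
        assert np.allclose(np.round(s * B), s * B, atol=1e-9)

    def test_deterministic_under_seed(self, Xy):
        X, y = Xy
        s1 = RandomForestModel(20, 8, seed=11).fit(X, y).decision_scores(X)
        s2 = RandomForestModel(20, 8, seed=11).fit(X, y).decision_scores(X)
        assert np.array_equal(s1, s2)

    def test_grid_derives_j_from_log2_panel_size(self):
        grid = default_grid("rf", n_markers=175)
        assert {g["B"] for g in grid} == {1, 5, 10, 50, 100}
        assert {g["m"] for g in grid} == {8, 2, 4}  # j = int(log2(175) + 1) = 8

    def test_m_exceeding_marker_count_rejected(self):
        with pytest.raises(ValueError):
            RandomForestModel(5, 20, seed=0).fit(np.zeros((4, 3)), np.array([0, 1, 0, 1]))


class TestSVM:
    def test_separated_points_linear(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        y = np.array([0, 1])
        model = SVMModel("linear", C=512.0).fit(X, y)
        s = model.decision_scores(X)
        assert s[0] < 0 < s[1]
        assert (model.predict(X) == y).all()

    def test_rbf_gamma_to_zero_flattens_decision(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(20, 5)).astype(float)
        y = np.array([1] * 15 + [0] * 5)
        model = SVMModel("rbf", C=4.0, gamma=1e-8).fit(X, y)
        s = model.decision_scores(X)
        assert s.std() < 0.05

    def test_xor_linear_fails_rbf_succeeds(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0], [0.0, 2.0], [2.0, 0.0]])
        y = np.array([1, 1, 0, 0])
        lin = SVMModel("linear", C=512.0).fit(X, y)
        assert (lin.predict(X) != y).any()
        rbf = SVMModel("rbf", C=512.0, gamma=1.0).fit(X, y)
        assert (rbf.predict(X) == y).all()

    def test_grids(self):
        lin = default_grid("svm-lin")
        assert [g["C"] for g in lin] == [2.0**e for e in range(2, 10)]
        rbf = default_grid("svm-rbf")
        assert len(rbf) == 40
        assert {g["gamma"] for g in rbf} == {1e-3, 1e-2, 1e-1, 1.0, 10.0}

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            SVMModel("rbf", C=1.0)  # missing gamma
        with pytest.raises(ValueError):
            SVMModel("linear", C=-1.0)


class TestUniformContract:
    @pytest.mark.parametrize("family,params", [
        ("knn", {"k": 3, "weighting": "inv"}),
        ("lr", {"lam": 1.0}),
        ("rf", {"B": 10, "m": 4}),
        ("svm-lin", {"C": 4.0}),
        ("svm-rbf", {"C": 4.0, "gamma": 0.1}),
    ])
    def test_fit_score_predict(self, family, params, Xy):
        X, y = Xy
        idx = np.random.default_rng(0).permutation(len(y))
        tr, te = idx[:80], idx[80:]
        model = make_model(family, params, seed=0)
        model.fit(X[tr], y[tr])
        s = model.decision_scores(X[te])
        p = model.predict(X[te])
        assert s.shape == (43,)
        assert set(np.unique(p)).issubset({0, 1})
        # higher score = more positive: prediction is a threshold on the score
        thr = 0.0 if family.startswith("svm") else 0.5
        assert np.array_equal(p, (s >= thr).astype(int))
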