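"""Five classifier families under one fit/score contract.

Every model exposes ``fit(X, y)`` and ``decision_scores(X)`` where a higher
score means "more positive" (positive = high vigor = label 1), and
``predict(X)`` thresholds the score with ties resolved toward the positive
class. AUC computed on the scores is invariant to monotone rescaling, so the
five families are directly comparable.

KNN (with the nonstandard ``1 - D_E`` and ``1 / D_E`` vote weightings) and
ridge-penalized logistic regression (unpenalized intercept, IRLS) are
implemented natively. Random forest and the two SVMs delegate their solvers
to scikit-learn behind this contract: the forest votes with trees grown to
purity on bootstrap resamples (so the averaged leaf probabilities equal the
vote fraction), and the SVMs expose the signed decision value
f(x) = beta_0 + sum_i alpha_i K(x, x_i).

Dosages are scaled to [0, 1] and distances normalized by sqrt(m) for KNN so
that D_E lies in [0, 1] and the ``1 - D_E`` weight is a proper weight;
zero-distance neighbours dominate under ``1 / D_E``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "FAMILIES",
    "WEIGHTINGS",
    "ModelSpec",
    "euclidean_distance",
    "KNNClassifier",
    "knn_score",
    "RidgeLogistic",
    "ridge_logistic_fit",
    "RandomForestModel",
    "rf_fit",
    "SVMModel",
    "svm_fit",
    "make_model",
    "default_grid",
]

FAMILIES = ("knn", "lr", "rf", "svm-lin", "svm-rbf")
WEIGHTINGS = ("uniform", "inv", "recip")  # 1, 1 - D_E, 1 / D_E


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameters."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


def euclidean_distance(x0, xi, scaled: bool = False) -> float:
    """Euclidean distance between two dosage vectors.

    With ``scaled=True`` dosages are divided by 2 and the distance by
    sqrt(m), so the result lies in [0, 1] and equals unscaled / (2 sqrt(m)).
    """
    x0 = np.asarray(x0, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if x0.shape != xi.shape:
        raise ValueError("vectors must have equal length")
    d = float(np.sqrt(((x0 - xi) ** 2).sum()))
    if scaled:
        d /= 2.0 * np.sqrt(len(x0))
    return d


class KNNClassifier:
    """K-nearest-neighbour vote over normalized genotype distances.

    The score is the (optionally distance-weighted) fraction of positive
    votes among the K nearest training samples; distance ties break toward
    the lower training index. Under ``recip`` weighting, exact genotype
    matches (distance zero) carry infinite weight: the score is the plain
    majority among the exact matches.
    """

    def __init__(self, k: int = 1, weighting: str = "uniform"):
        if k < 1:
            raise ValueError("K must be >= 1")
        if weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        self.k = int(k)
        self.weighting = weighting

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._X = X / 2.0
        self._y = np.asarray(y, dtype=float)
        if self.k > len(self._y):
            raise ValueError("K exceeds the number of training samples")
        self._sqrt_m = np.sqrt(X.shape[1])
        return self

    def decision_scores(self, X) -> np.ndarray:
        Xq = np.asarray(X, dtype=float) / 2.0
        D = cdist(Xq, self._X) / self._sqrt_m
        order = np.argsort(D, axis=1, kind="stable")[:, : self.k]
        nd = np.take_along_axis(D, order, axis=1)
        ny = self._y[order]
        if self.weighting == "uniform":
            w = np.ones_like(nd)
        elif self.weighting == "inv":
            w = np.clip(1.0 - nd, 0.0, None)
        else:  # recip
            with np.errstate(divide="ignore"):
                w = np.where(nd > 0, 1.0 / np.where(nd > 0, nd, 1.0), 0.0)
            exact = nd == 0
            rows = exact.any(axis=1)
            w[rows] = exact[rows].astype(float)
        tw = w.sum(axis=1)
        s = (w * ny).sum(axis=1)
        return np.where(tw > 0, s / np.where(tw > 0, tw, 1.0), ny.mean(axis=1))

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


def knn_score(train_X, train_y, x0, k: int, weighting: str = "uniform") -> float:
    """Score a single query against a training set (functional form)."""
    model = KNNClassifier(k, weighting).fit(train_X, train_y)
    return float(model.decision_scores(np.atleast_2d(x0))[0])


class RidgeLogistic:
    """Logistic regression with an l2 penalty on the marker effects.

    Maximizes sum_i [y_i eta_i - log(1 + exp(eta_i))] - (lam/2) sum_j beta_j^2
    with eta_i = mu + z_i . beta, by iteratively reweighted least squares
    (Newton) with step halving; the intercept mu is unpenalized. The penalty
    is required for identifiability when markers outnumber samples.
    """

    def __init__(self, lam: float = 1.0, max_iter: int = 100, tol: float = 1e-6):
        if lam < 0:
            raise ValueError("lam must be >= 0")
        self.lam = float(lam)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    def _penalized_loglik(self, eta, y):
        # log(1 + e^eta) computed stably
        return float(
            (y * eta - np.logaddexp(0.0, eta)).sum()
            - 0.5 * self.lam * (self.coef_**2).sum()
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        if self.lam == 0 and m > n:
            warnings.warn("unpenalized fit with more markers than samples is unidentifiable")
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        self.intercept_ = float(np.log(pbar / (1 - pbar)))
        self.coef_ = np.zeros(m)
        pen = np.concatenate(([1e-10], np.full(m, self.lam)))  # jitter keeps H nonsingular
        Xd = np.hstack([np.ones((n, 1)), X])
        theta = np.concatenate(([self.intercept_], self.coef_))
        self.converged_ = False
        self.n_iter_ = 0
        for it in range(self.max_iter):
            eta = Xd @ theta
            p = 1.0 / (1.0 + np.exp(-eta))
            grad = Xd.T @ (y - p) - pen * theta
            if np.linalg.norm(grad) <= self.tol:
                self.converged_ = True
                break
            w = np.clip(p * (1 - p), 1e-10, None)
            H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step halving on the penalized log-likelihood
            self.coef_ = theta[1:]
            ll0 = self._penalized_loglik(eta, y)
            scale = 1.0
            for _ in range(20):
                cand = theta + scale * step
                self.coef_ = cand[1:]
                if self._penalized_loglik(Xd @ cand, y) >= ll0 - 1e-12:
                    theta = cand
                    break
                scale /= 2.0
            else:
                theta = theta + step / 2**20
            self.n_iter_ = it + 1
        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:]
        if not self.converged_ and self.n_iter_ == self.max_iter:
            warnings.warn(
                f"ridge logistic IRLS did not converge in {self.max_iter} iterations"
            )
        return self

    def penalized_loglik(self, X, y) -> float:
        eta = self.intercept_ + np.asarray(X, dtype=float) @ self.coef_
        return self._penalized_loglik(eta, np.asarray(y, dtype=float))

    def decision_scores(self, X) -> np.ndarray:
        eta = self.intercept_ + np.asarray(X, dtype=float) @ self.coef_
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


def ridge_logistic_fit(X, y, lam: float, **kwargs) -> RidgeLogistic:
    return RidgeLogistic(lam, **kwargs).fit(X, y)


class RandomForestModel:
    """Bagged classification trees voting by majority.

    B trees are grown to purity on bootstrap resamples with Gini splits over
    m randomly chosen markers per node; the score is the fraction of trees
    voting positive (pure leaves make scikit-learn's averaged probabilities
    identical to the vote fraction).
    """

    def __init__(self, n_trees: int = 100, m_features: int = 8, seed: int | None = 0):
        if n_trees < 1:
            raise ValueError("B must be >= 1")
        self.n_trees = int(n_trees)
        self.m_features = int(m_features)
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if not 1 <= self.m_features <= X.shape[1]:
            raise ValueError("m must lie in 1..n_markers")
        self._clf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.m_features,
            criterion="gini",
            bootstrap=True,
            random_state=self.seed,
        ).fit(X, np.asarray(y, dtype=int))
        return self

    def decision_scores(self, X) -> np.ndarray:
        proba = self._clf.predict_proba(np.asarray(X, dtype=float))
        pos = int(np.flatnonzero(self._clf.classes_ == 1)[0]) if 1 in self._clf.classes_ else None
        if pos is None:  # single-class training data
            return np.zeros(len(proba))
        return proba[:, pos]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


def rf_fit(X, y, B: int, m: int, seed: int | None = 0) -> RandomForestModel:
    return RandomForestModel(B, m, seed).fit(X, y)


class SVMModel:
    """Soft-margin SVM with linear or radial-basis-function kernel.

    The score is the signed decision value f(x) = beta_0 + sum alpha_i
    K(x, x_i); the label is its sign (ties to positive). C controls the
    margin width; gamma the RBF kernel's locality.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0, gamma: float | None = None):
        if kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if C <= 0:
            raise ValueError("C must be > 0")
        if kernel == "rbf" and (gamma is None or gamma <= 0):
            raise ValueError("rbf kernel requires gamma > 0")
        self.kernel = kernel
        self.C = float(C)
        self.gamma = gamma

    def fit(self, X, y):
        kw = {"gamma": self.gamma} if self.kernel == "rbf" else {}
        try:
            self._clf = SVC(kernel=self.kernel, C=self.C, tol=1e-3, **kw).fit(
                np.asarray(X, dtype=float), np.asarray(y, dtype=int)
            )
        except Exception as exc:  # pragma: no cover - solver failure path
            raise RuntimeError(
                f"SVM solver failed (kernel={self.kernel}, C={self.C}, gamma={self.gamma})"
            ) from exc
        return self

    def decision_scores(self, X) -> np.ndarray:
        return self._clf.decision_function(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0).astype(int)


def svm_fit(X, y, kernel: str, C: float, gamma: float | None = None) -> SVMModel:
    return SVMModel(kernel, C, gamma).fit(X, y)


def make_model(family: str, params: dict, seed: int | None = None):
    """Instantiate an unfitted model of the given family."""
    if family == "knn":
        return KNNClassifier(k=params["k"], weighting=params.get("weighting", "uniform"))
    if family == "lr":
        return RidgeLogistic(lam=params["lam"])
    if family == "rf":
        return RandomForestModel(params["B"], params["m"], seed=seed)
    if family == "svm-lin":
        return SVMModel("linear", C=params["C"])
    if family == "svm-rbf":
        return SVMModel("rbf", C=params["C"], gamma=params["gamma"])
    raise ValueError(f"unknown family {family!r}")


def default_grid(family: str, n_markers: int | None = None) -> list[dict]:
    """Tuning grid per family, listed simplest-first for tie-breaking.

    KNN: K in {1,3,5,7} x three weightings. RF: B in {1,5,10,50,100},
    m in {j,2,4} with j = int(log2(n_markers) + 1). LR: powers of ten for
    lambda, largest (most regularized) first. SVM: C in {2^2..2^9};
    gamma in {1e-3..1e1} for the RBF kernel.
    """
    if family == "knn":
        return [{"k": k, "weighting": w} for k in (1, 3, 5, 7) for w in WEIGHTINGS]
    if family == "rf":
        if n_markers is None:
            raise ValueError("rf grid needs n_markers to derive j")
        j = int(np.log2(n_markers) + 1)
        return [{"B": b, "m": m} for b in (1, 5, 10, 50, 100) for m in (j, 2, 4)]
    if family == "lr":
        return [{"lam": lam} for lam in (1e3, 1e2, 10.0, 1.0, 0.1, 1e-2, 1e-3)]
    if family == "svm-lin":
        return [{"C": float(2**e)} for e in range(2, 10)]
    if family == "svm-rbf":
        return [
            {"C": float(2**e), "gamma": float(10.0**g)}
            for e in range(2, 10)
            for g in range(-3, 2)
        ]
    raise ValueError(f"unknown family {family!r}")
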