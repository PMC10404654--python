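"""The five learner families behind the ensemble.

Each learner satisfies a minimal fit/predict contract: ``fit(X, y)`` on a
presence (1) / absence-or-background (0) design, ``predict_score(X)`` → a
suitability score in [0, 1]. Families:

GLM
    Logistic regression fitted natively by iteratively reweighted least
    squares (IRLS), the classical presence–absence baseline.
MARS
    A hinge-spline logistic model: piecewise-linear hinge basis functions
    placed at per-feature quantile knots, with L1-penalized logistic
    regression selecting the active terms — an adaptive regression-splines
    style learner that captures thresholded responses.
BRT
    Boosted regression trees (gradient boosting).
RF
    Random forest.
MAXENT
    A maximum-entropy-style model realized as L2-penalized logistic
    regression of presences against a large background sample (the
    infinitely-weighted logistic equivalence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

FAMILIES = ("GLM", "MARS", "BRT", "RF", "MAXENT")

# families fitted on equal-count buffered pseudo-absences vs. a large
# unconstrained background sample
PRESENCE_ABSENCE_FAMILIES = ("GLM", "MARS", "BRT", "RF")
BACKGROUND_FAMILIES = ("MAXENT",)


@dataclass
class LearnerSpec:
    """Family tag plus hyperparameter overrides for one learner."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")


class GLMLearner:
    """Logistic regression via IRLS (Newton–Raphson on the log-likelihood)."""

    def __init__(self, max_iter: int = 50, tol: float = 1e-8, ridge: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge  # tiny stabilizer for separable designs

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GLMLearner":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        Z = np.column_stack([np.ones(len(X)), X])
        beta = np.zeros(Z.shape[1])
        for _ in range(self.max_iter):
            eta = Z @ beta
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            # working response IRLS update with ridge stabilization
            WZ = Z * w[:, None]
            H = Z.T @ WZ + self.ridge * np.eye(Z.shape[1])
            g = Z.T @ (y - mu) - self.ridge * beta
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < self.tol:
                break
        self.coef_ = beta[1:]
        self.intercept_ = beta[0]
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept_ + np.asarray(X, float) @ self.coef_)


class MARSLearner:
    """Hinge-spline logistic model with lasso term selection."""

    def __init__(self, n_knots: int = 3, C: float = 1.0):
        self.n_knots = n_knots
        self.C = C

    def _basis(self, X: np.ndarray) -> np.ndarray:
        cols = [X]
        for j in range(X.shape[1]):
            for k in self.knots_[j]:
                cols.append(np.maximum(0.0, X[:, j] - k)[:, None])
                cols.append(np.maximum(0.0, k - X[:, j])[:, None])
        return np.concatenate(cols, axis=1)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MARSLearner":
        X = np.asarray(X, float)
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        self.knots_ = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]
        B = self._basis(X)
        self.model_ = LogisticRegression(
            solver="liblinear", l1_ratio=1.0, C=self.C, max_iter=2000
        )
        self.model_.fit(B, y)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        B = self._basis(np.asarray(X, float))
        return self.model_.predict_proba(B)[:, 1]


class _SklearnProba:
    """Adapter exposing predict_score over an sklearn probabilistic classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_score(self, X):
        return self.estimator.predict_proba(X)[:, 1]


class MaxentLearner(_SklearnProba):
    """Penalized logistic on presence vs. large background (MaxEnt analogue)."""

    def __init__(self, C: float = 1.0, max_iter: int = 2000):
        super().__init__(LogisticRegression(C=C, max_iter=max_iter))


def make_learner(spec: LearnerSpec, seed: int | None = None):
    """Instantiate a learner for a family spec; seeded where stochastic."""
    hp = dict(spec.hyperparameters)
    if spec.family == "GLM":
        return GLMLearner(**hp)
    if spec.family == "MARS":
        return MARSLearner(**hp)
    if spec.family == "BRT":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("learning_rate", 0.05)
        hp.setdefault("max_depth", 3)
        return _SklearnProba(GradientBoostingClassifier(random_state=seed, **hp))
    if spec.family == "RF":
        hp.setdefault("n_estimators", 200)
        return _SklearnProba(RandomForestClassifier(random_state=seed, **hp))
    if spec.family == "MAXENT":
        return MaxentLearner(**hp)
    raise ValueError(spec.family)
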