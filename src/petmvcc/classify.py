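"""L2-penalized logistic classification with LOOCV-AUC hyperparameter search.

The model minimizes the mean negative log-likelihood plus lam/2 * ||w||^2
with an unpenalized intercept (so lam multiplies the penalty of the *mean*
log-loss; in the common C = 1/(n*lam) convention the default grid spans
2^-10 ... 2^10). The regularization strength is selected by leave-one-out
cross-validation: for each candidate, the held-out probability of every
left-out sample is pooled into a single ROC, and the candidate with the
highest pooled AUC wins (ties break toward the smallest lam). Labels are
1 = patient, 0 = healthy; a sample is called a patient when its predicted
probability strictly exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_auc_score, roc_curve

from .ica import CoefficientMatrix

__all__ = [
    "make_lambda_grid",
    "fit_logistic",
    "loocv_select_lambda",
    "predict",
    "evaluate",
    "MVCCLogisticRegression",
    "LogisticModel",
    "CVResult",
    "ClassificationReport",
]


def make_lambda_grid(low_exp: int = -10, high_exp: int = 10) -> np.ndarray:
    """Geometric grid of penalties: powers of two from 2**low to 2**high."""
    return 2.0 ** np.arange(low_exp, high_exp + 1)


@dataclass
class LogisticModel:
    """Fitted weights/intercept at a given penalty lam."""

    weights: np.ndarray
    intercept: float
    lam: float


@dataclass
class CVResult:
    lambda_grid: np.ndarray
    auc_per_lambda: np.ndarray
    selected_lambda: float


@dataclass
class ClassificationReport:
    """Per-subject probabilities plus threshold and ranking metrics."""

    probabilities: np.ndarray
    predicted_labels: np.ndarray
    true_labels: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    auc: float | None
    confusion: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": self.confusion,
            "probabilities": self.probabilities.tolist(),
            "predicted_labels": self.predicted_labels.tolist(),
            "true_labels": self.true_labels.tolist(),
        }


def _coef_array(A) -> np.ndarray:
    if isinstance(A, CoefficientMatrix):
        return np.asarray(A.A, dtype=np.float64)
    return np.asarray(A, dtype=np.float64)


def _objective_grad_hess(theta, X1, y_pm, lam):
    """Mean logistic loss + lam/2 ||w||^2; theta = [w, b], X1 has 1s column."""
    n = X1.shape[0]
    eta = X1 @ theta
    z = y_pm * eta
    # stable log(1 + exp(-z))
    loss = np.mean(np.logaddexp(0.0, -z))
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    y01 = (y_pm + 1) / 2.0
    grad = X1.T @ (p - y01) / n
    w = theta[:-1]
    loss += 0.5 * lam * w @ w
    grad[:-1] += lam * w
    d = p * (1.0 - p)
    hess = (X1.T * d) @ X1 / n
    hess[np.arange(len(w)), np.arange(len(w))] += lam
    return loss, grad, hess


def fit_logistic(A, labels, lam: float, max_iter: int = 200, grad_tol: float = 1e-8) -> LogisticModel:
    """Newton fit of the penalized logistic objective.

    Converges to gradient infinity-norm <= ``grad_tol`` or raises
    reporting the achieved gradient norm.
    """
    X = _coef_array(A)
    y = np.asarray(labels, dtype=np.float64)
    if lam <= 0:
        raise ValueError("lam must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one sample per class")
    y_pm = np.where(y > 0.5, 1.0, -1.0)
    n, k = X.shape
    X1 = np.column_stack([X, np.ones(n)])
    theta = np.zeros(k + 1)
    for _ in range(max_iter):
        loss, grad, hess = _objective_grad_hess(theta, X1, y_pm, lam)
        gnorm = np.max(np.abs(grad))
        if gnorm <= grad_tol:
            break
        # damped Newton step with backtracking on the convex objective
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(k + 1), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        t = 1.0
        for _bt in range(60):
            new_loss, _, _ = _objective_grad_hess(theta + t * step, X1, y_pm, lam)
            if new_loss <= loss + 1e-4 * t * grad @ step:
                break
            t *= 0.5
        theta = theta + t * step
    else:
        _, grad, _ = _objective_grad_hess(theta, X1, y_pm, lam)
        raise RuntimeError(
            f"logistic fit did not converge: gradient norm {np.max(np.abs(grad)):.3e}"
        )
    return LogisticModel(weights=theta[:-1].copy(), intercept=float(theta[-1]), lam=float(lam))


def predict(model: LogisticModel, A) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (patient iff probability > 0.5)."""
    X = _coef_array(A)
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError("component count mismatch with the fitted model")
    eta = X @ model.weights + model.intercept
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    labels = (prob > 0.5).astype(int)
    return prob, labels


def loocv_select_lambda(A, labels, grid=None) -> CVResult:
    """Pooled-LOOCV AUC per candidate penalty; argmax with min-lam ties.

    For each candidate, every sample is held out once, the model is fit
    on the remaining n-1, and the held-out probability is recorded; the
    AUC is computed once on the n pooled probabilities.
    """
    X = _coef_array(A)
    y = np.asarray(labels, dtype=np.float64)
    if grid is None:
        grid = make_lambda_grid()
    grid = np.asarray(grid, dtype=np.float64)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    aucs = np.empty(grid.size)
    for gi, lam in enumerate(grid):
        held = np.empty(n)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            if len(np.unique(y[keep])) < 2:
                raise ValueError(
                    f"LOOCV fold {i} leaves a single class in training"
                )
            m = fit_logistic(X[keep], y[keep], lam)
            p_i, _ = predict(m, X[i : i + 1])
            held[i] = p_i[0]
        aucs[gi] = roc_auc_score(y, held)
    best = int(np.argmax(aucs > aucs.max() - 1e-12))
    return CVResult(lambda_grid=grid, auc_per_lambda=aucs, selected_lambda=float(grid[best]))


def evaluate(probabilities, labels) -> ClassificationReport:
    """Confusion metrics at the 0.5 threshold plus threshold-free ROC/AUC."""
    prob = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if prob.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    pred = (prob > 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    accuracy = (tp + tn) / y.size
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    if n_pos and n_neg:
        fpr, tpr, _ = roc_curve(y, prob, drop_intermediate=False)
        roc_points = np.column_stack([fpr, tpr])
        auc_val = float(_auc(fpr, tpr))
    else:
        roc_points = np.empty((0, 2))
        auc_val = None
    return ClassificationReport(
        probabilities=prob,
        predicted_labels=pred,
        true_labels=y,
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        roc_points=roc_points,
        auc=auc_val,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


class MVCCLogisticRegression(BaseEstimator, ClassifierMixin):
    """Logistic classifier with LOOCV-AUC-selected L2 penalty.

    Parameters
    ----------
    lambda_grid : array-like or None
        Candidate penalties; None uses the default 21-value power-of-two
        grid 2^-10 ... 2^10.
    fixed_lambda : float or None
        Skip the search and fit at this penalty.

    Attributes
    ----------
    coef_ : ndarray, shape (n_components,)
    intercept_ : float
    lambda_ : float
        Selected penalty.
    cv_result_ : CVResult or None
    """

    def __init__(self, lambda_grid=None, fixed_lambda: float | None = None):
        self.lambda_grid = lambda_grid
        self.fixed_lambda = fixed_lambda

    def fit(self, A, y):
        X = _coef_array(A)
        y = np.asarray(y)
        if self.fixed_lambda is not None:
            self.cv_result_ = None
            self.lambda_ = float(self.fixed_lambda)
        else:
            grid = self.lambda_grid if self.lambda_grid is not None else make_lambda_grid()
            self.cv_result_ = loocv_select_lambda(X, y, grid)
            self.lambda_ = self.cv_result_.selected_lambda
        model = fit_logistic(X, y, self.lambda_)
        self.coef_ = model.weights
        self.intercept_ = model.intercept
        self.classes_ = np.array([0, 1])
        return self

    def _model(self) -> LogisticModel:
        return LogisticModel(weights=self.coef_, intercept=self.intercept_, lam=self.lambda_)

    def predict_proba(self, A) -> np.ndarray:
        prob, _ = predict(self._model(), A)
        return np.column_stack([1 - prob, prob])

    def predict(self, A) -> np.ndarray:
        _, labels = predict(self._model(), A)
        return labels

    def report(self, A, y) -> ClassificationReport:
        prob, _ = predict(self._model(), A)
        return evaluate(prob, y)
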