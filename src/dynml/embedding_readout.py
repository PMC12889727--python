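"""Input projection, standardization, reservoir embedding and readouts.

The pipeline is: scale the input u, project it to a reservoir initial
condition x0 = R u, integrate the ensemble, and decode the final state x*
with a single global linear readout, y_hat = S x*. S is the ordinary
least-squares minimizer of ||Y - S X||_F^2 over all pooled training
transitions; rank-deficient feature blocks get the minimum-norm solution.
A multinomial-logistic readout plays the same role for classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .core_dynamics import IntegratorConfig, evolve_ensemble

__all__ = [
    "ProjectionMatrix",
    "Scaler",
    "ReadoutMatrix",
    "TrainingBatch",
    "make_projection",
    "project_input",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "embed_dataset",
    "fit_readout",
    "predict",
    "fit_classifier_readout",
    "predict_labels",
    "accuracy",
    "evaluate",
]


@dataclass(frozen=True)
class ProjectionMatrix:
    """Fixed random input projection R in R^{3N x M}."""

    R: np.ndarray
    scale: float

    @property
    def M(self) -> int:
        return self.R.shape[1]

    @property
    def N(self) -> int:
        return self.R.shape[0] // 3


@dataclass(frozen=True)
class ReadoutMatrix:
    """Trained global linear readout S in R^{P x 3N}."""

    S: np.ndarray

    @property
    def P(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class TrainingBatch:
    """Pooled reservoir states X (3N x D) and targets Y (P x D).

    ``task_labels`` optionally tags each column with a (variable,
    transition) pair for per-task evaluation slices.
    """

    X: np.ndarray
    Y: np.ndarray
    task_labels: np.ndarray | None = None

    def __post_init__(self):
        if self.X.shape[1] != self.Y.shape[1]:
            raise ValueError("X and Y must have the same number of columns")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one training column")

    @property
    def D(self) -> int:
        return self.X.shape[1]


def make_projection(M: int, N: int, rng: np.random.Generator,
                    scale: float = 1.0) -> ProjectionMatrix:
    """Gaussian projection with entries ~ Normal(0, (scale/sqrt(M))^2).

    The 1/sqrt(M) keeps ||x0|| comparable across input dimensions.
    """
    if M < 1 or N < 1:
        raise ValueError("M and N must be >= 1")
    R = rng.normal(0.0, scale / np.sqrt(M), size=(3 * N, M))
    return ProjectionMatrix(R=R, scale=scale)


def project_input(u: np.ndarray, proj: ProjectionMatrix) -> np.ndarray:
    """x0 = R u, for a single input (M,) or a batch (D, M)."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != proj.M:
        raise ValueError(f"input dimension {u.shape[-1]} != M = {proj.M}")
    return u @ proj.R.T


class Scaler:
    """Per-column standard scaler with a zero-variance guard.

    Thin wrapper over sklearn's StandardScaler (constant columns are mapped
    with scale 1, so they transform to 0 and round-trip exactly) recording
    which partition it was fitted on.
    """

    def __init__(self):
        self._impl = StandardScaler()
        self.fitted_on: str | None = None

    @property
    def mean(self) -> np.ndarray:
        self._require_fitted()
        return self._impl.mean_

    @property
    def sd(self) -> np.ndarray:
        self._require_fitted()
        return self._impl.scale_

    def _require_fitted(self):
        if self.fitted_on is None:
            raise RuntimeError("scaler has not been fitted")


def fit_scaler(data: np.ndarray, fitted_on: str = "train") -> Scaler:
    """Fit a per-column scaler. Fit on the training partition only."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D (samples x features) matrix")
    sc = Scaler()
    sc._impl.fit(data)
    sc.fitted_on = fitted_on
    return sc


def apply_scaler(sc: Scaler, data: np.ndarray) -> np.ndarray:
    sc._require_fitted()
    data = np.asarray(data, dtype=float)
    return (data - sc.mean) / sc.sd


def invert_scaler(sc: Scaler, data: np.ndarray) -> np.ndarray:
    sc._require_fitted()
    data = np.asarray(data, dtype=float)
    return data * sc.sd + sc.mean


def embed_dataset(
    U: np.ndarray,
    proj: ProjectionMatrix,
    params,
    integ: IntegratorConfig | None = None,
) -> np.ndarray:
    """Feature block X (3N x D): column d is the final reservoir state for
    input row d of U. The same R and params serve every sample."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be (D, M)")
    x0 = project_input(U, proj)
    final = evolve_ensemble(x0, params, integ)
    return final.T


def fit_readout(batch: TrainingBatch, rcond: float | None = None) -> ReadoutMatrix:
    """Minimize ||Y - S X||_F^2 by (minimum-norm) ordinary least squares."""
    if not (np.isfinite(batch.X).all() and np.isfinite(batch.Y).all()):
        raise ValueError("non-finite entries in training batch")
    # lstsq solves min ||A s - b||; A = X^T (D x 3N), b = Y^T (D x P).
    sol, _, _, _ = scipy.linalg.lstsq(batch.X.T, batch.Y.T, cond=rcond,
                                      lapack_driver="gelsd")
    return ReadoutMatrix(S=sol.T)


def predict(readout: ReadoutMatrix, states: np.ndarray,
            target_scaler: Scaler | None = None) -> np.ndarray:
    """y_hat = S x* per column of a (3N x D) state block.

    If a target scaler is given, predictions are inverse-transformed back to
    original units (columns of the result are samples, rows variables).
    """
    if states.shape[0] != readout.S.shape[1]:
        raise ValueError(
            f"state dimension {states.shape[0]} != 3N = {readout.S.shape[1]}"
        )
    pred = readout.S @ states
    if target_scaler is not None:
        pred = invert_scaler(target_scaler, pred.T).T
    return pred


def fit_classifier_readout(X: np.ndarray, labels: np.ndarray,
                           C: float = 10.0, max_iter: int = 2000,
                           seed: int = 0) -> LogisticRegression:
    """Multinomial logistic readout on a (3N x D) feature block."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training labels must contain at least two classes")
    clf = LogisticRegression(C=C, max_iter=max_iter, random_state=seed)
    clf.fit(X.T, labels)
    return clf


def predict_labels(clf: LogisticRegression, X: np.ndarray) -> np.ndarray:
    """Deterministic argmax-score prediction; sklearn breaks exact ties by
    the lowest class index."""
    return clf.predict(X.T)


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean(pred == truth))


def evaluate(pred: np.ndarray, truth: np.ndarray):
    """(Pearson r, two-sided p, MSE) for one evaluation slice.

    r and p come from the exact t-transform; for a constant vector r and p
    are NaN (callers exclude such slices from aggregates). MSE is computed
    in whatever units the vectors are passed in.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length vectors")
    if pred.size < 3:
        raise ValueError("need at least 3 points to evaluate")
    mse = float(np.mean((pred - truth) ** 2))
    if np.std(pred) == 0 or np.std(truth) == 0:
        return float("nan"), float("nan"), mse
    res = stats.pearsonr(pred, truth)
    return float(res.statistic), float(res.pvalue), mse
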