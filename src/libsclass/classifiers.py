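"""Global discriminant models: PLS-DA and a small feed-forward ANN.

Unlike SIMCA, which models each class separately and can reject a
spectrum, both models here are single "global" classifiers trained on all
classes at once and always assign a label (argmax — structurally zero
unclassification).

PLS-DA regresses one-hot class indicators on the mean-centered spectra by
NIPALS partial least squares (scikit-learn's ``PLSRegression`` provides
the NIPALS engine); a row is assigned to the class with the largest
predicted indicator, ties going to the lowest-index class. The number of
latent variables is chosen by stratified cross-validation on the training
split when not fixed.

The ANN operates on global PCA scores rather than raw channels: one
tanh hidden layer, softmax output, cross-entropy loss minimized by
full-batch gradient descent for a fixed epoch budget. Inputs are
standardized with training statistics. Training is deterministic under
the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .errors import DimensionError
from .spectra import SpectraSet

__all__ = [
    "PLSDAModel",
    "ANNModel",
    "fit_plsda",
    "predict_plsda",
    "fit_ann",
    "predict_ann",
]


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PLSDAModel:
    """Fitted PLS-DA: the NIPALS regression plus class bookkeeping."""

    pls: PLSRegression
    classes: tuple[str, ...]
    n_latent: int
    wavelengths: np.ndarray
    valid_mask: np.ndarray

    @property
    def x_weights(self) -> np.ndarray:
        """NIPALS weight vectors, one column per latent variable."""
        return self.pls.x_weights_


def _one_hot(labels: list[str], classes: list[str]) -> np.ndarray:
    index = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, index[l]] = 1.0
    return Y


def _fit_pls(X: np.ndarray, Y: np.ndarray, n_comp: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_comp, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # deflation warnings on tiny folds
        pls.fit(X, Y)
    return pls


def fit_plsda(
    train: SpectraSet,
    n_latent: int | None = None,
    max_latent: int = 10,
    cv_folds: int = 5,
) -> PLSDAModel:
    """Fit PLS-DA on mean-centered valid channels vs one-hot labels.

    When ``n_latent`` is None the latent-variable count is picked by
    stratified ``cv_folds``-fold cross-validated accuracy on the training
    split (smallest count on ties). Deterministic.
    """
    classes = train.classes
    if len(classes) < 2:
        raise DimensionError("PLS-DA needs at least two classes")
    X = train.valid_matrix()
    Y = _one_hot(train.labels, classes)
    if float(np.ptp(X)) == 0.0:
        raise DimensionError("degenerate training matrix (zero variance)")
    cap = min(max_latent, X.shape[0] - 1, X.shape[1])
    if n_latent is None:
        n_latent = _select_n_latent(X, train.labels, classes, cap, cv_folds)
    if not (1 <= n_latent <= cap):
        raise DimensionError(f"n_latent={n_latent} out of range 1..{cap}")
    pls = _fit_pls(X, Y, n_latent)
    return PLSDAModel(
        pls, tuple(classes), n_latent, train.wavelengths.copy(), train.valid_mask.copy()
    )


def _select_n_latent(X, labels, classes, cap, cv_folds) -> int:
    y = np.array([classes.index(l) for l in labels])
    counts = np.bincount(y)
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        return min(cap, len(classes))
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    Y = _one_hot(labels, classes)
    accuracy = np.zeros(cap)
    for train_idx, test_idx in skf.split(X, y):
        fold_cap = min(cap, len(train_idx) - 1)
        pls = _fit_pls(X[train_idx], Y[train_idx], fold_cap)
        for n in range(1, fold_cap + 1):
            # truncated prediction: first n latent variables only
            pred = _truncated_predict(pls, X[test_idx], n)
            accuracy[n - 1] += float(np.mean(np.argmax(pred, axis=1) == y[test_idx]))
    return int(np.argmax(accuracy)) + 1  # argmax takes the smallest on ties


def _truncated_predict(pls: PLSRegression, X: np.ndarray, n: int) -> np.ndarray:
    W, P, Q = pls.x_rotations_[:, :n], None, pls.y_loadings_[:, :n]
    T = (X - pls._x_mean) @ W
    return T @ Q.T + pls._y_mean


def predict_plsda(model: PLSDAModel, spectra: SpectraSet) -> list[str]:
    """Assigned class per row: argmax of predicted indicators, no rejection."""
    if spectra.n_channels != model.wavelengths.size or not np.allclose(
        spectra.wavelengths, model.wavelengths
    ) or not np.array_equal(spectra.valid_mask, model.valid_mask):
        raise DimensionError("spectra grid/mask does not match the model")
    pred = model.pls.predict(spectra.valid_matrix())
    return [model.classes[j] for j in np.argmax(pred, axis=1)]


# ---------------------------------------------------------------------------
# ANN on PCA scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ANNModel:
    """One-hidden-layer tanh/softmax network on standardized PCA scores."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    classes: tuple[str, ...]
    input_mean: np.ndarray
    input_sd: np.ndarray
    seed: int
    final_loss: float


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fit_ann(
    scores: np.ndarray,
    labels: list[str],
    width: int = 8,
    seed: int = 0,
    epochs: int = 800,
    learning_rate: float = 0.5,
    loss_tol: float = 0.5,
) -> ANNModel:
    """Train the network by full-batch gradient descent, fixed epoch budget.

    A warning is emitted when the final cross-entropy per sample is still
    above ``loss_tol`` (the model is returned regardless).
    """
    if width < 1:
        raise ValueError("hidden width must be >= 1")
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise DimensionError("scores must be a 2-D matrix")
    seen: dict[str, None] = {}
    for l in labels:
        seen.setdefault(l, None)
    classes = list(seen)
    y = np.array([classes.index(l) for l in labels])
    n, d = X.shape
    c = len(classes)

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    T = np.eye(c)[y]

    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d), (d, width))
    b1 = np.zeros(width)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(width), (width, c))
    b2 = np.zeros(c)

    loss = np.inf
    for _ in range(epochs):
        H = np.tanh(Xs @ W1 + b1)
        P = _softmax(H @ W2 + b2)
        loss = float(-np.mean(np.sum(T * np.log(P + 1e-300), axis=1)))
        dZ2 = (P - T) / n
        dW2 = H.T @ dZ2
        db2 = dZ2.sum(axis=0)
        dH = dZ2 @ W2.T * (1.0 - H**2)
        dW1 = Xs.T @ dH
        db1 = dH.sum(axis=0)
        W1 -= learning_rate * dW1
        b1 -= learning_rate * db1
        W2 -= learning_rate * dW2
        b2 -= learning_rate * db2
    if loss > loss_tol:
        warnings.warn(
            f"ANN training ended with cross-entropy {loss:.4g} > {loss_tol:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ANNModel(W1, b1, W2, b2, tuple(classes), mean, sd, seed, loss)


def predict_ann(model: ANNModel, scores: np.ndarray) -> list[str]:
    """Argmax class per row of a score matrix; no rejection option."""
    X = (np.asarray(scores, dtype=float) - model.input_mean) / model.input_sd
    H = np.tanh(X @ model.W1 + model.b1)
    P = _softmax(H @ model.W2 + model.b2)
    return [model.classes[j] for j in np.argmax(P, axis=1)]
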