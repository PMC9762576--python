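"""Regularized multinomial decoding of stimulus features from NMF coefficients.

A softmax (multinomial logistic) model with L2 penalty, fit by L-BFGS, maps a
trial's activation-coefficient vector to posterior probabilities over the
values of one stimulus feature. The regularization strength C is chosen by
stratified 5-fold cross-validation on the training half, scored by mean
cross-entropy; the final model is refit on the full training half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DecoderModel",
    "ConfusionMatrix",
    "DEFAULT_C_GRID",
    "train_decoder",
    "posterior",
    "decode",
    "confusion_matrix",
]

DEFAULT_C_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))


@dataclass
class DecoderModel:
    """Fitted multinomial decoder for one stimulus feature."""

    estimator: LogisticRegression
    C: float
    classes_: np.ndarray
    cv_results: pd.DataFrame  # columns: C, mean_cross_entropy
    seed: int | None = None

    @property
    def coef_(self) -> np.ndarray:
        return self.estimator.coef_

    @property
    def n_outcomes(self) -> int:
        return self.classes_.size


@dataclass
class ConfusionMatrix:
    """Counts of (presented, decoded) outcome pairs over test trials.

    Rows index the presented stimulus, columns the decoded one.
    """

    counts: np.ndarray
    outcome_labels: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.outcome_labels, columns=self.outcome_labels)


def _make_estimator(C: float, seed: int | None, max_iter: int) -> LogisticRegression:
    # L2 penalty (sklearn's default) with strength 1/C, per the lbfgs solver
    return LogisticRegression(
        C=C,
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )


def train_decoder(
    H_train: np.ndarray,
    labels: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    seed: int | None = 0,
    n_splits: int = 5,
    max_iter: int = 2000,
) -> DecoderModel:
    """Grid-search C by stratified K-fold cross-entropy, then refit.

    Ties in mean cross-entropy resolve to the smallest C (strongest
    regularization). Requires at least ``n_splits`` trials per outcome.
    """
    H_train = np.asarray(H_train, dtype=float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)  # encode outcome values
    counts = np.bincount(y)
    if classes.size < 2:
        raise ValueError("need at least 2 outcome values to decode")
    if counts.min() < n_splits:
        raise ValueError(
            f"every outcome needs >= {n_splits} training trials (min found {counts.min()})"
        )
    codes = np.arange(classes.size)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(H_train, y))
    mean_losses = []
    for C in C_grid:
        losses = []
        for tr, va in folds:
            est = _make_estimator(C, seed, max_iter)
            est.fit(H_train[tr], y[tr])
            p = est.predict_proba(H_train[va])
            losses.append(log_loss(y[va], p, labels=codes))
        mean_losses.append(float(np.mean(losses)))
    best = int(np.argmin(mean_losses))
    C_best = float(C_grid[best])
    final = _make_estimator(C_best, seed, max_iter)
    final.fit(H_train, y)
    cv = pd.DataFrame({"C": list(C_grid), "mean_cross_entropy": mean_losses})
    return DecoderModel(estimator=final, C=C_best, classes_=classes, cv_results=cv, seed=seed)


def posterior(model: DecoderModel, h_trial: np.ndarray) -> np.ndarray:
    """Posterior probability over outcomes for one trial's coefficients."""
    h = np.asarray(h_trial, dtype=float).reshape(1, -1)
    return model.estimator.predict_proba(h)[0]


def decode(model: DecoderModel, H: np.ndarray) -> np.ndarray:
    """Decoded outcome per trial: argmax of the posterior (lowest index wins).

    ``predict_proba`` + explicit argmax is used rather than ``predict`` so the
    tie-break is the documented lowest-outcome-index rule.
    """
    P = model.estimator.predict_proba(np.asarray(H, dtype=float))
    return model.classes_[np.argmax(P, axis=1)]


def confusion_matrix(model: DecoderModel, H_test: np.ndarray, labels_test: np.ndarray) -> ConfusionMatrix:
    """Empirical confusion counts of (presented, decoded) over test trials."""
    P = model.estimator.predict_proba(np.asarray(H_test, dtype=float))
    pred_idx = np.argmax(P, axis=1)
    true_idx = np.searchsorted(model.classes_, np.asarray(labels_test))
    if np.any(true_idx >= model.classes_.size) or np.any(
        model.classes_[true_idx] != np.asarray(labels_test)
    ):
        raise ValueError("labels_test contains outcomes unseen in training")
    S = model.classes_.size
    counts = np.bincount(true_idx * S + pred_idx, minlength=S * S).reshape(S, S)
    return ConfusionMatrix(counts=counts, outcome_labels=model.classes_)
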