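"""Comparator classifiers: SCRDA, nearest neighbor, and the top-gene screen.

SCRDA (shrunken-centroids regularized discriminant analysis) shrinks the
pooled covariance toward the identity, Sigma_tilde = alpha * Sigma_hat +
(1 - alpha) * I (or the correlation-matrix analogue), and soft-thresholds the
transformed centroids x*_k = Sigma_tilde^{-1} x_bar_k by Delta.  (alpha,
Delta) are tuned by cross-validation with the MIN-MIN tie rule: among pairs
with minimal CV error, the pair with the fewest nonzero score components
wins.

The nearest-neighbor rule classifies by majority vote among the h nearest
training samples in Euclidean distance (h = 3 by convention in genomics
benchmarks).

The top-gene screen ranks features by |t| (two classes) or ANOVA F and picks
the number of top features by cross-validation over a count grid, default
50..2000 in steps of 50.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .model import _stratified_folds, feature_ranking_scores

__all__ = [
    "SCRDA",
    "SCRDAResults",
    "scrda_fit",
    "nn_classify",
    "top_gene_cv_screen",
    "DEFAULT_GENE_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 0.99)
DEFAULT_DELTA_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
DEFAULT_GENE_GRID = tuple(range(50, 2001, 50))


def _pooled_cov(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled within-class covariance, class means, class labels."""
    classes = np.unique(y)
    p = X.shape[1]
    S = np.zeros((p, p))
    means = np.empty((len(classes), p))
    dof = 0
    for i, c in enumerate(classes):
        g = X[y == c]
        means[i] = g.mean(axis=0)
        D = g - means[i]
        S += D.T @ D
        dof += g.shape[0] - 1
    return S / dof, means, classes


def _shrunk_matrix(S: np.ndarray, alpha: float, target: str) -> np.ndarray:
    p = S.shape[0]
    if target == "covariance":
        return alpha * S + (1.0 - alpha) * np.eye(p)
    if target == "correlation":
        s = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        R = S / np.outer(s, s)
        R_t = alpha * R + (1.0 - alpha) * np.eye(p)
        return R_t * np.outer(s, s)
    raise ValueError(f"unknown shrink target {target!r}")


def _soft(v: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


@dataclass
class SCRDAResults:
    """Fitted SCRDA rule: shrunken discriminant scores per class."""

    classes: np.ndarray
    means: np.ndarray           # K x p class centroids
    scores: np.ndarray          # K x p shrunken x*_k = soft(Sigma~^{-1} x_bar_k, Delta)
    alpha: float
    delta: float
    cv_error: float
    config: dict

    @property
    def n_selected_features(self) -> int:
        """Features with a nonzero score component in at least one class."""
        return int((np.abs(self.scores) > 0).any(axis=0).sum())

    def predict(self, X_test) -> np.ndarray:
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        d = X_test @ self.scores.T - 0.5 * np.sum(self.means * self.scores, axis=1)
        return self.classes[np.argmax(d, axis=1)]

    def summary(self) -> str:
        return (
            "SCRDA (shrunken-centroids regularized discriminant analysis)\n"
            f"alpha = {self.alpha}, Delta = {self.delta} "
            f"(CV error {self.cv_error:.4f})\n"
            f"{self.n_selected_features} features with nonzero scores "
            f"out of {self.means.shape[1]}"
        )


class SCRDA:
    """SCRDA model: construct from data, ``fit()`` tunes (alpha, Delta) by CV."""

    def __init__(
        self,
        X,
        y,
        alpha_grid=DEFAULT_ALPHA_GRID,
        delta_grid=DEFAULT_DELTA_GRID,
        shrink_target: str = "covariance",
        folds: int = 5,
        seed: int = 0,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.alpha_grid = tuple(alpha_grid)
        self.delta_grid = tuple(delta_grid)
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 1]")
        if any(d < 0 for d in self.delta_grid):
            raise ValueError("Delta values must be non-negative")
        self.shrink_target = shrink_target
        self.folds = folds
        self.seed = seed

    def _scores_for(self, X, y, alpha):
        """(classes, means, unshrunk transformed centroids) on one data split."""
        S, means, classes = _pooled_cov(X, y)
        chol = cho_factor(_shrunk_matrix(S, alpha, self.shrink_target), lower=True)
        raw = cho_solve(chol, means.T).T
        return classes, means, raw

    def fit(self) -> SCRDAResults:
        folds = _stratified_folds(self.y, self.folds, self.seed)
        n = len(self.y)
        errs = np.zeros((len(self.alpha_grid), len(self.delta_grid)))
        for tr, va in folds:
            for ai, alpha in enumerate(self.alpha_grid):
                classes, means, raw = self._scores_for(self.X[tr], self.y[tr], alpha)
                for di, delta in enumerate(self.delta_grid):
                    sc = _soft(raw, delta)
                    d = self.X[va] @ sc.T - 0.5 * np.sum(means * sc, axis=1)
                    pred = classes[np.argmax(d, axis=1)]
                    errs[ai, di] += int((pred != self.y[va]).sum())
        errs /= n

        # MIN-MIN: minimal CV error, then fewest nonzero score components on
        # the full training fit; remaining ties -> larger Delta, smaller alpha.
        full = {
            alpha: self._scores_for(self.X, self.y, alpha)
            for alpha in self.alpha_grid
        }
        best = None
        for ai, alpha in enumerate(self.alpha_grid):
            classes, means, raw = full[alpha]
            for di, delta in enumerate(self.delta_grid):
                nz = int((np.abs(_soft(raw, delta)) > 0).sum())
                key = (errs[ai, di], nz, -delta, alpha)
                if best is None or key < best[0]:
                    best = (key, alpha, delta)
        _, alpha, delta = best
        classes, means, raw = full[alpha]
        scores = _soft(raw, delta)
        if not (np.abs(scores) > 0).any():
            logger.warning(
                "all SCRDA score components shrunk to zero; falling back to "
                "the nearest centroid in the shrunken-covariance metric"
            )
            scores = raw
        return SCRDAResults(
            classes=classes,
            means=means,
            scores=scores,
            alpha=alpha,
            delta=delta,
            cv_error=float(errs.min()),
            config={
                "alpha_grid": list(self.alpha_grid),
                "delta_grid": list(self.delta_grid),
                "shrink_target": self.shrink_target,
                "folds": self.folds,
                "seed": self.seed,
            },
        )


def scrda_fit(
    X,
    y,
    alpha_grid=DEFAULT_ALPHA_GRID,
    delta_grid=DEFAULT_DELTA_GRID,
    folds: int = 5,
    seed: int = 0,
    **kwargs,
) -> SCRDAResults:
    """Functional entry point for SCRDA."""
    return SCRDA(
        X, y, alpha_grid=alpha_grid, delta_grid=delta_grid, folds=folds,
        seed=seed, **kwargs,
    ).fit()


def nn_classify(X_train, y_train, X_test, h: int = 3) -> np.ndarray:
    """h-nearest-neighbor majority vote in Euclidean distance.

    Vote ties are broken in favour of the class of the nearest neighbor
    among the tied classes.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train)
    if not 1 <= h <= X_train.shape[0]:
        raise ValueError(f"h must lie in [1, {X_train.shape[0]}]")
    D = cdist(X_test, X_train)
    nearest = np.argsort(D, axis=1, kind="stable")[:, :h]
    out = []
    for row in nearest:
        votes = Counter(y_train[row])
        top = max(votes.values())
        tied = {c for c, v in votes.items() if v == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            out.append(next(y_train[i] for i in row if y_train[i] in tied))
    return np.array(out)


def top_gene_cv_screen(
    X,
    y,
    method,
    grid=DEFAULT_GENE_GRID,
    folds: int = 5,
    seed: int = 0,
    rank_within_folds: bool = True,
) -> int:
    """Choose the number of top-ranked features by cross-validation.

    Features are ranked by |t| (two classes) or ANOVA F; within each CV fold
    the ranking is recomputed on the training part only, so the validation
    samples never influence which features are scored — otherwise the
    selection optimism at small counts biases the chosen m downward.  For
    each count m in ``grid`` the CV misclassification error of ``method`` on
    the top-m features is computed and the m with the smallest error is
    returned, ties going to the smallest m.

    Parameters
    ----------
    method : callable
        ``method(X_train, y_train, X_eval) -> labels``.
    grid : iterable of int
        Candidate counts; values exceeding the feature count are dropped
        with a warning.
    rank_within_folds : bool
        If False, rank once on the full training data and cross-validate
        only the count — the classical shortcut protocol.  Its leakage
        biases the selection toward small counts; the default avoids it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    grid = sorted(set(int(m) for m in grid))
    if any(m > p for m in grid):
        warnings.warn(
            f"gene-count grid truncated to the {p} available features",
            stacklevel=2,
        )
        grid = [m for m in grid if m <= p]
    if not grid:
        raise ValueError("empty gene-count grid")
    fold_indices = _stratified_folds(y, folds, seed)
    global_order = None
    if not rank_within_folds:
        global_order = np.argsort(-feature_ranking_scores(X, y), kind="stable")
    wrong = np.zeros(len(grid))
    for tr, va in fold_indices:
        if global_order is None:
            order = np.argsort(-feature_ranking_scores(X[tr], y[tr]), kind="stable")
        else:
            order = global_order
        Xs_tr, Xs_va = X[tr][:, order], X[va][:, order]
        for i, m in enumerate(grid):
            pred = method(Xs_tr[:, :m], y[tr], Xs_va[:, :m])
            wrong[i] += int((np.asarray(pred) != y[va]).sum())
    # ascending grid: argmin takes the first minimum, i.e. the smallest m
    return grid[int(np.argmin(wrong))]
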