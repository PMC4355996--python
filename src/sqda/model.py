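"""Sparse quadratic discriminant analysis (SQDA) and its diagonal variants.

The procedure, end to end:

1. Rank features by the absolute pooled two-sample t statistic (one-way
   ANOVA F for more than two classes), largest first.
2. Partition the ranked features into consecutive equal-size blocks (default
   100); ranked features that do not fill a final block are dropped.
3. Variable selection by blocks: estimate each block's cross-validated
   misclassification error using a per-block Gaussian rule (sparse covariance
   at a fixed screening lambda of 0.2 for SQDA; diagonal estimators for the
   DLDA2/DQDA2 variants) and keep every block whose error is within
   ``error_margin`` (default 0.05) of the best block.
4. For each retained block, tune the sparsity parameter lambda by
   cross-validation over a grid shared by all classes; among ties the
   smallest lambda wins.
5. The final classifier is quadratic discriminant analysis with, per class,
   a block-diagonal covariance assembled from the penalized correlation
   estimates rescaled by sample variances.

``SQDA``, ``DLDA2`` and ``DQDA2`` are model classes in the statsmodels
mould: construct from data, call ``fit()`` to obtain a results object that
carries the layout, the fitted Gaussian model, diagnostics, ``predict`` and
``summary``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .discriminant import ClassGaussianModel, classify_ml, fit_dlda, fit_dqda
from .sparse_cov import (
    correlation_to_covariance,
    sample_correlation,
    solve_penalized_correlation,
)

__all__ = [
    "BlockLayout",
    "SQDA",
    "DLDA2",
    "DQDA2",
    "SQDAResults",
    "two_sample_t",
    "feature_ranking_scores",
    "make_blocks",
    "select_blocks",
    "fit_sqda",
    "predict_sqda",
]

DEFAULT_LAMBDA_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.5)
ESTIMATOR_KINDS = ("sparse", "diagonal-common", "diagonal-perclass")


def two_sample_t(X: np.ndarray, y) -> np.ndarray:
    """Pooled-variance two-sample t statistic for every feature.

    The sign convention is (mean of first sorted class) minus (mean of the
    second); features are later ranked by absolute value, so the sign only
    matters for interpretation.

    Raises
    ------
    ValueError
        If the labels do not form exactly two classes, a class has fewer
        than 2 samples, or some feature has zero pooled variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"two_sample_t requires exactly 2 classes, got {len(classes)}")
    g1, g2 = X[y == classes[0]], X[y == classes[1]]
    n1, n2 = g1.shape[0], g2.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("each class needs at least 2 samples")
    s2p = ((n1 - 1) * g1.var(axis=0, ddof=1) + (n2 - 1) * g2.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    bad = np.flatnonzero(s2p <= 0)
    if bad.size:
        raise ValueError(f"feature {bad[0]} has zero pooled variance")
    se = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
    return (g1.mean(axis=0) - g2.mean(axis=0)) / se


def feature_ranking_scores(X: np.ndarray, y) -> np.ndarray:
    """Per-feature ranking score: |t| for two classes, ANOVA F otherwise."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) == 2:
        return np.abs(two_sample_t(X, y))
    X = np.asarray(X, dtype=float)
    F, _ = stats.f_oneway(*(X[y == c] for c in classes))
    return np.asarray(F)


@dataclass
class BlockLayout:
    """Ranked feature order partitioned into equal-size blocks.

    ``feature_order`` holds original feature indices sorted by ranking score
    descending (score ties broken by the lower original index); the first
    ``block_size`` entries form block 0, and so on.  Ranked features beyond
    ``n_blocks * block_size`` are dropped — by construction they are the
    least informative.  ``selected`` and ``per_block_cv_error`` are filled
    by :func:`select_blocks`.
    """

    feature_order: np.ndarray
    block_size: int
    n_blocks: int
    selected: np.ndarray | None = None
    per_block_cv_error: np.ndarray | None = None
    scores: np.ndarray | None = field(default=None, repr=False)

    def block_features(self, b: int) -> np.ndarray:
        """Original feature indices of block ``b``."""
        if not 0 <= b < self.n_blocks:
            raise ValueError(f"block index {b} out of range")
        return self.feature_order[b * self.block_size : (b + 1) * self.block_size]

    @property
    def selected_blocks(self) -> np.ndarray:
        if self.selected is None:
            raise ValueError("block selection has not been run")
        return np.flatnonzero(self.selected)

    @property
    def selected_features(self) -> np.ndarray:
        """Original indices of all features in selected blocks, block order."""
        return np.concatenate([self.block_features(b) for b in self.selected_blocks])

    @property
    def n_selected_features(self) -> int:
        return int(self.selected.sum()) * self.block_size


def make_blocks(scores: np.ndarray, block_size: int, top_m: int | None = None) -> BlockLayout:
    """Partition score-ranked features into consecutive equal-size blocks.

    Parameters
    ----------
    scores : ndarray
        Per-feature ranking scores (e.g. |t|); ranked descending, ties broken
        by the lower original index.
    block_size : int
    top_m : int, optional
        Optional pre-screen: keep only the ``top_m`` best-ranked features
        before blocking.
    """
    scores = np.asarray(scores, dtype=float)
    p = scores.shape[0]
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if block_size > p:
        raise ValueError(f"block_size {block_size} exceeds feature count {p}")
    order = np.argsort(-scores, kind="stable")
    if top_m is not None:
        if top_m < block_size:
            raise ValueError("top_m must be at least block_size")
        order = order[:top_m]
    n_blocks = len(order) // block_size
    return BlockLayout(
        feature_order=order[: n_blocks * block_size],
        block_size=block_size,
        n_blocks=n_blocks,
        scores=scores,
    )


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _fit_block_model(
    X: np.ndarray,
    y: np.ndarray,
    estimator_kind: str,
    lam: float,
    tau: float,
    warm: list | None = None,
):
    """Fit a per-block Gaussian model on the given (already-subset) features.

    Returns (model, warm_solutions); warm_solutions is a per-class list of
    penalized-correlation solutions usable as warm starts at a nearby lambda
    (sparse kind only).
    """
    if estimator_kind == "diagonal-common":
        return fit_dlda(X, y), None
    if estimator_kind == "diagonal-perclass":
        return fit_dqda(X, y), None
    if estimator_kind != "sparse":
        raise ValueError(f"unknown estimator kind {estimator_kind!r}")
    classes = np.unique(y)
    means, covs, sols = [], [], []
    for i, c in enumerate(classes):
        g = X[y == c]
        R_hat = sample_correlation(g)
        R0 = warm[i].R_tilde if warm is not None else None
        sol = solve_penalized_correlation(R_hat, lam, tau=tau, R0=R0)
        means.append(g.mean(axis=0))
        covs.append(correlation_to_covariance(sol, g.var(axis=0, ddof=1)).sigma)
        sols.append(sol)
    model = ClassGaussianModel(
        classes, np.vstack(means), kind="full", shared=False, covariances=covs
    )
    return model, sols


def _cv_block_error(
    X: np.ndarray,
    y: np.ndarray,
    feats: np.ndarray,
    fold_indices,
    estimator_kind: str,
    lam: float,
    tau: float,
) -> float:
    """Cross-validated misclassification error of one block's Gaussian rule."""
    Xb = X[:, feats]
    wrong = 0
    for tr, va in fold_indices:
        model, _ = _fit_block_model(Xb[tr], y[tr], estimator_kind, lam, tau)
        wrong += int((classify_ml(model, Xb[va]) != y[va]).sum())
    return wrong / len(y)


def select_blocks(
    X: np.ndarray,
    y,
    layout: BlockLayout,
    error_margin: float = 0.05,
    folds: int = 5,
    seed: int = 0,
    screening_lambda: float = 0.2,
    estimator_kind: str = "sparse",
    tau: float = 1e-4,
) -> BlockLayout:
    """Variable selection by blocks.

    Each block's cross-validated misclassification error is computed with a
    per-block Gaussian rule fitted on that block's features only; blocks with
    error <= (smallest block error + ``error_margin``) are selected, so the
    best block is always kept.
    """
    if not 0.0 <= error_margin <= 0.5:
        raise ValueError("error_margin must lie in [0, 0.5]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold_indices = _stratified_folds(y, folds, seed)
    errs = np.array(
        [
            _cv_block_error(
                X, y, layout.block_features(b), fold_indices, estimator_kind,
                screening_lambda, tau,
            )
            for b in range(layout.n_blocks)
        ]
    )
    layout.per_block_cv_error = errs
    layout.selected = errs <= errs.min() + error_margin
    return layout


class _BlockSelectedModel:
    """Shared machinery for SQDA and the diagonal block variants.

    Subclasses set ``estimator_kind`` — the only difference between SQDA,
    DLDA2 and DQDA2 is which per-block covariance estimator is plugged in.
    """

    estimator_kind: str = "sparse"

    def __init__(
        self,
        X,
        y,
        block_size: int = 100,
        error_margin: float = 0.05,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        folds: int = 5,
        screening_lambda: float = 0.2,
        tau: float = 1e-4,
        top_m: int | None = None,
        seed: int = 0,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.block_size = int(block_size)
        self.error_margin = float(error_margin)
        self.lambda_grid = tuple(sorted(lambda_grid))
        self.folds = int(folds)
        self.screening_lambda = float(screening_lambda)
        self.tau = float(tau)
        self.top_m = top_m
        self.seed = int(seed)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, y, **kwargs) -> "_BlockSelectedModel":
        obj = cls(frame.to_numpy(dtype=float), y, **kwargs)
        obj.feature_names = list(map(str, frame.columns))
        return obj

    @property
    def config(self) -> dict:
        return {
            "estimator_kind": self.estimator_kind,
            "block_size": self.block_size,
            "error_margin": self.error_margin,
            "lambda_grid": list(self.lambda_grid),
            "folds": self.folds,
            "screening_lambda": self.screening_lambda,
            "tau": self.tau,
            "top_m": self.top_m,
            "seed": self.seed,
        }

    def _tune_block_lambda(self, feats: np.ndarray, fold_indices) -> float:
        """Per-block lambda by CV; ties go to the smallest lambda."""
        Xb = self.X[:, feats]
        best_lam, best_err = None, np.inf
        warm_by_fold: dict[int, list] = {}
        for lam in self.lambda_grid:  # ascending, so first strict win = smallest
            wrong = 0
            for fi, (tr, va) in enumerate(fold_indices):
                model, sols = _fit_block_model(
                    Xb[tr], self.y[tr], "sparse", lam, self.tau,
                    warm=warm_by_fold.get(fi),
                )
                warm_by_fold[fi] = sols
                wrong += int((classify_ml(model, Xb[va]) != self.y[va]).sum())
            err = wrong / len(self.y)
            if err < best_err:
                best_err, best_lam = err, lam
        return best_lam

    def fit(self) -> "SQDAResults":
        scores = feature_ranking_scores(self.X, self.y)
        layout = make_blocks(scores, self.block_size, top_m=self.top_m)
        fold_indices = _stratified_folds(self.y, self.folds, self.seed)
        select_blocks(
            self.X,
            self.y,
            layout,
            error_margin=self.error_margin,
            folds=self.folds,
            seed=self.seed,
            screening_lambda=self.screening_lambda,
            estimator_kind=self.estimator_kind,
            tau=self.tau,
        )
        sel = layout.selected_blocks

        lambda_per_block: dict[int, float] = {}
        if self.estimator_kind == "sparse":
            for b in sel:
                lambda_per_block[int(b)] = self._tune_block_lambda(
                    layout.block_features(b), fold_indices
                )

        classes = np.unique(self.y)
        feats = layout.selected_features
        groups = [self.X[self.y == c][:, feats] for c in classes]
        means = np.vstack([g.mean(axis=0) for g in groups])

        if self.estimator_kind == "sparse":
            covs = [[] for _ in classes]
            for j, b in enumerate(sel):
                cols = slice(j * self.block_size, (j + 1) * self.block_size)
                for i, g in enumerate(groups):
                    gb = g[:, cols]
                    sol = solve_penalized_correlation(
                        sample_correlation(gb), lambda_per_block[int(b)], tau=self.tau
                    )
                    covs[i].append(
                        correlation_to_covariance(sol, gb.var(axis=0, ddof=1)).sigma
                    )
            model = ClassGaussianModel(
                classes, means, kind="blocks", shared=False, covariances=covs
            )
        elif self.estimator_kind == "diagonal-common":
            model = fit_dlda(self.X[:, feats], self.y)
        else:
            model = fit_dqda(self.X[:, feats], self.y)

        return SQDAResults(
            layout=layout,
            model=model,
            lambda_per_block=lambda_per_block,
            config=self.config,
        )


class SQDA(_BlockSelectedModel):
    """Sparse quadratic discriminant analysis.

    Per-class block-diagonal covariances, each block estimated by the
    L1-penalized positive-definite correlation fit and rescaled by the
    sample variances.
    """

    estimator_kind = "sparse"


class DLDA2(_BlockSelectedModel):
    """Diagonal LDA combined with variable selection by blocks."""

    estimator_kind = "diagonal-common"


class DQDA2(_BlockSelectedModel):
    """Diagonal QDA combined with variable selection by blocks."""

    estimator_kind = "diagonal-perclass"


@dataclass
class SQDAResults:
    """Fitted block-selected discriminant rule.

    Attributes
    ----------
    layout : BlockLayout
        Feature ranking, blocking, and per-block selection record.
    model : ClassGaussianModel
        The final Gaussian rule on the selected features.
    lambda_per_block : dict
        Chosen sparsity parameter per selected block (sparse estimator only).
    config : dict
        Snapshot of the fitting configuration.
    """

    layout: BlockLayout
    model: ClassGaussianModel
    lambda_per_block: dict
    config: dict

    @property
    def n_selected_features(self) -> int:
        return self.layout.n_selected_features

    def predict(self, X_test) -> np.ndarray:
        """Classify test samples (columns indexed as in the training matrix)."""
        X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
        feats = self.layout.selected_features
        if X_test.shape[1] <= feats.max():
            raise ValueError(
                f"test matrix has {X_test.shape[1]} features but the model "
                f"requires original feature index {feats.max()}"
            )
        return classify_ml(self.model, X_test[:, feats])

    def summary(self) -> str:
        lay = self.layout
        lines = [
            f"{self.config['estimator_kind']} block-selected discriminant rule",
            "-" * 58,
            "classes: " + ", ".join(str(c) for c in self.model.classes),
            f"block size {lay.block_size}, {lay.n_blocks} blocks, "
            f"{int(lay.selected.sum())} selected "
            f"({self.n_selected_features} features)",
            f"error margin {self.config['error_margin']}, "
            f"screening lambda {self.config['screening_lambda']}, "
            f"{self.config['folds']}-fold CV, seed {self.config['seed']}",
            "",
            f"{'block':>5} {'cv error':>9} {'selected':>9} {'lambda':>7}",
        ]
        for b in range(lay.n_blocks):
            lam = self.lambda_per_block.get(b)
            lines.append(
                f"{b:>5} {lay.per_block_cv_error[b]:>9.4f} "
                f"{str(bool(lay.selected[b])):>9} "
                f"{'' if lam is None else f'{lam:.3g}':>7}"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        """Serialize the fitted rule (means, block matrices, layout)."""
        m = self.model
        if m.kind == "blocks":
            covs = [[B.tolist() for B in cov] for cov in m.covariances]
        elif m.shared:
            covs = np.asarray(m.covariances).tolist()
        else:
            covs = [np.asarray(c).tolist() for c in m.covariances]
        doc = {
            "config": self.config,
            "classes": np.asarray(m.classes).tolist(),
            "means": m.means.tolist(),
            "cov_kind": m.kind,
            "cov_shared": m.shared,
            "covariances": covs,
            "layout": {
                "feature_order": self.layout.feature_order.tolist(),
                "block_size": self.layout.block_size,
                "n_blocks": self.layout.n_blocks,
                "selected": self.layout.selected.tolist(),
                "per_block_cv_error": self.layout.per_block_cv_error.tolist(),
            },
            "lambda_per_block": {str(k): v for k, v in self.lambda_per_block.items()},
        }
        return json.dumps(doc)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SQDAResults":
        doc = json.loads(text)
        kind = doc["cov_kind"]
        if kind == "blocks":
            covs = [[np.array(B) for B in cov] for cov in doc["covariances"]]
        elif doc["cov_shared"]:
            covs = np.array(doc["covariances"])
        else:
            covs = [np.array(c) for c in doc["covariances"]]
        model = ClassGaussianModel(
            np.array(doc["classes"]),
            np.array(doc["means"]),
            kind=kind,
            shared=doc["cov_shared"],
            covariances=covs,
        )
        lay = doc["layout"]
        layout = BlockLayout(
            feature_order=np.array(lay["feature_order"], dtype=int),
            block_size=lay["block_size"],
            n_blocks=lay["n_blocks"],
            selected=np.array(lay["selected"], dtype=bool),
            per_block_cv_error=np.array(lay["per_block_cv_error"]),
        )
        return cls(
            layout=layout,
            model=model,
            lambda_per_block={int(k): v for k, v in doc["lambda_per_block"].items()},
            config=doc["config"],
        )

    @classmethod
    def load(cls, path) -> "SQDAResults":
        with open(path) as fh:
            return cls.from_json(fh.read())


#: alias used where the fit is thought of as a standalone object
SQDAFit = SQDAResults


def fit_sqda(
    X,
    y,
    block_size: int = 100,
    error_margin: float = 0.05,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
    **kwargs,
) -> SQDAResults:
    """Functional entry point: fit SQDA with the given configuration."""
    return SQDA(
        X,
        y,
        block_size=block_size,
        error_margin=error_margin,
        lambda_grid=lambda_grid,
        folds=folds,
        seed=seed,
        **kwargs,
    ).fit()


def predict_sqda(fit: SQDAResults, X_test) -> np.ndarray:
    """Classify test samples with a fitted SQDA rule."""
    return fit.predict(X_test)
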