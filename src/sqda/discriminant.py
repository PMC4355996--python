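"""Gaussian maximum-likelihood discriminant rules.

Each class k is modelled as multivariate normal N(mu_k, Sigma_k); a sample is
assigned to the class maximising the log-density (equal priors — the pure
maximum-likelihood rule; ties go to the lowest class index).  Covariances may
be dense (LDA/QDA, small p only), diagonal (DLDA/DQDA), or block-diagonal
(one square matrix per block), in which case the log-density decomposes as a
sum of per-block Gaussian log-densities: log|Sigma| = sum_b log|Sigma_b| and
the quadratic form splits over blocks.

Variance estimators use n_k - 1 degrees of freedom per class; pooled
estimators use sum_k (n_k - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = [
    "ClassGaussianModel",
    "log_density",
    "classify_ml",
    "fit_lda",
    "fit_qda",
    "fit_dlda",
    "fit_dqda",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ClassGaussianModel:
    """Per-class Gaussian parameters with a flexible covariance structure.

    Attributes
    ----------
    classes : ndarray, shape (K,)
        Class labels in sorted order; index order defines tie-breaking.
    means : ndarray, shape (K, p)
    kind : {"full", "diag", "blocks"}
        Dense p x p covariance, per-feature variances, or a list of square
        blocks realising a block-diagonal covariance.
    shared : bool
        If True a single covariance object is shared by all classes
        (LDA-type); otherwise one per class (QDA-type).
    covariances : object
        ``shared``: one covariance object; else a list of K objects.  A
        covariance object is a (p, p) array ("full"), a (p,) variance vector
        ("diag"), or a list of (b_i, b_i) arrays ("blocks").
    """

    classes: np.ndarray
    means: np.ndarray
    kind: str
    shared: bool
    covariances: object
    _factors: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.kind not in ("full", "diag", "blocks"):
            raise ValueError(f"unknown covariance kind {self.kind!r}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def cov_for(self, k: int):
        """Covariance object for class index ``k``."""
        return self.covariances if self.shared else self.covariances[k]

    def blocks_for(self, k: int) -> list[np.ndarray]:
        """Class-``k`` covariance as a list of dense blocks."""
        cov = self.cov_for(k)
        if self.kind == "blocks":
            return list(cov)
        if self.kind == "full":
            return [np.asarray(cov)]
        return [np.asarray(cov)]  # diag: handled separately in scoring

    def dense_covariance(self, k: int) -> np.ndarray:
        """Assemble the full p x p covariance of class ``k`` (small p only)."""
        cov = self.cov_for(k)
        if self.kind == "full":
            return np.asarray(cov, dtype=float)
        if self.kind == "diag":
            return np.diag(np.asarray(cov, dtype=float))
        out = np.zeros((self.n_features, self.n_features))
        i = 0
        for B in cov:
            b = B.shape[0]
            out[i : i + b, i : i + b] = B
            i += b
        return out

    def _factorisation(self, k: int):
        """Cached per-block Cholesky factors and log-determinant."""
        key = 0 if self.shared else k
        if key in self._factors:
            return self._factors[key]
        cov = self.cov_for(k)
        if self.kind == "diag":
            v = np.asarray(cov, dtype=float)
            fac = ("diag", v, float(np.log(v).sum()))
        else:
            blocks = [np.asarray(cov)] if self.kind == "full" else list(cov)
            chols = []
            logdet = 0.0
            for B in blocks:
                try:
                    c = cho_factor(B, lower=True)
                except LinAlgError as err:
                    raise ValueError(
                        "covariance block is not positive definite"
                    ) from err
                chols.append(c)
                logdet += 2.0 * float(np.log(np.diag(c[0])).sum())
            fac = ("chol", chols, logdet)
        self._factors[key] = fac
        return fac

    def log_density_matrix(self, X: np.ndarray) -> np.ndarray:
        """Log-density of every sample under every class: shape (n, K)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        n = X.shape[0]
        p = self.n_features
        out = np.empty((n, self.n_classes))
        for k in range(self.n_classes):
            kind, fac, logdet = self._factorisation(k)
            D = X - self.means[k]
            if kind == "diag":
                q = (D**2 / fac).sum(axis=1)
            else:
                q = np.zeros(n)
                i = 0
                for c in fac:
                    b = c[0].shape[0]
                    Db = D[:, i : i + b]
                    q += (Db * cho_solve(c, Db.T).T).sum(axis=1)
                    i += b
            out[:, k] = -0.5 * (p * _LOG_2PI + logdet + q)
        return out


def log_density(model: ClassGaussianModel, k: int, x: np.ndarray) -> float:
    """Multivariate-normal log-density of ``x`` under class index ``k``."""
    if not 0 <= k < model.n_classes:
        raise ValueError(f"class index {k} out of range")
    return float(model.log_density_matrix(np.atleast_2d(x))[0, k])


def classify_ml(model: ClassGaussianModel, X: np.ndarray) -> np.ndarray:
    """Maximum-likelihood class assignment (equal priors).

    Ties are broken deterministically in favour of the lowest class index.
    """
    scores = model.log_density_matrix(X)
    return model.classes[np.argmax(scores, axis=1)]


def _class_split(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    groups = [X[y == c] for c in classes]
    for c, g in zip(classes, groups):
        if g.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return X, classes, groups


def fit_lda(X, y) -> ClassGaussianModel:
    """Dense LDA: class means with a pooled within-class covariance.

    Only valid when the pooled covariance is invertible (roughly n - K > p);
    use the diagonal or sparse block variants in high dimension.
    """
    X, classes, groups = _class_split(X, y)
    p = X.shape[1]
    means = np.vstack([g.mean(axis=0) for g in groups])
    dof = sum(g.shape[0] - 1 for g in groups)
    S = np.zeros((p, p))
    for g, m in zip(groups, means):
        D = g - m
        S += D.T @ D
    S /= dof
    try:
        cho_factor(S, lower=True)
    except LinAlgError as err:
        raise ValueError(
            "pooled covariance is singular (n too small for dense LDA); "
            "use fit_dlda or the sparse block-diagonal model"
        ) from err
    return ClassGaussianModel(classes, means, kind="full", shared=True, covariances=S)


def fit_qda(X, y) -> ClassGaussianModel:
    """Dense QDA: per-class means and sample covariances (needs n_k > p)."""
    X, classes, groups = _class_split(X, y)
    p = X.shape[1]
    for c, g in zip(classes, groups):
        if g.shape[0] <= p:
            raise ValueError(
                f"class {c!r} has n_k={g.shape[0]} <= p={p}: dense per-class "
                "covariance is singular; use fit_dqda or the sparse "
                "block-diagonal model"
            )
    means = np.vstack([g.mean(axis=0) for g in groups])
    covs = [np.cov(g, rowvar=False, ddof=1).reshape(p, p) for g in groups]
    return ClassGaussianModel(classes, means, kind="full", shared=False, covariances=covs)


def fit_dlda(X, y) -> ClassGaussianModel:
    """Diagonal LDA: pooled per-feature within-class variances."""
    X, classes, groups = _class_split(X, y)
    means = np.vstack([g.mean(axis=0) for g in groups])
    dof = sum(g.shape[0] - 1 for g in groups)
    ss = np.zeros(X.shape[1])
    for g, m in zip(groups, means):
        ss += ((g - m) ** 2).sum(axis=0)
    var = ss / dof
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(f"feature {bad[0]} has zero pooled variance")
    return ClassGaussianModel(classes, means, kind="diag", shared=True, covariances=var)


def fit_dqda(X, y) -> ClassGaussianModel:
    """Diagonal QDA: per-class per-feature variances."""
    X, classes, groups = _class_split(X, y)
    means = np.vstack([g.mean(axis=0) for g in groups])
    variances = []
    for c, g in zip(classes, groups):
        v = g.var(axis=0, ddof=1)
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            raise ValueError(f"feature {bad[0]} has zero variance in class {c!r}")
        variances.append(v)
    return ClassGaussianModel(classes, means, kind="diag", shared=False, covariances=variances)
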