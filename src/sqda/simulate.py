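"""Synthetic gene-expression generator for the four benchmark regimes.

Two classes ("tumor" = 1, "normal" = 2) are drawn from multivariate normals
N(mu_1, Sigma_1) and N(mu_2, Sigma_2).  mu_2 = 0 throughout; the first
``signal_count`` coordinates of mu_1 equal ``mean_shift``.  The regimes:

- ISSC: Sigma_1 = Sigma_2 = I (independent structure, same covariance).
- ISDC: as ISSC but the first ``signal_count`` diagonal entries of Sigma_1
  are ``var_shift`` (different diagonal covariances).
- DSSC: both classes share a block-diagonal correlation structure of
  alternating AR blocks Sigma_rho, Sigma_{-rho}, Sigma_rho, ... with
  (Sigma_rho)_{ij} = rho^{|i-j|} and block dimension ``ar_block``.
- DSDC: as DSSC, except the order of Sigma_rho and Sigma_{-rho} is reversed
  in class 2 for the first two blocks — a rewired covariance that only a
  class-specific (quadratic) rule can exploit.

Reference scale: p = 10,000 features, 50 training and 500 test samples per
class, 400 informative features, mean shift 0.5, variance shift 1.5,
rho = 0.95, AR block dimension 200.  Covariances are block-diagonal in every
regime, so samples are drawn block by block from a per-block Cholesky factor
and a full p x p matrix is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import toeplitz

from .data import LabeledMatrix

__all__ = ["SimulationSpec", "ar_block", "build_sigma", "generate", "SETTINGS"]

SETTINGS = ("ISSC", "ISDC", "DSSC", "DSDC")


@dataclass
class SimulationSpec:
    """One simulation regime with its sizes, shifts and seed."""

    setting: str
    p: int = 10_000
    n_train_per_class: int = 50
    n_test_per_class: int = 500
    signal_count: int = 400
    mean_shift: float = 0.5
    var_shift: float = 1.5
    rho: float = 0.95
    ar_block: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        if not 0 <= self.signal_count <= self.p:
            raise ValueError("signal_count must lie in [0, p]")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.setting in ("DSSC", "DSDC") and self.p % self.ar_block != 0:
            raise ValueError(
                f"ar_block {self.ar_block} must divide p {self.p} for {self.setting}"
            )

    def scaled(self, factor: float, scale_n: bool = True) -> "SimulationSpec":
        """Proportionally scaled-down (or up) copy of this regime.

        Scales p, signal_count and ar_block (and the per-class sample sizes
        unless ``scale_n`` is False); p is rounded to a multiple of the
        scaled AR block so the block structure stays valid.
        """
        ar = max(2, round(self.ar_block * factor))
        p = ar * max(1, round(self.p * factor / ar))
        kw = dict(
            p=p,
            signal_count=min(p, max(1, round(self.signal_count * factor))),
            ar_block=ar,
        )
        if scale_n:
            kw["n_train_per_class"] = max(4, round(self.n_train_per_class * factor))
            kw["n_test_per_class"] = max(4, round(self.n_test_per_class * factor))
        return replace(self, **kw)


def ar_block(dim: int, rho: float) -> np.ndarray:
    """AR correlation matrix: entry (i, j) = rho^|i-j|.

    Symmetric Toeplitz with unit diagonal; positive definite for |rho| < 1.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    return toeplitz(rho ** np.arange(dim))


def _block_dims(p: int, chunk: int) -> list[int]:
    dims = [chunk] * (p // chunk)
    if p % chunk:
        dims.append(p % chunk)
    return dims


def build_sigma(spec: SimulationSpec, class_index: int) -> list[np.ndarray]:
    """Covariance of the given class (1 or 2) as a list of diagonal blocks.

    Blocks of repeated structure share the same array object, so downstream
    Cholesky factors can be cached per distinct block.
    """
    if class_index not in (1, 2):
        raise ValueError("class_index must be 1 or 2")
    p, chunk = spec.p, spec.ar_block
    if spec.setting in ("ISSC", "ISDC"):
        diag = np.ones(p)
        if spec.setting == "ISDC" and class_index == 1:
            diag[: spec.signal_count] = spec.var_shift
        blocks = []
        i = 0
        for d in _block_dims(p, chunk):
            blocks.append(np.diag(diag[i : i + d]))
            i += d
        return blocks

    pos = ar_block(chunk, spec.rho)
    neg = ar_block(chunk, -spec.rho)
    n_blocks = p // chunk
    signs = [pos if b % 2 == 0 else neg for b in range(n_blocks)]
    if spec.setting == "DSDC" and class_index == 2 and n_blocks >= 2:
        signs[0], signs[1] = signs[1], signs[0]
    return signs


def _class_mean(spec: SimulationSpec, class_index: int) -> np.ndarray:
    mu = np.zeros(spec.p)
    if class_index == 1:
        mu[: spec.signal_count] = spec.mean_shift
    return mu


def _sample_class(
    rng: np.random.Generator, n: int, mu: np.ndarray, blocks: list[np.ndarray], chol_cache: dict
) -> np.ndarray:
    X = rng.standard_normal((n, len(mu)))
    i = 0
    for B in blocks:
        d = B.shape[0]
        L = chol_cache.get(id(B))
        if L is None:
            L = np.linalg.cholesky(B)
            chol_cache[id(B)] = L
        X[:, i : i + d] = X[:, i : i + d] @ L.T
        i += d
    return X + mu


def generate(spec: SimulationSpec) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Draw one (train, test) pair for the regime, seeded and reproducible.

    Rows are class 1 ("tumor") first, then class 2 ("normal"); exactly
    ``n_train_per_class`` / ``n_test_per_class`` rows per class.
    """
    rng = np.random.default_rng(spec.seed)
    chol_cache: dict = {}
    parts = {}
    for cls in (1, 2):
        mu = _class_mean(spec, cls)
        blocks = build_sigma(spec, cls)
        parts[("train", cls)] = _sample_class(
            rng, spec.n_train_per_class, mu, blocks, chol_cache
        )
        parts[("test", cls)] = _sample_class(
            rng, spec.n_test_per_class, mu, blocks, chol_cache
        )
    names = [f"g{j}" for j in range(spec.p)]
    train = LabeledMatrix(
        np.vstack([parts[("train", 1)], parts[("train", 2)]]),
        np.repeat([1, 2], spec.n_train_per_class),
        names,
    )
    test = LabeledMatrix(
        np.vstack([parts[("test", 1)], parts[("test", 2)]]),
        np.repeat([1, 2], spec.n_test_per_class),
        names,
    )
    return train, test
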