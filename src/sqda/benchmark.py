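"""Multi-replicate benchmarking of the classifiers on simulated data.

Reproduces the evaluation protocol of the simulation study: for each
replicate a fresh (train, test) pair is generated from the regime; every
method is tuned on the training data and scored by test-set
misclassification; errors are averaged over replicates (mean, SD with n-1
denominator, and the median selected-feature count for methods that select).
All methods see identical datasets within a replicate.

Registered methods: dlda, dqda, nn, svm (top-gene CV screen over 50..2000
step 50), scrda, rf (built-in selection / none), and sqda, dlda2, dqda2
(variable selection by blocks).  svm and rf delegate to scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import (
    DEFAULT_GENE_GRID,
    SCRDA,
    nn_classify,
    top_gene_cv_screen,
)
from .data import LabeledMatrix
from .discriminant import classify_ml, fit_dlda, fit_dqda
from .model import DLDA2, DQDA2, SQDA, feature_ranking_scores
from .simulate import SimulationSpec, generate

__all__ = ["BenchmarkResult", "run_setting", "sweep", "aggregate", "METHODS", "plot_sweep"]

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    """Aggregated performance of one method under one regime."""

    method: str
    setting: str
    errors: list[float]
    mean_error: float
    sd_error: float
    sd_defined: bool
    median_features: float | None
    features: list = field(default_factory=list)
    n_failed: int = 0
    config: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "setting": self.setting,
            "mean_error": self.mean_error,
            "sd_error": self.sd_error,
            "median_features": self.median_features,
            "replicates": len(self.errors),
        }


def aggregate(method: str, setting: str, errors, features, **extra) -> BenchmarkResult:
    """Pure aggregation of per-replicate errors and selected-feature counts."""
    errors = [float(e) for e in errors]
    if not errors:
        raise ValueError("no successful replicates to aggregate")
    sd_defined = len(errors) > 1
    feats = [f for f in features if f is not None]
    return BenchmarkResult(
        method=method,
        setting=setting,
        errors=errors,
        mean_error=float(np.mean(errors)),
        sd_error=float(np.std(errors, ddof=1)) if sd_defined else 0.0,
        sd_defined=sd_defined,
        median_features=float(np.median(feats)) if feats else None,
        features=list(features),
        **extra,
    )


# ---------------------------------------------------------------------------
# method registry: each entry maps (train, test, seed, cfg) -> (error, n_feat)

def _rule_dlda(X_tr, y_tr, X_ev):
    return classify_ml(fit_dlda(X_tr, y_tr), X_ev)


def _rule_dqda(X_tr, y_tr, X_ev):
    return classify_ml(fit_dqda(X_tr, y_tr), X_ev)


def _rule_nn(X_tr, y_tr, X_ev):
    return nn_classify(X_tr, y_tr, X_ev, h=3)


def _rule_svm(X_tr, y_tr, X_ev):
    from sklearn.svm import SVC

    return SVC(kernel="linear").fit(X_tr, y_tr).predict(X_ev)


def _screened(rule):
    def run(train: LabeledMatrix, test: LabeledMatrix, seed: int, cfg: dict):
        grid = cfg.get("gene_grid", DEFAULT_GENE_GRID)
        folds = cfg.get("folds", 5)
        m = top_gene_cv_screen(train.X, train.y, rule, grid=grid, folds=folds, seed=seed)
        order = np.argsort(-feature_ranking_scores(train.X, train.y), kind="stable")
        top = order[:m]
        pred = rule(train.X[:, top], train.y, test.X[:, top])
        return float((pred != test.y).mean()), m

    return run


def _block_method(cls):
    def run(train: LabeledMatrix, test: LabeledMatrix, seed: int, cfg: dict):
        res = cls(
            train.X,
            train.y,
            block_size=cfg.get("block_size", 100),
            error_margin=cfg.get("error_margin", 0.05),
            folds=cfg.get("folds", 5),
            seed=seed,
        ).fit()
        pred = res.predict(test.X)
        return float((pred != test.y).mean()), res.n_selected_features

    return run


def _scrda(train: LabeledMatrix, test: LabeledMatrix, seed: int, cfg: dict):
    res = SCRDA(train.X, train.y, folds=cfg.get("folds", 5), seed=seed).fit()
    pred = res.predict(test.X)
    return float((pred != test.y).mean()), res.n_selected_features


def _rf(train: LabeledMatrix, test: LabeledMatrix, seed: int, cfg: dict):
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(n_estimators=500, random_state=seed)
    clf.fit(train.X, train.y)
    return float((clf.predict(test.X) != test.y).mean()), None


METHODS = {
    "dlda": _screened(_rule_dlda),
    "dqda": _screened(_rule_dqda),
    "nn": _screened(_rule_nn),
    "svm": _screened(_rule_svm),
    "scrda": _scrda,
    "rf": _rf,
    "sqda": _block_method(SQDA),
    "dlda2": _block_method(DLDA2),
    "dqda2": _block_method(DQDA2),
}


def _replicate_seeds(seed: int, replicates: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(replicates) % (2**31)


def run_setting(
    spec: SimulationSpec,
    methods,
    replicates: int = 10,
    seed: int = 0,
    **cfg,
) -> dict[str, BenchmarkResult]:
    """Benchmark the given methods on ``replicates`` fresh datasets.

    Per replicate, one dataset is generated with a seed derived from
    ``seed`` and shared by every method.  A method failing on a replicate is
    logged and excluded from its aggregation.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; available: {sorted(METHODS)}")
    seeds = _replicate_seeds(seed, replicates)
    errors = {m: [] for m in methods}
    features = {m: [] for m in methods}
    failed = {m: 0 for m in methods}
    for r, s in enumerate(seeds):
        data_spec = SimulationSpec(**{**spec.__dict__, "seed": int(s)})
        train, test = generate(data_spec)
        for m in methods:
            try:
                err, feat = METHODS[m](train, test, int(s), cfg)
            except Exception:  # noqa: BLE001 - a failing method must not sink the run
                failed[m] += 1
                logger.exception("method %s failed on replicate %d", m, r)
                continue
            errors[m].append(err)
            features[m].append(feat)
    for m, k in failed.items():
        if k:
            logger.warning("method %s failed on %d/%d replicates", m, k, replicates)
    return {
        m: aggregate(
            m, spec.setting, errors[m], features[m], n_failed=failed[m], config=dict(cfg)
        )
        for m in methods
    }


SWEEPABLE = ("block_size", "error_margin", "n_train_per_class")


def sweep(
    spec: SimulationSpec,
    parameter: str,
    values,
    method: str = "sqda",
    replicates: int = 5,
    seed: int = 0,
    **cfg,
) -> pd.DataFrame:
    """Mean error of one method as a function of one tuning parameter.

    ``parameter`` is ``block_size`` or ``error_margin`` (classifier knobs) or
    ``n_train_per_class`` (a data knob).  Returns a long-format table with
    one row per swept value.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"parameter must be one of {SWEEPABLE}")
    rows = []
    for v in values:
        if parameter == "n_train_per_class":
            sp = SimulationSpec(**{**spec.__dict__, "n_train_per_class": int(v)})
            res = run_setting(sp, [method], replicates=replicates, seed=seed, **cfg)
        else:
            res = run_setting(
                spec, [method], replicates=replicates, seed=seed, **{**cfg, parameter: v}
            )
        row = res[method].as_row()
        row[parameter] = v
        rows.append(row)
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, parameter: str, ax=None):
    """Line plot of mean error against a swept parameter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table[parameter], table["mean_error"], marker="o")
    ax.set_xlabel(parameter)
    ax.set_ylabel("mean test misclassification rate")
    ax.set_title(f"{table['method'].iloc[0]} on {table['setting'].iloc[0]}")
    return ax
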