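"""Cross-validated classification error of selected gene subsets.

Estimates, for each (method, k) gene subset, the average misclassification
rate of a Random Forest and a K-nearest-neighbour classifier (Euclidean
distance) under repeated stratified k-fold cross-validation.  Two selection
timings are supported:

* ``pre_cv`` (default): genes are selected once on the full dataset and
  the classifier is cross-validated on that fixed subset.  This mirrors
  the common filter-then-evaluate protocol but is optimistically biased,
  because the test folds influenced the selection.
* ``nested``: genes are re-selected inside each training fold, giving an
  unbiased error estimate at extra cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .dataset import ExpressionDataset
from .scores import ScoreConfig, score_all
from .selection import SelectionResult, select_top_k

__all__ = ["EvalConfig", "ErrorReport", "cv_error", "error_grid", "CLASSIFIERS"]

CLASSIFIERS = ("rf", "knn")


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation and classifier settings.

    classifier
        ``"rf"`` (Random Forest) or ``"knn"`` (K-nearest neighbours,
        Euclidean distance, majority vote).
    knn_neighbors
        Neighbour count for K-NN (default 3).
    rf_trees
        Number of trees in the forest (default 500).
    cv_folds, cv_repeats
        Stratified k-fold scheme: ``cv_folds`` folds repeated
        ``cv_repeats`` times with re-shuffling (defaults 5 x 10).
    seed
        Seeds both the fold shuffling and the forest; a fixed seed makes
        the whole report reproducible (K-NN exactly across platforms, RF
        within one environment).
    selection_mode
        ``"pre_cv"`` or ``"nested"`` (see module docstring).
    standardize
        Per-gene z-scoring using training-fold statistics only (off by
        default).
    """

    classifier: str = "rf"
    knn_neighbors: int = 3
    rf_trees: int = 500
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0
    selection_mode: str = "pre_cv"
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; valid: {list(CLASSIFIERS)}"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1 or self.knn_neighbors < 1 or self.rf_trees < 1:
            raise ValueError("cv_repeats, knn_neighbors and rf_trees must be positive")
        if self.selection_mode not in ("pre_cv", "nested"):
            raise ValueError(
                f"unknown selection_mode {self.selection_mode!r}; valid: pre_cv, nested"
            )


@dataclass(frozen=True)
class ErrorReport:
    """Rows of (method, k, classifier, mean_error, sd_error, n_folds_total)."""

    table: pd.DataFrame

    COLUMNS = ("method", "k", "classifier", "mean_error", "sd_error", "n_folds_total")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ErrorReport missing columns {missing}")

    def to_csv(self, path_or_buf=None, sep: str = ","):
        return self.table.to_csv(path_or_buf, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, sep: str = ",") -> "ErrorReport":
        return cls(table=pd.read_csv(path_or_buf, sep=sep))

    def round_trip(self) -> "ErrorReport":
        return ErrorReport.from_csv(StringIO(self.to_csv()))

    def pivot(self, classifier: str) -> pd.DataFrame:
        """Wide layout: rows = k, columns = method, one classifier."""
        sub = self.table[self.table["classifier"] == classifier]
        return sub.pivot(index="k", columns="method", values="mean_error")


def _make_classifier(config: EvalConfig, seed: int):
    if config.classifier == "rf":
        return RandomForestClassifier(n_estimators=config.rf_trees, random_state=seed)
    return KNeighborsClassifier(n_neighbors=config.knn_neighbors, metric="euclidean")


def cv_error(
    data: ExpressionDataset,
    genes: Sequence[str] | None,
    config: EvalConfig,
    method: str | None = None,
    k: int | None = None,
) -> tuple[float, float]:
    """Mean and SD of per-fold misclassification over the CV grid.

    With ``selection_mode="pre_cv"`` the fixed gene list ``genes`` is
    evaluated.  With ``"nested"``, ``method`` and ``k`` must be given and
    genes are re-selected on each training fold.  Deterministic given
    ``config.seed``.
    """
    n0, n1 = data.class_sizes
    if min(n0, n1) < config.cv_folds:
        raise ValueError(
            f"stratified {config.cv_folds}-fold CV needs >= {config.cv_folds} samples "
            f"per class; have ({n0}, {n1})"
        )
    if config.selection_mode == "nested":
        if method is None or k is None:
            raise ValueError("nested selection requires method and k")
    else:
        if genes is None or len(genes) == 0:
            raise ValueError("empty gene list")
        data_sel = data.subset_genes(genes)

    y = data.labels
    splitter = RepeatedStratifiedKFold(
        n_splits=config.cv_folds, n_repeats=config.cv_repeats, random_state=config.seed
    )
    errors = []
    for train, test in splitter.split(data.values, y):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError("a CV fold lost a class; data too small for this config")
        if config.selection_mode == "nested":
            train_ds = data.subset_samples(train)
            fold_table = score_all(train_ds, ScoreConfig())
            fold_genes = select_top_k(fold_table, method, k).gene_ids
            x = data.subset_genes(fold_genes).values
        else:
            x = data_sel.values
        x_train, x_test = x[train], x[test]
        if config.standardize:
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            x_train = (x_train - mu) / sd
            x_test = (x_test - mu) / sd
        clf = _make_classifier(config, seed=config.seed)
        clf.fit(x_train, y[train])
        errors.append(float(np.mean(clf.predict(x_test) != y[test])))
    errors = np.asarray(errors)
    sd = float(errors.std(ddof=1)) if len(errors) > 1 else 0.0
    return float(errors.mean()), sd


def error_grid(
    data: ExpressionDataset,
    selections: Sequence[SelectionResult],
    config: EvalConfig,
    classifiers: Sequence[str] = CLASSIFIERS,
) -> ErrorReport:
    """Drive :func:`cv_error` over selections x classifiers.

    One row per (selection, classifier), selections-major.  Errors from
    individual cells are re-raised with the offending row identified.
    """
    if not selections:
        raise ValueError("selections must be non-empty")
    rows = []
    n_total = config.cv_folds * config.cv_repeats
    for sel in selections:
        for cl in classifiers:
            cfg = replace(config, classifier=cl)
            try:
                mean_err, sd_err = cv_error(
                    data, sel.gene_ids, cfg, method=sel.method, k=sel.k
                )
            except Exception as exc:
                raise RuntimeError(
                    f"cv_error failed for method={sel.method} k={sel.k} classifier={cl}: {exc}"
                ) from exc
            rows.append(
                {
                    "method": sel.method,
                    "k": sel.k,
                    "classifier": cl,
                    "mean_error": mean_err,
                    "sd_error": sd_err,
                    "n_folds_total": n_total,
                }
            )
    return ErrorReport(table=pd.DataFrame(rows, columns=list(ErrorReport.COLUMNS)))
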