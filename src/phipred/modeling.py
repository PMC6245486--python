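"""Grid-searched, cross-validated classification and evaluation.

Four classifier families are explored over the candidate datasets with
10-fold stratified cross-validation: k-nearest neighbours, random forests,
RBF-kernel SVMs and single-hidden-layer neural networks (sigmoid
activations, SGD with momentum). Features are standardized per fold using
training-fold statistics only.

Two phases: an exploration phase runs the full dataset x method x
parameter grid; a refinement phase extends the network's hidden-layer
sweep on a selected subset of datasets. The configuration selected on
validation F1 is finally evaluated by letting the 10 fold-models predict
the held-out test set and averaging their metrics.

Fold assignment is stratified by label; an optional group-aware mode keeps
all replicates of a distinct pair inside one fold, which removes the
replicate-leakage inflation that memorizing methods (k-NN, RF) otherwise
enjoy on oversampled corpora.
"""

from __future__ import annotations

import csv
import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

KNN = "knn"
RF = "rf"
SVM = "svm"
ANN = "ann"

METRIC_NAMES = ("accuracy", "f1", "sensitivity", "specificity")

#: datasets carried into the refinement phase by default
DEFAULT_REFINEMENT_DATASETS = ("SB1e-06", "NBN50", "NB50", "CH")


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass
class ModelGrid:
    """One method plus named lists of parameter values to sweep."""

    method: str
    parameters: dict[str, list]

    def __post_init__(self) -> None:
        if self.method not in (KNN, RF, SVM, ANN):
            raise ValueError(f"unknown method {self.method!r}")
        for name, values in self.parameters.items():
            if not values:
                raise ValueError(f"empty value list for parameter {name!r}")

    def points(self) -> list[dict]:
        """The Cartesian product of parameter values, in listed order."""
        names = list(self.parameters)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.parameters[n] for n in names))
        ]


def exploration_grids() -> list[ModelGrid]:
    """The exploration-phase grids for all four methods."""
    return [
        ModelGrid(KNN, {"k": list(range(1, 10))}),
        ModelGrid(RF, {"n_trees": [10**2, 10**3, 10**4], "leaf_size": [2, 3, 4]}),
        ModelGrid(SVM, {
            "penalty": [10.0**e for e in range(4, -3, -1)],
            "kernel_width": [10.0**e for e in range(-4, 5)],
        }),
        ModelGrid(ANN, {
            "n_neurons": [2, 3, 4, 5, 6],
            "epochs": [10, 25, 50, 75, 100],
            "momentum": [0.1, 0.4, 0.7],
            "learning_rate": [1e-4],
        }),
    ]


def refinement_grid() -> ModelGrid:
    """The refinement-phase grid: networks only, deeper hidden-layer sweep."""
    return ModelGrid(ANN, {
        "n_neurons": [7, 8, 9, 10],
        "epochs": [10, 25, 50, 75, 100],
        "momentum": [0.1, 0.4, 0.7],
        "learning_rate": [1e-4],
    })


def make_estimator(method: str, params: Mapping, seed: int = 0):
    """Instantiate a classifier for one grid point."""
    if method == KNN:
        return KNeighborsClassifier(n_neighbors=int(params["k"]))
    if method == RF:
        return RandomForestClassifier(
            n_estimators=int(params["n_trees"]),
            min_samples_leaf=int(params["leaf_size"]),
            random_state=seed,
        )
    if method == SVM:
        return SVC(C=params["penalty"], kernel="rbf", gamma=params["kernel_width"])
    if method == ANN:
        return MLPClassifier(
            hidden_layer_sizes=(int(params["n_neurons"]),),
            activation="logistic",
            solver="sgd",
            momentum=params["momentum"],
            nesterovs_momentum=False,
            learning_rate_init=params.get("learning_rate", 1e-4),
            max_iter=int(params["epochs"]),
            random_state=seed,
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, F1, sensitivity and specificity from confusion counts.

    Undefined denominators yield 0 with a warning.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("no observations")

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reporting 0", name)
            return 0.0
        return num / den

    return {
        "accuracy": (tp + tn) / total,
        "f1": safe(2 * tp, 2 * tp + fp + fn, "f1"),
        "sensitivity": safe(tp, tp + fn, "sensitivity"),
        "specificity": safe(tn, tn + fp, "specificity"),
    }


@dataclass
class EvalReport:
    """Per-fold and mean metrics for one (dataset, method, parameters)."""

    dataset_name: str
    method: str
    parameters: dict
    fold_metrics: list[dict[str, float]]
    mean_metrics: dict[str, float]
    split: str = "validation"

    def param_key(self) -> tuple:
        return tuple(self.parameters[k] for k in sorted(self.parameters))


def _mean_metrics(fold_metrics: Sequence[Mapping[str, float]]) -> dict[str, float]:
    return {
        m: float(np.mean([fm[m] for fm in fold_metrics])) for m in METRIC_NAMES
    }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    params: Mapping,
    folds: int = 10,
    seed: int = 0,
    groups: Sequence | None = None,
    dataset_name: str = "",
    return_models: bool = False,
):
    """Stratified k-fold cross-validation of one grid point.

    ``groups`` switches to group-aware folding (replicates of one pair stay
    in a single fold). Features are standardized per fold on training-fold
    statistics only. Returns an :class:`EvalReport`; with
    ``return_models=True``, also the list of fitted ``(scaler, estimator)``
    per fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(X) < folds:
        raise ValueError(f"{len(X)} rows cannot fill {folds} folds")
    if len(np.unique(y)) < 2:
        raise ValueError("need both labels for cross-validation")

    seeds = np.random.SeedSequence(seed).generate_state(folds + 1)
    if groups is not None:
        splitter = StratifiedGroupKFold(
            n_splits=folds, shuffle=True, random_state=int(seeds[0] % 2**31)
        )
        split_iter = splitter.split(X, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(seeds[0] % 2**31)
        )
        split_iter = splitter.split(X, y)

    fold_metrics: list[dict[str, float]] = []
    models = []
    for i, (train_idx, val_idx) in enumerate(split_iter):
        scaler = StandardScaler().fit(X[train_idx])
        est = make_estimator(method, params, seed=int(seeds[i + 1] % 2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(scaler.transform(X[train_idx]), y[train_idx])
        pred = est.predict(scaler.transform(X[val_idx]))
        fold_metrics.append(compute_metrics(*_confusion(y[val_idx], pred)))
        if return_models:
            models.append((scaler, est))

    report = EvalReport(
        dataset_name=dataset_name,
        method=method,
        parameters=dict(params),
        fold_metrics=fold_metrics,
        mean_metrics=_mean_metrics(fold_metrics),
    )
    return (report, models) if return_models else report


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------

def explore(
    datasets: Mapping[str, tuple[np.ndarray, np.ndarray]],
    grids: Sequence[ModelGrid],
    folds: int = 10,
    seed: int = 0,
    groups: Mapping[str, Sequence] | None = None,
) -> list[EvalReport]:
    """Cross-validate the full datasets x methods x grid-points product."""
    reports: list[EvalReport] = []
    for name in sorted(datasets):
        X, y = datasets[name]
        for grid in grids:
            for params in grid.points():
                reports.append(cross_validate(
                    X, y, grid.method, params,
                    folds=folds, seed=seed,
                    groups=groups.get(name) if groups else None,
                    dataset_name=name,
                ))
    reports.sort(key=lambda r: (r.dataset_name, r.method, r.param_key()))
    return reports


def refine(
    datasets: Mapping[str, tuple[np.ndarray, np.ndarray]],
    folds: int = 10,
    seed: int = 0,
    grid: ModelGrid | None = None,
) -> list[EvalReport]:
    """Refinement phase: the extended network grid on selected datasets."""
    return explore(datasets, [grid or refinement_grid()], folds=folds, seed=seed)


def _model_complexity(report: EvalReport) -> float:
    p = report.parameters
    if report.method == KNN:
        return -p["k"]  # larger k = smoother = preferred on ties
    if report.method == RF:
        return p["n_trees"]
    if report.method == SVM:
        return p["penalty"]
    return p["n_neurons"]


def select_best(reports: Sequence[EvalReport]) -> EvalReport:
    """Highest mean validation F1; ties by accuracy, then smaller model."""
    if not reports:
        raise ValueError("no reports to select from")
    return max(
        reports,
        key=lambda r: (
            r.mean_metrics["f1"],
            r.mean_metrics["accuracy"],
            -_model_complexity(r),
        ),
    )


def final_evaluate(
    method: str,
    params: Mapping,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    folds: int = 10,
    seed: int = 0,
    dataset_name: str = "",
) -> EvalReport:
    """Evaluate the selected configuration on the held-out test set.

    The ``folds`` models fitted during cross-validation on the training
    matrix each predict the test set; reported metrics are their mean.
    """
    X_train, y_train = train
    X_test, y_test = test
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError(
            f"feature-length mismatch: train has {X_train.shape[1]}, test "
            f"has {X_test.shape[1]}"
        )
    _, models = cross_validate(
        X_train, y_train, method, params,
        folds=folds, seed=seed, dataset_name=dataset_name, return_models=True,
    )
    fold_metrics = []
    for scaler, est in models:
        pred = est.predict(scaler.transform(X_test))
        fold_metrics.append(compute_metrics(*_confusion(np.asarray(y_test), pred)))
    return EvalReport(
        dataset_name=dataset_name,
        method=method,
        parameters=dict(params),
        fold_metrics=fold_metrics,
        mean_metrics=_mean_metrics(fold_metrics),
        split="test",
    )


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------

def _config_label(report: EvalReport) -> str:
    inner = ",".join(f"{k}={report.parameters[k]}" for k in report.parameters)
    return f"{report.method}({inner})"


def export_result_matrix(
    reports: Sequence[EvalReport], metric: str, path: str | Path
) -> None:
    """Write a datasets x configurations CSV of one metric."""
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    splits = {r.split for r in reports}
    if len(splits) > 1:
        raise ValueError(f"reports mix splits {sorted(splits)}")
    columns: list[str] = []
    rows: dict[str, dict[str, float]] = {}
    for r in reports:
        col = _config_label(r)
        if col not in columns:
            columns.append(col)
        cell = rows.setdefault(r.dataset_name, {})
        if col in cell:
            raise ValueError(f"duplicate report for ({r.dataset_name!r}, {col!r})")
        cell[col] = r.mean_metrics[metric]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dataset"] + columns)
        for name in rows:
            line: list = [name]
            for col in columns:
                if col in rows[name]:
                    line.append(repr(rows[name][col]))
                else:
                    logger.warning("missing cell (%s, %s)", name, col)
                    line.append("")
            writer.writerow(line)


def read_result_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a result-matrix CSV back as (datasets, configs, values)."""
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        configs = header[1:]
        names: list[str] = []
        values: list[list[float]] = []
        for rec in reader:
            names.append(rec[0])
            values.append([float(v) if v else np.nan for v in rec[1:]])
    return names, configs, np.array(values)


def export_reports_csv(reports: Sequence[EvalReport], path: str | Path) -> None:
    """Tidy CSV: one row per report per fold."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["dataset", "method", "parameters", "split", "fold"] + list(METRIC_NAMES)
        )
        for r in reports:
            pstr = ";".join(f"{k}={v}" for k, v in r.parameters.items())
            for i, fm in enumerate(r.fold_metrics):
                writer.writerow(
                    [r.dataset_name, r.method, pstr, r.split, i]
                    + [repr(fm[m]) for m in METRIC_NAMES]
                )
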