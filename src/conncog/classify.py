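"""Balanced-ensemble SVM classification of subjects from nodal graph metrics.

Protocol:

1. Feature selection keeps only (metric, node) pairs significant at corrected
   p < alpha in BOTH group contrasts (CP vs HV and CI vs CP).
2. Class imbalance is handled by building many instances (default 100), each
   keeping the minority class whole and randomly undersampling the majority
   class to equal size; for the patients-vs-HV task the patient subsample is
   stratified over CP/CI in cohort proportion (largest-remainder rounding).
3. Each instance is evaluated by stratified k-fold cross-validation (k = 10).
   Within each outer training fold, (C, gamma) of an RBF SVM are grid-searched
   over growing dyadic sequences by inner cross-validation, with features
   z-scored on training data only. Fold confusion counts are pooled into
   accuracy, sensitivity, specificity and F1 (percent).
4. Performance is summarised as mean +/- SD over instances; feature weights
   come from companion linear-kernel SVMs fitted per instance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graphmetrics import NodeMetricTable

__all__ = [
    "TASKS",
    "FEATURE_SETS",
    "ClassificationTask",
    "InstanceResult",
    "PerformanceSummary",
    "ClassifyError",
    "FeatureSelectionError",
    "default_c_grid",
    "default_gamma_grid",
    "select_features",
    "build_instances",
    "grid_search_svm",
    "run_cv",
    "aggregate_performance",
    "feature_weights",
    "feature_matrix",
    "run_task",
]

TASKS = ("ms_vs_hv", "ci_vs_cp")
FEATURE_SETS = ("LE", "NS", "LE+NS")
_FEATURE_SET_METRICS = {
    "LE": ("local_efficiency",),
    "NS": ("strength",),
    "LE+NS": ("local_efficiency", "strength"),
}


class ClassifyError(ValueError):
    """Invalid classification input."""


class FeatureSelectionError(ClassifyError):
    """No feature survived the significance filter."""


def default_c_grid() -> np.ndarray:
    """Growing dyadic sequence for C: 2^-5, 2^-3, ..., 2^15."""
    return 2.0 ** np.arange(-5, 16, 2, dtype=float)


def default_gamma_grid() -> np.ndarray:
    """Growing dyadic sequence for gamma: 2^-15, 2^-13, ..., 2^3."""
    return 2.0 ** np.arange(-15, 4, 2, dtype=float)


@dataclass
class ClassificationTask:
    name: str                     # ms_vs_hv | ci_vs_cp
    positive_class: str           # MS for task 1, CI for task 2
    feature_set: str              # LE | NS | LE+NS
    selected_features: list[tuple[str, str]]  # (metric, node) pairs

    def __post_init__(self) -> None:
        if self.name not in TASKS:
            raise ClassifyError(f"unknown task '{self.name}'")
        if self.feature_set not in FEATURE_SETS:
            raise ClassifyError(f"unknown feature set '{self.feature_set}'")
        if not self.selected_features:
            raise FeatureSelectionError("selected_features must be non-empty")


@dataclass
class InstanceResult:
    instance_id: int
    fold_params: list[tuple[float, float]]      # (C, gamma) chosen per fold
    fold_scaler_means: list[np.ndarray] = field(repr=False, default_factory=list)
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # TP, FP, TN, FN
    accuracy: float = 0.0
    sensitivity: float = 0.0
    specificity: float = 0.0
    f1: float = 0.0


@dataclass
class PerformanceSummary:
    task: str
    feature_set: str
    n_features: int
    n_instances: int
    mean: dict[str, float]
    sd: dict[str, float]

    def display(self) -> str:
        parts = [
            f"{k.capitalize()} {self.mean[k]:.2f} ± {self.sd[k]:.2f}"
            for k in ("accuracy", "sensitivity", "specificity", "f1")
        ]
        return (
            f"{self.task} [{self.feature_set}] ({self.n_features} features, "
            f"{self.n_instances} instances): " + "; ".join(parts)
        )

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "feature_set": self.feature_set,
            "n_features": self.n_features,
            "n_instances": self.n_instances,
            "mean": {k: round(v, 6) for k, v in self.mean.items()},
            "sd": {k: round(v, 6) for k, v in self.sd.items()},
        }


# -- feature selection ------------------------------------------------------


def select_features(
    stats_df: pd.DataFrame, feature_set: str, alpha: float = 0.05
) -> list[tuple[str, str]]:
    """(metric, node) pairs significant in BOTH contrasts at corrected p < alpha."""
    if feature_set not in _FEATURE_SET_METRICS:
        raise ClassifyError(f"unknown feature set '{feature_set}'")
    selected: list[tuple[str, str]] = []
    for metric in _FEATURE_SET_METRICS[feature_set]:
        sub = stats_df[stats_df["metric"] == metric]
        nodes_both = None
        for contrast in ("CP-HV", "CI-CP"):
            sig = set(
                sub[(sub["contrast"] == contrast) & (sub["corrected_p"] < alpha)][
                    "node"
                ]
            )
            nodes_both = sig if nodes_both is None else (nodes_both & sig)
        node_order = list(dict.fromkeys(sub["node"]))
        selected.extend((metric, node) for node in node_order if node in (nodes_both or set()))
    if not selected:
        raise FeatureSelectionError(
            f"no node passed corrected p < {alpha} in both contrasts for "
            f"feature set {feature_set}; relax alpha or increase the effect size"
        )
    return selected


# -- balanced instances -----------------------------------------------------


def _largest_remainder(targets: Sequence[float], total: int) -> list[int]:
    floors = [int(np.floor(t)) for t in targets]
    remainder = total - sum(floors)
    order = sorted(
        range(len(targets)),
        key=lambda i: (-(targets[i] - floors[i]), -targets[i], i),
    )
    for i in order[:remainder]:
        floors[i] += 1
    return floors


def build_instances(
    subjects_df: pd.DataFrame,
    task: str,
    n_instances: int = 100,
    seed: int = 0,
) -> list[pd.Index]:
    """Index lists of balanced instances by random undersampling.

    The minority class is kept whole; the majority class is subsampled
    without replacement to the minority size. For ``ms_vs_hv`` the patient
    subsample is stratified over CP/CI in proportion to their cohort counts
    (largest-remainder rounding). Deterministic given ``seed``.
    """
    if task not in TASKS:
        raise ClassifyError(f"unknown task '{task}'")
    rng = np.random.default_rng(seed)
    df = subjects_df.reset_index(drop=True)
    if task == "ms_vs_hv":
        minority = df.index[df["group"] == "HV"]
        strata = {
            g: df.index[df["group"] == g].to_numpy() for g in ("CP", "CI")
        }
        majority_n = sum(len(v) for v in strata.values())
    else:
        cp = df.index[df["group"] == "CP"].to_numpy()
        ci = df.index[df["group"] == "CI"].to_numpy()
        if len(ci) <= len(cp):
            minority, strata = pd.Index(ci), {"CP": cp}
        else:
            minority, strata = pd.Index(cp), {"CI": ci}
        majority_n = sum(len(v) for v in strata.values())
    if len(minority) == 0 or majority_n == 0:
        raise ClassifyError(f"task {task}: one of the classes is empty")
    if len(minority) > majority_n:
        raise ClassifyError(
            f"task {task}: minority class ({len(minority)}) larger than "
            f"majority ({majority_n})"
        )

    n_draw = len(minority)
    names = sorted(strata, key=lambda g: (-len(strata[g]), g))
    quotas = _largest_remainder(
        [n_draw * len(strata[g]) / majority_n for g in names], n_draw
    )
    instances = []
    for _ in range(n_instances):
        picked = [minority.to_numpy()]
        for g, q in zip(names, quotas):
            picked.append(rng.choice(strata[g], size=q, replace=False))
        instances.append(pd.Index(np.sort(np.concatenate(picked))))
    return instances


# -- SVM training -----------------------------------------------------------


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ClassifyError("training labels contain a single class")


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """(C, gamma) maximising mean stratified k-fold CV accuracy of an RBF SVM.

    Features are z-scored on each training fold only. Ties are broken toward
    smaller C, then smaller gamma. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    C_grid = np.sort(np.asarray(C_grid if C_grid is not None else default_c_grid()))
    gamma_grid = np.sort(
        np.asarray(gamma_grid if gamma_grid is not None else default_gamma_grid())
    )
    k_eff = min(k, int(np.bincount(pd.factorize(y)[0]).min()))
    if k_eff < 2:
        raise ClassifyError("a class has too few members for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        folds.append(
            (scaler.transform(X[tr]), y[tr], scaler.transform(X[te]), y[te])
        )
    best = (-1.0, None, None)
    for C in C_grid:
        for gamma in gamma_grid:
            correct = total = 0
            for Xtr, ytr, Xte, yte in folds:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(Xtr, ytr)
                correct += int((clf.predict(Xte) == yte).sum())
                total += len(yte)
            acc = correct / total
            if acc > best[0]:
                best = (acc, C, gamma)
    return float(best[1]), float(best[2])


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    positive_class,
    k: int = 10,
    seed: int = 0,
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    inner_k: int = 10,
    instance_id: int = 0,
) -> InstanceResult:
    """Stratified k-fold evaluation of one balanced instance.

    Per outer fold: grid-search (C, gamma) by inner CV on the training fold,
    z-score on the training fold, fit the RBF SVM and predict the held-out
    fold. Confusion counts are pooled over folds before computing the four
    indicators (percent).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    fold_params: list[tuple[float, float]] = []
    fold_means: list[np.ndarray] = []
    for fold_i, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[te])) < 2 and len(te) > 1:
            # stratification keeps both classes per fold whenever possible
            pass
        C, gamma = grid_search_svm(
            X[tr], y[tr], C_grid, gamma_grid, k=inner_k, seed=seed + 1000 + fold_i
        )
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(scaler.transform(X[tr]), y[tr])
        pred = clf.predict(scaler.transform(X[te]))
        pos = y[te] == positive_class
        tp += int(((pred == positive_class) & pos).sum())
        fn += int(((pred != positive_class) & pos).sum())
        fp += int(((pred == positive_class) & ~pos).sum())
        tn += int(((pred != positive_class) & ~pos).sum())
        fold_params.append((C, gamma))
        fold_means.append(scaler.mean_.copy())
    total = tp + fp + tn + fn
    res = InstanceResult(
        instance_id=instance_id,
        fold_params=fold_params,
        fold_scaler_means=fold_means,
        confusion=(tp, fp, tn, fn),
    )
    res.accuracy = 100.0 * (tp + tn) / total
    res.sensitivity = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    res.specificity = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    res.f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return res


def aggregate_performance(
    results: Sequence[InstanceResult], task: str = "", feature_set: str = "",
    n_features: int = 0,
) -> PerformanceSummary:
    """Mean and sample SD of each indicator over instances."""
    if len(results) < 2:
        raise ClassifyError("need at least two instances to aggregate")
    mean, sd = {}, {}
    for key in ("accuracy", "sensitivity", "specificity", "f1"):
        vals = np.array([getattr(r, key) for r in results])
        mean[key] = float(vals.mean())
        sd[key] = float(vals.std(ddof=1))
    return PerformanceSummary(
        task, feature_set, n_features, len(results), mean, sd
    )


# -- feature weights --------------------------------------------------------


def feature_weights(
    instance_data: Sequence[tuple[np.ndarray, np.ndarray]],
    selected_features: Sequence[tuple[str, str]],
    top_k: int = 15,
    C: float = 1.0,
) -> pd.DataFrame:
    """Mean +/- SD of absolute linear-SVM coefficients across instances.

    RBF kernels expose no primal weights, so a companion linear-kernel SVM is
    fitted on each instance's standardized data and its absolute coefficients
    are averaged. Returns the ``top_k`` features by mean weight (all features,
    with a warning, if fewer are available).
    """
    names = [f"{m}:{n}" for m, n in selected_features]
    weights = []
    for X, y in instance_data:
        Xs = StandardScaler().fit_transform(np.asarray(X, float))
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xs, y)
        weights.append(np.abs(clf.coef_.ravel()))
    W = np.asarray(weights)
    df = pd.DataFrame(
        {
            "feature": names,
            "metric": [m for m, _ in selected_features],
            "node": [n for _, n in selected_features],
            "mean_weight": W.mean(axis=0),
            "sd_weight": W.std(ddof=1, axis=0) if W.shape[0] > 1 else 0.0,
        }
    ).sort_values("mean_weight", ascending=False, kind="mergesort")
    if len(df) < top_k:
        warnings.warn(
            f"requested top {top_k} features but only {len(df)} available",
            stacklevel=2,
        )
        return df.reset_index(drop=True)
    return df.head(top_k).reset_index(drop=True)


# -- end-to-end task runner -------------------------------------------------


def feature_matrix(
    metric_tables: Mapping[str, NodeMetricTable],
    selected_features: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Subjects x selected-features value matrix."""
    cols = {}
    for metric, node in selected_features:
        cols[f"{metric}:{node}"] = metric_tables[metric].values[node]
    return pd.DataFrame(cols)


def _task_labels(subjects_df: pd.DataFrame, task: str) -> tuple[np.ndarray, str]:
    if task == "ms_vs_hv":
        return np.where(subjects_df["group"] == "HV", "HV", "MS"), "MS"
    mask = subjects_df["group"].isin(["CP", "CI"])
    return np.where(subjects_df["group"] == "CI", "CI", "CP"), "CI"


def run_task(
    metric_tables: Mapping[str, NodeMetricTable],
    subjects_df: pd.DataFrame,
    task: str,
    selected_features: Sequence[tuple[str, str]],
    feature_set: str = "LE+NS",
    n_instances: int = 100,
    k: int = 10,
    inner_k: int = 10,
    seed: int = 0,
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
) -> tuple[PerformanceSummary, list[InstanceResult], pd.DataFrame]:
    """Full ensemble evaluation of one task: summary, per-instance results,
    feature-weight ranking."""
    subjects_df = subjects_df.reset_index(drop=True)
    if task == "ci_vs_cp":
        subjects_df = subjects_df[subjects_df["group"].isin(["CP", "CI"])]
        subjects_df = subjects_df.reset_index(drop=False)
    feats = feature_matrix(metric_tables, selected_features)
    if task == "ci_vs_cp":
        feats = feats.iloc[subjects_df["index"].to_numpy()].reset_index(drop=True)
    labels, positive = _task_labels(subjects_df, task)
    instances = build_instances(subjects_df, task, n_instances, seed)
    results, inst_data = [], []
    Xall = feats.to_numpy(dtype=float)
    for i, idx in enumerate(instances):
        rows = idx.to_numpy()
        X, y = Xall[rows], labels[rows]
        results.append(
            run_cv(
                X, y, positive, k=k, seed=seed + i, C_grid=C_grid,
                gamma_grid=gamma_grid, inner_k=inner_k, instance_id=i,
            )
        )
        inst_data.append((X, y))
    summary = aggregate_performance(
        results, task, feature_set, n_features=len(selected_features)
    )
    ranking = feature_weights(inst_data, selected_features)
    return summary, results, ranking
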