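"""Disease and nuisance-variable classification from network edges.

Disease-vs-control models are L1-regularized logistic regressions on the
harmonized edge vectors: a seeded 70/30 stratified split, inverse-
regularization grid search scored by average precision under repeated
stratified k-fold cross-validation (k reduced so every fold holds at least
one positive), then held-out AP / ROC AUC with stratified percentile
bootstrap CIs. The sparse coefficients support regional importance scores
(sum of |beta| over a region's incident edges) and cross-disease overlap
(Kendall tau-b between coefficient vectors). Nuisance targets (batch, sex,
genotype) are probed with elastic-net logistic regression, k-NN and SVMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, balanced_accuracy_score,
                             confusion_matrix, roc_auc_score)
from sklearn.model_selection import (GridSearchCV, RepeatedStratifiedKFold,
                                     StratifiedKFold, train_test_split)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .atlas import RoiAtlas
from .network import edge_index_pairs

__all__ = [
    "ClassifierConfig", "ClassificationReport", "MulticlassReport",
    "NuisanceReport", "chance_ap", "binary_disease_classifier",
    "multiclass_classifier", "nuisance_classifier", "regional_importance",
    "coefficient_overlap",
]


@dataclass
class ClassifierConfig:
    """Tunable settings for all classification tasks.

    Defaults follow the analysis protocol (70/30 split, 10-fold CV repeated
    10 times, 1000 bootstrap resamples, 7-point logarithmic C grid spanning
    1e-3..1e3); reduce folds/repeats/grids for quick runs.
    """

    test_size: float = 0.3
    n_folds: int = 10
    n_repeats: int = 10
    c_grid: tuple = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    n_boot: int = 1000
    seed: int = 0
    max_iter: int = 5000
    knn_grid: tuple = (3, 5, 7, 9)
    l1_ratio_grid: tuple = (0.1, 0.5, 0.9)
    svm_kernels: tuple = ("linear", "poly", "rbf")


@dataclass
class ClassificationReport:
    task: str
    test_ap: float
    chance_ap: float
    test_auc: float
    ap_ci: tuple
    auc_ci: tuple
    best_c: float
    coef: np.ndarray
    n_train: int
    n_test: int
    cv_folds: int
    seed: int


@dataclass
class MulticlassReport:
    task: str
    balanced_accuracy: float
    ci: tuple
    confusion: np.ndarray
    classes: tuple
    per_class_recall: np.ndarray
    best_c: float
    seed: int


@dataclass
class NuisanceReport:
    target: str
    results: pd.DataFrame      # per model: balanced accuracy + CI
    best_model: str
    best_balanced_accuracy: float
    best_ci: tuple
    seed: int


def one_vs_all_tasks(covariates: pd.DataFrame) -> dict:
    """Cohort assembly for disease-vs-control tasks.

    Each diagnostic group is compared against the healthy controls scanned
    with the same tracer(s). Psychosis-spectrum scans (SCZ and FEP) are
    pooled into one task against the combined control pools of their
    tracers. Returns ``{task_name: boolean mask over rows}``; within a
    task, positives are the non-HC scans.
    """
    groups = set(covariates["group"]) - {"HC"}
    if not groups:
        raise ValueError("no disease groups present")
    pooled = {"SCZ", "FEP"} & groups
    tasks = {}
    for g in sorted(groups - pooled):
        tracers = set(covariates.loc[covariates["group"] == g, "tracer"])
        mask = (covariates["group"] == g) | (
            (covariates["group"] == "HC") & covariates["tracer"].isin(tracers))
        tasks[g] = mask.to_numpy()
    if pooled:
        tracers = set(covariates.loc[covariates["group"].isin(pooled),
                                     "tracer"])
        mask = covariates["group"].isin(pooled) | (
            (covariates["group"] == "HC") & covariates["tracer"].isin(tracers))
        tasks["+".join(sorted(pooled))] = mask.to_numpy()
    return tasks


def chance_ap(labels) -> float:
    """Average-precision chance level: the positive-class prevalence."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty labels")
    n_pos = int(np.sum(y == 1)) if y.dtype.kind in "biu" else int(np.sum(y))
    if n_pos < 1:
        raise ValueError("need at least one positive label")
    return n_pos / y.size


def _stratified_bootstrap_indices(y, n_boot, rng):
    """Index resamples of a test set drawn with replacement within each
    class, preserving class counts."""
    y = np.asarray(y)
    per_class = [np.flatnonzero(y == c) for c in np.unique(y)]
    out = np.empty((n_boot, y.size), dtype=int)
    for b in range(n_boot):
        parts = [rng.choice(idx, size=idx.size, replace=True) for idx in per_class]
        out[b] = np.concatenate(parts)
    return out


def _bootstrap_ci(metric, y_true, y_score, n_boot, rng):
    idx = _stratified_bootstrap_indices(y_true, n_boot, rng)
    vals = np.array([metric(y_true[i], y_score[i]) for i in idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def _check_both_classes(y, where):
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"only one class present in the {where} set")
    return classes, counts


def binary_disease_classifier(edges, labels, config: ClassifierConfig | None = None,
                              task: str = "disease") -> ClassificationReport:
    """Train and evaluate one disease-vs-control L1 logistic model.

    ``labels`` are binary with 1 = disease-positive. ``edges`` should be
    confound-residualized, z-scored edge values [n_scans x n_edges].
    """
    cfg = config or ClassifierConfig()
    X = np.asarray(edges, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_both_classes(y, "full")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=cfg.test_size, stratify=y, random_state=cfg.seed)
    _check_both_classes(y_tr, "training")
    _check_both_classes(y_te, "test")
    n_pos_train = int(y_tr.sum())
    k = max(2, min(cfg.n_folds, n_pos_train))
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=cfg.n_repeats,
                                 random_state=cfg.seed)
    grid = GridSearchCV(
        LogisticRegression(l1_ratio=1.0, solver="liblinear",
                           max_iter=cfg.max_iter, random_state=cfg.seed),
        param_grid={"C": list(cfg.c_grid)},
        scoring="average_precision", cv=cv)
    grid.fit(X_tr, y_tr)
    model = grid.best_estimator_
    scores = model.decision_function(X_te)
    ap = float(average_precision_score(y_te, scores))
    auc = float(roc_auc_score(y_te, scores))
    rng = np.random.default_rng(cfg.seed)
    ap_ci = _bootstrap_ci(average_precision_score, y_te, scores, cfg.n_boot, rng)
    auc_ci = _bootstrap_ci(roc_auc_score, y_te, scores, cfg.n_boot, rng)
    return ClassificationReport(
        task=task, test_ap=ap, chance_ap=chance_ap(y), test_auc=auc,
        ap_ci=ap_ci, auc_ci=auc_ci, best_c=float(grid.best_params_["C"]),
        coef=model.coef_.ravel().copy(), n_train=len(y_tr), n_test=len(y_te),
        cv_folds=k, seed=cfg.seed)


def multiclass_classifier(edges, group_labels, config: ClassifierConfig | None = None,
                          task: str = "multiclass") -> MulticlassReport:
    """Multiclass L1 logistic discrimination between disease groups,
    evaluated by balanced accuracy with a stratified bootstrap CI."""
    cfg = config or ClassifierConfig()
    X = np.asarray(edges, dtype=float)
    y = np.asarray(group_labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 groups")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=cfg.test_size, stratify=y, random_state=cfg.seed)
    for where, part in (("training", y_tr), ("test", y_te)):
        if np.unique(part).size < classes.size:
            raise ValueError(f"a group is absent from the {where} split")
    min_count = int(min(np.sum(y_tr == c) for c in classes))
    k = max(2, min(cfg.n_folds, min_count))
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=cfg.n_repeats,
                                 random_state=cfg.seed)
    grid = GridSearchCV(
        LogisticRegression(l1_ratio=1.0, solver="saga", max_iter=cfg.max_iter,
                           random_state=cfg.seed),
        param_grid={"C": list(cfg.c_grid)},
        scoring="balanced_accuracy", cv=cv)
    grid.fit(X_tr, y_tr)
    y_pred = grid.best_estimator_.predict(X_te)
    bacc = float(balanced_accuracy_score(y_te, y_pred))
    rng = np.random.default_rng(cfg.seed)
    ci = _bootstrap_ci(balanced_accuracy_score, y_te, y_pred, cfg.n_boot, rng)
    cm = confusion_matrix(y_te, y_pred, labels=classes)
    recall = cm.diagonal() / cm.sum(axis=1)
    return MulticlassReport(task=task, balanced_accuracy=bacc, ci=ci,
                            confusion=cm, classes=tuple(classes),
                            per_class_recall=recall,
                            best_c=float(grid.best_params_["C"]), seed=cfg.seed)


def _nuisance_models(cfg: ClassifierConfig):
    models = {
        "logistic_elasticnet": (
            LogisticRegression(solver="saga",
                               max_iter=cfg.max_iter, random_state=cfg.seed),
            {"clf__C": list(cfg.c_grid), "clf__l1_ratio": list(cfg.l1_ratio_grid)}),
        "knn": (KNeighborsClassifier(),
                {"clf__n_neighbors": list(cfg.knn_grid)}),
    }
    for kernel in cfg.svm_kernels:
        models[f"svm_{kernel}"] = (
            SVC(kernel=kernel, random_state=cfg.seed),
            {"clf__C": list(cfg.c_grid)})
    return models


def nuisance_classifier(edges, target_labels, target_name: str = "batch",
                        config: ClassifierConfig | None = None) -> NuisanceReport:
    """Probe how decodable a nuisance variable (batch/site, sex, genotype)
    is from the edges, using several classifier families with
    within-training standardization and grid-searched hyperparameters."""
    cfg = config or ClassifierConfig()
    X = np.asarray(edges, dtype=float)
    y = np.asarray(target_labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"target {target_name!r} has fewer than 2 levels")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=cfg.test_size, stratify=y, random_state=cfg.seed)
    for where, part in (("training", y_tr), ("test", y_te)):
        if np.unique(part).size < classes.size:
            raise ValueError(f"a level of {target_name!r} is absent from the "
                             f"{where} split")
    min_count = int(min(np.sum(y_tr == c) for c in classes))
    k = max(2, min(cfg.n_folds, min_count))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    rows = []
    for name, (est, param_grid) in _nuisance_models(cfg).items():
        pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
        grid = GridSearchCV(pipe, param_grid=param_grid,
                            scoring="balanced_accuracy", cv=cv)
        grid.fit(X_tr, y_tr)
        y_pred = grid.best_estimator_.predict(X_te)
        bacc = float(balanced_accuracy_score(y_te, y_pred))
        rng = np.random.default_rng(cfg.seed)
        lo, hi = _bootstrap_ci(balanced_accuracy_score, y_te, y_pred,
                               cfg.n_boot, rng)
        rows.append({"model": name, "balanced_accuracy": bacc,
                     "ci_low": lo, "ci_high": hi})
    results = pd.DataFrame(rows).set_index("model")
    best = results["balanced_accuracy"].idxmax()
    return NuisanceReport(
        target=target_name, results=results, best_model=str(best),
        best_balanced_accuracy=float(results.loc[best, "balanced_accuracy"]),
        best_ci=(float(results.loc[best, "ci_low"]),
                 float(results.loc[best, "ci_high"])),
        seed=cfg.seed)


def regional_importance(coefficients, atlas: RoiAtlas | int) -> pd.DataFrame:
    """Per-region importance: the sum of |coefficient| over all edges
    incident to the region, sorted descending with the top 3 flagged."""
    beta = np.asarray(coefficients, dtype=float)
    if isinstance(atlas, RoiAtlas):
        n_roi = atlas.n_roi
        names = list(atlas.roi_names)
    else:
        n_roi = int(atlas)
        names = [f"roi_{i}" for i in range(n_roi)]
    n_edges = n_roi * (n_roi - 1) // 2
    if beta.size != n_edges:
        raise ValueError(f"coefficient length {beta.size} does not match "
                         f"{n_edges} edges for {n_roi} regions")
    pairs = edge_index_pairs(n_roi)
    scores = np.zeros(n_roi)
    np.add.at(scores, pairs[:, 0], np.abs(beta))
    np.add.at(scores, pairs[:, 1], np.abs(beta))
    df = pd.DataFrame({"roi": names, "importance": scores})
    df = df.sort_values("importance", ascending=False, kind="stable")
    df["top3"] = False
    df.iloc[:3, df.columns.get_loc("top3")] = True
    return df.reset_index(drop=True)


def coefficient_overlap(coef_by_task: dict) -> pd.DataFrame:
    """Pairwise Kendall tau-b between the coefficient vectors of the
    classification tasks, with Bonferroni-corrected two-sided p-values.

    Returns a long-form DataFrame (task_a, task_b, tau, p, p_bonferroni,
    significant)."""
    tasks = list(coef_by_task)
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks")
    vecs = {t: np.asarray(v, dtype=float) for t, v in coef_by_task.items()}
    lengths = {v.size for v in vecs.values()}
    if len(lengths) != 1:
        raise ValueError("coefficient vectors must have equal length")
    for t, v in vecs.items():
        if np.all(v == v[0]):
            raise ValueError(f"constant coefficient vector for task {t!r}")
    n_pairs = len(tasks) * (len(tasks) - 1) // 2
    rows = []
    for i, a in enumerate(tasks):
        for b in tasks[i + 1:]:
            tau, p = kendalltau(vecs[a], vecs[b])
            p_corr = min(1.0, p * n_pairs)
            rows.append({"task_a": a, "task_b": b, "tau": float(tau),
                         "p": float(p), "p_bonferroni": p_corr,
                         "significant": p_corr < 0.05})
    return pd.DataFrame(rows)
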