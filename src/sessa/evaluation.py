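"""Experiment protocol: stratified 80/20 external split, 5-fold internal
cross-validation on the training partition, repeated seeded runs, a bank of
six classifiers, and the optimizer comparison harness.

All feature and model selection happens strictly inside the training
partition; the external test partition is touched exactly once per run, for
the final evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .filters import StatisticalPrefilter
from .metrics import MetricReport, confusion_counts, metrics_from_confusion, r_squared
from .optimizers import make_selector

__all__ = [
    "SplitPlan",
    "split_train_test",
    "classifier_bank",
    "CLASSIFIER_TAGS",
    "CVResult",
    "cross_validate",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "compare_algorithms",
]


# --------------------------------------------------------------------- split


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    fraction_train: float
    stratified: bool
    seed: int


def split_train_test(
    n: int,
    fraction_train: float = 0.8,
    stratified: bool = True,
    labels=None,
    seed: int = 0,
) -> SplitPlan:
    """Deterministic external train/test split.

    The test size is ``round((1 - fraction_train) * n)`` (half-up) and the
    train size the remainder — e.g. 260 samples at 0.8 give 208/52 and
    10661 give 8529/2132.  Stratification preserves class proportions to
    within one sample per class (largest-remainder allocation).
    """
    if not 0.0 < fraction_train < 1.0:
        raise ValueError("fraction_train must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples")
    n_test = int(math.floor((1.0 - fraction_train) * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        return SplitPlan(
            sorted(perm[n_test:].tolist()), sorted(perm[:n_test].tolist()),
            fraction_train, False, seed,
        )

    if labels is None:
        raise ValueError("stratified split requires labels")
    yv = np.asarray(labels)
    classes, counts = np.unique(yv, return_counts=True)
    ideal = (1.0 - fraction_train) * counts
    base = np.floor(ideal).astype(int)
    short = n_test - base.sum()
    # largest remainder gets the leftover test slots
    order = np.argsort(-(ideal - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    test_idx: list[int] = []
    for cls, take, total in zip(classes, base, counts):
        if take == 0 or take == total:
            raise ValueError(
                f"stratification leaves class {cls!r} empty on one side "
                f"({total} samples, {take} to test)"
            )
        members = np.nonzero(yv == cls)[0]
        perm = rng.permutation(members.size)
        test_idx.extend(members[perm[:take]].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(n) if i not in test_set]
    return SplitPlan(train_idx, sorted(test_idx), fraction_train, True, seed)


# ----------------------------------------------------------- classifier bank

CLASSIFIER_TAGS = ("linear-svm", "knn", "decision-tree", "naive-bayes", "adaboost", "mlp")


def classifier_bank(tag: str, seed: int = 0):
    """A fit/predict handle for one of the six evaluation classifiers.

    Fixed, documented hyperparameters: linear-kernel SVM with C=1; 5-nearest
    neighbors; CART decision tree; Gaussian naive Bayes; AdaBoost with 50
    rounds; one-hidden-layer (width 100) perceptron.  Scale-sensitive models
    are wrapped with a standardizer.
    """
    if tag == "linear-svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0, random_state=seed))
    if tag == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if tag == "knn1":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=1))
    if tag == "decision-tree":
        return DecisionTreeClassifier(random_state=seed)
    if tag == "naive-bayes":
        return GaussianNB()
    if tag == "adaboost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed)
    if tag == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(100,), max_iter=300, random_state=seed),
        )
    raise ValueError(f"unknown classifier tag {tag!r}; expected one of {CLASSIFIER_TAGS}")


# ------------------------------------------------------------ internal CV


@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    mean_report: dict  # mean of per-fold metric values
    pooled_predictions: np.ndarray
    r2: float | None

    @property
    def accuracy(self) -> float:
        return self.mean_report["accuracy"]


_MEANED = ("accuracy", "sensitivity", "specificity", "precision", "f1_paper", "f1_standard", "rmse")


def cross_validate(
    X, y, classifier: str = "linear-svm", n_folds: int = 5, seed: int = 0
) -> CVResult:
    """Stratified k-fold CV; the aggregate is the mean of the per-fold
    metric values (folds are also pooled for the R² of the held-out
    predictions)."""
    A = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    _, counts = np.unique(yv, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify into {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    pooled = np.empty(yv.shape, dtype=yv.dtype)
    for tr, te in skf.split(A, yv):
        clf = classifier_bank(classifier, seed=seed)
        clf.fit(A[tr], yv[tr])
        pred = clf.predict(A[te])
        pooled[te] = pred
        reports.append(metrics_from_confusion(confusion_counts(yv[te], pred)))
    mean_report = {k: float(np.mean([getattr(r, k) for r in reports])) for k in _MEANED}
    try:
        r2 = r_squared(yv, pooled)
    except ValueError:
        r2 = None
    return CVResult(reports, mean_report, pooled, r2)


# -------------------------------------------------------------- experiment


@dataclass
class ExperimentConfig:
    """Everything one repeated-runs experiment needs.

    Defaults mirror the reference protocol: 10 agents, 100 iterations,
    80/20 stratified external split, 5 internal folds, 30 repeated runs,
    candidate-pool search space.
    """

    algorithm: str = "sessa"
    n_runs: int = 30
    fraction_train: float = 0.8
    n_folds: int = 5
    n_agents: int = 10
    n_iterations: int = 100
    classifiers: tuple[str, ...] = CLASSIFIER_TAGS
    search_space: str = "candidate"  # "candidate" (pre-filter pool) or "full"
    k_chi2: int | None = None
    k_rfe: int | None = None
    k_tree: int | None = None
    corr_threshold: float = 0.95
    combine_policy: str = "hybrid"
    optimizer_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.search_space not in ("candidate", "full"):
            raise ValueError("search_space must be 'candidate' or 'full'")


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    runs: list[dict]
    aggregate: dict  # classifier -> scope -> metric -> {mean, min, max}

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "runs": self.runs,
            "aggregate": self.aggregate,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _run_seed(base: int, r: int) -> int:
    return (int(base) * 1009 + r * 9176) % (2**31 - 1)


def _external_report(tag, Xtr, ytr, Xte, yte, seed) -> tuple[MetricReport, float | None]:
    clf = classifier_bank(tag, seed=seed)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    rep = metrics_from_confusion(confusion_counts(yte, pred))
    try:
        r2 = r_squared(yte, pred)
    except ValueError:
        r2 = None
    return rep, r2


def run_experiment(X, y, config: ExperimentConfig) -> ExperimentReport:
    """Repeated seeded runs of: external split -> statistical filter ->
    swarm selection -> classifier bank (internal 5-fold CV on train, final
    one-shot evaluation on the untouched external test set).

    Raises if an external test index ever reaches a training stage (leakage
    guard).
    """
    A = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    n = A.shape[0]
    runs: list[dict] = []

    for r in range(config.n_runs):
        seed_r = _run_seed(config.seed, r)
        plan = split_train_test(n, config.fraction_train, True, yv, seed_r)
        train_idx = np.asarray(plan.train_ids)
        test_idx = np.asarray(plan.test_ids)
        if np.intersect1d(train_idx, test_idx).size:
            raise AssertionError("external test indices leaked into the training partition")
        Xtr, ytr = A[train_idx], yv[train_idx]
        Xte, yte = A[test_idx], yv[test_idx]

        if config.search_space == "candidate":
            prefilter = StatisticalPrefilter(
                k_chi2=config.k_chi2,
                k_rfe=config.k_rfe,
                k_tree=config.k_tree,
                corr_threshold=config.corr_threshold,
                policy=config.combine_policy,
                random_state=seed_r,
            ).fit(Xtr, ytr)
            candidate = prefilter.support_
        else:
            candidate = None

        selector = make_selector(
            config.algorithm,
            n_agents=config.n_agents,
            n_iterations=config.n_iterations,
            candidate_mask=candidate,
            n_folds=config.n_folds,
            random_state=seed_r,
            **config.optimizer_params,
        ).fit(Xtr, ytr)
        mask = selector.support_

        per_clf: dict[str, dict] = {}
        for tag in config.classifiers:
            internal = cross_validate(Xtr[:, mask], ytr, tag, config.n_folds, seed_r)
            ext_rep, ext_r2 = _external_report(tag, Xtr[:, mask], ytr, Xte[:, mask], yte, seed_r)
            per_clf[tag] = {
                "internal": {**internal.mean_report, "r2": internal.r2},
                "external": {
                    **{k: getattr(ext_rep, k) for k in _MEANED},
                    "r2": ext_r2,
                    "confusion": asdict(ext_rep.confusion),
                },
            }

        runs.append(
            {
                "seed": seed_r,
                "n_selected": int(mask.sum()),
                "n_candidates": int(candidate.sum()) if candidate is not None else A.shape[1],
                "best_fitness": selector.best_fitness_,
                "n_iter_to_best": selector.n_iter_to_best_,
                "history": selector.history_,
                "classifiers": per_clf,
            }
        )

    aggregate: dict[str, dict] = {}
    for tag in config.classifiers:
        aggregate[tag] = {}
        for scope in ("internal", "external"):
            aggregate[tag][scope] = {}
            for metric in (*_MEANED, "r2"):
                vals = [
                    run["classifiers"][tag][scope][metric]
                    for run in runs
                    if run["classifiers"][tag][scope][metric] is not None
                ]
                if vals:
                    aggregate[tag][scope][metric] = {
                        "mean": float(np.mean(vals)),
                        "min": float(np.min(vals)),
                        "max": float(np.max(vals)),
                    }
    aggregate["selection"] = {
        "n_selected": {"mean": float(np.mean([r["n_selected"] for r in runs]))},
        "n_iter_to_best": {"mean": float(np.mean([r["n_iter_to_best"] for r in runs]))},
    }
    return ExperimentReport(config, runs, aggregate)


# -------------------------------------------------------------- comparison

_TABLE_METRICS = ("rmse", "accuracy", "sensitivity", "specificity", "precision", "f1_paper")


def compare_algorithms(
    X,
    y,
    algorithms: list[str],
    config: ExperimentConfig | None = None,
    classifier: str = "linear-svm",
) -> pd.DataFrame:
    """Run the repeated-runs protocol for each optimizer and tabulate mean
    internal-CV and external-test metrics side by side (one row per
    algorithm; internal block then external block, plus mean selected
    feature count, external R² and mean iterations-to-best)."""
    if not algorithms:
        raise ValueError("need at least one algorithm")
    config = config or ExperimentConfig()
    rows = []
    for alg in algorithms:
        cfg = replace(config, algorithm=alg, classifiers=(classifier,))
        report = run_experiment(X, y, cfg)
        agg = report.aggregate[classifier]
        row: dict = {
            "algorithm": alg,
            "f_no": report.aggregate["selection"]["n_selected"]["mean"],
        }
        for scope, prefix in (("internal", "int"), ("external", "ext")):
            for metric in _TABLE_METRICS:
                row[f"{prefix}_{metric}"] = agg[scope][metric]["mean"]
        row["ext_r2"] = agg["external"].get("r2", {}).get("mean", float("nan"))
        row["iter_to_best"] = report.aggregate["selection"]["n_iter_to_best"]["mean"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("algorithm")
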