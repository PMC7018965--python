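"""Shared machinery for the swarm-based wrapper feature selectors.

All optimizers search a continuous box [lb, ub]^d over a candidate feature
pool (GA excepted — it works on binary chromosomes directly).  A position is
mapped to a feature subset by thresholding, the subset is scored by the RMSE
of held-out cross-validated predictions of a cheap internal classifier, and
the best-ever subset (the elitist "food source") is tracked per iteration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["binarize", "wrapper_fitness", "SelectionResult", "BaseSwarmSelector"]


def binarize(position, threshold: float = 0.5) -> np.ndarray:
    """Map a continuous position to a feature mask: dimension j selected iff
    position_j > threshold.  An all-false mask falls back to selecting the
    single largest dimension (lowest index among maxima), so the subset is
    never empty."""
    pos = np.asarray(position, dtype=float)
    mask = pos > threshold
    if not mask.any():
        mask = np.zeros(pos.shape, dtype=bool)
        mask[int(np.argmax(pos))] = True
    return mask


def _internal_classifier(tag: str = "knn5"):
    """Cheap internal classifier used inside the wrapper fitness."""
    if tag == "knn5":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if tag == "knn1":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=1))
    raise ValueError(f"unknown internal classifier {tag!r}")


def wrapper_fitness(
    X,
    y,
    mask,
    n_folds: int = 5,
    seed: int = 0,
    classifier: str = "knn5",
) -> float:
    """RMSE of pooled held-out CV predictions on the masked feature subset.

    For binary labels this equals sqrt(1 - CV accuracy), so minimizing it
    maximizes internal cross-validated accuracy.  Deterministic given seed.
    """
    A = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask selects no features")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    sub = A[:, m]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty(yv.shape, dtype=yv.dtype)
    for train_idx, test_idx in skf.split(sub, yv):
        clf = _internal_classifier(classifier)
        clf.fit(sub[train_idx], yv[train_idx])
        pred[test_idx] = clf.predict(sub[test_idx])
    return float(np.sqrt(np.mean((pred.astype(float) - yv.astype(float)) ** 2)))


@dataclass
class SelectionResult:
    """Outcome of one wrapper-selection run over the full feature space."""

    best_mask: np.ndarray
    feature_names: list[str]
    best_fitness: float
    history: list[float]
    n_selected: int
    n_iter_to_best: int
    seed: int | None
    params: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    @property
    def selected_names(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.best_mask) if m]

    def to_dict(self) -> dict:
        def jsonify(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating, np.bool_)):
                return v.item()
            if isinstance(v, dict):
                return {k: jsonify(x) for k, x in v.items()}
            return v

        self.params = jsonify(self.params)
        return {
            "selected_features": self.selected_names,
            "n_selected": self.n_selected,
            "best_fitness": self.best_fitness,
            "history": list(map(float, self.history)),
            "n_iter_to_best": self.n_iter_to_best,
            "seed": self.seed,
            "params": self.params,
            "wall_time_s": self.wall_time_s,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_history(self, path: str | Path) -> None:
        """Two-column text (iteration, best-so-far fitness) for convergence plots."""
        lines = [f"{i}\t{f:.10g}" for i, f in enumerate(self.history)]
        Path(path).write_text("\n".join(lines) + "\n")


class BaseSwarmSelector(SelectorMixin, BaseEstimator):
    """Base class for the wrapper selectors.

    Subclasses implement ``_move`` (one continuous-position update step) or
    override ``_search`` entirely for non-continuous encodings.  The base
    class owns initialization, binarization, fitness evaluation with
    mask-level caching, elitist best tracking and history recording.

    Fitted attributes: ``support_`` (bool mask over input features),
    ``best_fitness_``, ``history_`` (best-so-far per iteration, length
    ``n_iterations``), ``n_iter_to_best_``, ``initial_fitness_``.
    """

    _algorithm = "base"

    def __init__(
        self,
        n_agents: int = 10,
        n_iterations: int = 100,
        lb: float = 0.0,
        ub: float = 1.0,
        binarize_threshold: float = 0.5,
        candidate_mask=None,
        n_folds: int = 5,
        internal_classifier: str = "knn5",
        random_state: int | None = None,
    ):
        self.n_agents = n_agents
        self.n_iterations = n_iterations
        self.lb = lb
        self.ub = ub
        self.binarize_threshold = binarize_threshold
        self.candidate_mask = candidate_mask
        self.n_folds = n_folds
        self.internal_classifier = internal_classifier
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        t0 = time.perf_counter()
        names = (
            [str(c) for c in X.columns]
            if isinstance(X, pd.DataFrame)
            else None
        )
        A = validate_data(self, X, ensure_2d=True, dtype=float)
        yv = np.asarray(y)
        if np.unique(yv).size < 2:
            raise ValueError("labels contain a single class")
        if self.n_agents < 1 or self.n_iterations < 0:
            raise ValueError("n_agents must be >= 1 and n_iterations >= 0")
        if not self.lb < self.ub:
            raise ValueError("lb must be < ub")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must be in (0, 1)")

        p = A.shape[1]
        if self.candidate_mask is None:
            pool = np.arange(p)
        else:
            cm = np.asarray(self.candidate_mask, dtype=bool)
            if cm.shape != (p,):
                raise ValueError("candidate_mask length must match n_features")
            pool = np.nonzero(cm)[0]
        if pool.size < 2:
            raise ValueError(f"candidate pool has {pool.size} feature(s); need >= 2")

        rng = np.random.default_rng(self.random_state)
        self._X, self._y, self._pool = A, yv, pool
        self._cache: dict[bytes, float] = {}
        self._fit_seed = (
            int(rng.integers(0, 2**31 - 1))
            if self.random_state is None
            else int(self.random_state) % (2**31 - 1)
        )

        best_pos, best_fit, history, n_iter_to_best, init_fit = self._search(rng, pool.size)

        full_mask = np.zeros(p, dtype=bool)
        full_mask[pool[binarize(best_pos, self.binarize_threshold)]] = True
        self.support_ = full_mask
        self.best_fitness_ = float(best_fit)
        self.history_ = list(map(float, history))
        self.n_iter_to_best_ = int(n_iter_to_best)
        self.initial_fitness_ = float(init_fit)
        self.feature_names_ = names or [f"f{i:05d}" for i in range(p)]
        self.wall_time_s_ = time.perf_counter() - t0
        del self._X, self._y, self._cache
        return self

    # ------------------------------------------------------------- internals

    def _evaluate(self, position) -> float:
        """Fitness of a continuous position (binarized), cached by mask."""
        mask = binarize(position, self.binarize_threshold)
        return self._evaluate_mask(mask)

    def _evaluate_mask(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            self._cache[key] = wrapper_fitness(
                self._X[:, self._pool],
                self._y,
                mask,
                n_folds=self.n_folds,
                seed=self._fit_seed,
                classifier=self.internal_classifier,
            )
        return self._cache[key]

    def _search(self, rng: np.random.Generator, d: int):
        """Default continuous-position elitist loop."""
        positions = rng.uniform(self.lb, self.ub, size=(self.n_agents, d))
        fitness = np.array([self._evaluate(pos) for pos in positions])
        best_idx = int(np.argmin(fitness))
        food_pos = positions[best_idx].copy()
        food_fit = float(fitness[best_idx])
        init_fit = food_fit

        state = self._init_state(positions, fitness, rng)
        history = []
        n_iter_to_best = 0
        for t in range(1, self.n_iterations + 1):
            positions = self._move(positions, fitness, food_pos, food_fit, t, rng, state)
            np.clip(positions, self.lb, self.ub, out=positions)
            fitness = np.array([self._evaluate(pos) for pos in positions])
            it_best = int(np.argmin(fitness))
            if fitness[it_best] < food_fit:
                food_fit = float(fitness[it_best])
                food_pos = positions[it_best].copy()
                n_iter_to_best = t
            history.append(food_fit)
        return food_pos, food_fit, history, n_iter_to_best, init_fit

    def _init_state(self, positions, fitness, rng) -> dict:
        return {}

    def _move(self, positions, fitness, food_pos, food_fit, t, rng, state):
        raise NotImplementedError

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    # ------------------------------------------------------------- reporting

    def selection_result(self) -> SelectionResult:
        check_is_fitted(self)
        return SelectionResult(
            best_mask=self.support_.copy(),
            feature_names=list(self.feature_names_),
            best_fitness=self.best_fitness_,
            history=list(self.history_),
            n_selected=int(self.support_.sum()),
            n_iter_to_best=self.n_iter_to_best_,
            seed=self.random_state,
            params={"algorithm": self._algorithm, **self.get_params(deep=False)},
            wall_time_s=self.wall_time_s_,
        )
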