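"""Statistical pre-filters: chi-square relevance, correlation pruning,
recursive feature elimination, tree-impurity importance, and the candidate
pool combiner feeding the swarm search.

These are the "statistical enhancement" applied before the wrapper search:
cheap, classifier-light scores that discard irrelevant or mutually redundant
columns so the swarm explores a small, signal-enriched pool.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

__all__ = [
    "chi_square_scores",
    "select_top_k",
    "prune_correlated",
    "rfe_rank",
    "tree_importance",
    "combine_candidates",
    "StatisticalPrefilter",
]


def _as_array(X) -> np.ndarray:
    return np.asarray(X, dtype=float)


def _feature_names(X, p: int) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"f{i:05d}" for i in range(p)]


def chi_square_scores(X, y) -> np.ndarray:
    """Chi-square relevance of each non-negative feature to the class label.

    Uses the class-conditional value-sum contingency formulation (suitable
    for continuous rectified features, no binning): for feature j,

        score_j = sum_k (O_kj - E_kj)^2 / E_kj

    where O_kj is the sum of feature j over samples of class k and
    E_kj = (class-k prior) x (column total) is its expectation were the
    feature independent of the class.  All-zero columns score exactly 0.
    """
    A = _as_array(X)
    yv = np.asarray(y)
    if A.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    neg = np.nonzero((A < 0).any(axis=0))[0]
    if neg.size:
        name = _feature_names(X, A.shape[1])[neg[0]]
        raise ValueError(f"chi-square requires non-negative values; feature {name!r} has negatives")
    classes, counts = np.unique(yv, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; chi-square undefined")

    priors = counts / yv.size
    onehot = (yv[:, None] == classes[None, :]).astype(float)  # n x k
    observed = onehot.T @ A  # k x p
    totals = A.sum(axis=0)  # p
    expected = priors[:, None] * totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=0)


def select_top_k(scores, k: int) -> np.ndarray:
    """Boolean mask keeping the k highest-scoring features.

    Ties at the k-th score are broken by ascending feature index, so the
    result is deterministic.
    """
    s = np.asarray(scores, dtype=float)
    p = s.size
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    # stable sort on (-score, index): mergesort keeps index order on ties
    order = np.argsort(-s, kind="stable")
    mask = np.zeros(p, dtype=bool)
    mask[order[:k]] = True
    return mask


def prune_correlated(X, threshold: float = 0.95) -> np.ndarray:
    """Greedy correlation pruning: scan features in index order, drop any
    whose absolute Pearson correlation with an already-kept feature exceeds
    ``threshold``.  Zero-variance columns are treated as correlation 0.
    """
    A = _as_array(X)
    p = A.shape[1]
    if p == 0:
        raise ValueError("need at least one feature")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    sd = A.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("prune_correlated: %d zero-variance columns treated as r=0", int(zero_var.sum()))
    centered = A - A.mean(axis=0)
    denom = np.where(zero_var, 1.0, sd * math.sqrt(A.shape[0]))
    Z = centered / denom  # columns have unit norm (or are all-zero)

    keep: list[int] = []
    for j in range(p):
        if keep:
            r = np.abs(Z[:, keep].T @ Z[:, j])
            if (r > threshold + 1e-12).any():
                continue
        keep.append(j)
    mask = np.zeros(p, dtype=bool)
    mask[keep] = True
    return mask


def _fit_coefs(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|standardized logistic coefficients| for the RFE criterion."""
    Z = StandardScaler().fit_transform(A)
    model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    model.fit(Z, y)
    return np.abs(model.coef_[0])


def rfe_rank(X, y, n_keep: int = 1) -> np.ndarray:
    """Recursive feature elimination ranks (1 = retained longest).

    Repeatedly fits an L2 logistic regression on the standardized remaining
    features and removes the one with the smallest absolute coefficient
    (ties: lowest index first), one per iteration, until ``n_keep`` remain.
    Survivors receive ranks 1..n_keep ordered by descending final-model
    |coefficient|; eliminated features get n_keep+1..P in reverse order of
    elimination.
    """
    A = _as_array(X)
    yv = np.asarray(y)
    if np.unique(yv).size < 2:
        raise ValueError("labels contain a single class; RFE undefined")
    p = A.shape[1]
    if not 1 <= n_keep <= p:
        raise ValueError(f"n_keep must be in [1, {p}], got {n_keep}")

    remaining = list(range(p))
    eliminated: list[int] = []
    while len(remaining) > n_keep:
        coefs = _fit_coefs(A[:, remaining], yv)
        j = int(np.argmin(coefs))  # argmin takes the first = lowest index on ties
        eliminated.append(remaining.pop(j))

    ranks = np.empty(p, dtype=int)
    if len(remaining) > 1:
        coefs = _fit_coefs(A[:, remaining], yv)
        surv_order = np.argsort(-coefs, kind="stable")
    else:
        surv_order = np.array([0]) if remaining else np.array([], dtype=int)
    for rank, idx in enumerate(surv_order, start=1):
        ranks[remaining[idx]] = rank
    for rank, feat in enumerate(reversed(eliminated), start=n_keep + 1):
        ranks[feat] = rank
    return ranks


def tree_importance(X, y, n_trees: int = 100, seed: int = 0) -> np.ndarray:
    """Mean-decrease-in-impurity importances from a random forest,
    normalized to sum to 1 (all-zero for unsplittable, e.g. constant, data).
    """
    A = _as_array(X)
    yv = np.asarray(y)
    if np.unique(yv).size < 2:
        raise ValueError("labels contain a single class; importances undefined")
    if n_trees < 1:
        raise ValueError("n_trees must be positive")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(A, yv)
    imp = forest.feature_importances_
    total = imp.sum()
    if total == 0:
        logger.warning("tree_importance: no split possible, importances all zero")
        return np.zeros(A.shape[1])
    return imp / total


def combine_candidates(
    chi2_scores,
    rfe_ranks,
    importances,
    policy: str = "hybrid",
    k_chi2: int = 1,
    k_rfe: int = 1,
    k_tree: int = 1,
) -> np.ndarray:
    """Combine the three per-criterion top-k masks into the candidate pool.

    Policies: ``union``, ``intersection``, ``chi2-only``, and the default
    ``hybrid`` = chi2 top-k intersected with (RFE survivors union tree
    top-k), falling back to the plain union when the intersection retains
    fewer than 2 features.  The result is never empty: as a last resort the
    single best chi-square feature is kept.
    """
    chi2_scores = np.asarray(chi2_scores, dtype=float)
    rfe_ranks = np.asarray(rfe_ranks)
    importances = np.asarray(importances, dtype=float)
    if not (chi2_scores.shape == rfe_ranks.shape == importances.shape):
        raise ValueError("rankings must cover the same feature set")

    m_chi2 = select_top_k(chi2_scores, k_chi2)
    m_rfe = rfe_ranks <= k_rfe
    m_tree = select_top_k(importances, k_tree)

    if policy == "chi2-only":
        mask = m_chi2
    elif policy == "union":
        mask = m_chi2 | m_rfe | m_tree
    elif policy == "intersection":
        mask = m_chi2 & m_rfe & m_tree
    elif policy == "hybrid":
        mask = m_chi2 & (m_rfe | m_tree)
        if mask.sum() < 2:
            logger.info("combine_candidates: hybrid intersection < 2, falling back to union")
            mask = m_chi2 | m_rfe | m_tree
    else:
        raise ValueError(f"unknown policy {policy!r}")

    if not mask.any():
        mask = select_top_k(chi2_scores, 1)
    return mask


@dataclass
class FilterRanking:
    """Per-feature filter diagnostics produced by :class:`StatisticalPrefilter`."""

    feature_names: list[str]
    chi2_scores: np.ndarray
    rfe_ranks: np.ndarray  # within the correlation-pruned pool; 0 outside
    importances: np.ndarray
    candidate_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chi2": self.chi2_scores,
                "rfe_rank": self.rfe_ranks,
                "importance": self.importances,
                "candidate": self.candidate_mask,
            },
            index=pd.Index(self.feature_names, name="feature"),
        )


class StatisticalPrefilter(SelectorMixin, BaseEstimator):
    """Filter stage reducing a wide non-negative feature matrix to a small
    candidate pool for the wrapper search.

    Stages, in order: (1) chi-square relevance, keep the top ``k_chi2``;
    (2) greedy correlation pruning at ``corr_threshold`` within that pool;
    (3) RFE ranks and random-forest importances on the pruned pool;
    (4) the ``policy`` combiner over the three criteria.

    Parameters default to 10% of the feature count for each top-k (the
    retention depth is a tuning knob, not a fixed constant of the method).

    Attributes (after ``fit``): ``support_`` — candidate mask over all input
    features; ``ranking_`` — a :class:`FilterRanking` with per-feature
    diagnostics.
    """

    def __init__(
        self,
        k_chi2: int | None = None,
        k_rfe: int | None = None,
        k_tree: int | None = None,
        corr_threshold: float = 0.95,
        policy: str = "hybrid",
        n_trees: int = 100,
        random_state: int = 0,
    ):
        self.k_chi2 = k_chi2
        self.k_rfe = k_rfe
        self.k_tree = k_tree
        self.corr_threshold = corr_threshold
        self.policy = policy
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        names = _feature_names(X, np.shape(X)[1])
        A = validate_data(self, X, ensure_2d=True, dtype=float)
        yv = np.asarray(y)
        p = A.shape[1]
        default_k = max(2, int(math.ceil(0.10 * p)))
        k_chi2 = min(self.k_chi2 or default_k, p)

        chi2 = chi_square_scores(A, yv)
        pool = np.nonzero(select_top_k(chi2, k_chi2))[0]
        keep_local = prune_correlated(A[:, pool], self.corr_threshold)
        pool = pool[keep_local]

        k_rfe = min(self.k_rfe or default_k, pool.size)
        k_tree = min(self.k_tree or default_k, pool.size)
        ranks_pool = rfe_rank(A[:, pool], yv, n_keep=k_rfe)
        imp_pool = tree_importance(A[:, pool], yv, self.n_trees, self.random_state)

        # lift pool-local diagnostics to full feature length
        rfe_full = np.zeros(p, dtype=int)
        rfe_full[pool] = ranks_pool
        imp_full = np.zeros(p)
        imp_full[pool] = imp_pool

        mask_pool = combine_candidates(
            chi2[pool], ranks_pool, imp_pool, self.policy, min(k_chi2, pool.size), k_rfe, k_tree
        )
        mask = np.zeros(p, dtype=bool)
        mask[pool[mask_pool]] = True

        self.support_ = mask
        self.chi2_scores_ = chi2
        self.ranking_ = FilterRanking(names, chi2, rfe_full, imp_full, mask)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
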