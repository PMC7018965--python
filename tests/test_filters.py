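"""Statistical filters: hand-computed contingency arithmetic, brute-force
oracles, tie-breaks, and the candidate combiner."""

import numpy as np
import pytest

from sessa import (
    StatisticalPrefilter,
    chi_square_scores,
    combine_candidates,
    prune_correlated,
    rfe_rank,
    select_top_k,
    tree_importance,
)


# ------------------------------------------------------------- chi-square


def brute_force_chi2(X, y):
    """Literal per-feature, per-class summation of (O-E)^2/E."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        total = X[:, j].sum()
        for c in classes:
            prior = (y == c).mean()
            O = X[y == c, j].sum()
            E = prior * total
            if E > 0:
                out[j] += (O - E) ** 2 / E
    return out


def test_chi2_hand_examples():
    y = [0, 0, 1, 1]
    assert chi_square_scores([[0], [0], [0], [0]], y)[0] == 0.0
    # O=(0,2), E=(1,1): (0-1)^2/1 + (2-1)^2/1 = 2
    assert chi_square_scores([[0], [0], [1], [1]], y)[0] == pytest.approx(2.0)
    # O=(1,1), E=(1,1): score 0
    assert chi_square_scores([[1], [0], [1], [0]], y)[0] == pytest.approx(0.0)


def test_chi2_errors():
    with pytest.raises(ValueError, match="non-negative"):
        chi_square_scores([[1.0], [-0.5]], [0, 1])
    with pytest.raises(ValueError, match="single class"):
        chi_square_scores([[1.0], [2.0]], [1, 1])


def test_chi2_matches_brute_force_oracle(rng):
    for _ in range(100):
        n = rng.integers(4, 30)
        p = rng.integers(1, 8)
        X = rng.random((n, p)) * rng.integers(1, 10)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        assert np.allclose(chi_square_scores(X, y), brute_force_chi2(X, y), atol=1e-10)


def test_chi2_matches_sklearn(planted):
    from sklearn.feature_selection import chi2 as sk_chi2

    X, y, _ = planted
    ours = chi_square_scores(X, y)
    theirs = sk_chi2(X.values, y.values)[0]
    assert np.allclose(ours, theirs)


def test_chi2_scales_linearly_under_dataset_duplication(planted):
    X, y, _ = planted
    base = chi_square_scores(X, y)
    doubled = chi_square_scores(np.vstack([X.values] * 2), np.concatenate([y.values] * 2))
    assert np.allclose(doubled, 2.0 * base)


# ---------------------------------------------------------------- top-k


def test_select_top_k():
    assert select_top_k([2, 0, 0], 1).tolist() == [True, False, False]
    assert select_top_k([1, 1, 1], 2).tolist() == [True, True, False]  # index tie-break
    assert select_top_k([3, 1, 2], 3).all()
    with pytest.raises(ValueError):
        select_top_k([1, 2], 3)


# ---------------------------------------------------------- corr pruning


def test_prune_duplicate_column(rng):
    a = rng.random(100)
    X = np.column_stack([a, a, rng.random(100)])
    keep = prune_correlated(X, 0.95)
    assert keep.tolist() == [True, False, True]


def test_prune_keeps_independent_columns(rng):
    X = rng.standard_normal((500, 20))
    assert prune_correlated(X, 0.95).all()


def test_prune_threshold_one_keeps_nonidentical(rng):
    a = rng.random(50)
    X = np.column_stack([a, a * 2 + 0.01 * rng.random(50)])
    assert prune_correlated(X, 1.0).all()


def test_prune_zero_variance_treated_as_uncorrelated(rng):
    X = np.column_stack([np.ones(40), rng.random(40)])
    assert prune_correlated(X, 0.9).all()


def test_pruned_set_has_no_pair_above_threshold(rng):
    base = rng.standard_normal((300, 5))
    mix = base @ rng.random((5, 25)) + 0.3 * rng.standard_normal((300, 25))
    keep = prune_correlated(mix, 0.9)
    kept = mix[:, keep]
    corr = np.abs(np.corrcoef(kept, rowvar=False))
    np.fill_diagonal(corr, 0.0)
    assert corr.max() <= 0.9 + 1e-9


# ------------------------------------------------------------------- RFE


def brute_force_rfe(X, y, n_keep):
    """Literal one-at-a-time re-fit elimination loop (independent oracle)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(X, float)
    remaining = list(range(X.shape[1]))
    eliminated = []
    while len(remaining) > n_keep:
        Z = StandardScaler().fit_transform(X[:, remaining])
        m = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000).fit(Z, y)
        coefs = np.abs(m.coef_[0])
        j = int(np.argmin(coefs))
        eliminated.append(remaining.pop(j))
    ranks = np.empty(X.shape[1], int)
    if len(remaining) > 1:
        Z = StandardScaler().fit_transform(X[:, remaining])
        m = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000).fit(Z, y)
        order = np.argsort(-np.abs(m.coef_[0]), kind="stable")
    else:
        order = np.array([0])
    for rank, idx in enumerate(order, 1):
        ranks[remaining[idx]] = rank
    for rank, feat in enumerate(reversed(eliminated), n_keep + 1):
        ranks[feat] = rank
    return ranks


def test_rfe_label_copy_feature_ranked_first(rng):
    y = rng.integers(0, 2, 100)
    X = np.column_stack([y + 0.01 * rng.standard_normal(100), rng.standard_normal((100, 2)).T[0], rng.standard_normal(100)])
    ranks = rfe_rank(X, y, n_keep=1)
    assert ranks[0] == 1


def test_rfe_single_feature():
    assert rfe_rank([[0.1], [0.9], [0.2], [0.8]], [0, 1, 0, 1], n_keep=1).tolist() == [1]


def test_rfe_matches_brute_force_oracle(rng):
    for p in (2, 4, 6):
        X = rng.standard_normal((60, p))
        y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        for n_keep in (1, max(1, p // 2)):
            assert np.array_equal(rfe_rank(X, y, n_keep), brute_force_rfe(X, y, n_keep))


def test_rfe_rank_is_permutation(rng):
    X = rng.standard_normal((50, 6))
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    ranks = rfe_rank(X, y, n_keep=3)
    assert sorted(ranks) == [1, 2, 3, 4, 5, 6]


def test_rfe_single_class_error():
    with pytest.raises(ValueError):
        rfe_rank([[1.0], [2.0]], [0, 0], 1)


# -------------------------------------------------------- tree importance


def test_tree_importance_finds_separating_feature(rng):
    y = np.repeat([0, 1], 100)
    X = rng.standard_normal((200, 5))
    X[:, 2] = y * 3 + 0.1 * rng.standard_normal(200)
    imp = tree_importance(X, y, n_trees=50, seed=0)
    assert imp.argmax() == 2
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)


def test_tree_importance_constant_matrix_all_zero():
    X = np.ones((30, 4))
    y = np.repeat([0, 1], 15)
    assert (tree_importance(X, y, 10, 0) == 0).all()


def test_tree_importance_deterministic(planted_arrays):
    X, y = planted_arrays
    a = tree_importance(X, y, 25, seed=42)
    b = tree_importance(X, y, 25, seed=42)
    assert np.array_equal(a, b)


# -------------------------------------------------------------- combiner


def test_combine_agreement_case():
    chi2 = np.array([5.0, 4.0, 0.1, 0.0])
    ranks = np.array([1, 2, 3, 4])
    imp = np.array([0.5, 0.4, 0.05, 0.05])
    for policy in ("union", "intersection", "hybrid"):
        mask = combine_candidates(chi2, ranks, imp, policy, 2, 2, 2)
        assert mask.tolist() == [True, True, False, False]


def test_combine_chi2_only_reduces_to_top_k():
    chi2 = np.array([1.0, 3.0, 2.0])
    mask = combine_candidates(chi2, np.array([3, 1, 2]), np.array([0.1, 0.1, 0.8]), "chi2-only", 1, 1, 1)
    assert np.array_equal(mask, select_top_k(chi2, 1))


def test_combine_disjoint_union_size():
    chi2 = np.array([9.0, 0, 0, 0, 0, 0])
    ranks = np.array([6, 1, 5, 4, 3, 2])  # rfe top-1 = index 1
    imp = np.array([0.0, 0.0, 1.0, 0, 0, 0])
    mask = combine_candidates(chi2, ranks, imp, "union", 1, 1, 1)
    assert mask.sum() == 3


def test_combine_never_empty():
    chi2 = np.array([1.0, 2.0, 3.0])
    ranks = np.array([3, 2, 1])
    imp = np.array([1.0, 0.0, 0.0])
    mask = combine_candidates(chi2, ranks, imp, "intersection", 1, 1, 1)
    assert mask.sum() >= 1


def test_combine_shape_mismatch():
    with pytest.raises(ValueError):
        combine_candidates(np.ones(3), np.ones(4, int), np.ones(3), "union", 1, 1, 1)


# ------------------------------------------------------------- prefilter


def test_prefilter_recovers_planted_columns(planted):
    X, y, truth = planted
    pf = StatisticalPrefilter(random_state=0).fit(X, y)
    chosen = set(np.array(X.columns)[pf.support_])
    signal = truth.informative_ids | set(truth.redundant_map)
    # every candidate is signal-bearing, and at least 2 informative survive
    assert chosen <= signal
    assert len(chosen & truth.informative_ids) >= 2


def test_prefilter_sklearn_transform_roundtrip(planted):
    X, y, _ = planted
    pf = StatisticalPrefilter(random_state=0).fit(X.values, y.values)
    Xt = pf.transform(X.values)
    assert Xt.shape == (X.shape[0], pf.support_.sum())
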