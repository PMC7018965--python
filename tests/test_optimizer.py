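"""Salp-swarm core: coefficient schedule, leader/follower updates,
binarization, wrapper fitness and the full search contract."""

import math

import numpy as np
import pytest

from sessa import (
    SalpSwarmSelector,
    SyntheticSpec,
    binarize,
    make_feature_dataset,
    update_c1,
    update_follower,
    update_leader,
    wrapper_fitness,
)


class FixedRng:
    """Stand-in rng yielding scripted uniform draws (c2 then c3)."""

    def __init__(self, *draws):
        self.draws = list(draws)

    def random(self, size):
        return np.full(size, self.draws.pop(0))


# ------------------------------------------------------------------- c1


def test_c1_closed_form_values():
    assert update_c1(0, 100) == pytest.approx(2.0)
    assert update_c1(1, 100) == pytest.approx(2 * math.exp(-0.0016))
    assert update_c1(100, 100) == pytest.approx(2 * math.exp(-16))


def test_c1_strictly_decreasing():
    vals = [update_c1(t, 50) for t in range(51)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert all(0 < v <= 2 for v in vals)


def test_c1_invalid_parameters():
    with pytest.raises(ValueError):
        update_c1(0, 0)
    with pytest.raises(ValueError):
        update_c1(5, 4)


# --------------------------------------------------------------- leader


def test_leader_zero_offset_returns_food():
    F = np.array([0.3, 0.7])
    out = update_leader(F, 0.0, 1.0, c1=1.5, rng=FixedRng(0.0, 0.9))
    assert np.allclose(out, F)


def test_leader_hand_arithmetic():
    # F=0.5, c1=0.5, c2=0.4, c3=0.7 -> minus branch: 0.5 - 0.5*0.4 = 0.3
    out = update_leader(np.array([0.5]), 0.0, 1.0, c1=0.5, rng=FixedRng(0.4, 0.7))
    assert out[0] == pytest.approx(0.3)
    # same draw with c3 < 0.5 -> plus branch
    out = update_leader(np.array([0.5]), 0.0, 1.0, c1=0.5, rng=FixedRng(0.4, 0.2))
    assert out[0] == pytest.approx(0.7)


def test_leader_clamped_at_bounds():
    out = update_leader(np.array([1.0, 0.0]), 0.0, 1.0, c1=2.0, rng=FixedRng(1.0, 0.0))
    assert (out >= 0).all() and (out <= 1).all()


# ------------------------------------------------------------- follower


def test_follower_midpoint(rng):
    a, b = rng.random(8), rng.random(8)
    assert np.allclose(update_follower(a, b), (a + b) / 2)
    assert np.allclose(update_follower(a, a), a)
    assert update_follower([0.0], [2.0])[0] == 1.0
    with pytest.raises(ValueError):
        update_follower([0.0, 1.0], [1.0])


# ------------------------------------------------------------- binarize


def test_binarize_cases():
    assert binarize([1.0, 1.0], 0.5).all()
    assert binarize([0.4, 0.6, 0.5], 0.5).tolist() == [False, True, False]
    # empty-mask fallback: lowest index among maxima
    assert binarize([0.0, 0.0, 0.0], 0.5).tolist() == [True, False, False]
    assert binarize([0.1, 0.3, 0.3], 0.5).tolist() == [False, True, False]


# -------------------------------------------------------------- fitness


def test_fitness_zero_for_separable_feature(rng):
    y = np.repeat([0, 1], 30)
    X = np.column_stack([y * 10.0 + 0.01 * rng.random(60), rng.random(60)])
    assert wrapper_fitness(X, y, [True, False], n_folds=5, seed=0) == 0.0


def test_fitness_equals_sqrt_one_minus_cv_accuracy(planted_arrays):
    """Wrapper identity: fitness^2 + CV accuracy = 1 for 0/1 predictions."""
    from sklearn.model_selection import StratifiedKFold
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X, y = planted_arrays
    mask = np.zeros(X.shape[1], bool)
    mask[:8] = True
    fit = wrapper_fitness(X, y, mask, n_folds=5, seed=3)

    skf = StratifiedKFold(5, shuffle=True, random_state=3)
    hits = 0
    for tr, te in skf.split(X[:, mask], y):
        clf = make_pipeline(StandardScaler(), KNeighborsClassifier(5))
        clf.fit(X[tr][:, mask], y[tr])
        hits += (clf.predict(X[te][:, mask]) == y[te]).sum()
    acc = hits / len(y)
    assert fit**2 + acc == pytest.approx(1.0, abs=1e-12)


def test_fitness_contract_violations(planted_arrays):
    X, y = planted_arrays
    with pytest.raises(ValueError):
        wrapper_fitness(X, y, np.zeros(X.shape[1], bool))
    with pytest.raises(ValueError):
        wrapper_fitness(X, y, np.ones(X.shape[1], bool), n_folds=1)


# ---------------------------------------------------------------- search


def test_sessa_zero_iterations_returns_initial_best(planted_arrays):
    X, y = planted_arrays
    sel = SalpSwarmSelector(n_agents=6, n_iterations=0, random_state=5).fit(X, y)
    assert sel.history_ == []
    assert sel.best_fitness_ == sel.initial_fitness_
    assert sel.support_.sum() >= 1


def test_sessa_history_non_increasing_and_bounds(planted_arrays):
    X, y = planted_arrays
    sel = SalpSwarmSelector(n_agents=8, n_iterations=10, random_state=2).fit(X, y)
    h = sel.history_
    assert len(h) == 10
    assert all(a >= b for a, b in zip(h, h[1:]))
    assert h[0] <= sel.initial_fitness_
    assert sel.best_fitness_ == h[-1]


def test_sessa_deterministic(planted_arrays):
    X, y = planted_arrays
    a = SalpSwarmSelector(n_agents=5, n_iterations=6, random_state=9).fit(X, y)
    b = SalpSwarmSelector(n_agents=5, n_iterations=6, random_state=9).fit(X, y)
    assert np.array_equal(a.support_, b.support_)
    assert a.history_ == b.history_
    assert a.best_fitness_ == b.best_fitness_
    ra, rb = a.selection_result(), b.selection_result()
    assert ra.selected_names == rb.selected_names


def test_sessa_candidate_pool_respected(planted_arrays):
    X, y = planted_arrays
    cand = np.zeros(X.shape[1], bool)
    cand[2:12] = True
    sel = SalpSwarmSelector(n_agents=5, n_iterations=4, candidate_mask=cand, random_state=1).fit(X, y)
    assert not sel.support_[~cand].any()


def test_sessa_rejects_tiny_pool(planted_arrays):
    X, y = planted_arrays
    cand = np.zeros(X.shape[1], bool)
    cand[0] = True
    with pytest.raises(ValueError, match="candidate pool"):
        SalpSwarmSelector(candidate_mask=cand).fit(X, y)


def test_sessa_selection_result_serializes(tmp_path, planted_arrays):
    X, y = planted_arrays
    sel = SalpSwarmSelector(n_agents=4, n_iterations=3, random_state=0).fit(X, y)
    res = sel.selection_result()
    res.save(tmp_path / "sel.json")
    res.save_history(tmp_path / "conv.tsv")
    assert (tmp_path / "sel.json").stat().st_size > 0
    lines = (tmp_path / "conv.tsv").read_text().strip().splitlines()
    assert len(lines) == 3


def test_sessa_recovers_strong_planted_signal():
    """On an easy planted problem the selected subset is signal-enriched."""
    spec = SyntheticSpec(n_samples=150, n_informative=5, n_redundant=0, n_noise=45,
                         effect_size=3.0, seed=21)
    X, y, truth = make_feature_dataset(spec)
    sel = SalpSwarmSelector(n_agents=8, n_iterations=15, random_state=21).fit(X.values, y.values)
    chosen = set(np.array(X.columns)[sel.support_])
    frac_inf_chosen = len(chosen & truth.informative_ids) / 5
    frac_all_chosen = sel.support_.mean()
    assert frac_inf_chosen > frac_all_chosen  # informative over-represented
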