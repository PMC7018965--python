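"""Salp swarm search for wrapper feature selection.

The salp chain: agent 1 (the leader) samples around the best subset found so
far (the food source), with an exponentially decaying step-size coefficient
c1 trading exploration for exploitation; agents 2..N (the followers) drift
toward their predecessor by pairwise averaging.  Combined with the
chi-square / RFE / tree-importance pre-filter this is the statistically
enhanced variant (SESSA).
"""

from __future__ import annotations

import math

import numpy as np

from ._base import BaseSwarmSelector

__all__ = ["update_c1", "update_leader", "update_follower", "SalpSwarmSelector"]


def update_c1(t: int, t_max: int) -> float:
    """Exploration/exploitation coefficient 2*exp(-(4t/t_max)^2).

    Strictly decreasing in t, starting at 2 for t=0 and essentially 0 at
    t=t_max (2*exp(-16)).
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    if not 0 <= t <= t_max:
        raise ValueError(f"t must be in [0, {t_max}], got {t}")
    return 2.0 * math.exp(-((4.0 * t / t_max) ** 2))


def update_leader(
    F,
    lb: float,
    ub: float,
    c1: float,
    rng: np.random.Generator,
    branch_threshold: float = 0.5,
) -> np.ndarray:
    """One leader step around the food source F.

    Per dimension j, with c2, c3 ~ U[0, 1]:

        offset_j = c1 * ((ub - lb) * c2 + lb)
        x_j = F_j + offset_j  if c3 < branch_threshold else F_j - offset_j

    then clamp to [lb, ub].  Branching at 0.5 keeps the two-sided search
    symmetric (a threshold at 0 would make the "+" branch measure-zero).
    """
    F = np.asarray(F, dtype=float)
    d = F.size
    c2 = rng.random(d)
    c3 = rng.random(d)
    offset = c1 * ((ub - lb) * c2 + lb)
    x = np.where(c3 < branch_threshold, F + offset, F - offset)
    return np.clip(x, lb, ub)


def update_follower(x_i, x_prev) -> np.ndarray:
    """Follower step: element-wise midpoint of the agent and its predecessor
    in the chain."""
    a = np.asarray(x_i, dtype=float)
    b = np.asarray(x_prev, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return 0.5 * (a + b)


class SalpSwarmSelector(BaseSwarmSelector):
    """Salp swarm wrapper feature selector (SSA search core).

    Chain order is agent index: agent 0 is the single leader, each follower
    averages with the already-updated predecessor, so leader movement
    propagates down the chain within an iteration.  The food source is the
    best-ever evaluated position (elitist), which makes the recorded
    best-so-far history non-increasing.

    Combine with :class:`~sessa.filters.StatisticalPrefilter` (via
    ``candidate_mask`` or an sklearn Pipeline) for the statistically
    enhanced variant.
    """

    _algorithm = "sessa"

    def __init__(
        self,
        n_agents: int = 10,
        n_iterations: int = 100,
        lb: float = 0.0,
        ub: float = 1.0,
        binarize_threshold: float = 0.5,
        branch_threshold: float = 0.5,
        candidate_mask=None,
        n_folds: int = 5,
        internal_classifier: str = "knn5",
        random_state: int | None = None,
    ):
        super().__init__(
            n_agents=n_agents,
            n_iterations=n_iterations,
            lb=lb,
            ub=ub,
            binarize_threshold=binarize_threshold,
            candidate_mask=candidate_mask,
            n_folds=n_folds,
            internal_classifier=internal_classifier,
            random_state=random_state,
        )
        self.branch_threshold = branch_threshold

    def _move(self, positions, fitness, food_pos, food_fit, t, rng, state):
        new = positions.copy()
        c1 = update_c1(t, max(self.n_iterations, 1))
        new[0] = update_leader(food_pos, self.lb, self.ub, c1, rng, self.branch_threshold)
        for i in range(1, new.shape[0]):
            new[i] = update_follower(new[i], new[i - 1])
        return new
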