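"""Baseline metaheuristic wrappers sharing the SESSA pre-filter,
binarization and fitness: particle swarm (SEPSO), genetic algorithm (SEGA),
grey wolf (SEGWO) and multi-verse (SEMVO) search cores.

Update rules follow the canonical published formulations of each algorithm:
PSO per Kennedy & Eberhart (1995) with inertia-weight damping; GWO per
Mirjalili, Mirjalili & Lewis (2014); MVO per Mirjalili, Mirjalili &
Hatamlou (2016); the GA is an elitist generational scheme with
Boltzmann-roulette parent selection, uniform crossover and bit-flip
mutation, operating directly on binary chromosomes.  Default parameter
values: PSO w=1, wDamp=0.99, C1=1, C2=2; GA pc=0.8, gamma=0.2, pm=0.3,
mu=0.02, beta=8; GWO a decaying linearly over [2, 0]; MVO WEPmin=0.2,
WEPmax=1.  (``gamma`` is the real-coded crossover blend range and is inert
for binary chromosomes; it is kept for parameter parity.)
"""

from __future__ import annotations

import numpy as np

from ._base import BaseSwarmSelector, binarize

__all__ = [
    "ParticleSwarmSelector",
    "GeneticSelector",
    "GreyWolfSelector",
    "MultiVerseSelector",
    "ALGORITHMS",
    "make_selector",
]


class ParticleSwarmSelector(BaseSwarmSelector):
    """PSO wrapper selector: velocity update with inertia weight ``w``
    (damped by ``w_damp`` per iteration), cognitive pull ``c1_cognitive``
    toward each particle's personal best and social pull ``c2_social``
    toward the global best."""

    _algorithm = "sepso"

    def __init__(
        self,
        n_agents: int = 10,
        n_iterations: int = 100,
        lb: float = 0.0,
        ub: float = 1.0,
        binarize_threshold: float = 0.5,
        w: float = 1.0,
        w_damp: float = 0.99,
        c1_cognitive: float = 1.0,
        c2_social: float = 2.0,
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
        self.w = w
        self.w_damp = w_damp
        self.c1_cognitive = c1_cognitive
        self.c2_social = c2_social

    def _init_state(self, positions, fitness, rng):
        return {
            "velocity": np.zeros_like(positions),
            "pbest_pos": positions.copy(),
            "pbest_fit": fitness.copy(),
            "w": float(self.w),
        }

    def _move(self, positions, fitness, food_pos, food_fit, t, rng, state):
        improved = fitness < state["pbest_fit"]
        state["pbest_fit"] = np.where(improved, fitness, state["pbest_fit"])
        state["pbest_pos"][improved] = positions[improved]

        r1 = rng.random(positions.shape)
        r2 = rng.random(positions.shape)
        state["velocity"] = (
            state["w"] * state["velocity"]
            + self.c1_cognitive * r1 * (state["pbest_pos"] - positions)
            + self.c2_social * r2 * (food_pos[None, :] - positions)
        )
        state["w"] *= self.w_damp
        return positions + state["velocity"]


class GreyWolfSelector(BaseSwarmSelector):
    """GWO wrapper selector: alpha/beta/delta (the three best-ever wolves)
    encircle the prey; the exploration coefficient ``a`` decays linearly
    from ``a_initial`` to 0 over the iterations."""

    _algorithm = "segwo"

    def __init__(
        self,
        n_agents: int = 10,
        n_iterations: int = 100,
        lb: float = 0.0,
        ub: float = 1.0,
        binarize_threshold: float = 0.5,
        a_initial: float = 2.0,
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
        self.a_initial = a_initial

    def _init_state(self, positions, fitness, rng):
        order = np.argsort(fitness, kind="stable")[:3]
        while order.size < 3:  # pad when fewer than 3 agents
            order = np.concatenate([order, order[:1]])
        return {"leaders": positions[order].copy(), "leader_fits": fitness[order].copy()}

    def _move(self, positions, fitness, food_pos, food_fit, t, rng, state):
        # refresh the best-ever three leaders with the current population
        all_pos = np.vstack([state["leaders"], positions])
        all_fit = np.concatenate([state["leader_fits"], fitness])
        order = np.argsort(all_fit, kind="stable")[:3]
        state["leaders"] = all_pos[order].copy()
        state["leader_fits"] = all_fit[order].copy()

        a = self.a_initial * (1 - t / max(self.n_iterations, 1))
        new = np.zeros_like(positions)
        for leader in state["leaders"]:
            r1 = rng.random(positions.shape)
            r2 = rng.random(positions.shape)
            A = 2 * a * r1 - a
            C = 2 * r2
            D = np.abs(C * leader[None, :] - positions)
            new += leader[None, :] - A * D
        return new / 3.0


class MultiVerseSelector(BaseSwarmSelector):
    """MVO wrapper selector: white/black-hole exchange between universes by
    roulette over inflation rates, plus wormhole jumps around the best-ever
    universe gated by the wormhole existence probability (ramping
    ``wep_min`` to ``wep_max``) and the travelling-distance rate."""

    _algorithm = "semvo"

    def __init__(
        self,
        n_agents: int = 10,
        n_iterations: int = 100,
        lb: float = 0.0,
        ub: float = 1.0,
        binarize_threshold: float = 0.5,
        wep_min: float = 0.2,
        wep_max: float = 1.0,
        tdr_power: float = 6.0,
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
        self.wep_min = wep_min
        self.wep_max = wep_max
        self.tdr_power = tdr_power

    def _move(self, positions, fitness, food_pos, food_fit, t, rng, state):
        t_max = max(self.n_iterations, 1)
        wep = self.wep_min + t * (self.wep_max - self.wep_min) / t_max
        tdr = 1.0 - (t ** (1.0 / self.tdr_power)) / (t_max ** (1.0 / self.tdr_power))

        # normalized inflation: worse (higher cost) universes lose objects
        span = fitness.max() - fitness.min()
        ni = (fitness - fitness.min()) / span if span > 0 else np.zeros_like(fitness)
        # donor roulette favors better universes
        weights = fitness.max() - fitness + 1e-12
        donor_p = weights / weights.sum()

        new = positions.copy()
        n, d = positions.shape
        for i in range(n):
            exchange = rng.random(d) < ni[i]
            if exchange.any():
                donors = rng.choice(n, size=d, p=donor_p)
                new[i, exchange] = positions[donors[exchange], exchange]
            worm = rng.random(d) < wep
            if worm.any():
                r3 = rng.random(d)
                r4 = rng.random(d)
                step = tdr * ((self.ub - self.lb) * r4 + self.lb)
                jump = np.where(r3 < 0.5, food_pos + step, food_pos - step)
                new[i, worm] = jump[worm]
        return new


class GeneticSelector(BaseSwarmSelector):
    """Elitist GA wrapper selector on binary chromosomes (no binarization
    step: a chromosome *is* a feature mask).

    Each generation: Boltzmann-roulette parent selection with pressure
    ``beta`` (selection probability proportional to exp(-beta * cost /
    worst cost)), uniform crossover producing ``2*round(pc*N/2)`` offspring,
    ``round(pm*N)`` mutants with per-bit flip rate ``mu``, then truncation
    of the merged population to the best N (so the best chromosome never
    worsens)."""

    _algorithm = "sega"

    def __init__(
        self,
        n_agents: int = 10,
        n_iterations: int = 100,
        lb: float = 0.0,
        ub: float = 1.0,
        binarize_threshold: float = 0.5,
        pc: float = 0.8,
        gamma: float = 0.2,
        pm: float = 0.3,
        mu: float = 0.02,
        beta: float = 8.0,
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
        self.pc = pc
        self.gamma = gamma
        self.pm = pm
        self.mu = mu
        self.beta = beta

    def _search(self, rng: np.random.Generator, d: int):
        def ensure_nonempty(chrom: np.ndarray) -> np.ndarray:
            if not chrom.any():
                chrom = chrom.copy()
                chrom[rng.integers(0, d)] = True
            return chrom

        pop = rng.random((self.n_agents, d)) > 0.5
        pop = np.array([ensure_nonempty(c) for c in pop])
        fits = np.array([self._evaluate_mask(c) for c in pop])

        best_idx = int(np.argmin(fits))
        best_chrom = pop[best_idx].copy()
        best_fit = float(fits[best_idx])
        init_fit = best_fit

        history = []
        n_iter_to_best = 0
        n_cross = 2 * int(round(self.pc * self.n_agents / 2))
        n_mut = int(round(self.pm * self.n_agents))

        for t in range(1, self.n_iterations + 1):
            worst = fits.max()
            if worst > 0:
                probs = np.exp(-self.beta * fits / worst)
            else:
                probs = np.ones_like(fits)
            probs = probs / probs.sum()

            children = []
            for _ in range(n_cross // 2):
                i, j = rng.choice(self.n_agents, size=2, p=probs)
                swap = rng.random(d) < 0.5
                c1, c2 = pop[i].copy(), pop[j].copy()
                c1[swap], c2[swap] = pop[j][swap], pop[i][swap]
                children += [ensure_nonempty(c1), ensure_nonempty(c2)]
            for _ in range(n_mut):
                k = rng.integers(0, self.n_agents)
                m = pop[k].copy()
                flips = rng.random(d) < self.mu
                m[flips] = ~m[flips]
                children.append(ensure_nonempty(m))

            if children:
                child_arr = np.array(children)
                child_fits = np.array([self._evaluate_mask(c) for c in child_arr])
                merged = np.vstack([pop, child_arr])
                merged_fits = np.concatenate([fits, child_fits])
                order = np.argsort(merged_fits, kind="stable")[: self.n_agents]
                pop, fits = merged[order], merged_fits[order]

            if fits[0] < best_fit:
                best_fit = float(fits[0])
                best_chrom = pop[0].copy()
                n_iter_to_best = t
            history.append(best_fit)

        # positions live in mask space already; report chromosome as position
        best_pos = np.where(best_chrom, self.ub, self.lb).astype(float)
        # guard: binarize(best_pos) must reproduce best_chrom exactly
        assert np.array_equal(binarize(best_pos, self.binarize_threshold), best_chrom)
        return best_pos, best_fit, history, n_iter_to_best, init_fit


ALGORITHMS: dict[str, type[BaseSwarmSelector]] = {
    "sepso": ParticleSwarmSelector,
    "sega": GeneticSelector,
    "segwo": GreyWolfSelector,
    "semvo": MultiVerseSelector,
}


def make_selector(algorithm: str, **params) -> BaseSwarmSelector:
    """Instantiate a wrapper selector by tag (``sessa`` or a baseline)."""
    from .salp import SalpSwarmSelector

    registry = {"sessa": SalpSwarmSelector, **ALGORITHMS}
    key = algorithm.lower()
    if key not in registry:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {sorted(registry)}"
        )
    return registry[key](**params)
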