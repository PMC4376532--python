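"""Naive per-agent reference scheduler.

A deliberately plain re-statement of the model: one Python object per
individual, scalar math, explicit loops — no vectorisation.  It follows the
same RNG stream discipline as :mod:`nutrilat.dynamics` (documented there),
so on the same seed the two engines must produce identical trajectories.
It exists purely as a cross-check oracle for the optimised engine and is
only meant for small instances.
"""

from __future__ import annotations

import math

import numpy as np

from .competition import CompetitionConfig
from .geometry import Environment
from .population import DISPLACED, FEEDING, SEARCHING, GenerationResult, Population

__all__ = ["ReferenceIndividual", "run_generation_reference"]


class ReferenceIndividual:
    def __init__(self, k: float, mu: float):
        self.x = 0.0
        self.y = 0.0
        self.k = k
        self.fit = math.exp(-mu)
        self.status = SEARCHING
        self.food = -1
        self.iters_displaced = 0
        self.contests_initiated = 0
        self.contests_involved = 0
        self.contests_won = 0
        self.beta_sum = 0.0
        self.feed_events = 0

    def rail_state(self, env: Environment):
        """(beta, appetite) at the current state on the current rail."""
        rail = env.foods[self.food].rail_angle
        it = env.intake_target
        dx = it.p - self.x
        dy = it.c - self.y
        dist = math.hypot(dx, dy)
        if dist == 0.0:
            return 0.0, 0.0
        ideal = math.atan2(dy, dx)
        beta = abs(ideal - rail)
        return beta, max(0.0, dist * math.cos(beta))


def run_generation_reference(k_values, env: Environment, cfg: CompetitionConfig,
                             phi: float = 2.0, mu: float = 2.0,
                             n_iterations: int = 500,
                             rng: np.random.Generator | None = None,
                             record_trajectory: bool = False) -> GenerationResult:
    if rng is None:
        rng = np.random.default_rng()
    inds = [ReferenceIndividual(float(k), mu) for k in np.asarray(k_values, dtype=float)]
    n = len(inds)
    cap = cfg.capacity
    trajectory: list = []

    for _ in range(n_iterations):
        # --- Choose Food ---
        perm = rng.permutation(n)
        for i in perm:
            me = inds[i]
            if me.status != SEARCHING:
                continue
            f = int(rng.integers(env.n_food))
            occupants = [j for j in range(n)
                         if inds[j].status == FEEDING and inds[j].food == f]
            if len(occupants) >= cap:
                opp = inds[occupants[int(rng.integers(len(occupants)))]]
                q = 1.0 / (1.0 + math.exp(-cfg.eta * (me.fit - opp.fit)))
                me.contests_initiated += 1
                me.contests_involved += 1
                opp.contests_involved += 1
                if rng.random() < q:
                    me.contests_won += 1
                    me.status = FEEDING
                    me.food = f
                    opp.status = DISPLACED
                    opp.food = -1
                    opp.iters_displaced += 1
                else:
                    opp.contests_won += 1
                    me.status = DISPLACED
                    me.iters_displaced += 1
            else:
                me.status = FEEDING
                me.food = f

        # --- Eat ---
        perm = rng.permutation(n)
        for i in perm:
            me = inds[i]
            if me.status != FEEDING:
                continue
            beta, app = me.rail_state(env)
            d = min(app, phi)
            rail = env.foods[me.food].rail_angle
            me.x += d * math.cos(rail)
            me.y += d * math.sin(rail)
            me.beta_sum += beta
            me.feed_events += 1

        # --- Calculate Fitness ---
        perm = rng.permutation(n)
        it = env.intake_target
        for i in perm:
            me = inds[i]
            dist = math.hypot(it.p - me.x, it.c - me.y)
            me.fit = math.exp(-mu * dist / env.initial_distance)

        # --- Leave ---
        perm = rng.permutation(n)
        for i in perm:
            me = inds[i]
            u = rng.random()
            if me.status == FEEDING:
                beta, app = me.rail_state(env)
                p = (1.0 - me.k) * beta / (0.5 * math.pi) + max(0.0, (me.k * phi - app) / phi)
                p = min(1.0, max(0.0, p))
                if u < p:
                    me.status = SEARCHING
                    me.food = -1
        for me in inds:
            if me.status == DISPLACED:
                me.status = SEARCHING

        if record_trajectory:
            trajectory.append({
                "x": np.array([m.x for m in inds]),
                "y": np.array([m.y for m in inds]),
                "fit": np.array([m.fit for m in inds]),
                "status": np.array([m.status for m in inds], dtype=np.int8),
                "food": np.array([m.food for m in inds], dtype=np.int64),
            })

    pop = Population(
        x=np.array([m.x for m in inds]),
        y=np.array([m.y for m in inds]),
        k=np.array([m.k for m in inds]),
        fit=np.array([m.fit for m in inds]),
        status=np.array([m.status for m in inds], dtype=np.int8),
        food=np.array([m.food for m in inds], dtype=np.int64),
        iters_displaced=np.array([m.iters_displaced for m in inds], dtype=np.int64),
        contests_initiated=np.array([m.contests_initiated for m in inds], dtype=np.int64),
        contests_involved=np.array([m.contests_involved for m in inds], dtype=np.int64),
        contests_won=np.array([m.contests_won for m in inds], dtype=np.int64),
        beta_sum=np.array([m.beta_sum for m in inds]),
        feed_events=np.array([m.feed_events for m in inds], dtype=np.int64),
    )
    return GenerationResult.from_population(pop, n_iterations, trajectory=trajectory)
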