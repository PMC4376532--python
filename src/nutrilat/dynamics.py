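"""Per-iteration scheduler: Choose Food -> Eat -> Calculate Fitness -> Leave.

All individuals complete a phase before the next phase starts.  Within a
phase, individuals act in a freshly drawn random permutation with immediate
state updates, so a contest resolved early in the choose phase changes the
occupancy seen by later challengers in the same phase.

RNG stream discipline (shared with the naive reference engine in
:mod:`nutrilat.reference` so the two produce identical trajectories from the
same seed): each phase first draws one permutation of the population; the
choose phase then draws, per searching individual in permutation order, a
uniform food index, and for a contested food a uniform opponent index into
the ascending-agent-index occupant list plus one uniform variate for the
outcome; the leave phase draws a single uniform vector of length n, entry j
belonging to the j-th individual of the leave permutation.  Eat and fitness
phases are order-independent, so their permutations only keep the streams
aligned.
"""

from __future__ import annotations

import numpy as np

from .competition import CompetitionConfig, dominance_probability
from .geometry import Environment, HALF_PI
from .population import DISPLACED, FEEDING, SEARCHING, GenerationResult, Population

__all__ = [
    "choose_food_phase",
    "eat_phase",
    "fitness_phase",
    "leave_probability",
    "leave_phase",
    "run_generation",
]


def _occupancy(pop: Population, n_food: int) -> np.ndarray:
    feeding = pop.status == FEEDING
    return np.bincount(pop.food[feeding], minlength=n_food).astype(float)


def choose_food_phase(pop: Population, env: Environment, cfg: CompetitionConfig,
                      rng: np.random.Generator) -> None:
    """Searching individuals pick a food uniformly at random; a pick at a
    food already at capacity triggers a dominance contest against one
    uniformly chosen occupant, and the loser is displaced for the rest of
    the iteration."""
    n_food = env.n_food
    if n_food == 0:
        raise ValueError("environment has no foods")
    cap = cfg.capacity
    occ = _occupancy(pop, n_food)
    perm = rng.permutation(pop.n)
    status, food, fit = pop.status, pop.food, pop.fit
    for i in perm:
        if status[i] != SEARCHING:
            continue
        f = int(rng.integers(n_food))
        if occ[f] >= cap:
            occupants = np.flatnonzero((status == FEEDING) & (food == f))
            j = occupants[int(rng.integers(occupants.size))]
            q = dominance_probability(fit[i], fit[j], cfg.eta)
            pop.contests_initiated[i] += 1
            pop.contests_involved[i] += 1
            pop.contests_involved[j] += 1
            if rng.random() < q:
                pop.contests_won[i] += 1
                status[i] = FEEDING
                food[i] = f
                status[j] = DISPLACED
                food[j] = -1
                pop.iters_displaced[j] += 1
            else:
                pop.contests_won[j] += 1
                status[i] = DISPLACED
                pop.iters_displaced[i] += 1
        else:
            status[i] = FEEDING
            food[i] = f
            occ[f] += 1


def _rail_state(pop: Population, env: Environment, mask: np.ndarray):
    """Ideal-rail angle, beta and appetite for the masked (feeding)
    individuals at their current state.  The degenerate state exactly at the
    IT gets beta = 0 and appetite = 0."""
    rails = env.rail_angles[pop.food[mask]]
    it = env.intake_target
    dx = it.p - pop.x[mask]
    dy = it.c - pop.y[mask]
    dist = np.hypot(dx, dy)
    ideal = np.arctan2(dy, dx)
    beta = np.abs(ideal - rails)
    beta[dist == 0.0] = 0.0
    app = np.maximum(0.0, dist * np.cos(beta))
    return rails, beta, app


def eat_phase(pop: Population, env: Environment, phi: float,
              rng: np.random.Generator | None = None) -> None:
    """Feeding individuals move min(A, phi) along their rail and record the
    angular difference beta between their rail and the ideal rail at the
    pre-move state.  Displaced and searching individuals do not move."""
    if rng is not None:
        rng.permutation(pop.n)  # stream alignment; order-independent phase
    mask = pop.status == FEEDING
    if not mask.any():
        return
    rails, beta, app = _rail_state(pop, env, mask)
    d = np.minimum(app, phi)
    pop.x[mask] += d * np.cos(rails)
    pop.y[mask] += d * np.sin(rails)
    pop.beta_sum[mask] += beta
    pop.feed_events[mask] += 1


def fitness_phase(pop: Population, env: Environment, mu: float,
                  rng: np.random.Generator | None = None) -> None:
    """Recompute every individual's fitness from its current state."""
    if rng is not None:
        rng.permutation(pop.n)  # stream alignment; order-independent phase
    it = env.intake_target
    dist = np.hypot(it.p - pop.x, it.c - pop.y)
    np.exp(-mu * dist / env.initial_distance, out=pop.fit)


def leave_probability(latitude_k, rail, ideal, appetite_a, phi):
    """Probability of spontaneously leaving the current food:

        P_leave = (1 - K) |alpha_ideal - alpha_f| / (pi/2)
                  + max{0, (K phi - A) / phi},

    clamped to [0, 1].  Low K punishes angular mismatch with the ideal rail;
    any K guarantees departure once appetite is exhausted (A -> 0)."""
    k = np.asarray(latitude_k, dtype=float)
    beta = np.abs(np.asarray(ideal, dtype=float) - rail)
    p = (1.0 - k) * beta / HALF_PI + np.maximum(0.0, (k * phi - appetite_a) / phi)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def leave_phase(pop: Population, env: Environment, phi: float,
                rng: np.random.Generator) -> None:
    """Feeding individuals leave with probability P_leave and become
    searching (they re-choose next iteration, possibly the same food);
    displaced individuals return to searching."""
    perm = rng.permutation(pop.n)
    u = np.empty(pop.n)
    u[perm] = rng.random(pop.n)
    mask = pop.status == FEEDING
    if mask.any():
        rails, beta, app = _rail_state(pop, env, mask)
        k = pop.k[mask]
        p = np.clip((1.0 - k) * beta / HALF_PI + np.maximum(0.0, (k * phi - app) / phi), 0.0, 1.0)
        leavers = np.flatnonzero(mask)[u[mask] < p]
        pop.status[leavers] = SEARCHING
        pop.food[leavers] = -1
    pop.status[pop.status == DISPLACED] = SEARCHING


def run_generation(pop: Population, env: Environment, cfg: CompetitionConfig,
                   phi: float = 2.0, mu: float = 2.0, n_iterations: int = 500,
                   rng: np.random.Generator | None = None,
                   record_fitness_every: int | None = None,
                   record_trajectory: bool = False) -> GenerationResult:
    """Run the four-phase scheduler for ``n_iterations`` iterations and
    return the per-individual outcomes.

    ``record_fitness_every=r`` appends ``(iteration, fitness.copy())`` after
    every r-th iteration; ``record_trajectory`` stores a full state snapshot
    per iteration (small instances only — used for engine equivalence
    checks).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    snapshots: list = []
    trajectory: list = []
    for it in range(1, n_iterations + 1):
        choose_food_phase(pop, env, cfg, rng)
        eat_phase(pop, env, phi, rng)
        fitness_phase(pop, env, mu, rng)
        leave_phase(pop, env, phi, rng)
        if record_fitness_every and it % record_fitness_every == 0:
            snapshots.append((it, pop.fit.copy()))
        if record_trajectory:
            trajectory.append(pop.snapshot())
    return GenerationResult.from_population(pop, n_iterations, snapshots, trajectory)
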