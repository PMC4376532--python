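"""Between-generation dynamics of nutritional latitude K.

Two selection regimes:

* **general** — a fixed-length generation; individuals ending with fitness
  strictly above the cutoff (default 0.5) are eligible, and parents are
  sampled fitness-proportionately among eligibles.  An empty eligible set is
  an extinction: the replicate terminates and is flagged.
* **truncated** — the generation has no fixed length; the first 10% of the
  population to exceed the cutoff (checked after each iteration's fitness
  phase) become equally weighted parents.  Extinction cannot occur because
  the generation runs until enough individuals qualify.

Offspring inherit the parent's K plus Normal(0, mutation_sd) noise, clamped
to [0, 1]; they start a new generation at the natal state (0, 0).  Under
neutral conditions the clamped random walk makes every K value roughly
equally likely, so directional change in K reflects selection, not drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competition import CompetitionConfig
from .dynamics import choose_food_phase, eat_phase, fitness_phase, leave_phase, run_generation
from .geometry import Environment
from .population import GenerationResult, Population

__all__ = [
    "SelectionConfig",
    "EvolutionTrajectory",
    "TruncatedGenerationOverrun",
    "eligible_parents_general",
    "sample_parents_proportionate",
    "mutate_k",
    "reproduce_general",
    "run_generation_truncated",
    "run_evolution",
]


@dataclass(frozen=True)
class SelectionConfig:
    mode: str = "general"  # "general" | "truncated"
    fitness_cutoff: float = 0.5
    truncation_fraction: float = 0.1
    mutation_sd: float = 0.025
    # truncated generations abort past this multiple of the nominal length
    max_iteration_factor: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("general", "truncated"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if not (0 < self.fitness_cutoff < 1):
            raise ValueError("fitness_cutoff must be in (0, 1)")
        if not (0 < self.truncation_fraction <= 1):
            raise ValueError("truncation_fraction must be in (0, 1]")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be >= 0")


class TruncatedGenerationOverrun(RuntimeError):
    """A truncated-selection generation hit the iteration safety cap before
    enough individuals crossed the fitness cutoff."""


def eligible_parents_general(fitness_values, fitness_cutoff: float) -> np.ndarray:
    """Indices of individuals with fitness strictly greater than the cutoff
    (an exact-boundary fitness does not qualify).  Empty means extinction."""
    return np.flatnonzero(np.asarray(fitness_values, dtype=float) > fitness_cutoff)


def sample_parents_proportionate(parent_indices, parent_fitness, n_offspring: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Sample parents with replacement, probability proportional to fitness
    among the eligible set."""
    idx = np.asarray(parent_indices)
    if idx.size == 0:
        raise ValueError("cannot sample parents from an empty eligible set")
    w = np.asarray(parent_fitness, dtype=float)
    return rng.choice(idx, size=n_offspring, replace=True, p=w / w.sum())


def mutate_k(parent_k, mutation_sd: float, rng: np.random.Generator,
             size: int | None = None):
    """Inherited K plus Normal(0, sd) noise, clamped to [0, 1]."""
    noise = rng.normal(0.0, mutation_sd, size=size)
    out = np.clip(np.asarray(parent_k, dtype=float) + noise, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def reproduce_general(result: GenerationResult, selection: SelectionConfig,
                      n_ind: int, rng: np.random.Generator,
                      mu: float = 2.0) -> tuple[Population | None, int]:
    """Build the next generation under the general regime, or return
    ``(None, 0)`` when no individual exceeds the cutoff (extinction)."""
    eligible = eligible_parents_general(result.fitness, selection.fitness_cutoff)
    if eligible.size == 0:
        return None, 0
    parents = sample_parents_proportionate(eligible, result.fitness[eligible], n_ind, rng)
    k_off = mutate_k(result.k[parents], selection.mutation_sd, rng, size=n_ind)
    return Population.initial(k_off, mu=mu), int(eligible.size)


def run_generation_truncated(pop: Population, env: Environment, cfg: CompetitionConfig,
                             selection: SelectionConfig, phi: float = 2.0, mu: float = 2.0,
                             nominal_iterations: int = 500,
                             rng: np.random.Generator | None = None) -> tuple[np.ndarray, int]:
    """Run the scheduler until the first ``ceil(truncation_fraction * n)``
    individuals have crossed the fitness cutoff; returns (parent indices,
    elapsed iterations).

    Crossings are checked after each iteration's fitness phase, in agent
    index order within an iteration.  When a final same-iteration batch of
    crossers overshoots the quota, earlier arrivals are kept and the batch
    is randomly subsampled to fill the remaining slots exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_parents = math.ceil(selection.truncation_fraction * pop.n)
    cap = selection.max_iteration_factor * nominal_iterations
    arrivals: list[int] = []
    crossed = np.zeros(pop.n, dtype=bool)
    iteration = 0
    while True:
        iteration += 1
        if iteration > cap:
            raise TruncatedGenerationOverrun(
                f"only {len(arrivals)}/{n_parents} individuals crossed "
                f"F={selection.fitness_cutoff} within {cap} iterations "
                f"(c={cfg.competition:.3f}); population maximum fitness "
                f"{pop.fit.max():.4f}"
            )
        choose_food_phase(pop, env, cfg, rng)
        eat_phase(pop, env, phi, rng)
        fitness_phase(pop, env, mu, rng)
        new = np.flatnonzero(~crossed & (pop.fit > selection.fitness_cutoff))
        if new.size:
            crossed[new] = True
            if len(arrivals) + new.size >= n_parents:
                short = n_parents - len(arrivals)
                if new.size > short:
                    new = rng.choice(new, size=short, replace=False)
                arrivals.extend(int(i) for i in new)
                leave_phase(pop, env, phi, rng)
                return np.array(arrivals), iteration
            arrivals.extend(int(i) for i in new)
        leave_phase(pop, env, phi, rng)


@dataclass
class EvolutionTrajectory:
    """Per-generation population summaries of K, plus the extinction flag."""

    generation: np.ndarray
    mean_k: np.ndarray
    p2_5_k: np.ndarray
    p97_5_k: np.ndarray
    n_eligible: np.ndarray
    elapsed_iterations: np.ndarray
    extinct: bool = False
    extinct_generation: int | None = None
    final_result: GenerationResult | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "mean_k": self.mean_k,
                "p2_5_k": self.p2_5_k,
                "p97_5_k": self.p97_5_k,
                "n_eligible": self.n_eligible,
                "elapsed_iterations": self.elapsed_iterations,
            }
        )


def run_evolution(env: Environment, cfg: CompetitionConfig,
                  selection: SelectionConfig | None = None,
                  n_ind: int = 150, phi: float = 2.0, mu: float = 2.0,
                  n_iterations: int = 500, n_generations: int = 1000,
                  rng: np.random.Generator | None = None,
                  init_k: float = 1.0) -> EvolutionTrajectory:
    """Evolve K over ``n_generations``.  Every individual of generation 1
    starts with K = ``init_k`` (the model's default, K = 1).  The recorded
    summaries describe each generation's population before selection acts.

    Terminates early (with the flag set) if a general-selection generation
    ends with nobody above the fitness cutoff.
    """
    if rng is None:
        rng = np.random.default_rng()
    if selection is None:
        selection = SelectionConfig()
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")

    pop = Population.initial(np.full(n_ind, float(init_k)), mu=mu)
    gens, means, lo, hi, nelig, iters = [], [], [], [], [], []
    extinct = False
    extinct_gen = None
    result = None
    for g in range(1, n_generations + 1):
        gens.append(g)
        means.append(float(pop.k.mean()))
        lo.append(float(np.percentile(pop.k, 2.5)))
        hi.append(float(np.percentile(pop.k, 97.5)))
        if selection.mode == "general":
            result = run_generation(pop, env, cfg, phi=phi, mu=mu,
                                    n_iterations=n_iterations, rng=rng)
            iters.append(n_iterations)
            pop_next, n_elig = reproduce_general(result, selection, n_ind, rng, mu=mu)
            nelig.append(n_elig)
            if pop_next is None:
                extinct = True
                extinct_gen = g
                break
            pop = pop_next
        else:
            parents, elapsed = run_generation_truncated(
                pop, env, cfg, selection, phi=phi, mu=mu,
                nominal_iterations=n_iterations, rng=rng)
            result = GenerationResult.from_population(pop, elapsed)
            iters.append(elapsed)
            nelig.append(int(parents.size))
            draws = parents[rng.integers(parents.size, size=n_ind)]
            k_off = mutate_k(pop.k[draws], selection.mutation_sd, rng, size=n_ind)
            pop = Population.initial(k_off, mu=mu)
    return EvolutionTrajectory(
        generation=np.array(gens),
        mean_k=np.array(means),
        p2_5_k=np.array(lo),
        p97_5_k=np.array(hi),
        n_eligible=np.array(nelig),
        elapsed_iterations=np.array(iters),
        extinct=extinct,
        extinct_generation=extinct_gen,
        final_result=result,
    )
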