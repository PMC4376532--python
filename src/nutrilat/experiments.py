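"""Replicate orchestration, sweeps and summary statistics.

Everything here is deterministic given the config's master seed: the seed
spawns one integer stream seed per (grid point, replicate) cell via
``numpy.random.SeedSequence``, each recorded in the run manifest, and each
replicate runs on its own independent generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .competition import CompetitionConfig
from .config import ExperimentConfig
from .dynamics import run_generation
from .evolution import SelectionConfig, run_evolution
from .geometry import Environment, NutrientPoint
from .population import Population

__all__ = [
    "replicate_seeds",
    "environment_from_config",
    "selection_from_config",
    "composition_k_values",
    "run_single_generation_replicates",
    "run_frequency_sweep",
    "run_evolution_replicates",
    "run_replicates",
    "summarize_k",
]


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """n independent stream seeds derived from one master seed (< 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def environment_from_config(cfg: ExperimentConfig) -> Environment:
    it = NutrientPoint(*cfg.intake_target)
    return Environment.from_ratios(cfg.food_ratios, intake_target=it)


def selection_from_config(cfg: ExperimentConfig) -> SelectionConfig:
    s = cfg.selection
    return SelectionConfig(mode=s.mode, fitness_cutoff=s.fitness_cutoff,
                           truncation_fraction=s.truncation_fraction,
                           mutation_sd=s.mutation_sd)


def composition_k_values(composition) -> np.ndarray:
    """Expand fixed-K groups [(k, count), ...] into a per-individual K array."""
    return np.concatenate([np.full(g.count, g.k) for g in composition])


def run_single_generation_replicates(env: Environment, c: float, k_values,
                                     n_replicates: int, seeds, *, eta: float = 25.0,
                                     mu: float = 2.0, phi: float = 2.0,
                                     n_iterations: int = 500) -> pd.DataFrame:
    """Fixed-K single-generation runs (no evolution): one row per replicate
    per K group, with the group means of the recorded behavioural variables."""
    k_values = np.asarray(k_values, dtype=float)
    cfg = CompetitionConfig.from_competition(c, env.n_food, k_values.size, eta)
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seeds[rep])
        pop = Population.initial(k_values, mu=mu)
        result = run_generation(pop, env, cfg, phi=phi, mu=mu,
                                n_iterations=n_iterations, rng=rng)
        gm = result.group_means()
        for k_group, row in gm.iterrows():
            rows.append({"c": c, "replicate": rep, "seed": seeds[rep],
                         "k_group": float(k_group), **row.to_dict()})
    return pd.DataFrame(rows)


def run_frequency_sweep(env: Environment, c_values, proportions_high,
                        n_replicates: int, master_seed: int, *,
                        k_low: float = 0.25, k_high: float = 0.85,
                        n_ind: int = 150, eta: float = 25.0, mu: float = 2.0,
                        phi: float = 2.0, n_iterations: int = 500) -> pd.DataFrame:
    """Single-generation runs co-varying competition and the proportion of
    the population carrying the high-K strategy; records each group's mean
    end-of-generation fitness."""
    cells = [(c, p) for c in c_values for p in proportions_high]
    seeds = replicate_seeds(master_seed, len(cells) * n_replicates)
    rows = []
    for ci, (c, p) in enumerate(cells):
        n_high = round(p * n_ind)
        k_values = np.concatenate([np.full(n_ind - n_high, k_low), np.full(n_high, k_high)])
        cfg = CompetitionConfig.from_competition(c, env.n_food, n_ind, eta)
        for rep in range(n_replicates):
            seed = seeds[ci * n_replicates + rep]
            rng = np.random.default_rng(seed)
            pop = Population.initial(k_values, mu=mu)
            result = run_generation(pop, env, cfg, phi=phi, mu=mu,
                                    n_iterations=n_iterations, rng=rng)
            row = {"c": c, "proportion_high": p, "replicate": rep, "seed": seed}
            if n_high < n_ind:
                row["fitness_low_k"] = float(result.fitness[k_values == k_low].mean())
            if n_high > 0:
                row["fitness_high_k"] = float(result.fitness[k_values == k_high].mean())
            row["fitness_population"] = float(result.fitness.mean())
            rows.append(row)
    return pd.DataFrame(rows)


def run_evolution_replicates(env: Environment, c_values, n_replicates: int,
                             master_seed: int, *, selection: SelectionConfig | None = None,
                             n_ind: int = 150, eta: float = 25.0, mu: float = 2.0,
                             phi: float = 2.0, n_iterations: int = 500,
                             n_generations: int = 1000) -> pd.DataFrame:
    """Multi-generation evolution runs over a competition grid; one row per
    (c, replicate) with end-state K summaries and the extinction flag."""
    if selection is None:
        selection = SelectionConfig()
    c_values = list(c_values)
    seeds = replicate_seeds(master_seed, len(c_values) * n_replicates)
    rows = []
    for ci, c in enumerate(c_values):
        cfg = CompetitionConfig.from_competition(c, env.n_food, n_ind, eta)
        for rep in range(n_replicates):
            seed = seeds[ci * n_replicates + rep]
            rng = np.random.default_rng(seed)
            traj = run_evolution(env, cfg, selection, n_ind=n_ind, phi=phi, mu=mu,
                                 n_iterations=n_iterations,
                                 n_generations=n_generations, rng=rng)
            row = {"c": c, "replicate": rep, "seed": seed,
                   "extinct": traj.extinct,
                   "extinct_generation": traj.extinct_generation}
            if traj.extinct:
                row.update(final_mean_k=np.nan, final_p2_5_k=np.nan,
                           final_p97_5_k=np.nan, generations_run=traj.extinct_generation)
            else:
                row.update(final_mean_k=float(traj.mean_k[-1]),
                           final_p2_5_k=float(traj.p2_5_k[-1]),
                           final_p97_5_k=float(traj.p97_5_k[-1]),
                           generations_run=int(traj.generation[-1]))
            rows.append(row)
    return pd.DataFrame(rows)


def run_replicates(cfg: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Execute the experiment a config describes and return (tidy results,
    manifest).  A config with ``composition`` set runs fixed-K single
    generations; otherwise a full evolution sweep over the c grid."""
    env = environment_from_config(cfg)
    manifest = {
        "config": cfg.model_dump(),
        "food_ratios": list(cfg.food_ratios),
        "quantile_convention": "linear interpolation (numpy.percentile default)",
        "master_seed": cfg.seed,
    }
    if cfg.composition is not None:
        k_values = composition_k_values(cfg.composition)
        seeds = replicate_seeds(cfg.seed, len(cfg.competition) * cfg.n_replicates)
        frames = []
        for ci, c in enumerate(cfg.competition):
            block = seeds[ci * cfg.n_replicates:(ci + 1) * cfg.n_replicates]
            frames.append(run_single_generation_replicates(
                env, c, k_values, cfg.n_replicates, block, eta=cfg.eta,
                mu=cfg.mu, phi=cfg.phi, n_iterations=cfg.n_iterations))
        df = pd.concat(frames, ignore_index=True)
    else:
        df = run_evolution_replicates(
            env, cfg.competition, cfg.n_replicates, cfg.seed,
            selection=selection_from_config(cfg), n_ind=cfg.n_ind, eta=cfg.eta,
            mu=cfg.mu, phi=cfg.phi, n_iterations=cfg.n_iterations,
            n_generations=cfg.n_generations)
        manifest["extinction_counts"] = {
            str(c): int(df[(df.c == c)].extinct.sum()) for c in cfg.competition
        }
    manifest["seeds"] = [int(s) for s in df["seed"].unique()]
    return df, manifest


def summarize_k(values) -> tuple[float, float, float]:
    """(mean, 2.5th percentile, 97.5th percentile) of a set of K values,
    with the linear-interpolation quantile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty set of K values")
    return float(v.mean()), float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))
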