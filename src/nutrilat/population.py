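"""Population state and per-generation results.

The engine keeps the whole population in flat numpy arrays (struct-of-arrays
layout); an individual is a row index.  Status is one of SEARCHING (off
food, will pick a rail in the next choose phase), FEEDING (occupies a slot
on ``food``), or DISPLACED (lost a contest this iteration and sits out the
rest of it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Environment

SEARCHING = 0
FEEDING = 1
DISPLACED = 2

__all__ = ["SEARCHING", "FEEDING", "DISPLACED", "Population", "GenerationResult"]


@dataclass
class Population:
    x: np.ndarray
    y: np.ndarray
    k: np.ndarray
    fit: np.ndarray
    status: np.ndarray
    food: np.ndarray
    iters_displaced: np.ndarray
    contests_initiated: np.ndarray
    contests_involved: np.ndarray
    contests_won: np.ndarray
    beta_sum: np.ndarray
    feed_events: np.ndarray

    @classmethod
    def initial(cls, k_values, mu: float = 2.0) -> "Population":
        """A fresh generation: all individuals at the natal state (0, 0),
        searching, with fitness exp(-mu) (distance proportion D_N = 1)."""
        k = np.asarray(k_values, dtype=float).copy()
        if k.ndim != 1 or k.size == 0:
            raise ValueError("k_values must be a non-empty 1-D array")
        if np.any((k < 0) | (k > 1)):
            raise ValueError("nutritional latitude K must lie in [0, 1]")
        n = k.size
        return cls(
            x=np.zeros(n),
            y=np.zeros(n),
            k=k,
            fit=np.full(n, np.exp(-mu)),
            status=np.full(n, SEARCHING, dtype=np.int8),
            food=np.full(n, -1, dtype=np.int64),
            iters_displaced=np.zeros(n, dtype=np.int64),
            contests_initiated=np.zeros(n, dtype=np.int64),
            contests_involved=np.zeros(n, dtype=np.int64),
            contests_won=np.zeros(n, dtype=np.int64),
            beta_sum=np.zeros(n),
            feed_events=np.zeros(n, dtype=np.int64),
        )

    @property
    def n(self) -> int:
        return self.x.size

    def snapshot(self) -> dict:
        """Copy of the dynamic state, for trajectory comparisons."""
        return {
            "x": self.x.copy(),
            "y": self.y.copy(),
            "fit": self.fit.copy(),
            "status": self.status.copy(),
            "food": self.food.copy(),
        }


@dataclass
class GenerationResult:
    """Per-individual end-of-generation outcomes.

    ``mean_beta_deg`` is the mean angular difference (degrees) between the
    consumed and ideal rails, averaged over every iteration of the
    generation: an iteration spent displaced (no eating) contributes zero,
    so the statistic reflects both diet balance and feeding opportunity.
    ``mean_beta_feed_deg`` is the same sum averaged over feed events only.
    ``win_rate`` is contests won over contests involved in (NaN when the
    individual had no contests).
    """

    k: np.ndarray
    fitness: np.ndarray
    mean_beta_deg: np.ndarray
    mean_beta_feed_deg: np.ndarray
    iters_displaced: np.ndarray
    contests_initiated: np.ndarray
    contests_involved: np.ndarray
    contests_won: np.ndarray
    win_rate: np.ndarray
    fitness_snapshots: list = field(default_factory=list)
    trajectory: list = field(default_factory=list)

    @classmethod
    def from_population(cls, pop: Population, n_iterations: int,
                        fitness_snapshots=None, trajectory=None) -> "GenerationResult":
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_beta = np.degrees(pop.beta_sum / n_iterations) if n_iterations > 0 \
                else np.full(pop.n, np.nan)
            mean_beta_feed = np.degrees(pop.beta_sum / pop.feed_events)
            win_rate = pop.contests_won / pop.contests_involved
        mean_beta_feed[pop.feed_events == 0] = np.nan
        win_rate[pop.contests_involved == 0] = np.nan
        return cls(
            k=pop.k.copy(),
            fitness=pop.fit.copy(),
            mean_beta_deg=mean_beta,
            mean_beta_feed_deg=mean_beta_feed,
            iters_displaced=pop.iters_displaced.copy(),
            contests_initiated=pop.contests_initiated.copy(),
            contests_involved=pop.contests_involved.copy(),
            contests_won=pop.contests_won.copy(),
            win_rate=win_rate,
            fitness_snapshots=fitness_snapshots or [],
            trajectory=trajectory or [],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "fitness": self.fitness,
                "mean_beta_deg": self.mean_beta_deg,
                "mean_beta_feed_deg": self.mean_beta_feed_deg,
                "iters_displaced": self.iters_displaced,
                "contests_initiated": self.contests_initiated,
                "contests_involved": self.contests_involved,
                "contests_won": self.contests_won,
                "win_rate": self.win_rate,
            }
        )

    def group_means(self) -> pd.DataFrame:
        """Mean of each recorded variable by K value.  NaN entries (no feed
        events / no contests) are excluded from the group means."""
        return self.to_frame().groupby("k").mean()
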