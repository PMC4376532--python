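"""Contest competition over feeding slots.

Each food rail can hold a limited number of simultaneous feeders
(``capacity``), set by the food abundance ``a``.  Competition intensity is
summarised as ``c = 1 - a / n_food``: one minus the proportion of the
population that each rail can support, so c = 0 means free access and
c -> 1 means almost nobody can feed.  A challenger displacing an occupant
wins with a logistic probability in the fitness difference, with steepness
eta (the strength of the nutritional-state -> dominance link).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CompetitionConfig",
    "capacity",
    "competition_level",
    "abundance_from_competition",
    "dominance_probability",
    "resolve_contest",
]


@dataclass(frozen=True)
class CompetitionConfig:
    abundance_a: float
    n_food: int
    n_ind: int
    eta: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.abundance_a <= self.n_food):
            raise ValueError(f"abundance a must be in (0, n_food]; got {self.abundance_a}")
        if self.n_food < 1 or self.n_ind < 1:
            raise ValueError("n_food and n_ind must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")

    @classmethod
    def from_competition(cls, c: float, n_food: int, n_ind: int, eta: float = 25.0) -> "CompetitionConfig":
        return cls(abundance_from_competition(c, n_food), n_food, n_ind, eta)

    @property
    def competition(self) -> float:
        return competition_level(self.abundance_a, self.n_food)

    @property
    def capacity(self) -> float:
        return capacity(self)


def capacity(cfg: CompetitionConfig) -> float:
    """Feeding slots per food, ``a * n_ind / n_food``.

    The value is kept real (e.g. 47.55): a food is at capacity iff its
    current occupant count is >= this value, so 47 occupants is below a
    capacity of 47.55 and 48 is at it.
    """
    return cfg.abundance_a * cfg.n_ind / cfg.n_food


def competition_level(abundance_a: float, n_food: int) -> float:
    """c = 1 - a / n_food, in [0, 1)."""
    if not (0 < abundance_a <= n_food):
        raise ValueError(f"abundance a must be in (0, n_food]; got {abundance_a}")
    return 1.0 - abundance_a / n_food


def abundance_from_competition(c: float, n_food: int) -> float:
    """Inverse of :func:`competition_level`; round-trips exactly."""
    if not (0 <= c < 1):
        raise ValueError(f"competition c must be in [0, 1); got {c}")
    return (1.0 - c) * n_food


def dominance_probability(f_i, f_j, eta):
    """Probability Q_ij that individual i displaces j: a logistic in the
    fitness difference, ``1 / (1 + exp(-eta (F_i - F_j)))``.  Satisfies
    Q_ij + Q_ji = 1."""
    q = 1.0 / (1.0 + np.exp(-eta * (np.asarray(f_i, dtype=float) - f_j)))
    return float(q) if q.ndim == 0 else q


def resolve_contest(q_ij: float, rng: np.random.Generator) -> bool:
    """Single Bernoulli dominance interaction; True iff the challenger wins."""
    return bool(rng.random() < q_ij)
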