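"""Geometric Framework primitives.

The nutrient space is a 2-D Cartesian plane: protein on the x axis,
carbohydrate on the y axis.  A food is a ray ("rail") from the origin whose
slope is the carbohydrate:protein ratio of the food; eating moves an
individual's nutritional state parallel to the rail of the food consumed.
The intake target (IT) is the point in the plane at which fitness is
maximal.  Under the nearest-distance rule of compromise an individual on a
rail eats until its Euclidean distance to the IT is minimised, i.e. until it
reaches the foot of the perpendicular from the IT onto the rail (the point
of nutritional compromise).

All angles are measured counter-clockwise from the protein axis, in
radians.  Scalar and array inputs are both accepted; every function is a
thin numpy expression so the agent engine can evaluate them vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NutrientPoint",
    "Food",
    "Environment",
    "rail_angle",
    "ideal_angle",
    "beta_angle",
    "appetite",
    "eat_step",
    "fitness",
]

HALF_PI = 0.5 * np.pi


@dataclass(frozen=True)
class NutrientPoint:
    """A point in nutrient space (protein, carbohydrate), both >= 0."""

    p: float
    c: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p) and np.isfinite(self.c)):
            raise ValueError("nutrient coordinates must be finite")
        if self.p < 0 or self.c < 0:
            raise ValueError("nutrient coordinates must be non-negative")

    def distance_to(self, other: "NutrientPoint") -> float:
        return float(np.hypot(other.p - self.p, other.c - self.c))


@dataclass(frozen=True)
class Food:
    """A food rail, defined by its nutrient ratio V (carbohydrate per unit
    protein).  The rail angle is derived and cached."""

    value_v: float
    rail_angle: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rail_angle", rail_angle(self.value_v))


@dataclass(frozen=True)
class Environment:
    """An ordered set of food rails plus the intake target."""

    foods: tuple[Food, ...]
    intake_target: NutrientPoint = NutrientPoint(500.0, 500.0)

    def __post_init__(self) -> None:
        if len(self.foods) < 1:
            raise ValueError("environment needs at least one food")
        if self.intake_target.p <= 0 or self.intake_target.c <= 0:
            raise ValueError("intake target must lie strictly inside the positive quadrant")

    @classmethod
    def from_ratios(cls, ratios, intake_target: NutrientPoint | None = None) -> "Environment":
        it = intake_target if intake_target is not None else NutrientPoint(500.0, 500.0)
        return cls(tuple(Food(float(v)) for v in ratios), it)

    @property
    def n_food(self) -> int:
        return len(self.foods)

    @property
    def rail_angles(self) -> np.ndarray:
        return np.array([f.rail_angle for f in self.foods])

    @property
    def initial_distance(self) -> float:
        """Distance from the origin (the natal nutritional state) to the IT;
        the normaliser of the fitness distance D_N."""
        return float(np.hypot(self.intake_target.p, self.intake_target.c))


def rail_angle(value_v):
    """Angle of a food rail with ratio ``value_v`` (carbohydrate per unit
    protein), in (0, pi/2)."""
    v = np.asarray(value_v, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("food ratio V must be finite and > 0")
    out = np.arctan(v)
    return float(out) if np.isscalar(value_v) else out


def ideal_angle(ns_p, ns_c, it_p, it_c):
    """Angle of the 'ideal' rail joining the nutritional state to the IT.

    States past the IT in the protein direction give angles in (pi/2, pi];
    the degenerate state ns == it returns 0 (the caller treats appetite as
    zero there, so the value is never load-bearing).
    """
    dp = np.asarray(it_p, dtype=float) - ns_p
    dc = np.asarray(it_c, dtype=float) - ns_c
    ang = np.arctan2(dc, dp)
    out = np.where((dp == 0) & (dc == 0), 0.0, ang)
    if out.ndim == 0:
        return float(out)
    return out


def beta_angle(ideal, rail):
    """Angular difference beta = |alpha_ideal - alpha_f|, no wrapping."""
    return np.abs(np.asarray(ideal, dtype=float) - rail)


def appetite(ns_p, ns_c, it_p, it_c, rail):
    """Appetite A: distance along the rail to the point of nutritional
    compromise, ``max(0, ||V_T|| cos beta)``.

    The clamp at zero covers states past the compromise point, where the
    rail leads away from the IT: intake is physically non-negative, so the
    individual simply does not eat (the leave rule then drives departure).
    """
    dist = np.hypot(np.asarray(it_p, dtype=float) - ns_p, np.asarray(it_c, dtype=float) - ns_c)
    beta = beta_angle(ideal_angle(ns_p, ns_c, it_p, it_c), rail)
    a = np.maximum(0.0, dist * np.cos(beta))
    return float(a) if a.ndim == 0 else a


def eat_step(ns_p, ns_c, rail, appetite_a, phi):
    """Move ``min(A, phi)`` along the rail direction; returns (p, c)."""
    d = np.minimum(np.asarray(appetite_a, dtype=float), phi)
    p = ns_p + d * np.cos(rail)
    c = ns_c + d * np.sin(rail)
    if np.ndim(p) == 0:
        return float(p), float(c)
    return p, c


def fitness(ns_p, ns_c, it_p, it_c, initial_distance, mu):
    """Fitness F = exp(-mu * D_N), with D_N the distance to the IT expressed
    as a proportion of the start-to-IT distance.  Equals 1 exactly at the
    IT and exp(-mu) at the natal state."""
    dist = np.hypot(np.asarray(it_p, dtype=float) - ns_p, np.asarray(it_c, dtype=float) - ns_c)
    f = np.exp(-mu * dist / initial_distance)
    return float(f) if f.ndim == 0 else f
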