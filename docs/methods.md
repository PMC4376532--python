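# Methods

## The model

`nutrilat` simulates the evolution of a single heritable behavioural trait —
**nutritional latitude, K ∈ [0, 1]** — in a population of foragers that
navigate a two-dimensional nutrient space under contest competition for
feeding slots.

**Nutrient space.** Protein on the x axis, carbohydrate on the y axis, in
abstract units. An individual's position is its nutritional state; every
individual is born at the origin and tries to reach the **intake target**
IT = (500, 500), the intake amount and balance that maximises fitness. A
food is a **rail**: a ray from the origin with slope equal to the food's
carbohydrate:protein ratio V (rail angle α_f = arctan V). Eating moves the
state parallel to the consumed food's rail.

**Appetite (nearest-distance rule of compromise).** On a rail with angle
α_f, an individual whose state is at distance ‖V_T‖ from the IT, with ideal
rail angle α_ideal (the direction from its state to the IT) and angular
mismatch β = |α_ideal − α_f|, has appetite

    A = max(0, ‖V_T‖ · cos β),

the distance along the rail to the foot of the perpendicular from the IT —
the *point of nutritional compromise*, the closest the rail can take it.
Per iteration it moves min(A, φ) with maximum consumption φ = 2. The
clamp at zero is a deliberate choice for states past the compromise point
(where the projection is negative): intake is physically non-negative, the
individual simply stops eating and the leave rule takes over. At the
degenerate state exactly on the IT we define β = 0 and A = 0.

**Fitness.** F = exp(−μ·D_N) with μ = 2 and D_N the current distance to
the IT as a proportion of the origin-to-IT distance (500√2). F is 1 at the
target and exp(−2) ≈ 0.135 at birth, and depends on distance only.

**Competition.** Each of the N_food rails supports at most
capacity = a·N_ind/N_food simultaneous feeders, where a is food abundance.
Competition intensity is reported as c = 1 − a/N_food — one minus the
fraction of the population each rail can support. Capacity is kept
real-valued: a food is *at capacity* iff its occupant count ≥ capacity, so
47 occupants are below a 47.55 capacity and 48 are at it. A searcher that
picks a full food fights one uniformly chosen occupant; the challenger
displaces it with probability

    Q_ij = 1 / (1 + exp(−η (F_i − F_j))),

with dominance steepness η = 25 by default (10 and 20 as documented
variants). The loser — failed challenger or displaced occupant — sits out
the remainder of the iteration.

**Leave rule (where K acts).** After eating, a feeding individual
spontaneously leaves its food with probability

    P_leave = (1 − K) · β / (π/2) + max{0, (K·φ − A)/φ},

clamped to [0, 1]. Low-K (picky) individuals abandon angularly poor foods
quickly; any individual leaves surely once its appetite on the rail is
exhausted. Leavers re-choose a food — possibly the same one — at the next
iteration's choose phase.

**Scheduling.** Each iteration runs four phases to completion over the
whole population, in order: Choose Food → Eat → Calculate Fitness → Leave.
Within each phase individuals act in a freshly drawn random permutation
with immediate state updates. A generation is 500 iterations (354 as a
documented variant for the stricter reading of the generation length).

**Selection.** Two regimes:

* *General* — individuals ending the generation with F strictly greater
  than 0.5 are eligible; N_ind = 150 offspring each draw a parent with
  probability proportional to fitness among eligibles. An empty eligible
  set is an extinction: the replicate terminates and is flagged (and
  counted, never silently dropped, in the output files).
* *Truncated* — the generation has no fixed length; after each iteration's
  fitness phase, individuals newly above the cutoff (0.5 or 0.9) join an
  arrival list, and the first ceil(0.1·N_ind) = 15 become equally weighted
  parents. When a same-iteration batch overshoots the quota, earlier
  arrivals are kept and only that batch is randomly subsampled to fill the
  remaining slots — this preserves "first 10%" semantics for unambiguous
  earlier arrivals. A safety cap (50× the nominal generation length)
  aborts with diagnostics rather than looping forever.

Offspring inherit the parent's K plus Normal(0, 0.025) noise, clamped (not
reflected) to [0, 1], and start at the origin. Generation 1 is initialised
with K = 1 for everyone. Under neutral conditions the clamped walk makes
all K values roughly equally likely (verified by simulation in the test
suite), so sustained directional change reflects selection.

## Recorded statistics

Per individual and generation: final fitness; cumulative iterations spent
displaced; contests initiated, involved in, and won (win rate is NaN with
no contests and excluded from group means); and the angular difference β
between the consumed and ideal rails, accumulated at each feed event.

`mean_beta_deg` divides the accumulated β by the **total number of
iterations** in the generation, so an iteration spent displaced contributes
zero: the statistic mixes diet balance with feeding opportunity. The
per-feed-event average is also exposed (`mean_beta_feed_deg`); the
per-iteration convention is the one whose group means line up with the
published behaviour of the model, and the per-generation accounting
(choose happens first, so every individual either feeds or is displaced
each iteration) makes feed events + displaced iterations = total
iterations.

## Default parameters

| Parameter | Meaning | Default |
|---|---|---|
| IT | intake target (nutrient units) | (500, 500) |
| V | carbohydrate per unit protein, per food | pool {0.0625, 0.5, 1, 2, 16} |
| φ | maximum consumption per iteration | 2 |
| μ | fitness decay with distance | 2 |
| η | dominance steepness | 25 |
| N_ind | population size | 150 |
| a / c | abundance / competition | c ∈ [0, 1) |
| iterations per generation | — | 500 |
| generations | — | 1000 |
| mutation SD of K | — | 0.025 |
| replicates | — | 30 |

Environment presets (config-overridable interpretations, since only the V
pool is pinned): `3-food-mild` {0.5, 1, 2}; `3-food-extreme`
{0.0625, 1, 16}; `2-food-mild` {1, 2}; `2-food-severe` {1, 16};
`2-food-complementary-mild` {0.5, 2}; `2-food-complementary-extreme`
{0.0625, 16}.

## Determinism and the dual engines

All stochasticity flows from one master seed: `SeedSequence(master)` spawns
one integer stream seed per (grid point, replicate) cell, recorded in the
run manifest, so every batch is exactly reproducible and replicates are
independent.

Two engines implement the identical model: the optimised engine
(`nutrilat.dynamics`) vectorises the order-independent phases over numpy
arrays, while `nutrilat.reference` is a deliberately naive per-agent
scheduler with scalar math. Both consume one documented RNG stream
discipline (a permutation per phase; per-searcher draws in the choose
phase; one uniform vector in the leave phase), so from the same seed they
must produce identical trajectories — asserted state-by-state in the test
suite on small instances. This guards the vectorisation against silent
semantic drift.

## Numerical and design choices

* Angles in radians internally, counter-clockwise from the protein axis;
  β = |α_ideal − α_f| without wrapping (both angles lie in [0, π] for
  reachable states). β statistics are reported in degrees.
* Quantiles (the 2.5th/97.5th percentiles of K) use numpy's
  linear-interpolation convention, recorded in every manifest.
* Opponent choice indexes the ascending-agent-index list of current
  occupants, part of the RNG discipline shared by both engines.
* A displaced individual loses exactly the current iteration (cannot eat or
  re-choose until the next choose phase); its displaced counter increments
  once per displacement.
* Contest eligibility uses strict inequality (F > cutoff) in both
  selection regimes.
* `mutation_sd = 0` is accepted (exact-inheritance limit used by tests);
  the scientific default stays 0.025.

## Scaled problem sizes in the test suite

The full study design (30 replicates × 1000 generations per grid point) is
what the CLI reproductions run. The test suite verifies the
single-generation statistics at full size (30 replicates, 500 iterations)
and the evolutionary equilibria at a scaled size chosen to keep the suite
desk-runnable: 5 replicates × 200 generations, which the K trajectories
(initialised at K = 1) have reached their regime by.

## Known limitations

* The location of the sharp low-K → high-K transition along the
  competition axis is sensitive to scheduling micro-details that are not
  pinned down by the model description (who re-chooses when, occupant
  bookkeeping order). Under this implementation's scheduling the
  transition in the mild 3-food environment sits near c ≈ 0.73–0.75;
  single-generation behavioural statistics on either side of it (c = 0.683
  and c = 0.767) are insensitive to this and reproduce tightly.
* Rails are inexhaustible (only slots are limited); there is no spatial
  structure, no satiation, no sex structure, and a single rule of
  compromise (nearest distance). These are model assumptions, not
  simplifications of this implementation.
* The model is not calibrated to any organism's empirical nutrient budget;
  all units are abstract, so conclusions are qualitative (regime structure,
  orderings), not quantitative predictions for a real forager.
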