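"""Truncated selection: the first decile past the fitness cutoff breed.

Runs one open-ended generation in which iterations continue until the first
10% of the population (15 of 150) cross F = 0.5; those arrivals become the
(equally weighted) parents.  Under this regime extinction is impossible —
the generation simply runs longer when food is scarce.
"""

import numpy as np

from nutrilat import (CompetitionConfig, Environment, Population,
                      SelectionConfig, run_generation_truncated)

env = Environment.from_ratios([0.5, 1.0, 2.0])
cfg = CompetitionConfig.from_competition(0.7, env.n_food, 150, eta=25.0)
sel = SelectionConfig(mode="truncated", fitness_cutoff=0.5)
pop = Population.initial(np.ones(150))
parents, elapsed = run_generation_truncated(pop, env, cfg, sel,
                                            rng=np.random.default_rng(5))
print(f"{parents.size} parents assigned after {elapsed} iterations "
      "(a fixed-length generation would have stopped at 500)")
print(f"parent fitness range: {pop.fit[parents].min():.3f} .. {pop.fit[parents].max():.3f}")
print(f"population fitness range: {pop.fit.min():.3f} .. {pop.fit.max():.3f}")
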