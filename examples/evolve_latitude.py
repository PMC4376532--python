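"""Evolution of nutritional latitude K under intense competition.

One replicate, 80 generations at c = 0.767 in the mild 3-food environment:
every individual starts at K = 1 and the population mean drifts under
selection and mutation (SD 0.025 per transmission).
"""

import numpy as np

from nutrilat import CompetitionConfig, Environment, run_evolution

env = Environment.from_ratios([0.5, 1.0, 2.0])
cfg = CompetitionConfig.from_competition(0.767, env.n_food, 150, eta=25.0)
traj = run_evolution(env, cfg, n_generations=80, rng=np.random.default_rng(1))

print("generation   mean K   [2.5th, 97.5th pct]   eligible parents")
for g in (1, 10, 20, 40, 60, 80):
    i = g - 1
    print(f"{traj.generation[i]:>10d}   {traj.mean_k[i]:.3f}    "
          f"[{traj.p2_5_k[i]:.3f}, {traj.p97_5_k[i]:.3f}]   {traj.n_eligible[i]:>6d}")
print("\nAt this competition level a high K is maintained: tolerating an "
      "imbalanced food beats losing feeding time to contests over scarce "
      "balanced foods.")
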