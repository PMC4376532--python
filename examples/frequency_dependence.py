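"""Frequency dependence of the two latitude strategies.

Co-varies the proportion of the population carrying high K (0.85) with the
competition level, one generation at a time, and prints the relative
fitness of high K (its group mean fitness minus the low-K group's).  A sign
change across proportions marks frequency-dependent selection.
"""

from nutrilat import Environment, run_frequency_sweep

env = Environment.from_ratios([0.5, 1.0, 2.0])
df = run_frequency_sweep(env, [0.683, 0.725, 0.767], [0.1, 0.3, 0.5, 0.7, 0.9],
                         n_replicates=4, master_seed=2)
g = df.groupby(["c", "proportion_high"])[["fitness_low_k", "fitness_high_k"]].mean()
g["relative_high"] = g.fitness_high_k - g.fitness_low_k
print(g.round(4))
print("\nNegative relative_high: the picky (low-K) strategy wins; positive: "
      "the tolerant strategy wins.  At intermediate competition the sign "
      "flips as high K becomes common -- the invasion is frequency dependent.")
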