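"""Nested comparison of per-dish amplitudes across three conditions.

Neurons are nested in dishes: each dish is first collapsed to its mean
amplitude, then the dish means are compared by one-way ANOVA with a
Bonferroni post-hoc — the per-replicate-unit reading of a nested design.
"""

import numpy as np
import pandas as pd

from motiflux import group_summary, nest_aggregate, one_way_anova, pairwise_posthoc

rng = np.random.default_rng(11)
rows = []
for cond, mu in [("control", 1.25), ("OVA", 1.30), ("OVA-FPM", 1.55)]:
    for dish in range(5):
        for neuron in range(rng.integers(5, 10)):
            rows.append((cond, f"{cond}_d{dish}", rng.normal(mu, 0.12)))
data = pd.DataFrame(rows, columns=["group", "unit", "value"])

dish_means = nest_aggregate(data)
groups = {g: grp["value"].tolist() for g, grp in dish_means.groupby("group")}

print("per-dish mean amplitudes (mean ± SEM per condition):")
print(group_summary(groups).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

res = one_way_anova(groups)
print(f"\none-way ANOVA on dish means: F({res.df_between},{res.df_within}) = "
      f"{res.f_statistic:.2f}, p = {res.p_value:.4f}")

print("\nBonferroni-adjusted pairwise comparisons:")
print(pairwise_posthoc(groups, "bonferroni")
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nCollapsing to dish means first keeps the replication unit honest: "
      "neurons within a dish are not independent samples.")
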