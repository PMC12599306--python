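"""Infer pairwise functional interactions and test their significance.

For each ordered strain pair (focal, partner) the interaction strength is
the difference in the focal strain's mean functional effect between
backgrounds containing vs lacking the partner (64 vs 64 backgrounds at
p=8), tested with a two-sided Welch t-test.  Negative = subadditive,
positive = synergistic.
"""

import subcomm as sc

params = sc.study_preset(seed=0)
landscape = sc.generate_landscape(params)

inter = sc.interaction_matrix(landscape, alpha=0.05)
neg, pos = sc.significant_interaction_counts(inter)
print(f"significant interactions at P<0.05: {neg} negative, {pos} positive "
      f"(of 28 unordered pairs)\n")

pairs = inter[inter["focal"] < inter["partner"]].sort_values("p").head(5)
print(pairs[["focal", "partner", "strength", "t", "p"]].to_string(index=False))
print("\nStrength is in activity-AUC units (RFU.h): how much the partner "
      "shifts the focal strain's average functional effect.")
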