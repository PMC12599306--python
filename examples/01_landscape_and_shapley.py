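"""Generate a study-scale synthetic landscape and rank strains by Shapley value.

Builds the full 2^8 = 256-composition landscape (4 replicates each), then
computes each nondegrader strain's Shapley value -- its average marginal
effect on community function over all 8! assembly orderings -- and compares
the estimates with the generator's closed-form ground truth.
"""

import numpy as np

import subcomm as sc

params = sc.study_preset(seed=0)
landscape = sc.generate_landscape(params)
print(f"landscape: {len(landscape.records)} records over "
      f"{len(landscape.compositions())} compositions (complete={landscape.is_complete})")

shap = sc.shapley_exact(landscape)
truth = sc.closed_form_shapley(params)
print("\nstrain   phi (RFU.h)   ground truth")
for s, phi, t in sorted(zip(shap.strain_ids, shap.phi, truth), key=lambda x: -x[1]):
    print(f"{s:6s} {phi:12.0f} {t:14.0f}")
print("\nPositive phi = the strain raises aniline-utilization activity on "
      "average across assembly orders; estimates differ from truth only "
      "through replicate noise.")
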