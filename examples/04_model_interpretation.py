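"""Recover key species and interactions from a trained forest.

Computes permutation importance (which strains the model relies on) and
Friedman's H (how strongly feature pairs interact inside the model) from a
forest trained only on 3-4-member subcommunities, then correlates them with
the empirical Shapley values and interaction strengths of the full
landscape.
"""

import numpy as np
from scipy import stats

import subcomm as sc

params = sc.study_preset(seed=0)
landscape = sc.generate_landscape(params)
names = list(params.panel.strain_ids)

X, y = sc.build_design_matrix(landscape, (3, 4))
model = sc.fit_regressor(X, y, seed=7)

imp = sc.permutation_importance(model, X, y, k_perms=50, seed=7, feature_names=names)
h_tab = sc.h_matrix(model, X, feature_names=names)
shap = sc.shapley_exact(landscape)
inter = sc.interaction_matrix(landscape)

report = sc.compare_to_empirical(imp, h_tab, shap, inter)
print(report[["metric", "r", "p", "spearman_rho", "n"]].to_string(index=False))

gabs = np.abs(params.gamma[np.triu_indices(8, 1)])
r_truth = stats.pearsonr(h_tab["H"], gabs)[0]
print(f"\nH vs true |gamma| (generator ground truth): r = {r_truth:.2f}")
print("High correlations mean a model trained only on small subcommunities "
      "identifies the same key strains and strain pairs as the exhaustive "
      "empirical landscape analysis.")
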