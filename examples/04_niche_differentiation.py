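"""Climatic niche comparison between two species.

Generates two virtual species whose niches differ only in one driver's
optimum (3 grid standard deviations apart), then runs the full comparison:
PCA with broken-stick retention and Tukey tests, exhaustive condition-number/
VIF variable selection, cross-validated L2 logistic discrimination, and
linear Shapley attributions.
"""

import numpy as np

from climniche import synthetic
from climniche.differentiation import (
    anova_tukey, classification_metrics, fit_l2_logistic_cv, linear_shap,
    pca, split_train_test, subset_select_condition_vif,
)

table, truth = synthetic.two_species_scenario(
    spec=synthetic.SyntheticClimateSpec(n_vars=6, seed=21),
    offset_sd=3.0, n_per_species=200, seed=21,
)
df = table.drop(columns=["lon", "lat"])
print(f"species: {truth['species']}, planted driver: {truth['offset_variables']}")

res = pca(df)
print(f"PCA: first two components explain "
      f"{100 * res.proportions[:2].sum():.1f}% of the variation; "
      f"broken-stick retains {res.retained} component(s)")
_, tukey = anova_tukey(res.scores, df["species"], components=range(max(1, res.retained)))
row = tukey.iloc[0]
print(f"Tukey on PC1: p = {row['p']:.2e} "
      f"({'significant' if row['significant'] else 'not significant'} at p < 0.001)")

sel = subset_select_condition_vif(df)
print(f"VIF-selected variables: {sel.final_subset} "
      f"(all VIF <= 10; kappa of final set = "
      f"{sel.per_size[sel.per_size['size'] == len(sel.final_subset)]['condition_number'].iloc[0]:.2f})")

train, test = split_train_test(df[["species", *sel.final_subset]], seed=21)
model = fit_l2_logistic_cv(train, sel.final_subset, tuple(truth["species"]), seed=21)
metrics = classification_metrics(model, test)
print(f"L2 penalty chosen by 5-fold CV: {model.lambda_pen:.3f}")
print("test metrics: " + "  ".join(f"{k}={v:.3f}" for k, v in metrics.items()))

phi, _ = linear_shap(model, test)
ranking = phi.abs().mean().sort_values(ascending=False)
print("mean |Shapley attribution| per variable:")
for var, val in ranking.items():
    print(f"  {var}: {val:.3f}")
print("The planted driver should dominate the attributions: the classifier "
      "separates the species chiefly along the variable whose optimum differs.")
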