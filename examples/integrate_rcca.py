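"""Regularized CCA between the human cytokine block and the in-vivo outcomes.

rCCA extracts correlated latent dimensions between two matrices even when
features outnumber samples; the feature-feature similarity matrix is the
quantity usually drawn as a cross-correlation heatmap.
"""

import adjuscreen as ads

blocks, outcomes, truth = ads.generate_cohort(ads.SimConfig(seed=0))
X = ads.scale_columns(blocks["human_cytokine"].data).data
Y = ads.scale_columns(outcomes).data

lam1, lam2, surface = ads.tune_rcc(X, Y, lambda_grid=[1e-3, 1e-2, 1e-1, 1.0], seed=1)
print(f"tuned ridge penalties: lambda1={lam1}, lambda2={lam2}")

model = ads.rcca(X, Y, lam1, lam2, n_dims=3)
print("canonical correlations:", model.canonical_correlations.round(3))

sim = ads.similarity_matrix(model, n_dims=2)
pairs = sim.stack().sort_values(ascending=False)
print("strongest positive feature-outcome similarities:")
print(pairs.head(5).round(3).to_string())
# The planted cytokines should dominate the top pairs against the IgG
# fold-change endpoints, mirroring what the heatmap view would highlight.
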