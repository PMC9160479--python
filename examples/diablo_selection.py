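"""Discriminant multiblock feature selection (high vs low adjuvanticity).

Substances are dichotomized at the cohort-mean total-IgG fold change; the
sparse multiblock discriminant model then selects 10 features per block on
component 1 and tags each with the class it is dominant in -- the analysis
that identifies positive (cytokine) and negative (particle) screening
parameters.
"""

import adjuscreen as ads

blocks, outcomes, truth = ads.generate_cohort(ads.SimConfig(seed=0))
scaled = {name: ads.scale_columns(b.data).data for name, b in blocks.items()}
labels = ads.dichotomize(outcomes["totalIgG_fc"])

model = ads.block_splsda(scaled, labels, keepX=10, n_comp=1)

for block in model.block_names:
    tags = model.dominant_class[block][0]
    print(f"{block}: " + ", ".join(f"{f}({c})" for f, c in tags.items()))

print("\nplanted positive human cytokines:", truth.informative_human)
print("planted negative particle population:", truth.informative_particle)
print(
    "negative population tagged:",
    model.dominant_class["particle"][0].get(truth.informative_particle),
)
# The planted cytokines should appear tagged "high" and the planted particle
# population tagged "low" -- a negative screening parameter.
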