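"""Generate a synthetic 80-substance cohort and inspect its planted structure.

The cohort mimics a screening library of 73 extracts plus 7 potent control
adjuvants: three in-vitro feature blocks and six in-vivo endpoints, driven
by a positive latent factor (on a handful of cytokines) and an independent
negative latent factor (on one particle population).
"""

import numpy as np

import adjuscreen as ads

blocks, outcomes, truth = ads.generate_cohort(ads.SimConfig(seed=0))

print("block shapes:", {name: b.data.shape for name, b in blocks.items()})
print("outcome endpoints:", list(outcomes.columns))
print("planted positive human cytokines:", truth.informative_human)
print("planted negative particle population:", truth.informative_particle)

r_pos = np.corrcoef(
    blocks["human_cytokine"].data[truth.informative_human[0]], outcomes["totalIgG_fc"]
)[0, 1]
r_neg = np.corrcoef(
    blocks["particle"].data[truth.informative_particle], outcomes["totalIgG_fc"]
)[0, 1]
print(f"corr({truth.informative_human[0]}, total IgG fold change) = {r_pos:+.3f}")
print(f"corr(population {truth.informative_particle}, total IgG fold change) = {r_neg:+.3f}")
# A positive correlation for the planted cytokine and a negative one for the
# particle population confirm the two independent planted signals.
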