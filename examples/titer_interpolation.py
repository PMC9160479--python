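"""Endpoint-titer interpolation and fold changes from ELISA dilution curves.

The endpoint titer is the reciprocal plasma dilution at which the OD450
curve crosses 0.2, found by linear interpolation in (log10 dilution, OD).
"""

import adjuscreen as ads

series = ads.generate_dilution_series(true_titer=9000.0, seed=4)
print("dilutions:", series.dilutions.astype(int).tolist())
print("OD450:    ", series.od_values.round(3).tolist())

result = ads.titer_from_od(series)
print(f"interpolated endpoint titer: {result.titer:.1f} (censored: {result.censored})")

# fold change of an adjuvanted group against the antigen-alone group
fc = ads.fold_change(group_values=[9000.0, 12000.0], reference_values=[800.0, 1200.0])
print(f"fold change vs antigen alone: {fc:.2f}")

# background-subtracted cytokine concentration (pg/mL)
delta = ads.background_subtract(values=[412.0, 388.0], background_values=[55.0, 45.0])
print(f"background-subtracted concentration: {delta:.1f} pg/mL")
# The titer should recover the 9000 used to build the curve; the fold change
# and subtraction are the group-level summaries fed into the feature blocks.
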