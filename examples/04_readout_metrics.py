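"""ΔΔCq relative expression and control-normalised readouts.

A knockdown sample with target Cq one cycle above the non-targeting
control (housekeeping unchanged) has ΔΔCq = 1, i.e. half the expression.
"""

import crispri_specificity as cs

rel = cs.relative_expression(
    cq_target_sample=21.0, cq_hk_sample=20.0,
    cq_target_ntc=20.0, cq_hk_ntc=20.0,
)
print(f"relative expression (2^-DDCq): {rel}")
print(f"percent repression: {100 * (1 - rel):.1f}%")

norm = cs.normalized_readout(350.0, 140.0)
print(f"normalised fluorescence readout: {norm}")
# 2.5x the untreated-control signal; percent_knockdown(30, 120) would give
# 0.75, i.e. 75% loss of signal relative to control.
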