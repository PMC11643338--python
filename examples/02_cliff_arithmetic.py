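"""Potency conversions and activity-cliff magnitudes.

Converts nanomolar potencies to the pChEMBL scale, measures the cliff
between two compounds, and labels a matched molecular pair by its
delta-pKi.
"""

from cliffaware import cliff_value, fold_change, label_mmp, pchembl_from_nanomolar

potent, weak = 56.5, 1357.0  # IC50 values in nM for two structural analogs
y1 = pchembl_from_nanomolar(potent)
y2 = pchembl_from_nanomolar(weak)
cliff = cliff_value(y1, y2)
print(f"{potent} nM  -> pChEMBL {y1:.3f}")
print(f"{weak} nM -> pChEMBL {y2:.3f}")
print(f"cliff = |{y1:.3f} - {y2:.3f}| = {cliff:.3f} pChEMBL units")
print(f"fold change = 10^{cliff:.3f} = {fold_change(cliff):.1f}x in potency")
# A cliff of 1 unit is a 10-fold potency change; 2 units is 100-fold.

for delta in (2.5, 1.5, 0.4):
    print(f"MMP with delta-pKi {delta}: {label_mmp(delta).value}")
# Pairs between the two bands (1, 2) carry no label and are excluded.
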