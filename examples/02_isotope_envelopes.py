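"""Isotope envelopes of an analyte and its 18O-labeled internal standard.

The standard is the same peptide with up to two C-terminal carboxyl
oxygens exchanged to 18O (95% per site). Because incorporation is
incomplete, the labeled envelope has binomial components at +0, +2 and
+4 Da that overlap the analyte's natural envelope — the reason
quantitation uses envelope deconvolution rather than single peak
heights.
"""

from acecleave import composition_of, get_substrate, fragment
from acecleave.isotopes import LabelingModel, isotope_pattern, labeled_pattern

analyte = fragment(get_substrate("Ac-ratAbeta1-16-amide"), 1, 13)
comp = composition_of(analyte)
print(f"analyte: {analyte.name} ({comp.hill_formula()})\n")

print("natural envelope (neutral mass, fraction):")
for mass, abundance in isotope_pattern(comp).peaks:
    print(f"  {mass:10.4f}  {abundance:.4f}")

lm = LabelingModel(n_sites=2, p_inc=0.95)
print("\n18O-labeled standard envelope (p_inc=0.95, 2 sites):")
for mass, abundance in labeled_pattern(comp, lm).peaks:
    print(f"  {mass:10.4f}  {abundance:.4f}")

print("\nbinomial label-site weights (shift, weight):")
for shift, weight in lm.site_state_weights():
    print(f"  +{shift:.4f} Da  {weight:.4f}")
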