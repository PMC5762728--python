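"""Absolute quantitation with an 18O-labeled internal standard.

Builds a synthetic mixture spectrum of an analyte (5 uM) and its
heavy standard (10 uM, 95% per-site 18O over 2 sites), with 5%
intensity noise and a random calibration offset, then recovers the
analyte concentration by nonnegative envelope deconvolution.
"""

import numpy as np

from acecleave import SpectrumParams, fragment, get_substrate, quantify_analyte, render_spectrum
from acecleave.isotopes import LabelingModel

analyte = fragment(get_substrate("Ac-ratAbeta1-16-amide"), 1, 13)
lm = LabelingModel(n_sites=2, p_inc=0.95)
true_conc, standard_conc = 5.0, 10.0

sp = SpectrumParams(noise_cv=0.05, seed=1)
spectrum = render_spectrum(
    [(analyte, true_conc, None), (analyte, standard_conc, lm)], sp
)
est = quantify_analyte(spectrum, analyte, lm, standard_conc)
print(f"analyte: {analyte.name}")
print(f"true concentration:      {true_conc:.3f} uM")
print(f"recovered concentration: {est.analyte_conc:.3f} uM "
      f"(analyte/standard ratio {est.ratio:.3f})")

errors = []
for seed in range(50):
    sp = SpectrumParams(noise_cv=0.05, seed=seed)
    s = render_spectrum(
        [(analyte, true_conc, None), (analyte, standard_conc, lm)], sp
    )
    e = quantify_analyte(s, analyte, lm, standard_conc)
    errors.append(abs(e.analyte_conc - true_conc) / true_conc)
print(f"\nmedian |relative error| over 50 replicates: "
      f"{100 * float(np.median(errors)):.2f}% "
      "(the reference method error bound is 10%)")
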