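# acecleave

Limited-proteolysis cleavage mapping of amyloid-β metal-binding-domain
peptides by angiotensin-converting enzyme (ACE), with MALDI-TOF peak
matching, ¹⁸O internal-standard quantitation, and molecular-dynamics
contact statistics.

## The scientific problem

The N-terminal region 1–16 of amyloid-β (the metal-binding domain, MBD:
`DAEFRHDSGYEVHHQK` in human) carries the sites at which somatic ACE
attacks Aβ. Whether ACE acts there as a canonical dipeptidyl
carboxypeptidase or as an endopeptidase — and which of its two catalytic
domains (N-ACE, C-ACE) is responsible — depends critically on the
substrate's termini: a C-terminal amide mimics continuation of the chain
in full-length Aβ(1-40/42) and switches N-ACE to an arginine-specific
endopeptidase (Arg↓His: Arg5-His6 in human, Arg13-His14 in the rat MBD,
which differs by R5G/Y10F/H13R). This package implements the complete
computational chain behind that kind of study, for researchers mapping
protease specificity on synthetic peptide panels by peptide-mass
fingerprinting:

* **exact masses** — monoisotopic \[M+H\]⁺ of peptides with N-acetyl /
  C-amide terminal modifications (amide −0.984 Da, acetyl +42.011 Da);
* **isotope envelopes** — elemental convolution on a 0.2 Da
  reflector-resolution grid, plus the binomial ¹⁸O labeling model for
  internal standards made by hydrolysis in heavy water;
* **a protease rule engine** — declarative cleavage rules (endopeptidase,
  dipeptidyl/processive carboxypeptidase, substrate-condition and
  inhibitor clauses) with the observed ACE behaviour shipped as the
  `ace_observed` preset, and complete tryptic digestion for standard
  preparation;
* **peak matching and mode inference** — assignment of centroid peaks to
  candidate fragments within a mass tolerance (±0.3 Da default),
  cleavage-map inference with explicit bookkeeping of complementary
  evidence and matrix-suppressed complements (< m/z 500), enzyme-mode
  classification, and inhibitor-control validation;
* **quantitation** — absolute product concentration from the overlapping
  analyte/¹⁸O-standard envelopes by nonnegative least-squares
  deconvolution (c ≈ (c_A/c_S)·c_standard), plus the peak-height-ratio
  calibration-line variant;
* **synthetic data** — first-order digestion time courses and MALDI-like
  centroid spectra (envelopes × concentration, calibration offset,
  lognormal intensity noise, matrix suppression) so every stage is
  testable without an instrument;
* **trajectory statistics** — Kabsch-superposed RMSD series, hydrogen-bond
  contact populations (d(D···A) ≤ 3.5 Å, ∠H-D-A ≤ 30°), φ/ψ dihedral
  series and tetrahedral-zinc retention checks for Michaelis-complex
  stability analyses.

## Worked example

```python
from acecleave import (SpectrumParams, digest_with_rules,
                       enumerate_candidate_fragments, get_substrate,
                       infer_cleavage_map, match_peaks, render_spectrum)

substrate = get_substrate("Ac-Abeta1-16-amide")   # [Acetyl]-DAEFRHDSGYEVHHQK-[Amide]
digest = digest_with_rules(substrate, "N-ACE")
mixture = {substrate: 20.0, **{p: 10.0 for p in digest.products}}
spectrum = render_spectrum(mixture, SpectrumParams(noise_cv=0.0, calibration_offset=0.0))
matches = match_peaks(spectrum, enumerate_candidate_fragments(substrate),
                      tol=0.3, substrate=substrate)
cmap = infer_cleavage_map(matches, substrate)
print(sorted(cmap.bonds), cmap.mode_call)
```

prints

```
[5] endopeptidase
```

meaning a single cleaved bond between residues 5 and 6 (Arg5-His6),
corroborated by both complementary fragments — \[Acetyl\]-Aβ(1-5) at m/z
679.30458 and Aβ(6-16)-\[Amide\] at 1335.61887 — and classified as
endoproteolytic because the cut is far from the C-terminus. The
`examples/` directory holds one short narrative script per capability
(exact masses, envelopes, closed-loop inference, quantitation,
trajectory statistics); each prints the numbers it computes and one
line on what they mean. A thin CLI mirrors the library:
`acecleave mass|pattern|digest|simulate|match|infer|quant|trajstats|run`.

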