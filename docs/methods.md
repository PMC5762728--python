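# Methods

This note documents the models, parameter choices and numerical
conventions behind `acecleave`, and what the synthetic-data tests do and
do not demonstrate about real instrument data.

## Mass arithmetic

Peptide masses are monoisotopic sums over fixed atomic masses
(H 1.0078250319, C 12, N 14.0030740052, O 15.9949146221, S 31.97207069;
proton 1.00727646 Da). Residue compositions cover the 20 standard amino
acids in their dehydrated (in-chain) form; a peptide adds one water plus
the terminal deltas: N-acetyl +C2H2O (+42.010565 Da), C-amide +NH−O
(−0.984016 Da). \[M+zH\]z+ is (M + z·m_p)/z; all MALDI work here is z=1.
Fragments inherit terminal modifications positionally: an N-terminal
fragment keeps the substrate's N-modification and gains a free carboxyl,
a C-terminal fragment gains a free amine and keeps the C-modification,
internal fragments are free/free. Bond *i–(i+1)* means the peptide bond
between 1-based parent positions i and i+1; cleaving it yields
(start..i) and (i+1..end). Two useful identities follow and are enforced
as property tests: complementary fragments' \[M+H\]⁺ values exceed the
parent's by 19.01784 Da (one water + one extra proton), and composition
is additive over concatenation minus one water per bond formed.

Average masses, multiple charging and side-chain modifications are out
of scope; only the two terminal groups are modelled.

## Isotope envelopes

Envelopes are predicted by convolving per-element isotope distributions
(fixed IUPAC representative abundances; the n-atom distribution of an
element is built by binary powering of its single-atom distribution).
Peaks are pruned below 1e-15 during convolution and finally aggregated
on a 0.2 Da grid (abundance-weighted centroids), which is what a
MALDI-TOF reflector resolves: isotopomer spacing but not fine
structure. The default truncation threshold of 1e-4 relative abundance
leaves ~8 visible peaks for a 2 kDa peptide. Truncation drops peaks
without renormalizing, so retained abundances remain true fractions of
the whole envelope.

### ¹⁸O labeling model

Internal standards are made by enzymatic hydrolysis of a known amount
of the same peptide in heavy water, which places solvent oxygen at the
new C-terminal carboxyl. The model has two parameters: `n_sites`
(0–2 exchangeable carboxyl oxygens) and `p_inc` (per-site ¹⁸O
probability, default 0.95 for 95–98% ¹⁸O water). The labeled envelope
is the natural envelope of the composition minus `n_sites` oxygens,
convolved with a binomial over the sites (¹⁶O with 1−p, ¹⁸O with p;
shift 2.0042458 Da per heavy oxygen). Two modelling notes: (i) label
sites carry pure ¹⁶O/¹⁸O rather than natural oxygen isotopy, so the
p=0 envelope differs from the natural one by the missing ¹⁷O/¹⁸O
contribution of those sites (~0.4% of abundance for two oxygens) — an
approximation inherent to the site model; (ii) how an *amidated*
analyte acquires two exchangeable oxygens under tryptic labeling
chemistry is not fully determined (the water-derived oxygen lands on
the N-terminal-side fragment), so `n_sites` is configurable per
standard rather than hard-coded to 2.

## The cleavage rule engine

Rules are declarative: an enzyme name, a mode, optional P1/P1′ residue
sets, substrate conditions (required/forbidden C-terminal modification,
an exact-sequence clause), a trim range for carboxypeptidase modes, and
the inhibitors that silence the rule. Modes:

* *endopeptidase* — cut every bond whose flanking residues are in
  P1/P1′, emitting both complementary fragments;
* *dipeptidyl_carboxypeptidase* — remove exactly the C-terminal
  dipeptide (bond n−2);
* *processive_carboxypeptidase* — remove k residues from the C-terminus
  for every k in `min_trim..max_trim`. The trim range generalizes a
  fixed depth because the observed C-domain behaviour differs between
  substrates: di- and tripeptide removal from the free human MBD
  (depths 2–3) versus depths 1–3 on the amidated rat MBD.

A single call applies each matching rule once to the intact substrate
(limited hydrolysis); iterative digestion is available by feeding
products back. The shipped `ace_observed` preset encodes the observed
domain behaviour — N-ACE: Arg↓His endopeptidase on C-amidated MBDs,
dipeptidyl carboxypeptidase on the free acid; C-ACE: processive
carboxypeptidase on free substrates, blocked by amidation of the human
MBD, active at depths 1–3 on the amidated rat MBD; lisinopril silences
every ACE rule. The preset encodes observed products, not mechanism:
the engine itself is generic and presets are plain YAML. Tryptic
digestion (standard preparation) cleaves after Lys/Arg except before
Pro, to completion, partitioning the substrate.

Kinetic competition between sites, pH and buffer effects are not
modelled; buffers are metadata only.

## Synthetic spectra and time courses

The generator emulates positive-reflector-mode centroid spectra of
digestion mixtures. Each species contributes its (optionally labeled)
envelope scaled by concentration × response; the spectrum then receives
one calibration offset (default drawn per spectrum from N(0, 0.15 Da),
matching ≤0.2 Da calculated-vs-observed centroid discrepancies),
multiplicative lognormal intensity noise (default CV 5%, unit mean),
removal of peaks below the matrix-suppression cutoff (default m/z 500 —
chosen so the unobservable Gln15-Lys16 dipeptide at ~275 falls below it
and the smallest observed product at 679.3 stays above), and 0.2 Da
centroid merging. Spectra are centroid-only (no peak shapes, detector
saturation or dead-time distortion) and bit-reproducible per seed.

Digestion kinetics are independent first-order events per bond: the
substrate decays with the summed rate and each bond's complementary
product pair accrues in proportion to its rate share, conserving chain
count exactly. Rate constants are free generator parameters (the
incubation conditions constrain but do not determine them); the
pipeline default is 0.05 min⁻¹ per cleavable bond.

What passing tests show: the analysis chain is correct on data whose
noise model is known. What they do not show: robustness to chemical
background, adducts, detector saturation, or envelope distortion in
real MALDI spectra.

## Peak matching and cleavage-map inference

Matching is monoisotopic against each candidate's first envelope peak,
with a ±0.3 Da default tolerance — wide enough for reflector centroid
error (largest printed calculated-vs-observed gap ~0.2 Da), narrow
enough that no alternative candidate of these substrates comes within
0.9 Da. In a full-envelope spectrum, peaks recognized as higher
isotopomers (a comparable peak one 1.00335 Da spacing below) are not
assigned. All candidates within tolerance are reported nearest-first;
ambiguity is preserved, never resolved silently.

Each non-parent matched fragment implies its boundary bond(s). A bond
is *corroborated* when both complementary fragments matched; a
one-sided bond is *accepted* when the missing complement's \[M+H\]⁺
falls below the suppression cutoff (it could not have been seen), and
kept but flagged *tentative* otherwise. Mode classification is
geometric, with precedence: a single cut exactly two residues from the
C-terminus → dipeptidyl carboxypeptidase; cuts at several depths within
the last three residues → processive carboxypeptidase; cuts at internal
bonds (≥3 residues from the C-terminus) evidenced by an N-terminally
truncated product, a complementary pair, or a suppressed complement →
endopeptidase; anything else → ambiguous. Notably an N-terminally
truncated product is direct endoproteolysis evidence regardless of
complement status, since no carboxypeptidase can produce it. Inhibitor
validation checks that no mapped product peak appears in a control
spectrum above an intensity floor (default 3× the control's median
intensity, configurable — the floor convention is a package choice, as
no printed value exists).

## Quantitation

Because ¹⁸O incorporation is incomplete, the standard's envelope
overlaps the analyte's at +2 Da; peak-height ratios are therefore
biased, and the default estimator deconvolves instead: both predicted
envelopes and the observed region are projected onto a common 0.2 Da
grid and split by nonnegative least squares (`scipy.optimize.nnls`),
giving c_A, c_S and a residual; the concentration is
(c_A/c_S)·c_standard. Before fitting, a global recalibration removes
the per-spectrum offset as the median observed-minus-predicted
difference against the combined model envelope (envelope peaks are ~1 Da
apart, so nearest-peak assignment is unambiguous for offsets ≪0.5 Da).
Identical (degenerate) patterns and absent-standard fits raise explicit
errors rather than returning numbers. The calibration-line variant
(least-squares line of peak-height ratio vs known load, with an
inverting predictor) is provided as the simpler published alternative.
The noiseless generator round trip is exact to 1e-6 relative; at 5%
intensity noise the median recovery error is ~3% (see
`scripts/acceptance.py`), within the 10% method-error bound.

## Trajectory statistics

Superposition is the Kabsch SVD solution restricted to proper
rotations; RMSD series use frame 0 as reference, matching the
convention of reporting drift relative to initial structures.
Hydrogen-bond populations use the common geometric criterion —
donor–acceptor distance ≤ 3.5 Å and H-donor-acceptor angle ≤ 30°,
boundary values counting as satisfied — as the fraction of frames
passing. Dihedrals follow the IUPAC sign convention in (−180°, 180°],
computed by the projection/atan2 formula, with circular mean/variance
helpers for motility summaries. The zinc check declares tetrahedral
coordination retained when all four Zn-ligand distances lie in
1.8–2.6 Å and the mean deviation of the six ligand-Zn-ligand angles
from arccos(−1/3) ≈ 109.47° is ≤15° (both configurable). Coordinates
are Å internally; multi-model PDB and XYZ trajectories are read via
MDAnalysis; selections use a `chain:resid:atom` mini-language.

Production-scale (100 ns) trajectories of the enzyme–peptide complexes
are not distributed, so no published contact-population numbers are
asserted; instead `synth_trajectory` builds frames with contacts
geometrically enforced on/off per a schedule (plus Gaussian jitter),
and every statistic is validated by construction against such
trajectories, plus brute-force oracles (random rotation grids for
Kabsch optimality, an independent normal-vector dihedral formula).

## Problem sizes and determinism

Default test and acceptance problem sizes — 16-residue substrates
(136-candidate fragment spaces), 100 quantitation replicates, 500–1000
frame synthetic trajectories, 10⁴-rotation oracle grids — were chosen
to exercise every code path at full fidelity while keeping the whole
suite around a minute. Every stochastic component takes an explicit
seed (`numpy.random.default_rng`); fixed seeds make spectra,
trajectories and pipeline artifacts bit-reproducible.

## Known limitations

Only the 20 standard residues and two terminal groups; no isoAsp or
other side-chain chemistry (the isomerized-Asp7 species discussed in
the wider literature is not measurable here). Centroid-only spectral
model. Single-cleavage digestion per call. Mode classification is
geometric and can return *ambiguous* where real assays would resolve
the mode with kinetics or inhibitor panels. Quantitation assumes equal
ionization response of analyte and standard — exact for an isotopic
pair, but calibration-line usage across different peptides inherits
response differences.
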