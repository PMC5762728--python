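# Observed ACE-domain behaviour on amyloid-beta metal-binding-domain
# substrates, encoded as declarative cleavage rules (preset "ace_observed").
# Human MBD: DAEFRHDSGYEVHHQK; rat MBD: DAEFGHDSGFEVRHQK (R5G, Y10F, H13R).
schema_version: 1
preset: ace_observed
rules:
  # N-ACE is an arginine-specific endopeptidase (Arg|His) on C-amidated MBDs.
  - enzyme: N-ACE
    mode: endopeptidase
    p1: [R]
    p1prime: [H]
    requires_c_mod: amide
    inhibitable_by: [lisinopril]
  # On the free acid, N-ACE falls back to canonical dipeptidyl
  # carboxypeptidase action (His14-Gln15 on the human MBD).
  - enzyme: N-ACE
    mode: dipeptidyl_carboxypeptidase
    requires_c_mod: free
    inhibitable_by: [lisinopril]
  # C-ACE removes C-terminal di- and tripeptides from free substrates
  # (bonds His13-His14 and His14-Gln15 on the human MBD) ...
  - enzyme: C-ACE
    mode: processive_carboxypeptidase
    requires_c_mod: free
    min_trim: 2
    max_trim: 3
    inhibitable_by: [lisinopril]
  # ... is fully blocked by C-amidation of the human MBD (no rule), but
  # trims the amidated rat MBD processively at depths 1-3 (bonds
  # Arg13-His14, His14-Gln15, Gln15-Lys16).
  - enzyme: C-ACE
    mode: processive_carboxypeptidase
    requires_c_mod: amide
    requires_sequence: DAEFGHDSGFEVRHQK
    min_trim: 1
    max_trim: 3
    inhibitable_by: [lisinopril]
  # Trypsin (standard preparation): after K/R, not before P.
  - enzyme: trypsin
    mode: endopeptidase
    p1: [K, R]
    p1prime: [A, C, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, W, Y]
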