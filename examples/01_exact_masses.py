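"""Exact [M+H]+ masses of the four MBD substrates and their fragments.

Computes monoisotopic masses of the amyloid-beta metal-binding-domain
(MBD) substrates from sequence and terminal modifications, and shows
the characteristic mass shifts: C-amidation (-0.984 Da, mimicking
chain continuation) and N-acetylation (+42.011 Da).
"""

from acecleave import SUBSTRATE_REGISTRY, composition_of, fragment, mz_of

print(f"{'substrate':32s} {'formula':22s} [M+H]+")
for name, peptide in SUBSTRATE_REGISTRY.items():
    print(f"{name:32s} {composition_of(peptide).hill_formula():22s} "
          f"{mz_of(peptide):.5f}")

sub = SUBSTRATE_REGISTRY["Ac-Abeta1-16-amide"]
left, right = fragment(sub, 1, 5), fragment(sub, 6, 16)
print(f"\nendopeptidase products of {sub.name}:")
print(f"  {left.name:28s} {mz_of(left):.5f}")
print(f"  {right.name:28s} {mz_of(right):.5f}")
surplus = mz_of(left) + mz_of(right) - mz_of(sub)
print(f"  fragment sum - parent = {surplus:.5f} Da "
      "(one water + one extra proton: complementarity check)")
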