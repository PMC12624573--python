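"""Enumerate the hybrid (fusion) peptide search library.

Fuses every N-terminal secretory-granule fragment variant (0-6 residues
trimmed from its C terminus) to every C-terminal fragment variant (0-6
trimmed from its N terminus), then demonstrates junction-spanning matching.
"""

from isletpep import enumerate_fusions, match_fusions

fusions = enumerate_fusions()
print(f"fusion library size: {len(fusions)}  (5 x 7 N variants  x  9 x 7 C variants)")

example = fusions[0]
print(f"first record: {example.header}")
print(f"  sequence {example.sequence}")
print(f"  junction after residue {example.junction}")

# a peptide straddling the fusion point is a hit; one inside a single
# fragment is not
spanning = example.sequence[example.junction - 4 : example.junction + 4]
internal = example.sequence[: example.junction][:10]
for pep, hits in match_fusions([spanning, internal], fusions):
    print(f"peptide {pep}: {len(hits)} junction-spanning hit(s)")
print()
print("Only junction-spanning matches count as evidence for a hybrid peptide;")
print("matches inside one un-fused fragment are explained by the parent protein.")
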