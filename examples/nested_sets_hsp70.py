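"""Cluster MHC-II length variants into a nested set.

Uses eight naturally processed Hsp70 (HSPA1B) peptides that bracket the
predicted DQ6 binding core NQPGVLIQV: endosomal proteases trim the termini
of an MHC-II-bound peptide, so one binding event shows up as a family of
length variants sharing a core.
"""

from isletpep import ElutionClass, PeptideRecord, cluster_nested_sets

VARIANTS = [
    "TYSDNQPGVLIQVYEGER",
    "TYSDNQPGVLIQVYEGE",
    "YSDNQPGVLIQVYEGE",
    "YSDNQPGVLIQVYEG",
    "SDNQPGVLIQVYEGE",
    "SDNQPGVLIQVYEG",
    "DNQPGVLIQVYEGER",
    "DNQPGVLIQVYEGE",
]

records = [
    PeptideRecord(sequence=s, sample_id="donor1", elution_class=ElutionClass.DQ)
    for s in VARIANTS
]
sets = cluster_nested_sets(records, overlap_min=6)
for nset in sets:
    print(f"nested set: {nset.size} members, core {nset.core}")
    for member in nset.members:
        print(f"  {member.sequence}")
print()
print("One set means all eight variants overlap (directly or through chains)")
print("by >=6 residues; the core is the longest substring common to all of")
print("them and contains the predicted DQ6 binding core NQPGVLIQV.")
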