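"""Candidate-epitope triage: gene-set flags, Venn partition, rank abundance.

Tags curated peptides by membership of their source genes in the three
candidate gene sets (pancreas-enriched, cytokine-upregulated,
T1D-upregulated), partitions them into Venn cells, ranks source proteins by
summed precursor intensity, and tests two gene sets for overlap.
"""

from isletpep import (
    GeneSetTable,
    SyntheticConfig,
    curate,
    gene_set_overlap_test,
    generate_immunopeptidome,
    rank_abundance,
    tag_candidates,
    venn_counts,
)

syn = generate_immunopeptidome(SyntheticConfig(seed=17))
curated, _ = curate(syn.records)

table = GeneSetTable.from_dict(syn.gene_sets)
labels = tag_candidates(curated, table)
print("Venn cells (counts of curated peptides):")
for cell, n in sorted(venn_counts(labels).items()):
    print(f"  {cell:45s} {n}")
n_cand = sum(1 for l in labels if l.is_candidate)
print(f"candidate epitopes (any set flag): {n_cand}")

rows = rank_abundance(curated)
top = [r for r in rows if r.elution_class == "ABC"][:3]
print("\ntop MHC-I source proteins by summed precursor intensity:")
for r in top:
    print(f"  rank {r.rank}: {r.accession} ({r.gene_symbol}) total {r.total_intensity:.3g}")

odds, p = gene_set_overlap_test(
    syn.gene_sets["cytokine_up"], syn.gene_sets["t1d_up"], universe_size=len(syn.proteome)
)
print(f"\ncytokine_up vs t1d_up overlap: odds ratio {odds:.2f}, Fisher p = {p:.3g}")
print("A small p would mean the two gene sets share more genes than chance.")
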