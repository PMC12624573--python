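# isletpep

Curation and epitope-discovery analysis for MHC-I / MHC-II immunopeptidomes
of inflamed human pancreatic islets.

In type 1 diabetes (T1D), autoreactive T cells destroy insulin-producing β
cells. Finding the naturally processed, MHC-presented peptides that those T
cells see requires eluting peptides from MHC complexes of islet tissue and
identifying them by mass spectrometry — but islet elutions carry a heavy
background of secretory-hormone processing intermediates that co-purify even
on control columns, and the surviving peptides still need allele assignment,
clustering, and triage before any are worth synthesizing for T cell assays.
`isletpep` implements that analysis as a tested Python library for
computational immunologists working from identified-peptide tables (spectra
and search engines are upstream and out of scope).

## What it does

* **Background subtraction** — removes contaminant-derived peptides
  (keratins, immunoglobulins, actin), everything eluted from beads-only /
  isotype-control columns, and every MHC-elution peptide sharing a
  contiguous identical substring of ≥ 6 residues with a control peptide;
  then applies the class length windows (8–13 aa for MHC-I, 12–30 aa for
  MHC-II). Each stage reports per-sample counts, and retained + removed
  always equals the input.
* **Nested-set clustering** — MHC-II peptides are grouped into connected
  components of the ≥ 6-residue-overlap graph; each set's core is the
  maximal substring common to all members. Summary statistics report unique
  counts, median lengths, and the fraction of peptides in multi-member sets.
* **Tiered HLA allele assignment** — each peptide is scored against the
  donor's alleles by a pluggable percentile-rank predictor (rank ∈ [0,100],
  lower = stronger). Primary tier: any allele at rank ≤ 2% (MHC-I) or ≤ 5%
  (MHC-II); otherwise the cutoff extends to ≤ 10%; the rest stay
  unassigned. A position-weight-matrix predictor and a rank-table adapter
  (for externally computed ranks) are included.
* **Hybrid (fusion) peptide library** — enumerates every fusion of 5
  N-terminal × 9 C-terminal secretory-granule fragments with 0–6 residues
  trimmed from the fusing ends (5·7 × 9·7 = 2 205 sequences), writes the
  library as FASTA, and screens observed peptides for junction-spanning
  matches.
* **PTM prevalence** — filters modification sites by localization A-score
  (A = −10·log₁₀ p; the default threshold 13 corresponds to p ≤ 0.05) and
  summarizes each modification as an intensity fraction,
  modified / (modified + unmodified) at the same peptide loci.
* **Candidate triage** — flags peptides whose source genes fall in
  pancreas-enriched / cytokine-upregulated / T1D-upregulated gene sets,
  partitions them into Venn cells, matches against known-epitope catalogs,
  builds rank-abundance tables of source proteins, and tests gene-set
  overlaps with a one-sided Fisher exact test.
* **Validation statistics** —
  ELISpot positivity by distribution-free resampling (DFR): for each
  peptide, H₀: mean(exp wells) ≤ m · mean(control wells) with m = 1 (DFR1x)
  or m = 2 (DFR2x), tested by permutation with Westfall–Young maxT
  adjustment across the plate, after imputing empty wells to the 0.3
  spots-per-well detection floor. Competition binding: fluorescence
  polarization readings are normalized to fraction bound
  y = (FP_sample − FP_free)/(FP_no_comp − FP_free) and fit to the
  one-parameter model y = 1/(1 + [pep]/IC50).
* **Synthetic data** — a seeded generator emits fully labelled peptide
  tables (motif-bearing MHC-I peptides, MHC-II nested sets, hormone
  background shared with control elutions, PTMs, gene sets) and validation
  assays, so every stage has ground truth to recover.

## Worked example

Clustering eight naturally processed Hsp70 (HSPA1B) length variants into a
nested set (`python examples/nested_sets_hsp70.py`):

```
nested set: 8 members, core DNQPGVLIQVYEG
  DNQPGVLIQVYEGE
  DNQPGVLIQVYEGER
  SDNQPGVLIQVYEG
  SDNQPGVLIQVYEGE
  TYSDNQPGVLIQVYEGE
  TYSDNQPGVLIQVYEGER
  YSDNQPGVLIQVYEG
  YSDNQPGVLIQVYEGE
```

All eight variants chain together through ≥ 6-residue overlaps; the core
`DNQPGVLIQVYEG` is the longest substring common to all members and contains
the predicted DQ6 binding core `NQPGVLIQV` — one MHC-II binding event seen
through eight protease trim states.

Running the tiered allele assignment on a default synthetic peptidome
(`python examples/assign_alleles.py`):

```
tier counts: {'primary': 586, 'extended': 2, 'unassigned': 2}
true allele recovered at primary tier: 586/590 (99.3%)
```

Each curated peptide receives exactly one call; on motif-generated synthetic
peptides the generating allele is recovered at the primary tier for ≥ 90% of
peptides. The other `examples/` scripts demonstrate curation, the fusion
library, PTM summaries, triage, and the validation statistics the same way.

## Layout

* `src/isletpep/` — the library (`model`, `io`, `background_filter`,
  `nested_sets`, `alleles`, `hybrids`, `ptm`, `triage`, `validation`,
  `synth`).
* `examples/` — one short narrative script per capability.
* `tests/` — unit, property, and acceptance tests, including brute-force
  oracle cross-checks.
* `docs/methods.md` — the statistical and algorithmic methods note.
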