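# Methods

This note records the models, algorithmic choices, and parameter defaults
behind `isletpep`, and what the synthetic-data generator does and does not
emulate.

## Scope and data model

The pipeline begins at *identified-peptide tables*: rows of (sequence,
sample, elution column, source protein, precursor intensity, PTM
annotations). Spectrum processing, database search, and FDR control are
upstream concerns of the search engine; their outputs are consumed, never
recomputed. Elution columns are ABC (pan-MHC-I), DR/DQ/DP (locus-specific
MHC-II), and two control columns (protein A-only beads, isotype-control
antibody beads) whose eluates define the non-MHC background. Sequences are
restricted to the 20 canonical residues; rows carrying ambiguity codes
(B, J, X, Z, U, O) are rejected rather than coerced, because the overlap
and motif machinery below assumes the canonical alphabet.

## Background subtraction

Curation runs three fixed stages, each reporting per-sample removal counts
so that retained + removed = input at every stage:

1. **Contaminants.** Records whose any parent accession or gene matches a
   blocklist of regular expressions (keratins `^KRT`, immunoglobulins
   `^IG[HKL]`, actins `^ACT[ABG]`, plus spelled-out names) are removed.
   Multi-mapped peptides are removed if *any* parent matches.
2. **Control overlap.** Within each sample, an MHC-elution peptide is
   removed when it equals a control-elution peptide or shares a contiguous
   identical substring of ≥ `overlap_min` residues (default 6) with one.
   "Overlap by ≥ 6 residues" is interpreted as an exact contiguous
   substring — no gaps, no mismatches — which is equivalent to sharing a
   6-mer; the implementation uses a control 6-mer index and the tests
   cross-check it against a full dynamic-programming longest-common-
   substring oracle. Control rows are dropped (and counted as removed). A
   config switch pools controls across samples; a sequence whitelist
   exempts curated hormone epitopes an analyst has manually rescued
   (empty by default). Samples with no control rows pass through with a
   warning.
3. **Length windows.** MHC-I (ABC) peptides outside 8–13 residues and
   MHC-II (DR/DQ/DP) peptides outside 12–30 residues are removed.

The stage order (contaminants → control overlap → lengths) affects per-rule
counts but not the final set; the chain is idempotent.

## Nested-set clustering

MHC-II binding is open-groove: protruding termini are variably trimmed by
endosomal proteases, so one binding event yields several length variants
sharing a core. Peptides (within one sample × elution class, or pooled via
a flag) are clustered as **connected components** of the graph whose edges
join peptides with a shared ≥ 6-residue substring — transitive closure, so
chain members need not overlap directly. Each set's **core** is the
maximal-length substring common to all members; ties resolve to the
leftmost occurrence in the lexicographically first member, making the
output independent of input order. The core is a string-algebra object,
not an inferred 9-mer binding register. Summary statistics count unique
sequences; a peptide is "nested" when its set has ≥ 2 distinct member
sequences.

## Tiered allele assignment

A *rank predictor* maps (peptide, allele) to a percentile rank in [0, 100],
lower = stronger predicted binding, mirroring how eluted-ligand predictors
report ranks against a random-peptide background. Two implementations:

* **Table adapter** — reads externally computed ranks (TSV of peptide,
  allele, rank), so production predictions can be slotted in without
  running the external tool here.
* **PWM predictor** — score = best-window sum of log-odds (PWM weight over
  the uniform 1/20 background) across all contiguous windows of the motif
  length; rank = midrank percentile of that score against 10,000 random
  length-matched substrings of a background proteome. Background draws are
  seeded per (allele, length) so ranks are deterministic regardless of
  query order. Peptides shorter than the motif rank 100. The midrank
  convention makes the rank of a background-like peptide uniform with
  median ≈ 50.

Assignment: MHC-I peptides are tested against the donor's class-I alleles,
MHC-II peptides against class-II alleles of the eluting antibody's locus
(DR column → DRB alleles, etc.; a flag disables locus matching). If ≥ 1
allele has rank ≤ τ_class (2% for MHC-I, 5% for MHC-II) the peptide is
**primary** and all such alleles are assigned; otherwise alleles at rank
≤ 10% give an **extended** call; otherwise **unassigned**. The extended
cutoff is consulted per peptide, not per allele. Non-classical class-I
products are simply not listed in donor genotypes by default.

## Hybrid (fusion) peptide library

Fusion candidates are enumerated from a panel of 5 N-terminal and 9
C-terminal secretory-granule fragments: for each N fragment, variants with
0–6 residues removed from its C terminus; for each C fragment, 0–6 removed
from its N terminus; every N variant fused to every C variant. Depth 0 (the
untrimmed fragment) is included, giving 5·7 × 9·7 = 2 205 records, and
identical sequences are deliberately **not** deduplicated — the library is
an enumeration, not a set. Each record carries its four coordinates
(N name, N trim, C name, C trim) and the junction index, and reconstructs
from them. Matching against an observed peptidome requires the match to
span the junction (≥ 1 residue on each side); matches inside one un-fused
fragment are evidence for the parent protein, not a hybrid.

## PTM summaries

Modification sites carry an A-score on the A = −10·log₁₀ p scale; sites
with A < 13 (p > 0.05) are dropped (the comparator is configurable; the
inclusive ≥ 13 is the default). Prevalence per modification is an
**intensity fraction**: for modification m, the loci are the backbone
sequences of peptides carrying an accepted m; the fraction is the summed
precursor intensity of m-carrying records at those loci over the summed
intensity of all records (modified or not) at the same loci, computed per
tissue (pooling samples within tissue; per-sample available). Defining the
denominator at the stripped-backbone locus level is this module's principal
interpretive decision: it compares each modified form against the
co-observed unmodified form of the same peptide. Fractions are invariant to
uniform intensity rescaling; a locus set with zero reference intensity
reports `None`, not 0.

## Candidate triage

Peptides are flagged by membership of any parent gene (multi-mapped
peptides use the union of parents) in three gene sets — pancreas-enriched,
cytokine-upregulated, T1D-upregulated — whose upstream differential-
expression computation is out of scope; the sets are consumed as tables.
The three flags induce a 7-cell Venn partition plus "none", which always
partitions the input. Known-epitope matching defaults to bidirectional
containment (the observed peptide equals, contains, or is contained in a
catalog sequence). Rank-abundance tables sum precursor intensity per source
protein within each elution class (multi-mapped peptides contribute full
intensity to every parent; no splitting), sort descending with
lexicographic tie-break, and assign ranks 1..N; sums use `fsum` over sorted
addends so results are independent of row order. Gene-set overlap is a
one-sided (enrichment) Fisher exact test on the 2×2 membership table
against a stated universe size.

## Validation statistics

**FP competition binding.** Fraction bound is
y = (FP_sample − FP_free)/(FP_no_comp − FP_free); values outside [0, 1] are
kept (they are informative noise) but logged, and a zero dynamic range is a
hard error. The competition curve is the one-parameter model
y = 1/(1 + [pep]/IC50) — no Hill slope, floor, or ceiling. Fitting scans
log₁₀ IC50 on a grid spanning 4 decades beyond the tested concentrations
(241 points) and refines the best grid point with bounded scalar
minimization (tolerance 1e−10 in log space); the procedure is
deterministic, recovers noiseless truth to ≪ 1% across ≥ 3 decades, and
flags a flat response (range < 10⁻³) as non-converged instead of returning
a number.

**DFR ELISpot positivity.** Wells below the 0.3 spots-per-well detection
floor are raised to it *before* testing. For each peptide the statistic is
mean(exp) − m·mean(ctrl); control wells are scaled by m (1 for DFR1x, 2 for
DFR2x) and pooled with the experimental wells, and well labels are
permuted. With a single hypothesis and ≤ 10,000 distinct label
arrangements the permutation distribution is enumerated exactly (the
p-value includes the observed arrangement); otherwise Monte-Carlo
permutations (default 2,000, seeded) are shared across the peptides of a
plate and adjusted by Westfall–Young step-down maxT. Two deliberate
choices: the statistic is the *raw* mean difference (not studentized), and
permutations are shared across multipliers under the same seed. For
non-negative counts, the permuted-minus-observed statistic is then
non-decreasing in m for every permutation, which makes "DFR2x positive ⇒
DFR1x positive" hold deterministically, matching the interpretation of
DFR2x as the stricter null. The permutation form of the resampling is
implemented from the stated nulls; it is documented as this package's
construction, not asserted to be bit-identical to any external tool.
Hypotheses with fewer than 2 experimental or 2 control wells are skipped
with a warning.

## Synthetic-data generator

The generator emits the structure the analysis assumes, with ground-truth
labels for every record, from a single PCG64 seed:

* **MHC-I peptides** (default 400): length drawn from
  {8: .12, 9: .42, 10: .20, 11: .12, 12: .09, 13: .05} (median 9), with an
  8-mer allele motif sampled from the allele's PWM embedded at a random
  offset.
* **Motifs**: one PWM per donor allele (8-mer class I, 9-mer class II), 4
  anchor positions at weight 0.95, spread evenly across the motif as in
  real MHC motifs — clustered anchors would let unrelated motif peptides
  share ≥ 6-residue runs and corrupt nested-set clustering. Non-anchor rows
  get mild log-normal perturbations (σ = 0.15) so PWM scores are
  effectively continuous, as for real predictors; exactly uniform rows
  would make percentile ranks collapse onto tie classes.
* **MHC-II nested sets** (default 150 cores, DR:DQ:DP ≈ .68:.25:.07): each
  core (length 12–16, containing a 9-mer class-II motif) sits in a parent
  context with 6-residue flanks; members are context windows with
  geometric (p = 0.5, capped at 6) terminal extensions. A core spawns a
  multi-member set with probability 0.16, of size 2 + Poisson(1.5), so the
  expected fraction of peptides in multi-member sets is
  0.16·3.5 / (0.16·3.5 + 0.84) = 0.40, and the member-length median is 16.
* **Hormone background**: windows (9–25 aa) of five synthetic prohormone
  proteins planted in both control elutions (60 each) and, with ≤ 3-residue
  start/length jitter (guaranteeing a shared ≥ 6-mer), in the MHC elutions
  (40) — realistic prey for the control-overlap filter. Contaminant
  peptides (20) come from keratin/Ig/actin parents.
* **Intensities** log-normal (μ = 10, σ = 1.5 on the log scale); **PTMs**
  sprinkled on 15% of peptides with A-scores uniform on [0, 40] (truth
  records whether each passes the 13 threshold); **gene sets** of 15 genes
  drawn from the ordinary-protein genes.
* **ELISpot plates**: 2 experimental wells per peptide and 6 DMSO control
  wells (duplicate test wells with 6–10 controls being the usual design),
  Poisson counts with control mean 3.0 spw and a 10× mean shift for true
  responders. The 3.0 spw background is a deliberate choice: with integer
  counts, duplicate wells, and an exact permutation p floored at 1/28, a
  near-zero background produces ties that cap DFR power regardless of
  effect size; a moderate background — well within the typical PBMC
  IFN-γ ELISpot range — is the regime in which DFR2x retains high power at
  large effects while keeping its low false-positive rate.
* **FP series**: 8 five-fold dilutions from 40 µM, true IC50 285 nM,
  Gaussian noise σ = 0.03 on fraction bound.

What the generator does *not* emulate: MS acquisition and identification
error (no missed or false identifications), real motif degeneracy and
allele cross-reactivity, shared flank sequence biology beyond the parent
context, inter-sample batch structure, and correlated PTM placement.
Passing parameter-recovery tests therefore demonstrates correctness of the
implemented statistics and algorithms under their stated assumptions, not
performance on real immunopeptidome data.

## Numerical and determinism notes

* All randomness flows from integer seeds through `numpy.random.default_rng`
  (PCG64); derived seeds are kept below 2³¹.
* The ≥ k-overlap predicate is implemented as shared-k-mer membership,
  provably equivalent to longest-common-substring ≥ k, and tested against
  the O(n·m) DP oracle.
* Ties: nested-set cores break leftmost-in-first-member after lexicographic
  sort; rank-abundance ties break by accession; fusion enumeration order is
  (N index, n_trim, C index, c_trim).
* Degenerate inputs: empty FASTA, zero-range FP series, zero-size gene
  sets, and fragments shorter than the trim depth are hard errors; missing
  controls, empty blocklists, and too-few-well hypotheses are warnings with
  pass-through/skip semantics.

## Test-suite problem sizes

Randomized oracle-equivalence suites run 100 seeds with instances of tens
to hundreds of peptides (the regime where the brute-force references are
exact and fast); parameter-recovery runs use the generator defaults
(~600-peptide curated tables, ~1,000 unique MHC-II peptides for the
nested-fraction check); calibration uses 1,000 null ELISpot plates, 300
Fisher null draws, and 100 noisy IC50 replicates. These sizes are the
package's own choice of test scale: large enough for the stated tolerances
(±5 percentage points, < 1% / < 5% IC50 error, α + 2·SE) to be meaningful,
small enough that the whole suite runs in well under a minute.
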