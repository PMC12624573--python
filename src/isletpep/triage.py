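"""Candidate-epitope triage against gene sets and known-epitope catalogs.

Candidate selection flags each curated peptide by membership of its source
gene(s) in three sets — proteins enriched in pancreas, genes upregulated by
in vitro cytokine treatment, and genes upregulated in T1D donors — and by
exact/nested identity with a catalog of known autoimmune epitopes. The
three boolean flags induce a 7-cell Venn partition (plus "none"). Rank-
abundance tables sum precursor intensity per source protein within each
elution class for the classic rank-abundance display, and gene-set
similarity is tested with a one-sided Fisher exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import fisher_exact

from .model import PeptideRecord

logger = logging.getLogger("isletpep")

SET_NAMES = ("pancreas_enriched", "cytokine_up", "t1d_up")


@dataclass(frozen=True)
class GeneSetTable:
    pancreas_enriched: frozenset[str]
    cytokine_up: frozenset[str]
    t1d_up: frozenset[str]

    @classmethod
    def from_dict(cls, sets: dict[str, Sequence[str]]) -> "GeneSetTable":
        def norm(name: str) -> frozenset[str]:
            return frozenset(g.upper() for g in sets.get(name, ()))

        return cls(*(norm(n) for n in SET_NAMES))

    def membership(self, genes: Sequence[str]) -> tuple[bool, bool, bool]:
        gset = {g.upper() for g in genes}
        return (
            not gset.isdisjoint(self.pancreas_enriched),
            not gset.isdisjoint(self.cytokine_up),
            not gset.isdisjoint(self.t1d_up),
        )


@dataclass(frozen=True)
class CandidateLabel:
    peptide: PeptideRecord
    pancreas_enriched: bool
    cytokine_up: bool
    t1d_up: bool
    known_epitope_exact: bool
    known_antigen_source: bool

    @property
    def is_candidate(self) -> bool:
        return self.pancreas_enriched or self.cytokine_up or self.t1d_up

    @property
    def venn_cell(self) -> str:
        parts = [
            name
            for name, flag in zip(
                SET_NAMES, (self.pancreas_enriched, self.cytokine_up, self.t1d_up)
            )
            if flag
        ]
        return "+".join(parts) if parts else "none"


def _epitope_match(peptide: str, catalog: Sequence[str], bidirectional: bool) -> bool:
    for epi in catalog:
        if peptide == epi:
            return True
        if bidirectional and (peptide in epi or epi in peptide):
            return True
    return False


def tag_candidates(
    records: Sequence[PeptideRecord],
    gene_sets: GeneSetTable,
    known_epitopes: Sequence[str] = (),
    known_antigens: Sequence[str] = (),
    bidirectional_epitope_match: bool = True,
) -> list[CandidateLabel]:
    """Flag each peptide by gene-set membership and catalog identity.

    Any parent gene counts for the set flags (multi-mapped peptides use the
    union of parents). Known-epitope matching is bidirectional containment
    by default: the observed peptide may equal, contain, or be nested
    inside a catalog epitope.
    """
    if not (gene_sets.pancreas_enriched or gene_sets.cytokine_up or gene_sets.t1d_up):
        logger.warning("all gene sets empty: no candidate flags will be set")
    antigens = {g.upper() for g in known_antigens}
    labels = []
    for rec in records:
        p, c, t = gene_sets.membership(rec.genes)
        labels.append(
            CandidateLabel(
                peptide=rec,
                pancreas_enriched=p,
                cytokine_up=c,
                t1d_up=t,
                known_epitope_exact=_epitope_match(
                    rec.sequence, known_epitopes, bidirectional_epitope_match
                ),
                known_antigen_source=not antigens.isdisjoint(
                    g.upper() for g in rec.genes
                ),
            )
        )
    return labels


def venn_counts(labels: Sequence[CandidateLabel]) -> dict[str, int]:
    """Counts per Venn cell; cells plus "none" partition the input."""
    out: dict[str, int] = {}
    for lab in labels:
        out[lab.venn_cell] = out.get(lab.venn_cell, 0) + 1
    return out


@dataclass(frozen=True)
class RankAbundanceRow:
    accession: str
    gene_symbol: str
    elution_class: str
    total_intensity: float
    rank: int  # 1 = most intense within the elution class


def rank_abundance(records: Sequence[PeptideRecord]) -> list[RankAbundanceRow]:
    """Sum precursor intensity per source protein and rank within class.

    Multi-mapped peptides contribute their full intensity to every parent
    protein. Ties in total intensity break by accession lexicographic
    order; ranks are 1..N within each elution class.
    """
    sums: dict[tuple[str, str], list[float]] = {}
    genes: dict[str, str] = {}
    for rec in records:
        if rec.elution_class.is_control:
            continue
        for acc in rec.accessions:
            key = (rec.elution_class.value, acc)
            sums.setdefault(key, []).append(rec.precursor_intensity)
            genes.setdefault(acc, ";".join(rec.genes))
    rows: list[RankAbundanceRow] = []
    by_class: dict[str, list[tuple[str, float]]] = {}
    for (cls, acc), vals in sums.items():
        # fsum keeps totals independent of input row order
        by_class.setdefault(cls, []).append((acc, math.fsum(sorted(vals))))
    for cls, items in sorted(by_class.items()):
        items.sort(key=lambda it: (-it[1], it[0]))
        for rank, (acc, total) in enumerate(items, 1):
            rows.append(
                RankAbundanceRow(
                    accession=acc,
                    gene_symbol=genes.get(acc, ""),
                    elution_class=cls,
                    total_intensity=total,
                    rank=rank,
                )
            )
    return rows


def gene_set_overlap_test(
    set_a: Sequence[str], set_b: Sequence[str], universe_size: int
) -> tuple[float, float]:
    """One-sided Fisher exact test for enrichment of the overlap.

    Returns (odds ratio, p). The 2x2 table counts genes in both sets, in
    one set only, and in neither, against a universe of ``universe_size``.
    """
    a = {g.upper() for g in set_a}
    b = {g.upper() for g in set_b}
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    both = len(a & b)
    only_a = len(a) - both
    only_b = len(b) - both
    neither = universe_size - both - only_a - only_b
    if neither < 0:
        raise ValueError("universe smaller than the union of the sets")
    odds, p = fisher_exact([[both, only_a], [only_b, neither]], alternative="greater")
    return float(odds), float(p)
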