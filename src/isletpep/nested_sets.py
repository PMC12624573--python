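"""Nested-set clustering of MHC-II peptides.

MHC-II peptides are captured in an open groove and their protruding termini
are variably trimmed by endosomal proteases, so one binding event yields a
family of length variants sharing a common core. Clustering joins peptides
that overlap by at least ``overlap_min`` contiguous residues and takes
connected components: variable trimming produces chains, so two members of
a set need not overlap directly. The reported core is the maximal-length
substring common to all members (leftmost in the lexicographically first
member on ties) — a string-algebra object, not a predicted binding frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Optional, Sequence

from ._strutil import kmers, maximal_common_substring
from .model import ElutionClass, PeptideRecord


@dataclass(frozen=True)
class NestedSet:
    members: tuple[PeptideRecord, ...]
    core: str
    sample_id: str
    elution_class: ElutionClass

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClassStats:
    """Peptidome summary for one elution class (None fields = empty class)."""

    n_unique: Optional[int] = None
    median_length: Optional[float] = None
    nested_fraction: Optional[float] = None


def _connected_components(seqs: Sequence[str], k: int) -> list[list[int]]:
    """Union-find over the shared-k-mer graph, via a k-mer -> members index."""
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    index: dict[str, int] = {}
    for i, seq in enumerate(seqs):
        for mer in kmers(seq, k):
            if mer in index:
                union(index[mer], i)
            else:
                index[mer] = i
    comps: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def cluster_nested_sets(
    records: Sequence[PeptideRecord],
    overlap_min: int = 6,
    pool_samples: bool = False,
) -> list[NestedSet]:
    """Partition MHC-II peptides into nested sets.

    Scope is sample x elution class unless ``pool_samples`` is set (whole-
    cohort statistics pool samples within each class). Duplicate sequences
    within a scope are clustered as one peptide but all records are kept as
    members. Output order and cores are independent of input order.
    """
    groups: dict[tuple, list[PeptideRecord]] = {}
    for rec in records:
        if not rec.elution_class.is_mhc2:
            continue
        key = (
            "" if pool_samples else rec.sample_id,
            rec.elution_class,
        )
        groups.setdefault(key, []).append(rec)

    sets: list[NestedSet] = []
    for (sample_id, elution_class), recs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        recs = sorted(recs, key=lambda r: (r.sequence, r.sample_id))
        uniq = sorted({r.sequence for r in recs})
        by_seq: dict[str, list[PeptideRecord]] = {}
        for r in recs:
            by_seq.setdefault(r.sequence, []).append(r)
        for comp in _connected_components(uniq, overlap_min):
            seqs = sorted(uniq[i] for i in comp)
            members = tuple(r for s in seqs for r in by_seq[s])
            core = seqs[0] if len(seqs) == 1 else maximal_common_substring(seqs)
            sets.append(
                NestedSet(
                    members=members,
                    core=core,
                    sample_id=sample_id,
                    elution_class=elution_class,
                )
            )
    sets.sort(key=lambda s: (s.sample_id, s.elution_class.value, s.members[0].sequence))
    return sets


def peptidome_statistics(
    records: Sequence[PeptideRecord],
    sets: Sequence[NestedSet],
    by_tissue: bool = False,
) -> dict:
    """Unique counts, median lengths and multi-member-set fractions.

    Keyed by elution-class value (or ``(tissue, class)`` with
    ``by_tissue``). The nested fraction counts unique peptide sequences
    belonging to sets with >= 2 distinct member sequences.
    """
    multi: set[tuple] = set()
    for s in sets:
        seqs = {m.sequence for m in s.members}
        if len(seqs) >= 2:
            for m in s.members:
                multi.add((m.tissue, m.elution_class, m.sequence))

    def key_of(rec: PeptideRecord):
        return (rec.tissue.value, rec.elution_class.value) if by_tissue else rec.elution_class.value

    uniq: dict = {}
    for rec in records:
        if rec.elution_class.is_control:
            continue
        uniq.setdefault(key_of(rec), {})[
            (rec.tissue, rec.elution_class, rec.sequence)
        ] = len(rec.sequence)

    out: dict = {}
    for key, seqmap in uniq.items():
        lengths = list(seqmap.values())
        elution = key[1] if by_tissue else key
        is_mhc2 = elution in ("DR", "DQ", "DP")
        nested = (
            sum(1 for sk in seqmap if sk in multi) / len(seqmap) if is_mhc2 else None
        )
        out[key] = ClassStats(
            n_unique=len(lengths),
            median_length=float(median(lengths)),
            nested_fraction=nested,
        )
    return out
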