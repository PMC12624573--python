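"""Curation of raw eluted-peptide tables into MHC-I / MHC-II peptidomes.

Immunoaffinity elutions of islet material carry heavy non-MHC background:
common MS contaminants (keratins, immunoglobulins, actin) and, specific to
pancreatic tissue, secretory-hormone processing intermediates that elute
from control (beads-only / isotype) columns just as readily as from MHC
columns. Curation therefore proceeds in three fixed stages:

1. drop peptides whose parent protein matches a contaminant blocklist;
2. drop peptides seen in control elutions, plus any MHC-elution peptide
   sharing a contiguous stretch of >= 6 residues with a control peptide;
3. keep only 8-13-mers for MHC-I columns and 12-30-mers for MHC-II columns.

Stage order affects per-rule removal counts but not the final set; each
stage reports per-sample counts so that retained + removed always equals
the input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._strutil import kmers
from .model import PeptideRecord

logger = logging.getLogger("isletpep")

#: accession/gene patterns for the standard contaminant families
DEFAULT_BLOCKLIST = (r"^KRT", r"^IG[HKL]", r"^ACT[ABG]", r"KERATIN", r"IMMUNOGLOBULIN")


@dataclass
class FilterConfig:
    overlap_min: int = 6  # contiguous residues shared with a control peptide
    mhc1_len: tuple[int, int] = (8, 13)
    mhc2_len: tuple[int, int] = (12, 30)
    contaminant_blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST
    pool_controls_across_samples: bool = False
    #: sequences exempt from the control-overlap rule (manually rescued
    #: hormone epitopes; empty by default)
    overlap_whitelist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.overlap_min < 1:
            raise ValueError("overlap_min must be >= 1")
        for lo, hi in (self.mhc1_len, self.mhc2_len):
            if lo > hi:
                raise ValueError("length window lower bound exceeds upper bound")


@dataclass
class FilterReport:
    """Counts removed per rule per sample, plus retained per elution class."""

    rule: str = ""
    removed_per_sample: dict[str, int] = field(default_factory=dict)
    retained_per_class: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_retained: int = 0

    def _finish(self, records_in: Sequence[PeptideRecord], kept: Sequence[PeptideRecord]) -> None:
        self.n_input = len(records_in)
        self.n_retained = len(kept)
        for r in kept:
            cls = r.elution_class.value
            self.retained_per_class[cls] = self.retained_per_class.get(cls, 0) + 1

    @property
    def n_removed(self) -> int:
        return sum(self.removed_per_sample.values())


def _mark_removed(report: FilterReport, rec: PeptideRecord) -> None:
    report.removed_per_sample[rec.sample_id] = (
        report.removed_per_sample.get(rec.sample_id, 0) + 1
    )


def remove_contaminants(
    records: Sequence[PeptideRecord], config: FilterConfig
) -> tuple[list[PeptideRecord], FilterReport]:
    """Drop records whose any parent accession or gene matches the blocklist."""
    report = FilterReport(rule="contaminants")
    if not config.contaminant_blocklist:
        logger.warning("empty contaminant blocklist: contaminant stage is a no-op")
        report._finish(records, records)
        return list(records), report
    patterns = [re.compile(p, re.IGNORECASE) for p in config.contaminant_blocklist]
    kept: list[PeptideRecord] = []
    for rec in records:
        parents = rec.accessions + rec.genes
        if any(p.search(name) for p in patterns for name in parents):
            _mark_removed(report, rec)
        else:
            kept.append(rec)
    report._finish(records, kept)
    return kept, report


def _control_kmer_index(
    controls: Iterable[PeptideRecord], k: int
) -> tuple[set[str], set[str]]:
    """(exact control sequences, all control k-mers)."""
    seqs: set[str] = set()
    mers: set[str] = set()
    for rec in controls:
        seqs.add(rec.sequence)
        mers |= kmers(rec.sequence, k)
    return seqs, mers


def remove_control_overlaps(
    records: Sequence[PeptideRecord], config: FilterConfig
) -> tuple[list[PeptideRecord], FilterReport]:
    """Remove control-elution peptides and everything overlapping them.

    An MHC-elution peptide is removed when it equals a control peptide of
    the same sample (or of any sample, when controls are pooled) or shares a
    contiguous identical substring of length >= ``overlap_min`` with one.
    Control rows themselves are dropped from the output (counted as
    removed). Whitelisted sequences are exempt: curated hormone epitopes the
    analyst has decided are genuinely MHC-bound survive this stage.
    """
    report = FilterReport(rule="control_overlap")
    k = config.overlap_min
    controls = [r for r in records if r.elution_class.is_control]
    if not controls:
        logger.warning("no control-elution rows present; control stage passes through")
        report._finish(records, records)
        return list(records), report

    if config.pool_controls_across_samples:
        pooled = _control_kmer_index(controls, k)
        index = {None: pooled}
    else:
        index = {}
        for rec in controls:
            index.setdefault(rec.sample_id, []).append(rec)
        index = {sid: _control_kmer_index(rows, k) for sid, rows in index.items()}

    kept: list[PeptideRecord] = []
    for rec in records:
        if rec.elution_class.is_control:
            _mark_removed(report, rec)
            continue
        key = None if config.pool_controls_across_samples else rec.sample_id
        if key not in index:
            kept.append(rec)  # sample had no controls
            continue
        ctrl_seqs, ctrl_kmers = index[key]
        if rec.sequence in config.overlap_whitelist:
            kept.append(rec)
            continue
        hit = rec.sequence in ctrl_seqs or not kmers(rec.sequence, k).isdisjoint(
            ctrl_kmers
        )
        if hit:
            _mark_removed(report, rec)
        else:
            kept.append(rec)
    report._finish(records, kept)
    return kept, report


def apply_length_windows(
    records: Sequence[PeptideRecord], config: FilterConfig
) -> tuple[list[PeptideRecord], FilterReport]:
    """Keep 8-13-mers from MHC-I columns and 12-30-mers from MHC-II columns."""
    report = FilterReport(rule="length_window")
    lo1, hi1 = config.mhc1_len
    lo2, hi2 = config.mhc2_len
    kept: list[PeptideRecord] = []
    for rec in records:
        n = rec.length
        if rec.elution_class.is_mhc1:
            ok = lo1 <= n <= hi1
        elif rec.elution_class.is_mhc2:
            ok = lo2 <= n <= hi2
        else:
            ok = True  # control rows are not length-filtered here
        if ok:
            kept.append(rec)
        else:
            _mark_removed(report, rec)
    report._finish(records, kept)
    return kept, report


def curate(
    records: Sequence[PeptideRecord], config: FilterConfig | None = None
) -> tuple[list[PeptideRecord], list[FilterReport]]:
    """Full curation chain: contaminants -> control overlap -> length windows."""
    config = config or FilterConfig()
    reports = []
    out, rep = remove_contaminants(records, config)
    reports.append(rep)
    out, rep = remove_control_overlaps(out, config)
    reports.append(rep)
    out, rep = apply_length_windows(out, config)
    reports.append(rep)
    for rep in reports:
        logger.info(
            "filter %s: %d in, %d removed, %d retained",
            rep.rule,
            rep.n_input,
            rep.n_removed,
            rep.n_retained,
        )
    return out, reports
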