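"""Hybrid (fusion) peptide library generation and matching.

Hybrid insulin peptides — non-templated ligations of two secretory-granule
fragments — are a proposed neoepitope class in type 1 diabetes. The library
enumerates every fusion of an N-terminal fragment panel to a C-terminal
fragment panel, trimming 0-6 residues from the fusing ends (the untrimmed
fragment counts as a variant), without sequence deduplication: the default
panel of 5 N-fragments and 9 C-fragments yields 5*7 * 9*7 = 2205 records.
The resulting FASTA can be merged with a proteome for search-engine use;
``match_fusions`` screens an observed peptidome for junction-spanning hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import PeptideRecord

#: insulin-granule N-terminal fragments (name, sequence)
DEFAULT_N_FRAGMENTS: tuple[tuple[str, str], ...] = (
    ("hEGGG", "FYTPKTRREAEDLQVGQVELGGGPGA"),
    ("hEL", "LQVGQVELGGGPGAGSLQPLALEGS"),
    ("InsB1-23", "AAAFVNQHLCGSHLVEALYLVCGERGF"),
    ("hChgA-1", "PMPVSQECFETLRGDERILSIL"),
    ("hChgA-2", "ILSILRHQNLLKELQDLALQGA"),
)

#: secretory-granule C-terminal fragments
DEFAULT_C_FRAGMENTS: tuple[tuple[str, str], ...] = (
    ("ChgA-WE14", "SKRWSKMDQLAKELTAEKRLEGQEEE"),
    ("ChgA-LF19", "EKRLEGQEEEEDNRDRSSMKLSFRAR"),
    ("C-peptide1", "TRREAEDLQVGQVELGGGPGAGSLQ"),
    ("C-peptide2", "GQVELGGGPGAGSLQPLALEG"),
    ("A-chain", "QKRGIVEQCCTSICSLYQLENYCN"),
    ("IAPP1", "LKATPIESHQVEKRKCNTATCATQR"),
    ("IAPP2", "GKRNAVEVLKREPLNYLPL"),
    ("SCG1", "EKRFLGEGHHRVQENQMDKARRHPQ"),
    ("NPY", "GKRSSPETLISDLLMRESTENVPRT"),
)


@dataclass(frozen=True)
class FragmentPanel:
    n_fragments: tuple[tuple[str, str], ...] = DEFAULT_N_FRAGMENTS
    c_fragments: tuple[tuple[str, str], ...] = DEFAULT_C_FRAGMENTS
    max_trim: int = 6

    def __post_init__(self) -> None:
        for name, seq in self.n_fragments + self.c_fragments:
            if len(seq) <= self.max_trim:
                raise ValueError(
                    f"fragment {name} ({len(seq)} aa) is not longer than "
                    f"max_trim={self.max_trim}"
                )


@dataclass(frozen=True)
class FusionPeptide:
    n_name: str
    n_trim: int  # residues removed from the C-terminal end of the N fragment
    c_name: str
    c_trim: int  # residues removed from the N-terminal end of the C fragment
    sequence: str
    junction: int  # index of the first C-fragment residue in ``sequence``

    @property
    def header(self) -> str:
        return f"{self.n_name}|{self.n_trim}|{self.c_name}|{self.c_trim}"


def enumerate_fusions(panel: Optional[FragmentPanel] = None) -> list[FusionPeptide]:
    """Enumerate all |N|*(max_trim+1) x |C|*(max_trim+1) fusion records.

    Trim depths 0..max_trim on both fusing ends; every N variant is fused to
    every C variant; identical sequences are *not* deduplicated. Order is
    deterministic: (N index, n_trim, C index, c_trim).
    """
    panel = panel or FragmentPanel()
    out: list[FusionPeptide] = []
    for n_name, n_seq in panel.n_fragments:
        for n_trim in range(panel.max_trim + 1):
            left = n_seq[: len(n_seq) - n_trim]
            for c_name, c_seq in panel.c_fragments:
                for c_trim in range(panel.max_trim + 1):
                    right = c_seq[c_trim:]
                    out.append(
                        FusionPeptide(
                            n_name=n_name,
                            n_trim=n_trim,
                            c_name=c_name,
                            c_trim=c_trim,
                            sequence=left + right,
                            junction=len(left),
                        )
                    )
    return out


def write_fusion_fasta(
    fusions: Sequence[FusionPeptide],
    out_path: str | Path,
    proteome_path: Optional[str | Path] = None,
) -> int:
    """Write the fusion library as FASTA, optionally appending a proteome.

    Proteome entries are appended byte-identically (their records are
    re-emitted unchanged by sequence and header). Returns the number of
    entries written. Duplicate fusion headers are a hard error.
    """
    if not fusions:
        raise ValueError("no fusions to write")
    headers = [f.header for f in fusions]
    if len(headers) != len(set(headers)):
        raise ValueError("fusion header collision")
    records = [
        SeqRecord(Seq(f.sequence), id=f.header, description="") for f in fusions
    ]
    if proteome_path is not None:
        records.extend(SeqIO.parse(str(proteome_path), "fasta"))
    return SeqIO.write(records, str(out_path), "fasta")


@dataclass(frozen=True)
class FusionHit:
    peptide: str
    fusion: FusionPeptide
    start: int  # match start within the fusion sequence


def match_fusions(
    records: Sequence[PeptideRecord] | Sequence[str],
    fusions: Sequence[FusionPeptide],
) -> list[tuple[str, list[FusionHit]]]:
    """Screen observed peptides for junction-spanning fusion matches.

    A hit requires the peptide to occur as a substring of a fusion sequence
    with at least one matched residue on each side of the fusion point;
    matches lying wholly within one un-fused fragment are excluded. Returns
    one entry per unique observed peptide (hits possibly empty).
    """
    seqs: list[str] = []
    seen = set()
    for rec in records:
        seq = rec if isinstance(rec, str) else rec.sequence
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    out = []
    for pep in seqs:
        hits: list[FusionHit] = []
        for fus in fusions:
            start = fus.sequence.find(pep)
            while start != -1:
                end = start + len(pep)
                if start < fus.junction < end:
                    hits.append(FusionHit(pep, fus, start))
                start = fus.sequence.find(pep, start + 1)
        out.append((pep, hits))
    return out
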