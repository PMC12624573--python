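"""Core data model for eluted-peptide observations and their annotations.

The pipeline operates on identified-peptide tables exported from MS search
engines, so the atoms here are peptide *observations* (sequence + sample +
elution column + intensity), not spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class ElutionClass(str, Enum):
    """Which immunoaffinity column a peptide was eluted from.

    ABC is the pan-MHC-I column; DR/DQ/DP are the MHC-II loci; the two
    control classes are protein A-only beads and isotype-control antibody
    beads, whose eluates define the non-MHC background.
    """

    ABC = "ABC"
    DR = "DR"
    DQ = "DQ"
    DP = "DP"
    BEADS_ONLY = "BEADS_ONLY"
    ISOTYPE_CONTROL = "ISOTYPE_CONTROL"

    @property
    def is_control(self) -> bool:
        return self in (ElutionClass.BEADS_ONLY, ElutionClass.ISOTYPE_CONTROL)

    @property
    def is_mhc1(self) -> bool:
        return self is ElutionClass.ABC

    @property
    def is_mhc2(self) -> bool:
        return self in (ElutionClass.DR, ElutionClass.DQ, ElutionClass.DP)


class Tissue(str, Enum):
    ISLET = "islet"
    SPLEEN = "spleen"


class MhcClass(str, Enum):
    I = "I"
    II = "II"


@dataclass(frozen=True)
class PtmAnnotation:
    """A localized post-translational modification on one residue.

    ``a_score`` follows the A = -10*log10(p) convention, so 13 corresponds
    to a site-localization p of ~0.05.
    """

    modification_name: str
    position: int  # 1-based index into the peptide sequence
    mass_delta: float  # Daltons
    a_score: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"PTM position must be >= 1, got {self.position}")
        if self.a_score < 0:
            raise ValueError(f"A-score must be >= 0, got {self.a_score}")


@dataclass(frozen=True)
class PeptideRecord:
    """One eluted-peptide observation."""

    sequence: str
    sample_id: str
    elution_class: ElutionClass
    source_accession: str = ""  # ';'-delimited when multi-mapped
    gene_symbol: str = ""  # ';'-delimited when multi-mapped
    precursor_intensity: float = 0.0
    ptms: tuple[PtmAnnotation, ...] = field(default_factory=tuple)
    tissue: Tissue = Tissue.ISLET

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"non-canonical residue(s) {sorted(bad)} in {self.sequence!r}"
            )
        if self.precursor_intensity < 0:
            raise ValueError("precursor_intensity must be >= 0")
        for ptm in self.ptms:
            if ptm.position > len(self.sequence):
                raise ValueError(
                    f"PTM position {ptm.position} beyond peptide length "
                    f"{len(self.sequence)}"
                )
        object.__setattr__(self, "ptms", tuple(self.ptms))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def genes(self) -> tuple[str, ...]:
        """All parent gene symbols (multi-mapping retained)."""
        return tuple(g for g in self.gene_symbol.split(";") if g)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(a for a in self.source_accession.split(";") if a)

    def with_mapping(self, accessions: list[str], genes: list[str]) -> "PeptideRecord":
        return replace(
            self,
            source_accession=";".join(accessions),
            gene_symbol=";".join(dict.fromkeys(g for g in genes if g)),
        )


@dataclass(frozen=True)
class ProteinEntry:
    """One proteome FASTA entry."""

    accession: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession} has empty sequence")


@dataclass(frozen=True)
class DonorGenotype:
    """HLA alleles typed for one tissue donor."""

    sample_id: str
    alleles: tuple[tuple[str, MhcClass], ...]

    def __post_init__(self) -> None:
        names = [a for a, _ in self.alleles]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate allele names for donor {self.sample_id}")

    def alleles_of_class(self, mhc_class: MhcClass) -> list[str]:
        return [a for a, c in self.alleles if c is mhc_class]

    def alleles_for_locus(self, elution_class: ElutionClass) -> list[str]:
        """Donor alleles eligible for a given elution column.

        ABC columns capture all class-I allotypes; DR/DQ/DP columns are
        locus-specific antibodies, so by default only alleles of the matching
        locus are candidates.
        """
        if elution_class.is_mhc1:
            return self.alleles_of_class(MhcClass.I)
        if elution_class.is_mhc2:
            prefix = {"DR": ("DRB",), "DQ": ("DQA", "DQB", "DQ"), "DP": ("DPA", "DPB", "DP")}[
                elution_class.value
            ]
            out = []
            for a in self.alleles_of_class(MhcClass.II):
                name = a.replace("HLA-", "")
                if name.startswith(prefix):
                    out.append(a)
            return out
        return []


def validate_sequence(seq: str) -> Optional[str]:
    """Return None if ``seq`` is a canonical peptide sequence, else a reason."""
    if not seq:
        return "empty sequence"
    bad = set(seq) - _AA_SET
    if bad:
        return f"non-canonical residue(s): {','.join(sorted(bad))}"
    return None
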