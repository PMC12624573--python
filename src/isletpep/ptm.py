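"""Post-translational modification filtering and prevalence summaries.

PTM site assignments come with an A-score (A = -10*log10 p of the site
localization), and only confidently localized sites (A >= 13, i.e.
p <= 0.05) enter the summaries. Prevalence per modification is expressed as
an intensity fraction: the summed precursor intensity of peptides carrying
the accepted modification over the summed intensity of modified plus
unmodified forms at the same peptide loci, where a locus is the peptide
backbone sequence with modifications disregarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .model import PeptideRecord, Tissue

#: modification vocabulary seeded from the oxidative-stress panel
MODIFICATION_VOCABULARY = (
    "deamidation",
    "citrullination",
    "amidation",
    "ubiquitination",
    "carboxymethylation",
    "propionamide",
    "alpha-amino adipic acid",
    "oxolactone",
    "glucosone",
    "dehydration",
    "phosphorylation",
    "pyroglutamate",
)


@dataclass(frozen=True)
class AScoreThreshold:
    a_min: float = 13.0
    #: comparator for the threshold; ">=" by default
    strict: bool = False

    def __post_init__(self) -> None:
        if self.a_min < 0:
            raise ValueError("a_min must be >= 0")

    def accepts(self, a_score: float) -> bool:
        return a_score > self.a_min if self.strict else a_score >= self.a_min

    @property
    def p_value(self) -> float:
        """Site-localization p corresponding to the threshold (10^(-A/10))."""
        return 10.0 ** (-self.a_min / 10.0)


@dataclass(frozen=True)
class PtmPrevalence:
    modification_name: str
    tissue: Optional[Tissue]
    modified_intensity: float
    reference_intensity: float

    @property
    def fraction(self) -> Optional[float]:
        if self.reference_intensity == 0:
            return None
        return self.modified_intensity / self.reference_intensity


def filter_ptms_by_ascore(
    records: Sequence[PeptideRecord],
    threshold: AScoreThreshold | None = None,
) -> list[PeptideRecord]:
    """Drop PTM annotations below the localization threshold; peptides stay."""
    threshold = threshold or AScoreThreshold()
    out = []
    for rec in records:
        kept = tuple(p for p in rec.ptms if threshold.accepts(p.a_score))
        out.append(rec if kept == rec.ptms else replace(rec, ptms=kept))
    return out


def ptm_intensity_fractions(
    records: Sequence[PeptideRecord],
    by_tissue: bool = True,
) -> list[PtmPrevalence]:
    """Intensity fraction of each modification, pooled within tissue.

    For each modification m, loci are the backbone sequences of peptides
    carrying an accepted m; ``modified_intensity`` sums records at those
    loci carrying m, ``reference_intensity`` sums all records (modified or
    not) at the same loci. PTMs must already be A-score filtered.
    """
    mods = sorted({p.modification_name for r in records for p in r.ptms})
    tissues: list[Optional[Tissue]] = (
        sorted({r.tissue for r in records}, key=lambda t: t.value)
        if by_tissue
        else [None]
    )
    out: list[PtmPrevalence] = []
    for tissue in tissues:
        recs = [r for r in records if tissue is None or r.tissue == tissue]
        by_locus: dict[str, list[PeptideRecord]] = {}
        for r in recs:
            by_locus.setdefault(r.sequence, []).append(r)
        for mod in mods:
            loci = {
                r.sequence
                for r in recs
                if any(p.modification_name == mod for p in r.ptms)
            }
            modified = sum(
                r.precursor_intensity
                for locus in loci
                for r in by_locus[locus]
                if any(p.modification_name == mod for p in r.ptms)
            )
            reference = sum(
                r.precursor_intensity for locus in loci for r in by_locus[locus]
            )
            out.append(
                PtmPrevalence(
                    modification_name=mod,
                    tissue=tissue,
                    modified_intensity=modified,
                    reference_intensity=reference,
                )
            )
    return out
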