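"""Readers and writers for the pipeline's plain-text formats.

Peptide tables are tab-separated with a required header. Because identified
peptide lists arrive from different search engines with different column
names, the reader takes a *dialect*: a mapping from the canonical field
names used here to the column names found in the file. FASTA handling goes
through Biopython.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DonorGenotype,
    ElutionClass,
    MhcClass,
    PeptideRecord,
    ProteinEntry,
    PtmAnnotation,
    Tissue,
    validate_sequence,
)

logger = logging.getLogger("isletpep")

#: canonical field -> default column header
DEFAULT_DIALECT: dict[str, str] = {
    "sequence": "sequence",
    "sample_id": "sample",
    "elution_class": "elution",
    "source_accession": "accession",
    "gene_symbol": "gene",
    "precursor_intensity": "intensity",
    "ptms": "ptms",
    "tissue": "tissue",
}

_MANDATORY = ("sequence", "sample_id", "elution_class")


@dataclass
class TableReadReport:
    """Per-file accounting of parsed and rejected rows."""

    n_rows: int = 0
    n_records: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (line, reason)


def _format_ptms(ptms: Sequence[PtmAnnotation]) -> str:
    return ",".join(
        f"{p.modification_name}@{p.position}:{p.mass_delta!r}:{p.a_score!r}"
        for p in ptms
    )


def _parse_ptms(text: str) -> tuple[PtmAnnotation, ...]:
    text = (text or "").strip()
    if not text or text in ("-", "nan"):
        return ()
    out = []
    for chunk in text.split(","):
        name_pos, mass, ascore = chunk.rsplit(":", 2)
        name, pos = name_pos.rsplit("@", 1)
        out.append(
            PtmAnnotation(
                modification_name=name,
                position=int(pos),
                mass_delta=float(mass),
                a_score=float(ascore),
            )
        )
    return tuple(out)


def read_peptide_table(
    path: str | Path,
    dialect: Optional[dict[str, str]] = None,
    report: Optional[TableReadReport] = None,
) -> list[PeptideRecord]:
    """Read a tab-separated identified-peptide table.

    Rows with non-canonical residues or malformed fields are rejected and
    logged with their line numbers; missing intensities are read as 0 (the
    policy is recorded in the log). A missing mandatory column is a hard
    error naming the column.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in _MANDATORY:
        col = dialect[fld]
        if col not in df.columns:
            raise ValueError(f"peptide table {path} lacks mandatory column {col!r}")
    if report is None:
        report = TableReadReport()
    report.n_rows += len(df)

    records: list[PeptideRecord] = []
    missing_intensity = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rowd = dict(zip(df.columns, row))

        def get(fld: str, default: str = "") -> str:
            return str(rowd.get(dialect[fld], default)).strip()

        seq = get("sequence").upper()
        reason = validate_sequence(seq)
        if reason:
            report.rejected.append((i, reason))
            logger.warning("line %d rejected: %s", i, reason)
            continue
        try:
            raw_intensity = get("precursor_intensity")
            if raw_intensity in ("", "nan", "NA"):
                intensity = 0.0
                missing_intensity += 1
            else:
                intensity = float(raw_intensity)
            rec = PeptideRecord(
                sequence=seq,
                sample_id=get("sample_id"),
                elution_class=ElutionClass(get("elution_class")),
                source_accession=get("source_accession"),
                gene_symbol=get("gene_symbol"),
                precursor_intensity=intensity,
                ptms=_parse_ptms(get("ptms")),
                tissue=Tissue(get("tissue") or "islet"),
            )
        except (ValueError, KeyError) as exc:
            report.rejected.append((i, str(exc)))
            logger.warning("line %d rejected: %s", i, exc)
            continue
        records.append(rec)
    report.n_records += len(records)
    if missing_intensity:
        logger.info(
            "%d rows had missing intensity; set to 0 by policy", missing_intensity
        )
    return records


def write_peptide_table(
    records: Iterable[PeptideRecord],
    path: str | Path,
    dialect: Optional[dict[str, str]] = None,
) -> None:
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    rows = [
        {
            dialect["sequence"]: r.sequence,
            dialect["sample_id"]: r.sample_id,
            dialect["elution_class"]: r.elution_class.value,
            dialect["source_accession"]: r.source_accession,
            dialect["gene_symbol"]: r.gene_symbol,
            dialect["precursor_intensity"]: repr(r.precursor_intensity),
            dialect["ptms"]: _format_ptms(r.ptms),
            dialect["tissue"]: r.tissue.value,
        }
        for r in records
    ]
    cols = [dialect[f] for f in DEFAULT_DIALECT]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_fasta_proteome(path: str | Path) -> list[ProteinEntry]:
    """Read a proteome FASTA; headers of the form ``accession GN=SYMBOL``
    (or UniProt-style ``db|accession|name ... GN=SYMBOL``) yield gene
    symbols, otherwise the symbol is left empty. Sequences are uppercased.
    """
    entries: list[ProteinEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        accession = rec.id
        if accession.count("|") == 2:  # UniProt db|ACC|entry
            accession = accession.split("|")[1]
        gene = ""
        for token in header.split():
            if token.startswith("GN="):
                gene = token[3:].upper()
        entries.append(
            ProteinEntry(
                accession=accession,
                gene_symbol=gene,
                sequence=str(rec.seq).upper(),
            )
        )
    if not entries:
        raise ValueError(f"FASTA {path} contains no entries")
    return entries


def write_fasta_proteome(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    recs = [
        SeqRecord(
            Seq(e.sequence),
            id=e.accession,
            description=f"GN={e.gene_symbol}" if e.gene_symbol else "",
        )
        for e in entries
    ]
    SeqIO.write(recs, str(path), "fasta")


def map_peptides_to_proteome(
    records: Sequence[PeptideRecord], proteome: Sequence[ProteinEntry]
) -> list[PeptideRecord]:
    """Fill source accession / gene symbol by exact-substring search.

    Every parent protein is retained (';'-delimited); peptides found in no
    protein keep empty fields and are counted in the log as unmapped.
    """
    if not proteome:
        raise ValueError("empty proteome")
    mapped: list[PeptideRecord] = []
    n_unmapped = 0
    cache: dict[str, tuple[list[str], list[str]]] = {}
    for rec in records:
        if rec.sequence not in cache:
            accs: list[str] = []
            genes: list[str] = []
            for prot in proteome:
                if rec.sequence in prot.sequence:
                    accs.append(prot.accession)
                    genes.append(prot.gene_symbol)
            cache[rec.sequence] = (accs, genes)
        accs, genes = cache[rec.sequence]
        if not accs:
            n_unmapped += 1
        mapped.append(rec.with_mapping(accs, genes))
    if n_unmapped:
        logger.info("%d records had no parent protein (left unmapped)", n_unmapped)
    return mapped


# ---------------------------------------------------------------------------
# genotype / gene-set / assay tables


def read_genotypes_yaml(path: str | Path) -> dict[str, DonorGenotype]:
    """Genotype YAML: ``{sample_id: {I: [alleles...], II: [alleles...]}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for sample_id, classes in raw.items():
        alleles: list[tuple[str, MhcClass]] = []
        for cls_name, names in classes.items():
            for name in names:
                alleles.append((name, MhcClass(cls_name)))
        out[sample_id] = DonorGenotype(sample_id=sample_id, alleles=tuple(alleles))
    return out


def write_genotypes_yaml(genotypes: dict[str, DonorGenotype], path: str | Path) -> None:
    raw = {}
    for sample_id, g in genotypes.items():
        raw[sample_id] = {
            "I": g.alleles_of_class(MhcClass.I),
            "II": g.alleles_of_class(MhcClass.II),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Gene-set TSV with columns ``gene`` and ``set_name``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["set_name"], set()).add(row["gene"].upper())
    return out


def write_gene_sets(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"gene": g.upper(), "set_name": name}
        for name, genes in sets.items()
        for g in sorted(set(genes))
    ]
    pd.DataFrame(rows, columns=["gene", "set_name"]).to_csv(path, sep="\t", index=False)


def read_rank_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Externally computed predictor ranks: TSV of peptide, allele, rank."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
    return {
        (row.peptide, row.allele): float(row.rank_percentile)
        for row in df.itertuples(index=False)
    }
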