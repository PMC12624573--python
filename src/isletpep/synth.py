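"""Synthetic immunopeptidome and assay generator with ground-truth labels.

Every downstream stage is exercised against data from this module, which
emulates the statistical structure of an islet immunopeptidome experiment:

* MHC-I peptides of length 8-13 (median 9) carrying an allele-specific
  anchor motif sampled from a position weight matrix;
* MHC-II peptides emitted core-out as nested sets — a binding core placed
  in a parent context, members cut with geometrically distributed terminal
  extensions — targeting a median length of 16 and ~40% of peptides in
  multi-member sets;
* a secretory-hormone fragment background of prohormone windows planted in
  *all* elutions, controls included, so the control-overlap filter has
  realistic prey;
* MS contaminant peptides (keratin/immunoglobulin/actin parents);
* log-normal precursor intensities, sprinkled PTMs with localization
  scores, and toy gene sets for triage.

All randomness flows from a single integer seed through numpy's PCG64, so
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    AMINO_ACIDS,
    DonorGenotype,
    ElutionClass,
    MhcClass,
    PeptideRecord,
    ProteinEntry,
    PtmAnnotation,
)
from .validation import ElispotPlate, FpSeries, competition_model

_CONTROL_CLASSES = (ElutionClass.BEADS_ONLY, ElutionClass.ISOTYPE_CONTROL)

#: default donor: class-I allotypes plus one class-II allele per locus group
DEFAULT_CLASS_I = ("A*02:01", "A*24:02", "B*39:06", "C*07:02")
DEFAULT_CLASS_II = ("DRB1*03:01", "DRB1*04:01", "DQB1*03:02", "DPB1*04:01")

_PROHORMONE_GENES = ("INS", "GCG", "CHGA", "SCG1", "PPY")
_CONTAMINANT_GENES = ("KRT1", "IGHG1", "ACTB")


@dataclass
class SyntheticConfig:
    seed: int = 0
    # proteome
    n_proteins: int = 80
    protein_length: int = 300
    prohormone_length: int = 120
    # peptidome
    n_mhc1_peptides: int = 400
    mhc1_length_probs: dict[int, float] = field(
        default_factory=lambda: {8: 0.12, 9: 0.42, 10: 0.20, 11: 0.12, 12: 0.09, 13: 0.05}
    )
    n_mhc2_cores: int = 150
    multi_set_prob: float = 0.16  # P(core spawns a multi-member nested set)
    multi_extra_rate: float = 1.5  # extra members beyond 2 ~ Poisson(rate)
    mhc2_class_probs: dict[str, float] = field(
        default_factory=lambda: {"DR": 0.68, "DQ": 0.25, "DP": 0.07}
    )
    # motifs
    motif_len_i: int = 8
    motif_len_ii: int = 9
    n_anchors: int = 4
    anchor_weight: float = 0.95
    # hormone background
    n_background_control: int = 60  # prohormone windows per control elution
    n_background_mhc: int = 40  # overlapping windows planted in MHC elutions
    n_contaminants: int = 20
    # intensities / PTMs
    log_intensity_mean: float = 10.0
    log_intensity_sigma: float = 1.5
    ptm_rate: float = 0.15
    # gene sets
    gene_set_size: int = 15
    # validation assays
    n_elispot_peptides: int = 8
    n_exp_wells: int = 2
    n_ctrl_wells: int = 6
    ctrl_spw_mean: float = 3.0  # typical DMSO background, spots per well
    responder_effect: float = 10.0  # fold increase of exp-well mean
    responder_fraction: float = 0.25
    fp_noise_sigma: float = 0.03
    fp_true_ic50: float = 285e-9  # molar
    fp_top_conc: float = 40e-6
    fp_n_dilutions: int = 8
    fp_dilution_factor: float = 5.0

    def __post_init__(self) -> None:
        for p in (self.multi_set_prob, self.ptm_rate, self.responder_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.mhc1_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("mhc1_length_probs must sum to 1")
        if self.n_mhc2_cores < 1 and self.multi_set_prob > 0:
            raise ValueError("cannot target nested sets with no cores")


@dataclass
class GroundTruth:
    """Per-record labels keyed by index into the emitted record list."""

    true_allele: dict[int, str] = field(default_factory=dict)
    nested_set_id: dict[int, int] = field(default_factory=dict)
    background: set[int] = field(default_factory=set)
    contaminant: set[int] = field(default_factory=set)
    ptm_accepted: dict[int, bool] = field(default_factory=dict)
    # validation assays
    responders: set[str] = field(default_factory=set)
    true_ic50: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticPeptidome:
    records: list[PeptideRecord]
    proteome: list[ProteinEntry]
    genotype: DonorGenotype
    motifs: dict[str, np.ndarray]
    gene_sets: dict[str, set[str]]
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_motif(
    rng: np.random.Generator,
    length: int,
    n_anchors: int,
    anchor_weight: float,
) -> np.ndarray:
    """Row-stochastic PWM: near-uniform except ``n_anchors`` strong positions.

    Anchors are spread evenly across the motif (as in real MHC motifs,
    e.g. P2/P-omega for class I, P1/P4/P6/P9 for class II); clustering them
    would let unrelated motif-bearing peptides share long identical runs.
    Non-anchor rows carry mild log-normal preferences so that PWM scores are
    effectively continuous, as they are for real predictors.
    """
    pwm = np.exp(rng.normal(0.0, 0.15, size=(length, 20)))
    pwm /= pwm.sum(axis=1, keepdims=True)
    anchors = np.unique(np.round(np.linspace(0, length - 1, n_anchors)).astype(int))
    for pos in anchors:
        residue = rng.integers(0, 20)
        row = np.full(20, (1.0 - anchor_weight) / 19.0)
        row[residue] = anchor_weight
        pwm[pos] = row
    return pwm


def _sample_from_pwm(rng: np.random.Generator, pwm: np.ndarray) -> str:
    aas = list(AMINO_ACIDS)
    return "".join(aas[rng.choice(20, p=row)] for row in pwm)


def _intensity(rng: np.random.Generator, cfg: SyntheticConfig) -> float:
    return float(rng.lognormal(cfg.log_intensity_mean, cfg.log_intensity_sigma))


_PTM_MASSES = {
    "deamidation": 0.984,
    "citrullination": 0.984,
    "amidation": -0.984,
    "phosphorylation": 79.966,
    "carboxymethylation": 58.005,
    "dehydration": -18.011,
}


def _maybe_ptms(
    rng: np.random.Generator, cfg: SyntheticConfig, seq: str
) -> tuple[tuple[PtmAnnotation, ...], Optional[bool]]:
    if rng.random() >= cfg.ptm_rate:
        return (), None
    name = str(rng.choice(list(_PTM_MASSES)))
    a_score = float(rng.uniform(0.0, 40.0))
    ptm = PtmAnnotation(
        modification_name=name,
        position=int(rng.integers(1, len(seq) + 1)),
        mass_delta=_PTM_MASSES[name],
        a_score=a_score,
    )
    return (ptm,), a_score >= 13.0


def generate_immunopeptidome(config: SyntheticConfig | None = None) -> SyntheticPeptidome:
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    sample_id = "SYN-01"

    # --- proteome: ordinary proteins, prohormones, contaminant parents
    proteome: list[ProteinEntry] = []
    for i in range(cfg.n_proteins):
        proteome.append(
            ProteinEntry(
                accession=f"P{i:04d}",
                gene_symbol=f"GENE{i:04d}",
                sequence=_random_seq(rng, cfg.protein_length),
            )
        )
    prohormones = []
    for gene in _PROHORMONE_GENES:
        entry = ProteinEntry(
            accession=f"H_{gene}",
            gene_symbol=gene,
            sequence=_random_seq(rng, cfg.prohormone_length),
        )
        prohormones.append(entry)
        proteome.append(entry)
    for gene in _CONTAMINANT_GENES:
        proteome.append(
            ProteinEntry(
                accession=f"C_{gene}",
                gene_symbol=gene,
                sequence=_random_seq(rng, cfg.protein_length),
            )
        )

    # --- genotype and motifs
    alleles = tuple(
        [(a, MhcClass.I) for a in DEFAULT_CLASS_I]
        + [(a, MhcClass.II) for a in DEFAULT_CLASS_II]
    )
    genotype = DonorGenotype(sample_id=sample_id, alleles=alleles)
    motifs: dict[str, np.ndarray] = {}
    for allele in DEFAULT_CLASS_I:
        motifs[allele] = make_motif(rng, cfg.motif_len_i, cfg.n_anchors, cfg.anchor_weight)
    for allele in DEFAULT_CLASS_II:
        motifs[allele] = make_motif(rng, cfg.motif_len_ii, cfg.n_anchors, cfg.anchor_weight)

    records: list[PeptideRecord] = []
    truth = GroundTruth()
    normal_genes = [p.gene_symbol for p in proteome[: cfg.n_proteins]]
    normal_accs = [p.accession for p in proteome[: cfg.n_proteins]]

    def add(rec: PeptideRecord) -> int:
        records.append(rec)
        return len(records) - 1

    def attach_source(rng: np.random.Generator) -> tuple[str, str]:
        j = int(rng.integers(0, len(normal_genes)))
        return normal_accs[j], normal_genes[j]

    # --- MHC-I peptides: motif window embedded in a random-length peptide
    lengths = np.array(sorted(cfg.mhc1_length_probs))
    probs = np.array([cfg.mhc1_length_probs[int(l)] for l in lengths])
    for _ in range(cfg.n_mhc1_peptides):
        allele = str(rng.choice(DEFAULT_CLASS_I))
        length = int(rng.choice(lengths, p=probs))
        core = _sample_from_pwm(rng, motifs[allele])
        offset = int(rng.integers(0, length - cfg.motif_len_i + 1))
        flank_left = _random_seq(rng, offset)
        flank_right = _random_seq(rng, length - cfg.motif_len_i - offset)
        seq = flank_left + core + flank_right
        acc, gene = attach_source(rng)
        ptms, accepted = _maybe_ptms(rng, cfg, seq)
        idx = add(
            PeptideRecord(
                sequence=seq,
                sample_id=sample_id,
                elution_class=ElutionClass.ABC,
                source_accession=acc,
                gene_symbol=gene,
                precursor_intensity=_intensity(rng, cfg),
                ptms=ptms,
            )
        )
        truth.true_allele[idx] = allele
        if accepted is not None:
            truth.ptm_accepted[idx] = accepted

    # --- MHC-II nested sets, emitted core-out from a parent context
    locus_alleles = {
        "DR": [a for a in DEFAULT_CLASS_II if a.startswith("DRB")],
        "DQ": [a for a in DEFAULT_CLASS_II if a.startswith("DQ")],
        "DP": [a for a in DEFAULT_CLASS_II if a.startswith("DP")],
    }
    class_names = sorted(cfg.mhc2_class_probs)
    class_p = np.array([cfg.mhc2_class_probs[c] for c in class_names])
    class_p = class_p / class_p.sum()
    for set_id in range(cfg.n_mhc2_cores):
        elution = str(rng.choice(class_names, p=class_p))
        allele = str(rng.choice(locus_alleles[elution]))
        core_len = int(rng.integers(12, 17))  # core >= 9; members target median 16
        motif = _sample_from_pwm(rng, motifs[allele])
        pad = core_len - cfg.motif_len_ii
        moff = int(rng.integers(0, pad + 1))
        core = _random_seq(rng, moff) + motif + _random_seq(rng, pad - moff)
        context = _random_seq(rng, 6) + core + _random_seq(rng, 6)
        if rng.random() < cfg.multi_set_prob:
            n_members = 2 + int(rng.poisson(cfg.multi_extra_rate))
        else:
            n_members = 1
        seen: set[str] = set()
        for _ in range(n_members):
            for _attempt in range(8):
                ext_l = min(int(rng.geometric(0.5)) - 1, 6)
                ext_r = min(int(rng.geometric(0.5)) - 1, 6)
                seq = context[6 - ext_l : 6 + core_len + ext_r]
                if seq not in seen:
                    break
            if seq in seen:
                continue
            seen.add(seq)
            acc, gene = attach_source(rng)
            ptms, accepted = _maybe_ptms(rng, cfg, seq)
            idx = add(
                PeptideRecord(
                    sequence=seq,
                    sample_id=sample_id,
                    elution_class=ElutionClass(elution),
                    source_accession=acc,
                    gene_symbol=gene,
                    precursor_intensity=_intensity(rng, cfg),
                    ptms=ptms,
                )
            )
            truth.true_allele[idx] = allele
            truth.nested_set_id[idx] = set_id
            if accepted is not None:
                truth.ptm_accepted[idx] = accepted

    # --- hormone-fragment background: windows of prohormones in every elution
    def hormone_window() -> tuple[str, ProteinEntry, int, int]:
        prot = prohormones[int(rng.integers(0, len(prohormones)))]
        length = int(rng.integers(9, 26))
        start = int(rng.integers(0, len(prot.sequence) - length + 1))
        return prot.sequence[start : start + length], prot, start, length

    control_windows: list[tuple[ProteinEntry, int, int]] = []
    for elution in _CONTROL_CLASSES:
        for _ in range(cfg.n_background_control):
            seq, prot, start, length = hormone_window()
            control_windows.append((prot, start, length))
            idx = add(
                PeptideRecord(
                    sequence=seq,
                    sample_id=sample_id,
                    elution_class=elution,
                    source_accession=prot.accession,
                    gene_symbol=prot.gene_symbol,
                    precursor_intensity=_intensity(rng, cfg),
                )
            )
            truth.background.add(idx)

    mhc_classes = [ElutionClass.ABC, ElutionClass.DR, ElutionClass.DQ, ElutionClass.DP]
    for _ in range(cfg.n_background_mhc):
        # jitter a control window so a >=6-residue overlap is guaranteed
        prot, start, length = control_windows[int(rng.integers(0, len(control_windows)))]
        jitter = int(rng.integers(-3, 4))
        new_len = int(np.clip(length + rng.integers(-3, 4), 9, 25))
        new_start = int(np.clip(start + jitter, 0, len(prot.sequence) - new_len))
        seq = prot.sequence[new_start : new_start + new_len]
        elution = mhc_classes[int(rng.integers(0, len(mhc_classes)))]
        idx = add(
            PeptideRecord(
                sequence=seq,
                sample_id=sample_id,
                elution_class=elution,
                source_accession=prot.accession,
                gene_symbol=prot.gene_symbol,
                precursor_intensity=_intensity(rng, cfg),
            )
        )
        truth.background.add(idx)

    # --- contaminant peptides
    contaminant_parents = proteome[-len(_CONTAMINANT_GENES) :]
    for _ in range(cfg.n_contaminants):
        prot = contaminant_parents[int(rng.integers(0, len(contaminant_parents)))]
        length = int(rng.integers(8, 20))
        start = int(rng.integers(0, len(prot.sequence) - length + 1))
        elution = mhc_classes[int(rng.integers(0, len(mhc_classes)))]
        idx = add(
            PeptideRecord(
                sequence=prot.sequence[start : start + length],
                sample_id=sample_id,
                elution_class=elution,
                source_accession=prot.accession,
                gene_symbol=prot.gene_symbol,
                precursor_intensity=_intensity(rng, cfg),
            )
        )
        truth.contaminant.add(idx)

    # --- toy gene sets over the ordinary-protein genes
    gene_sets = {
        name: set(rng.choice(normal_genes, size=cfg.gene_set_size, replace=False))
        for name in ("pancreas_enriched", "cytokine_up", "t1d_up")
    }

    return SyntheticPeptidome(
        records=records,
        proteome=proteome,
        genotype=genotype,
        motifs=motifs,
        gene_sets=gene_sets,
        truth=truth,
    )


@dataclass
class SyntheticAssays:
    plates: list[ElispotPlate]
    fp_series: list[tuple[str, FpSeries]]  # (series id, series)
    truth: GroundTruth


def generate_validation_assays(
    config: SyntheticConfig | None = None, n_plates: int = 1
) -> SyntheticAssays:
    """ELISpot plates with known responders and FP series with known IC50s.

    Control wells are Poisson around ``ctrl_spw_mean``; responder peptides
    get experimental wells Poisson around ``responder_effect`` times that
    mean, non-responders around the control mean. FP readings follow the
    one-parameter competition model plus Gaussian noise on fraction bound.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    truth = GroundTruth()
    plates: list[ElispotPlate] = []
    for p in range(n_plates):
        exp_wells: dict[str, tuple[float, ...]] = {}
        for i in range(cfg.n_elispot_peptides):
            pep = f"plate{p}_pep{i}"
            if rng.random() < cfg.responder_fraction:
                mean = cfg.ctrl_spw_mean * cfg.responder_effect
                truth.responders.add(pep)
            else:
                mean = cfg.ctrl_spw_mean
            exp_wells[pep] = tuple(
                float(x) for x in rng.poisson(mean, size=cfg.n_exp_wells)
            )
        ctrl = tuple(float(x) for x in rng.poisson(cfg.ctrl_spw_mean, size=cfg.n_ctrl_wells))
        plates.append(ElispotPlate(experimental_wells=exp_wells, control_wells=ctrl))

    fp_free, fp_no_comp = 50.0, 150.0
    conc = cfg.fp_top_conc / cfg.fp_dilution_factor ** np.arange(cfg.fp_n_dilutions)
    series_id = "fp0"
    y = competition_model(conc, cfg.fp_true_ic50)
    y_noisy = y + rng.normal(0.0, cfg.fp_noise_sigma, size=len(conc))
    obs = tuple(
        (float(c), float(fp_free + yy * (fp_no_comp - fp_free)))
        for c, yy in zip(conc, y_noisy)
    )
    series = FpSeries(fp_free=fp_free, fp_no_comp=fp_no_comp, observations=obs)
    truth.true_ic50[series_id] = cfg.fp_true_ic50
    return SyntheticAssays(plates=plates, fp_series=[(series_id, series)], truth=truth)
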