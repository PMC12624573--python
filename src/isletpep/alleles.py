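"""Tiered assignment of eluted peptides to donor HLA alleles.

Assignment consumes percentile ranks from a *predictor*: any callable
object scoring (peptide, allele) pairs on the 0-100 percentile scale, lower
meaning stronger predicted binding. Production runs would feed ranks from a
neural-network eluted-ligand predictor through the table adapter; the
built-in position-weight-matrix predictor provides a deterministic,
self-contained scorer with the same contract for testing and simulation.

Tier rule: a peptide is *primary* when at least one donor allele of the
matching class passes the class cutoff (2% for MHC-I, 5% for MHC-II), and
every allele passing is assigned; otherwise the cutoff is extended to 10%
(*extended* tier); peptides with no allele at 10% stay *unassigned*.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .model import (
    AMINO_ACIDS,
    DonorGenotype,
    MhcClass,
    PeptideRecord,
    ProteinEntry,
)

logger = logging.getLogger("isletpep")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class RankPredictor(Protocol):
    def rank(self, peptide: str, allele: str) -> float:
        """Percentile rank in [0, 100]; lower = stronger predicted binding."""
        ...


@dataclass(frozen=True)
class AssignmentThresholds:
    tau_class_i: float = 2.0  # percent
    tau_class_ii: float = 5.0
    tau_extended: float = 10.0

    def __post_init__(self) -> None:
        if not (self.tau_class_i < self.tau_extended and self.tau_class_ii < self.tau_extended):
            raise ValueError("class cutoffs must be below the extended cutoff")


@dataclass(frozen=True)
class AlleleCall:
    peptide: PeptideRecord
    assigned_alleles: tuple[tuple[str, float], ...]  # (allele, rank)
    tier: str  # "primary" | "extended" | "unassigned"


class TableRankPredictor:
    """Adapter for externally computed rank tables (peptide, allele) -> rank."""

    def __init__(self, table: dict[tuple[str, str], float], default: float = 100.0):
        self._table = table
        self._default = default

    def rank(self, peptide: str, allele: str) -> float:
        return self._table.get((peptide, allele), self._default)


class PssmRankPredictor:
    """Percentile-rank scorer backed by per-allele position weight matrices.

    The score of a peptide against an allele is the best-window sum of
    log-odds (PWM weight over uniform background) across all contiguous
    windows of the motif length; the percentile rank is taken against the
    empirical score distribution of ``n_background`` random length-matched
    peptides sampled from the background proteome. Background draws are
    seeded per (allele, length), so ranks are deterministic regardless of
    call order.
    """

    def __init__(
        self,
        motifs: dict[str, np.ndarray],
        background_proteome: Sequence[ProteinEntry],
        seed: int = 0,
        n_background: int = 10_000,
    ):
        if not background_proteome:
            raise ValueError("background proteome must be non-empty")
        for allele, pwm in motifs.items():
            if pwm.shape[1] != 20 or not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError(f"PWM for {allele} is not row-stochastic over 20 residues")
        self._logodds = {
            a: np.log(np.maximum(pwm, 1e-9) / 0.05) for a, pwm in motifs.items()
        }
        self._bg_residues = "".join(p.sequence for p in background_proteome)
        self._seed = int(seed)
        self._n_background = int(n_background)
        self._bg_scores: dict[tuple[str, int], np.ndarray] = {}

    def motif_length(self, allele: str) -> int:
        return self._logodds[allele].shape[0]

    def _encode(self, peptide: str) -> np.ndarray:
        return np.fromiter((_AA_INDEX[a] for a in peptide), dtype=np.int64)

    def score(self, peptide: str, allele: str) -> float:
        lo = self._logodds[allele]
        w = lo.shape[0]
        if len(peptide) < w:
            return -np.inf
        enc = self._encode(peptide)
        best = -np.inf
        for start in range(len(peptide) - w + 1):
            s = lo[np.arange(w), enc[start : start + w]].sum()
            best = max(best, s)
        return float(best)

    def _background_scores(self, allele: str, length: int) -> np.ndarray:
        key = (allele, length)
        if key not in self._bg_scores:
            mix = zlib.crc32(f"{allele}:{length}".encode())
            rng = np.random.default_rng((self._seed * 1_000_003 + mix) % (2**31))
            n = self._n_background
            bg = self._bg_residues
            starts = rng.integers(0, max(1, len(bg) - length), size=n)
            lo = self._logodds[allele]
            w = lo.shape[0]
            enc = np.fromiter((_AA_INDEX[a] for a in bg), dtype=np.int64)
            windows = np.stack([enc[s : s + length] for s in starts])
            pos = np.arange(w)
            scores = np.full(n, -np.inf)
            for start in range(length - w + 1):
                scores = np.maximum(
                    scores, lo[pos, windows[:, start : start + w]].sum(axis=1)
                )
            self._bg_scores[key] = np.sort(scores)
        return self._bg_scores[key]

    def rank(self, peptide: str, allele: str) -> float:
        lo = self._logodds[allele]
        if len(peptide) < lo.shape[0]:
            return 100.0
        s = self.score(peptide, allele)
        bg = self._background_scores(allele, len(peptide))
        n = len(bg)
        # midrank percentile of scores >= s: uniform for background-like input
        n_right = int(np.searchsorted(bg, s, side="right"))
        n_left = int(np.searchsorted(bg, s, side="left"))
        n_greater = n - n_right
        n_ties = n_right - n_left
        return float(100.0 * (n_greater + 0.5 * n_ties) / n)


def assign_alleles(
    records: Sequence[PeptideRecord],
    genotype: DonorGenotype,
    predictor: RankPredictor,
    thresholds: AssignmentThresholds | None = None,
    locus_matched: bool = True,
) -> list[AlleleCall]:
    """Assign every curated peptide to donor alleles by the tier rule.

    MHC-I (ABC) peptides are tested against the donor's class-I alleles;
    MHC-II peptides against class-II alleles, restricted to the locus of the
    eluting antibody unless ``locus_matched`` is disabled.
    """
    thresholds = thresholds or AssignmentThresholds()
    calls: list[AlleleCall] = []
    warned = False
    for rec in records:
        if rec.elution_class.is_control:
            continue
        if locus_matched:
            candidates = genotype.alleles_for_locus(rec.elution_class)
        else:
            cls = MhcClass.I if rec.elution_class.is_mhc1 else MhcClass.II
            candidates = genotype.alleles_of_class(cls)
        if not candidates:
            if not warned:
                logger.warning(
                    "donor %s has no alleles for elution class %s; peptides unassigned",
                    genotype.sample_id,
                    rec.elution_class.value,
                )
                warned = True
            calls.append(AlleleCall(rec, (), "unassigned"))
            continue
        tau = (
            thresholds.tau_class_i
            if rec.elution_class.is_mhc1
            else thresholds.tau_class_ii
        )
        ranks = [(a, predictor.rank(rec.sequence, a)) for a in candidates]
        primary = tuple((a, r) for a, r in ranks if r <= tau)
        if primary:
            calls.append(AlleleCall(rec, primary, "primary"))
            continue
        extended = tuple((a, r) for a, r in ranks if r <= thresholds.tau_extended)
        if extended:
            calls.append(AlleleCall(rec, extended, "extended"))
        else:
            calls.append(AlleleCall(rec, (), "unassigned"))
    return calls
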