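"""Validation statistics: competition-binding IC50 and the DFR ELISpot test.

Two assays back up the computational epitope calls.

*Fluorescence polarization (FP) competition binding.* A labelled probe
peptide bound to an MHC protein gives a high FP reading; competition by a
test peptide lowers it. Readings are normalized to fraction bound,
``y = (FP_sample - FP_free) / (FP_no_comp - FP_free)``, and the competition
curve is fit to the one-parameter model ``y = 1 / (1 + [pep]/IC50)``.

*Distribution-free resampling (DFR) ELISpot positivity.* For each peptide
the null hypothesis is that the mean of experimental wells is at most m
times the mean of negative-control wells (m = 1 for DFR1x, m = 2 for
DFR2x). The test permutes well assignments between the experimental wells
and the m-scaled control wells, and adjusts across the peptides of a plate
with Westfall-Young step-down maxT using a shared set of permutations.
Zero-response wells are raised to the assay detection floor (0.3 spots per
well) before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger("isletpep")

# ---------------------------------------------------------------------------
# fluorescence polarization


@dataclass(frozen=True)
class FpSeries:
    fp_free: float  # probe alone
    fp_no_comp: float  # probe + protein, no competitor
    observations: tuple[tuple[float, float], ...]  # (pep_conc [M], fp_sample)
    protein: str = ""
    probe: str = ""

    def __post_init__(self) -> None:
        if any(conc <= 0 for conc, _ in self.observations):
            raise ValueError("peptide concentrations must be > 0")


def fraction_bound(series: FpSeries) -> list[tuple[float, float]]:
    """Normalize FP readings to fraction bound by the printed formula.

    Values outside [0, 1] are retained (they carry noise information for
    the fit) but logged. Degenerate assays (no dynamic range) are an error.
    """
    span = series.fp_no_comp - series.fp_free
    if span == 0:
        raise ValueError("fp_no_comp equals fp_free: assay has no dynamic range")
    out = []
    n_outside = 0
    for conc, fp in series.observations:
        y = (fp - series.fp_free) / span
        if not 0.0 <= y <= 1.0:
            n_outside += 1
        out.append((conc, y))
    if n_outside:
        logger.info("%d fraction-bound values fall outside [0, 1]", n_outside)
    return out


@dataclass(frozen=True)
class Ic50Fit:
    ic50: Optional[float]  # molar
    rss: float
    converged: bool


def competition_model(conc: np.ndarray, ic50: float) -> np.ndarray:
    """One-parameter competition curve y = 1 / (1 + conc/IC50)."""
    return 1.0 / (1.0 + np.asarray(conc, dtype=float) / ic50)


def fit_ic50(points: Sequence[tuple[float, float]]) -> Ic50Fit:
    """Least-squares IC50 on a log-concentration grid, locally refined.

    The model has a single parameter, so a coarse scan over log10(IC50)
    spanning well beyond the tested concentrations followed by bounded
    scalar minimization is robust and deterministic. A flat response
    (no transition information) returns a non-converged fit.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit an IC50")
    conc = np.array([c for c, _ in points], dtype=float)
    y = np.array([v for _, v in points], dtype=float)
    if float(np.ptp(y)) < 1e-3:
        return Ic50Fit(ic50=None, rss=float(np.sum((y - y.mean()) ** 2)), converged=False)

    def rss_of(log_ic50: float) -> float:
        return float(np.sum((y - competition_model(conc, 10.0**log_ic50)) ** 2))

    lo = np.log10(conc.min()) - 4
    hi = np.log10(conc.max()) + 4
    grid = np.linspace(lo, hi, 241)
    best = grid[int(np.argmin([rss_of(g) for g in grid]))]
    res = minimize_scalar(
        rss_of, bounds=(best - 0.5, best + 0.5), method="bounded",
        options={"xatol": 1e-10},
    )
    return Ic50Fit(ic50=float(10.0**res.x), rss=float(res.fun), converged=True)


# ---------------------------------------------------------------------------
# DFR ELISpot positivity


@dataclass(frozen=True)
class ElispotPlate:
    """Well counts for one plate: per-peptide experimental wells and the
    shared negative-control (DMSO) wells, in spots per well (spw)."""

    experimental_wells: dict[str, tuple[float, ...]]  # peptide/pool id -> spw
    control_wells: tuple[float, ...]
    detection_floor: float = 0.3

    def __post_init__(self) -> None:
        for wells in (*self.experimental_wells.values(), self.control_wells):
            if any(w < 0 for w in wells):
                raise ValueError("spot counts must be >= 0")

    def imputed(self) -> "ElispotPlate":
        """Raise wells below the detection floor to the floor (0.3 spw)."""
        f = self.detection_floor
        return ElispotPlate(
            experimental_wells={
                k: tuple(max(w, f) for w in v)
                for k, v in self.experimental_wells.items()
            },
            control_wells=tuple(max(w, f) for w in self.control_wells),
            detection_floor=f,
        )


@dataclass(frozen=True)
class DfrResult:
    peptide: str
    multiplier: int
    p_adjusted: float
    positive: bool
    exact: bool
    n_perm: int
    seed: Optional[int]


def _arrangement_count(n_exp: int, n_ctrl: int) -> int:
    return comb(n_exp + n_ctrl, n_exp)


def dfr_test(
    plate: ElispotPlate,
    m: int = 2,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    exact_limit: int = 10_000,
) -> list[DfrResult]:
    """DFR positivity for every peptide on a plate at multiplier ``m``.

    Statistic: mean(experimental) - mean(m * control). Control wells are
    scaled by m and pooled with the experimental wells; labels are permuted
    and the observed statistic compared with the permutation distribution.
    With a single hypothesis and at most ``exact_limit`` distinct label
    arrangements, the permutation distribution is enumerated exactly;
    otherwise ``n_perm`` Monte-Carlo draws (shared across the peptides of
    the plate) feed a Westfall-Young step-down maxT adjustment. The raw
    mean-difference statistic with shared permutations makes DFR2x
    positivity imply DFR1x positivity for non-negative counts.

    Hypotheses with fewer than 2 experimental or control wells are skipped
    with a warning.
    """
    if m < 1:
        raise ValueError("multiplier must be >= 1")
    plate = plate.imputed()
    ctrl = np.array(plate.control_wells, dtype=float)
    peptides, stats_obs = [], []
    skipped = []
    for pep, wells in plate.experimental_wells.items():
        if len(wells) < 2 or len(ctrl) < 2:
            logger.warning("peptide %s skipped: too few wells for DFR", pep)
            skipped.append(pep)
            continue
        peptides.append(pep)
        stats_obs.append(float(np.mean(wells) - m * np.mean(ctrl)))
    results: list[DfrResult] = []
    if not peptides:
        return results

    scaled_ctrl = m * ctrl
    n_ctrl = len(ctrl)

    if len(peptides) == 1:
        pep = peptides[0]
        exp = np.array(plate.experimental_wells[pep], dtype=float)
        pooled = np.concatenate([exp, scaled_ctrl])
        n_exp = len(exp)
        total = _arrangement_count(n_exp, n_ctrl)
        obs = stats_obs[0]
        if total <= exact_limit:
            count = 0
            idx_all = range(len(pooled))
            for exp_idx in combinations(idx_all, n_exp):
                mask = np.zeros(len(pooled), dtype=bool)
                mask[list(exp_idx)] = True
                stat = pooled[mask].mean() - pooled[~mask].mean()
                if stat >= obs - 1e-12:
                    count += 1
            p = count / total
            results.append(
                DfrResult(pep, m, float(p), p <= alpha, True, total, None)
            )
            return results
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            stat = perm[:n_exp].mean() - perm[n_exp:].mean()
            if stat >= obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        results.append(DfrResult(pep, m, float(p), p <= alpha, False, n_perm, seed))
        return results

    # multiple hypotheses: Monte-Carlo maxT step-down with shared permutations
    rng = np.random.default_rng(seed)
    exps = {p: np.array(plate.experimental_wells[p], dtype=float) for p in peptides}
    perm_stats = np.empty((n_perm, len(peptides)))
    for b in range(n_perm):
        for j, pep in enumerate(peptides):
            pooled = np.concatenate([exps[pep], scaled_ctrl])
            perm = rng.permutation(pooled)
            n_exp = len(exps[pep])
            perm_stats[b, j] = perm[:n_exp].mean() - perm[n_exp:].mean()
    obs = np.array(stats_obs)
    order = np.argsort(-obs)  # most significant first
    p_adj = np.empty(len(peptides))
    prev = 0.0
    remaining = list(order)
    for rank_idx, j in enumerate(order):
        # maxT over hypotheses not yet stepped down past
        max_t = perm_stats[:, remaining].max(axis=1)
        p_raw = (np.sum(max_t >= obs[j] - 1e-12) + 1) / (n_perm + 1)
        p_adj[j] = max(prev, p_raw)  # enforce monotone step-down
        prev = p_adj[j]
        remaining = remaining[1:]
    for j, pep in enumerate(peptides):
        results.append(
            DfrResult(pep, m, float(p_adj[j]), p_adj[j] <= alpha, False, n_perm, seed)
        )
    return results


def dfr_both(
    plate: ElispotPlate,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
) -> dict[str, dict[int, DfrResult]]:
    """DFR1x and DFR2x for every peptide (the red/blue asterisk pair)."""
    out: dict[str, dict[int, DfrResult]] = {}
    for m in (1, 2):
        for res in dfr_test(plate, m=m, alpha=alpha, n_perm=n_perm, seed=seed):
            out.setdefault(res.peptide, {})[m] = res
    return out
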