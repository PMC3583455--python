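"""Deterministic expectations: prediction accuracy, selection response.

For a biparental DH family the number of independently segregating
chromosome segments ("effective number of loci", me) is the haploid
chromosome number plus the expected crossover count, i.e. the map length
in Morgans.  With a training set of n phenotyped lines of entry-mean
heritability h2, the expected accuracy of genomic predictions is

    r_hat = sqrt(lambda / (lambda + 1)),      lambda = n h2 / me,

with an approximate adjustment, accounting for all loci being fit
jointly rather than one at a time, that subtracts 0.5 r_hat^4 (me / n)
from the accuracy itself:

    r_adj = r_hat - 0.5 r_hat^4 (me / n).

(The placement of the adjustment -- on r_hat or on r_hat^2 -- is a
committed reading; this one makes the deterministic curves sit 0.01-0.03
above the simulated accuracies on the high-heritability grid, which is
how the adjustment is characterised in the source work.)

Truncation-selection intensity uses the infinite-population formula
i = phi(z) / p, which reproduces the printed study values (a finite-
sample order-statistic correction would not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .genome import Genome, GenomeMap, default_genome
from .phenosim import allocate

__all__ = [
    "AccuracyPrediction",
    "effective_loci",
    "entry_mean_h2",
    "expected_accuracy",
    "selection_intensity",
    "expected_response",
    "optimal_allocation",
    "OptimalAllocation",
    "theory_table",
]


def effective_loci(genome_map: GenomeMap | Genome) -> float:
    """Effective number of loci: chromosome number + map length in Morgans.

    Real-valued (27.96 for the default genome); round for reporting.
    """
    gmap = genome_map.map if isinstance(genome_map, Genome) else genome_map
    return gmap.n_chromosomes + gmap.total_length_morgans


def entry_mean_h2(h2plot: float, r: int) -> float:
    """Heritability of an entry mean of ``r`` plots.

    Averaging r plots divides the error variance by r:
    h2 = r h2plot / (r h2plot + 1 - h2plot).
    """
    if not 0 < h2plot <= 1:
        raise InvalidInputError("h2plot must be in (0, 1]")
    if r < 1:
        raise InvalidInputError("r must be >= 1")
    return r * h2plot / (r * h2plot + 1.0 - h2plot)


@dataclass(frozen=True)
class AccuracyPrediction:
    """Expected accuracy, with and without the joint-fit adjustment."""

    unadjusted: float
    adjusted: float


def expected_accuracy(n: float, h2: float, me: float) -> AccuracyPrediction:
    """Expected prediction accuracy for training size n, heritability h2."""
    if me <= 0:
        raise InvalidInputError("me must be positive")
    if not 0 <= h2 <= 1:
        raise InvalidInputError("h2 must be in [0, 1]")
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    if n == 0 or h2 == 0:
        return AccuracyPrediction(0.0, 0.0)
    lam = n * h2 / me
    r2 = lam / (lam + 1.0)
    r_un = math.sqrt(r2)
    adj = r_un - 0.5 * r2 * r2 * me / n
    return AccuracyPrediction(r_un, max(0.0, adj))


def selection_intensity(p: float) -> float:
    """Standardized selection differential of truncating the best fraction p."""
    if not 0 < p <= 1:
        raise InvalidInputError("selected proportion must be in (0, 1]")
    if p == 1:
        return 0.0
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)


def expected_response(i: float, r_a: float, sigma_a: float) -> float:
    """Expected response to selection R = i * r_A * sigma_A."""
    if sigma_a < 0:
        raise InvalidInputError("sigma_a must be >= 0")
    return i * r_a * sigma_a


@dataclass(frozen=True)
class OptimalAllocation:
    """Ranked accuracy table over replication candidates for one budget."""

    table: pd.DataFrame
    best_n: int
    best_r: int

    @property
    def label(self) -> str:
        return f"{self.best_n}:{self.best_r}"


def optimal_allocation(
    B: float,
    C: float,
    h2plot: float,
    r_candidates: tuple[int, ...] = (1, 2, 3, 4),
    F: float = 1.0,
    genome_map: GenomeMap | Genome | None = None,
) -> OptimalAllocation:
    """Best (n, r) under budget B by expected accuracy.

    For each candidate r the budget resolves to n = B / (C + r F) lines;
    the expected accuracy is evaluated at the phenotyped count truncated
    to a whole number of lines, with the entry-mean heritability for r
    plots.  Candidates are ranked by the base (unadjusted) formula, which
    reproduces the study's printed optimal strategies; the adjusted value
    is reported alongside.  Ties break toward smaller r.  The reported n
    uses the same half-to-even rounding as :func:`gsalloc.phenosim.allocate`.
    """
    if not r_candidates:
        raise InvalidInputError("r_candidates must be non-empty")
    me = effective_loci(genome_map if genome_map is not None else default_genome().map)
    rows = []
    for r in r_candidates:
        alloc = allocate(B, C, F, r)
        n_eval = math.floor(F * B / (C + r * F))
        h2 = entry_mean_h2(h2plot, r)
        pred = expected_accuracy(n_eval, h2, me)
        rows.append(
            {
                "B": B,
                "C": C,
                "F": F,
                "h2plot": h2plot,
                "r": r,
                "n": alloc.n,
                "n_ph": alloc.n_ph,
                "h2_entry": h2,
                "raa_eq2": pred.unadjusted,
                "raa_eq3": pred.adjusted,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table["raa_eq2"].to_numpy().argmax())  # argmax -> smallest r on ties
    table["is_optimal"] = np.arange(len(table)) == best
    return OptimalAllocation(table, int(table.loc[best, "n"]), int(table.loc[best, "r"]))


def theory_table(
    budgets: tuple[float, ...] = (250.0, 500.0),
    costs: tuple[float, ...] = (0.0, 0.5, 1.0),
    h2plots: tuple[float, ...] = (0.20, 0.60),
    r_candidates: tuple[int, ...] = (1, 2, 3, 4),
    F: float = 1.0,
    genome_map: GenomeMap | Genome | None = None,
) -> pd.DataFrame:
    """Expected-accuracy grid over (B, C, h2plot, r) with per-cell optima."""
    parts = []
    for B in budgets:
        for C in costs:
            for h2plot in h2plots:
                parts.append(
                    optimal_allocation(B, C, h2plot, r_candidates, F, genome_map).table
                )
    return pd.concat(parts, ignore_index=True)
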