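"""Replicated simulation experiments: cross-validation accuracy grids,
budget tradeoffs, theory-vs-observed comparison, random-mating decay, and
multi-cycle recurrent genomic selection.

Every driver follows the same pattern: a master seed spawns one child
random stream per replicate (so runs are bit-reproducible and replicates
are independent given their child streams); each replicate simulates a
fresh genome architecture and DH population; per-cell metrics are
averaged over replicates with standard errors.

Within a replicate, all cells of a grid share the same simulated
population (training lines are nested subsets and validation lines are
held fixed), mirroring a paired design: cell contrasts such as the
r = 1 -> 2 accuracy gain are then estimated with much smaller error than
under independent populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from . import genome as gen
from .phenosim import allocate, error_variance, realized_sigma_a2, simulate_entry_means
from .predictors import (
    BayesCPiConfig,
    fit_bayescpi,
    fit_ols_stepwise,
    fit_rrblup,
    predict,
    accuracy,
)
from .theory import effective_loci, entry_mean_h2, expected_accuracy, selection_intensity

__all__ = [
    "SimParams",
    "ExperimentResult",
    "summarize",
    "run_cross_validation",
    "run_budget_grid",
    "compare_theory",
    "run_random_mating_decay",
    "run_recurrent_selection",
]

logger = logging.getLogger("gsalloc")

DEFAULT_N_VALIDATION = 500
MIN_TRAINING = 10


@dataclass(frozen=True)
class SimParams:
    """Genome and trait-architecture constants shared by all experiments."""

    n_chrom: int = gen.MAIZE_N_CHROM
    chrom_lengths_cM: tuple[float, ...] | None = None  # None -> equal, 1796 total
    loci_per_chrom: int = gen.DEFAULT_LOCI_PER_CHROM
    n_qtl: int = gen.DEFAULT_N_QTL
    n_markers: int = gen.DEFAULT_N_MARKERS

    def build(self) -> gen.Genome:
        lengths = self.chrom_lengths_cM
        if lengths is None:
            lengths = tuple([gen.MAIZE_TOTAL_CM / self.n_chrom] * self.n_chrom)
        return gen.build_genome(self.n_chrom, lengths, self.loci_per_chrom)


@dataclass
class ExperimentResult:
    """Per-cell replicate arrays plus their mean/SE summary table."""

    summary: pd.DataFrame
    replicates: dict[tuple, np.ndarray] = field(default_factory=dict)

    def cell(self, key: tuple) -> np.ndarray:
        return self.replicates[key]


def summarize(replicate_values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error over replicates, ignoring NaN cells."""
    v = np.asarray(replicate_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise InvalidInputError("need at least 2 finite replicates")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _fit_model(model: str, Z: np.ndarray, y: np.ndarray, rng: np.random.Generator,
               alpha: float, bayes_config: BayesCPiConfig | None):
    if model == "rrblup":
        return fit_rrblup(Z, y)
    if model == "ols":
        return fit_ols_stepwise(Z, y, alpha=alpha)
    if model == "bayescpi":
        return fit_bayescpi(Z, y, bayes_config, rng)
    raise ConfigurationError(f"unknown model '{model}'")


def _simulate_base(
    params: SimParams, n_lines: int, rng: np.random.Generator
) -> tuple[gen.Genome, gen.TraitArchitecture, np.ndarray, np.ndarray]:
    """Fresh genome+architecture and a DH population of ``n_lines``.

    Returns (genome, architecture, true values, marker matrix).
    """
    g = params.build()
    arch = gen.assign_architecture(g, params.n_qtl, params.n_markers, rng)
    f1 = gen.f1_individual(g)
    pop = gen.make_dh_population(f1, n_lines, g, rng)
    gv = gen.genetic_values(pop, arch)
    Z = gen.marker_matrix(pop, arch).astype(np.float64)
    return g, arch, gv.values, Z


# ---------------------------------------------------------------------------
# Cross-validation accuracy grids
# ---------------------------------------------------------------------------


def run_cross_validation(
    models: tuple[str, ...] = ("rrblup",),
    n_grid: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 175, 200, 225, 250, 275, 300),
    r_grid: tuple[int, ...] = (1, 2, 3, 4),
    h2plot: float = 0.20,
    n_replicates: int = 200,
    seed: int = 0,
    n_validation: int = DEFAULT_N_VALIDATION,
    params: SimParams = SimParams(),
    alpha: float = 0.20,
    bayes_config: BayesCPiConfig | None = None,
) -> ExperimentResult:
    """Validation-set accuracy for every (model, n, r) cell.

    Per replicate one DH population of ``max(n_grid) + n_validation``
    lines is simulated from one F1; the first ``n`` lines are phenotyped
    (entry means of ``r`` plots at plot heritability ``h2plot``) and used
    to fit each model, and accuracy is the correlation between GEBVs and
    true genetic values over the held-out validation lines.
    """
    if min(n_grid) < MIN_TRAINING:
        raise ConfigurationError(f"training sizes must be >= {MIN_TRAINING}")
    if n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    max_n = max(n_grid)
    cells = [(mdl, n, r) for mdl in models for n in n_grid for r in r_grid]
    acc = {c: np.full(n_replicates, np.nan) for c in cells}

    for rep, rng in enumerate(_child_rngs(seed, n_replicates)):
        _, _, a, Z = _simulate_base(params, max_n + n_validation, rng)
        sigma_a2 = realized_sigma_a2(a)
        sigma_e2 = error_variance(sigma_a2, h2plot)
        a_val = a[max_n:]
        Z_val = Z[max_n:]
        for r in r_grid:
            y_full = simulate_entry_means(a[:max_n], r, sigma_e2, rng).entry_means
            for n in n_grid:
                for mdl in models:
                    fit = _fit_model(mdl, Z[:n], y_full[:n], rng, alpha, bayes_config)
                    acc[(mdl, n, r)][rep] = accuracy(predict(fit, Z_val), a_val)

    rows = []
    for (mdl, n, r), v in acc.items():
        mean, se = summarize(v)
        rows.append(
            {"model": mdl, "n": n, "r": r, "h2plot": h2plot,
             "metric": "accuracy", "mean": mean, "se": se,
             "n_reps": int(np.isfinite(v).sum())}
        )
    return ExperimentResult(pd.DataFrame(rows), acc)


# ---------------------------------------------------------------------------
# Budget grids
# ---------------------------------------------------------------------------


def run_budget_grid(
    models: tuple[str, ...] = ("rrblup",),
    B: float = 500.0,
    C_grid: tuple[float, ...] = (0.0, 0.5, 1.0),
    F: float = 1.0,
    r_grid: tuple[int, ...] = (1, 2, 3, 4),
    h2plot: float = 0.20,
    n_replicates: int = 200,
    seed: int = 0,
    n_validation: int = DEFAULT_N_VALIDATION,
    params: SimParams = SimParams(),
    alpha: float = 0.20,
    bayes_config: BayesCPiConfig | None = None,
) -> ExperimentResult:
    """Cross-validation accuracy for each budget cell (B, C, F, r).

    Each cell resolves to (n, n_ph) through :func:`gsalloc.phenosim.allocate`;
    the model trains on the ``n_ph`` phenotyped lines and is scored on the
    shared validation set.  Cells allocating fewer than 10 phenotyped
    lines are skipped with a logged warning.
    """
    cells = {}
    for C in C_grid:
        for r in r_grid:
            alloc = allocate(B, C, F, r)
            if alloc.n_ph < MIN_TRAINING:
                logger.warning(
                    "skipping cell B=%s C=%s F=%s r=%d: n_ph=%d < %d",
                    B, C, F, r, alloc.n_ph, MIN_TRAINING,
                )
                continue
            cells[(C, r)] = alloc
    if not cells:
        raise ConfigurationError("no feasible budget cells")
    max_train = max(a.n_ph for a in cells.values())
    acc = {(mdl, C, r): np.full(n_replicates, np.nan)
           for mdl in models for (C, r) in cells}

    for rep, rng in enumerate(_child_rngs(seed, n_replicates)):
        _, _, a, Z = _simulate_base(params, max_train + n_validation, rng)
        sigma_a2 = realized_sigma_a2(a)
        sigma_e2 = error_variance(sigma_a2, h2plot)
        a_val = a[max_train:]
        Z_val = Z[max_train:]
        for r in sorted({r for (_, r) in cells}):
            y_full = simulate_entry_means(a[:max_train], r, sigma_e2, rng).entry_means
            for (C, rr), alloc in cells.items():
                if rr != r:
                    continue
                n_ph = alloc.n_ph
                for mdl in models:
                    fit = _fit_model(mdl, Z[:n_ph], y_full[:n_ph], rng, alpha, bayes_config)
                    acc[(mdl, C, r)][rep] = accuracy(predict(fit, Z_val), a_val)

    rows = []
    for (mdl, C, r), v in acc.items():
        alloc = cells[(C, r)]
        mean, se = summarize(v)
        rows.append(
            {"model": mdl, "B": B, "C": C, "F": F, "r": r,
             "n": alloc.n, "n_ph": alloc.n_ph, "h2plot": h2plot,
             "metric": "accuracy", "mean": mean, "se": se,
             "n_reps": int(np.isfinite(v).sum())}
        )
    return ExperimentResult(pd.DataFrame(rows), acc)


# ---------------------------------------------------------------------------
# Theory vs observed
# ---------------------------------------------------------------------------


def compare_theory(
    n_grid: tuple[int, ...] = (25, 50, 75, 100, 125, 150, 175, 200, 225, 250, 275, 300),
    r_grid: tuple[int, ...] = (1, 2),
    h2plots: tuple[float, ...] = (0.20, 0.60),
    n_replicates: int = 200,
    seed: int = 0,
    params: SimParams = SimParams(),
    n_validation: int = DEFAULT_N_VALIDATION,
) -> pd.DataFrame:
    """Deterministic expected accuracy next to simulated RR-BLUP accuracy.

    One cross-validation run per plot heritability; the theory column
    uses the adjusted expected-accuracy formula with the real-valued
    effective-loci count of the simulated genome and the entry-mean
    heritability for each r.  Returns one row per cell with the
    (theory - observed) difference, from which per-r averages follow.
    """
    me = effective_loci(params.build())
    sub_seeds = [s.generate_state(1)[0] % (2**31) for s in
                 np.random.SeedSequence(seed).spawn(len(h2plots))]
    rows = []
    for h2p, s in zip(h2plots, sub_seeds):
        res = run_cross_validation(
            ("rrblup",), n_grid, r_grid, h2p, n_replicates, int(s),
            n_validation, params,
        )
        for _, row in res.summary.iterrows():
            n, r = int(row["n"]), int(row["r"])
            theo = expected_accuracy(n, entry_mean_h2(h2p, r), me)
            rows.append(
                {"n": n, "r": r, "h2plot": h2p,
                 "observed": row["mean"], "observed_se": row["se"],
                 "theory_unadjusted": theo.unadjusted,
                 "theory_adjusted": theo.adjusted,
                 "diff": theo.adjusted - row["mean"]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Random-mating decay of accuracy
# ---------------------------------------------------------------------------


def run_random_mating_decay(
    model: str = "rrblup",
    strategies: tuple[tuple[int, int], ...] = ((500, 1), (250, 2), (167, 3), (125, 4)),
    h2plot: float = 0.20,
    n_replicates: int = 100,
    seed: int = 0,
    n_cycles: int = 3,
    cycle_size: int = 1000,
    params: SimParams = SimParams(),
    alpha: float = 0.20,
    bayes_config: BayesCPiConfig | None = None,
) -> ExperimentResult:
    """Accuracy of a C0-trained model on cycles of random mating.

    ``strategies`` is a tuple of (n, r) training designs.  Per replicate
    and strategy: train on a C0 DH population of n lines; randomly mate
    the C0 lines (pairs with replacement) to produce ``cycle_size`` F1s,
    randomly mate those to produce the C1 S0 generation, and keep random
    mating to C2, C3, ...; accuracy is computed within each cycle's
    ``cycle_size`` individuals.  No selection is applied, so allele
    frequencies and genetic variance stay stable in expectation.
    """
    keys = [(n, r, cyc) for (n, r) in strategies for cyc in range(1, n_cycles + 1)]
    acc = {k: np.full(n_replicates, np.nan) for k in keys}

    for rep, rng in enumerate(_child_rngs(seed, n_replicates)):
        g = params.build()
        arch = gen.assign_architecture(g, params.n_qtl, params.n_markers, rng)
        f1 = gen.f1_individual(g)
        for (n, r) in strategies:
            pop0 = gen.make_dh_population(f1, n, g, rng)
            a0 = gen.genetic_values(pop0, arch)
            Z0 = gen.marker_matrix(pop0, arch).astype(float)
            sigma_e2 = error_variance(realized_sigma_a2(a0), h2plot)
            y = simulate_entry_means(a0, r, sigma_e2, rng).entry_means
            fit = _fit_model(model, Z0, y, rng, alpha, bayes_config)
            f1s = gen.random_mate(pop0, cycle_size, g, rng, generation="F1xF1")
            current = f1s
            for cyc in range(1, n_cycles + 1):
                current = gen.random_mate(current, cycle_size, g, rng,
                                          generation=f"C{cyc}")
                a_c = gen.genetic_values(current, arch).values
                gebv = predict(fit, gen.marker_matrix(current, arch).astype(float))
                acc[(n, r, cyc)][rep] = accuracy(gebv, a_c)

    rows = []
    for (n, r, cyc), v in acc.items():
        mean, se = summarize(v)
        rows.append(
            {"model": model, "n": n, "r": r, "h2plot": h2plot, "cycle": cyc,
             "metric": "accuracy", "mean": mean, "se": se,
             "n_reps": int(np.isfinite(v).sum())}
        )
    return ExperimentResult(pd.DataFrame(rows), acc)


# ---------------------------------------------------------------------------
# Recurrent genomic selection with genetic gain
# ---------------------------------------------------------------------------


def run_recurrent_selection(
    n: int,
    n_ph: int | None = None,
    r: int = 1,
    h2plot: float = 0.20,
    n_replicates: int = 500,
    seed: int = 0,
    n_select_c0: int = 10,
    n_select: int = 20,
    cycle_size: int = 200,
    n_cycles: int = 3,
    params: SimParams = SimParams(),
) -> ExperimentResult:
    """Marker-score recurrent selection over ``n_cycles`` cycles (RR-BLUP).

    Per replicate: a C0 DH population of ``n`` lines is simulated and a
    random subset of ``n_ph`` lines phenotyped (entry means of ``r``
    plots); RR-BLUP is trained once on C0.  The top ``n_select_c0`` of
    all ``n`` lines by GEBV are paired into ``n_select_c0 / 2`` random
    crosses (each line used once); their F1s are randomly mated to
    ``cycle_size`` C1 S0 plants.  Each later cycle selects the top
    ``n_select`` plants by GEBV and randomly mates them to ``cycle_size``
    progeny.  Cycle means of true genetic value are reported in units of
    the C0 genetic standard deviation, alongside C0 prediction accuracy
    split by phenotyped / non-phenotyped membership and the C0 selection
    intensity.
    """
    n_ph = n if n_ph is None else n_ph
    if n_ph < MIN_TRAINING:
        raise ConfigurationError(f"n_ph must be >= {MIN_TRAINING}")
    if n_ph > n:
        raise ConfigurationError("n_ph cannot exceed n")
    if n_select_c0 % 2 or n_select_c0 > n:
        raise ConfigurationError("n_select_c0 must be even and <= n")

    gains = {cyc: np.full(n_replicates, np.nan) for cyc in range(1, n_cycles + 1)}
    acc_ph = np.full(n_replicates, np.nan)
    acc_nonph = np.full(n_replicates, np.nan)

    for rep, rng in enumerate(_child_rngs(seed, n_replicates)):
        g = params.build()
        arch = gen.assign_architecture(g, params.n_qtl, params.n_markers, rng)
        f1 = gen.f1_individual(g)
        pop0 = gen.make_dh_population(f1, n, g, rng)
        gv0 = gen.genetic_values(pop0, arch)
        a0 = gv0.values
        Z0 = gen.marker_matrix(pop0, arch).astype(float)
        sd0 = math.sqrt(realized_sigma_a2(a0))
        sigma_e2 = error_variance(realized_sigma_a2(a0), h2plot)

        ph_idx = rng.permutation(n)[:n_ph]
        y = simulate_entry_means(a0[ph_idx], r, sigma_e2, rng).entry_means
        fit = fit_rrblup(Z0[ph_idx], y)
        gebv0 = predict(fit, Z0)
        acc_ph[rep] = accuracy(gebv0[ph_idx], a0[ph_idx])
        if n_ph < n:
            mask = np.ones(n, bool)
            mask[ph_idx] = False
            nonph = np.flatnonzero(mask)
            if nonph.size >= 3:
                acc_nonph[rep] = accuracy(gebv0[nonph], a0[nonph])

        sel = np.argsort(gebv0)[::-1][:n_select_c0]
        f1s = gen.random_mate(pop0.subset(sel), n_select_c0 // 2, g, rng,
                              with_replacement=False, generation="F1")
        current = gen.random_mate(f1s, cycle_size, g, rng, generation="C1")
        for cyc in range(1, n_cycles + 1):
            a_c = gen.genetic_values(current, arch).values
            gains[cyc][rep] = (a_c.mean() - a0.mean()) / sd0
            if cyc == n_cycles:
                break
            gebv_c = predict(fit, gen.marker_matrix(current, arch).astype(float))
            sel_c = np.argsort(gebv_c)[::-1][:n_select]
            current = gen.random_mate(current.subset(sel_c), cycle_size, g, rng,
                                      generation=f"C{cyc + 1}")

    replicates: dict[tuple, np.ndarray] = {
        ("cycle_mean", cyc): gains[cyc] for cyc in gains
    }
    replicates[("accuracy_phenotyped",)] = acc_ph
    replicates[("accuracy_nonphenotyped",)] = acc_nonph

    rows = []
    common = {"n": n, "n_ph": n_ph, "r": r, "h2plot": h2plot,
              "i_c0": selection_intensity(n_select_c0 / n)}
    for cyc in gains:
        mean, se = summarize(gains[cyc])
        rows.append({**common, "metric": f"cycle{cyc}_mean", "mean": mean,
                     "se": se, "n_reps": int(np.isfinite(gains[cyc]).sum())})
    mean, se = summarize(acc_ph)
    rows.append({**common, "metric": "accuracy_phenotyped", "mean": mean,
                 "se": se, "n_reps": int(np.isfinite(acc_ph).sum())})
    if np.isfinite(acc_nonph).sum() >= 2:
        mean, se = summarize(acc_nonph)
        rows.append({**common, "metric": "accuracy_nonphenotyped", "mean": mean,
                     "se": se, "n_reps": int(np.isfinite(acc_nonph).sum())})
    return ExperimentResult(pd.DataFrame(rows), replicates)
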