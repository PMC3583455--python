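"""Genome, trait architecture, meiosis, and population simulation.

Simulates a biparental doubled-haploid (DH) breeding population on a
maize-like genome.  The genome is a set of chromosomes with genetic
lengths in centimorgans; loci are abstract biallelic SNPs placed evenly
along each chromosome.  Because the population descends from a single F1
between two fully polymorphic inbred parents, every allele can be labelled
by its parental origin (0 = parent 1, 1 = parent 2) and a haplotype is a
vector of such labels over all loci.

Meiosis follows the no-interference (Haldane) model: the number of
crossovers per chromosome is Poisson with mean equal to the chromosome
length in Morgans, breakpoint positions are uniform, and the starting
strand is chosen with probability 1/2.  A DH line is a single gamete
doubled, hence homozygous at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "GenomeMap",
    "LocusSet",
    "Genome",
    "TraitArchitecture",
    "Population",
    "GeneticValues",
    "build_genome",
    "default_genome",
    "geometric_effects",
    "assign_architecture",
    "f1_individual",
    "meiosis",
    "crossover_counts",
    "make_dh_population",
    "random_mate",
    "genetic_values",
    "marker_matrix",
]

#: Total genetic length (cM) of the maize Genetic 2008 composite map.
MAIZE_TOTAL_CM = 1796.0
MAIZE_N_CHROM = 10
DEFAULT_LOCI_PER_CHROM = 500
DEFAULT_N_QTL = 100
DEFAULT_N_MARKERS = 200

# Gamete batches are generated in chunks to bound the size of the
# (gametes x loci x breakpoints) broadcast used for crossover parity.
_GAMETE_CHUNK = 2048


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome genetic lengths in centimorgans."""

    chromosome_lengths: tuple[float, ...]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.chromosome_lengths))

    @property
    def total_length_morgans(self) -> float:
        return self.total_length_cM / 100.0

    def lengths_morgans(self) -> np.ndarray:
        return np.asarray(self.chromosome_lengths, dtype=float) / 100.0


@dataclass(frozen=True)
class LocusSet:
    """Per-locus chromosome assignment and genetic position (cM).

    Positions are strictly increasing within each chromosome and lie in
    (0, chromosome length].
    """

    chromosome: np.ndarray  # (L,) int, chromosome index per locus
    position_cM: np.ndarray  # (L,) float
    n_per_chromosome: tuple[int, ...]

    @property
    def n_loci(self) -> int:
        return int(self.position_cM.size)

    def chrom_slice(self, c: int) -> slice:
        start = int(sum(self.n_per_chromosome[:c]))
        return slice(start, start + self.n_per_chromosome[c])


@dataclass(frozen=True)
class Genome:
    """A genetic map together with the loci placed on it."""

    map: GenomeMap
    loci: LocusSet


def build_genome(
    n_chrom: int,
    lengths_cM: Sequence[float],
    loci_per_chrom: int,
) -> Genome:
    """Build a genome of ``n_chrom`` chromosomes with evenly spaced loci.

    Loci on a chromosome of length ``L`` sit at ``L * k / m`` for
    ``k = 1..m``, i.e. evenly spaced spanning ``(0, L]``.
    """
    if n_chrom < 1:
        raise ConfigurationError("n_chrom must be >= 1")
    lengths = [float(x) for x in lengths_cM]
    if len(lengths) != n_chrom:
        raise ConfigurationError(
            f"expected {n_chrom} chromosome lengths, got {len(lengths)}"
        )
    if any(L <= 0 for L in lengths):
        raise ConfigurationError("chromosome lengths must be positive")
    if loci_per_chrom < 2:
        raise ConfigurationError("loci_per_chrom must be >= 2")

    chrom_idx = np.repeat(np.arange(n_chrom), loci_per_chrom)
    pos = np.concatenate(
        [L * np.arange(1, loci_per_chrom + 1) / loci_per_chrom for L in lengths]
    )
    gmap = GenomeMap(tuple(lengths))
    loci = LocusSet(chrom_idx, pos, tuple([loci_per_chrom] * n_chrom))
    return Genome(gmap, loci)


def default_genome(loci_per_chrom: int = DEFAULT_LOCI_PER_CHROM) -> Genome:
    """The default maize-like genome: 10 chromosomes totalling 1796 cM.

    Only the total map length is pinned down by the source map; the ten
    chromosomes are given equal lengths of 179.6 cM (overridable through
    :func:`build_genome`).
    """
    per_chrom = MAIZE_TOTAL_CM / MAIZE_N_CHROM
    return build_genome(MAIZE_N_CHROM, [per_chrom] * MAIZE_N_CHROM, loci_per_chrom)


def geometric_effects(l: int) -> np.ndarray:
    """Additive-effect magnitudes of ``l`` QTL following a geometric series.

    With ``a = (l - 1) / (l + 1)`` the k-th QTL has effect ``a**k`` for
    ``k = 1..l``; magnitudes are strictly decreasing and lie in (0, 1).
    """
    if l < 2:
        raise ConfigurationError("geometric series needs at least 2 QTL")
    a = (l - 1) / (l + 1)
    return a ** np.arange(1, l + 1, dtype=float)


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL positions/effects and marker positions for one simulated trait.

    ``qtl_effects`` holds positive magnitudes; ``qtl_phase`` is +1 when the
    favorable allele was assigned to parent 2 and -1 when to parent 1.
    """

    qtl_indices: np.ndarray  # (Q,) int, sorted
    qtl_effects: np.ndarray  # (Q,) float, positive magnitudes
    qtl_phase: np.ndarray  # (Q,) int in {-1, +1}
    marker_indices: np.ndarray  # (M,) int, sorted

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_indices.size)

    @property
    def n_markers(self) -> int:
        return int(self.marker_indices.size)

    def signed_effects(self) -> np.ndarray:
        """Substitution effects on the parent-2-dosage scale."""
        return self.qtl_effects * self.qtl_phase


def assign_architecture(
    genome: Genome,
    n_qtl: int = DEFAULT_N_QTL,
    n_markers: int = DEFAULT_N_MARKERS,
    rng: np.random.Generator | None = None,
) -> TraitArchitecture:
    """Designate marker and QTL loci and draw QTL effects.

    Markers are spread evenly: ``n_markers // n_chrom`` per chromosome
    (any remainder is given to the lowest-index chromosomes), placed
    evenly among that chromosome's loci.  QTL are sampled uniformly
    without replacement from the remaining (non-marker) loci, so the two
    sets are disjoint.  Effect magnitudes follow
    :func:`geometric_effects`; each QTL's favorable allele is assigned to
    parent 1 or parent 2 with probability 1/2.
    """
    rng = np.random.default_rng() if rng is None else rng
    loci = genome.loci
    n_chrom = genome.map.n_chromosomes
    if n_qtl + n_markers > loci.n_loci:
        raise ConfigurationError("n_qtl + n_markers exceeds the number of loci")

    base, rem = divmod(n_markers, n_chrom)
    marker_idx: list[np.ndarray] = []
    for c in range(n_chrom):
        m_c = base + (1 if c < rem else 0)
        sl = loci.chrom_slice(c)
        n_c = sl.stop - sl.start
        if m_c > n_c:
            raise ConfigurationError("more markers than loci on a chromosome")
        if m_c > 0:
            local = np.round(np.linspace(0, n_c - 1, m_c)).astype(int)
            marker_idx.append(sl.start + local)
    markers = np.concatenate(marker_idx) if marker_idx else np.empty(0, int)

    candidates = np.setdiff1d(np.arange(loci.n_loci), markers)
    chosen = rng.choice(candidates, size=n_qtl, replace=False)
    magnitudes = geometric_effects(n_qtl)
    order = np.argsort(chosen)
    qtl = chosen[order]
    effects = magnitudes[order]  # effect rank is random w.r.t. position
    phase = rng.integers(0, 2, n_qtl) * 2 - 1
    return TraitArchitecture(qtl, effects, phase.astype(int), markers)


@dataclass
class Population:
    """A set of individuals, each a pair of haplotypes over all loci.

    Alleles are coded by parental origin: 0 = parent-1 allele, 1 =
    parent-2 allele.  DH individuals carry two identical haplotypes.
    """

    haplotypes: np.ndarray  # (n, 2, L) uint8
    generation: str = "C0"

    @property
    def n(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.haplotypes.shape[2])

    def is_homozygous(self) -> bool:
        return bool((self.haplotypes[:, 0, :] == self.haplotypes[:, 1, :]).all())

    def subset(self, indices: np.ndarray, generation: str | None = None) -> "Population":
        return Population(
            self.haplotypes[np.asarray(indices)],
            self.generation if generation is None else generation,
        )


@dataclass(frozen=True)
class GeneticValues:
    """True genetic values of a population and their summary statistics."""

    values: np.ndarray  # (n,) float
    mean: float
    variance: float  # sample variance, denominator n - 1


def f1_individual(genome: Genome, generation: str = "F1") -> Population:
    """The F1 between two fully polymorphic inbred parents."""
    L = genome.loci.n_loci
    hap = np.zeros((1, 2, L), dtype=np.uint8)
    hap[0, 1, :] = 1
    return Population(hap, generation)


def _inheritance_vectors(
    genome: Genome,
    n_gametes: int,
    rng: np.random.Generator,
    counts_out: np.ndarray | None = None,
) -> np.ndarray:
    """Strand-origin vectors (n_gametes, L) in {0, 1} for meiotic gametes.

    Strand origin at a locus is the starting strand XOR the parity of the
    number of crossovers occurring before the locus position.  If
    ``counts_out`` (n_gametes, n_chrom) is given, crossover counts per
    chromosome are written into it.
    """
    loci = genome.loci
    out = np.empty((n_gametes, loci.n_loci), dtype=np.uint8)
    lengths_M = genome.map.lengths_morgans()
    for c in range(genome.map.n_chromosomes):
        sl = loci.chrom_slice(c)
        pos_M = loci.position_cM[sl] / 100.0
        L_M = lengths_M[c]
        k = rng.poisson(L_M, n_gametes) if L_M > 0 else np.zeros(n_gametes, int)
        start = rng.integers(0, 2, n_gametes, dtype=np.uint8)
        if counts_out is not None:
            counts_out[:, c] = k
        if k.max(initial=0) == 0:
            out[:, sl] = start[:, None]
            continue
        for lo in range(0, n_gametes, _GAMETE_CHUNK):
            hi = min(lo + _GAMETE_CHUNK, n_gametes)
            kc = k[lo:hi]
            kmax = int(kc.max(initial=0))
            if kmax == 0:
                out[lo:hi, sl] = start[lo:hi, None]
                continue
            bp = rng.uniform(0.0, L_M, (hi - lo, kmax))
            bp[np.arange(kmax)[None, :] >= kc[:, None]] = np.inf
            parity = (
                (bp[:, None, :] <= pos_M[None, :, None]).sum(axis=2).astype(np.uint8)
                & 1
            )
            out[lo:hi, sl] = start[lo:hi, None] ^ parity
    return out


def _gametes(
    population: Population,
    parent_idx: np.ndarray,
    genome: Genome,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic gamete (row) per entry of ``parent_idx``."""
    strands = _inheritance_vectors(genome, parent_idx.size, rng)
    h = population.haplotypes[parent_idx]  # (G, 2, L)
    return np.where(strands == 0, h[:, 0, :], h[:, 1, :])


def meiosis(
    individual: Population,
    genome: Genome,
    rng: np.random.Generator,
    index: int = 0,
) -> np.ndarray:
    """A single meiotic gamete from one individual of ``individual``."""
    return _gametes(individual, np.asarray([index]), genome, rng)[0]


def crossover_counts(
    genome: Genome, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Crossover counts per gamete and chromosome, shape (n, n_chrom).

    Diagnostic companion to :func:`meiosis`: counts are Poisson with mean
    equal to each chromosome's length in Morgans.
    """
    counts = np.zeros((n_gametes, genome.map.n_chromosomes), dtype=int)
    _inheritance_vectors(genome, n_gametes, rng, counts_out=counts)
    return counts


def make_dh_population(
    f1: Population,
    n_lines: int,
    genome: Genome,
    rng: np.random.Generator,
    generation: str = "C0",
) -> Population:
    """``n_lines`` doubled-haploid lines, each one gamete of the F1 doubled."""
    if n_lines < 1:
        raise InvalidInputError("n_lines must be >= 1")
    gam = _gametes(f1, np.zeros(n_lines, dtype=int), genome, rng)
    hap = np.stack([gam, gam], axis=1)
    return Population(hap, generation)


def random_mate(
    population: Population,
    n_progeny: int,
    genome: Genome,
    rng: np.random.Generator,
    with_replacement: bool = True,
    generation: str = "progeny",
) -> Population:
    """Random mating: each progeny from two distinct parents (no selfing).

    With ``with_replacement`` (the default) parents are drawn uniformly
    and may be reused across progenies.  Without replacement, parents are
    paired by a uniform random perfect matching and each is used exactly
    once (``n_progeny <= n // 2``).
    """
    n = population.n
    if n < 2:
        raise InvalidInputError("random mating needs at least 2 individuals")
    if with_replacement:
        p1 = rng.integers(0, n, n_progeny)
        p2 = (p1 + rng.integers(1, n, n_progeny)) % n
    else:
        if n_progeny > n // 2:
            raise InvalidInputError(
                "without replacement n_progeny must be <= half the population"
            )
        perm = rng.permutation(n)[: 2 * n_progeny]
        p1, p2 = perm[0::2], perm[1::2]
    gam_a = _gametes(population, p1, genome, rng)
    gam_b = _gametes(population, p2, genome, rng)
    return Population(np.stack([gam_a, gam_b], axis=1), generation)


def genetic_values(
    population: Population, architecture: TraitArchitecture
) -> GeneticValues:
    """True genetic values: sum over QTL of dosage code times effect.

    The dosage code at a QTL is -1/0/+1 for parent-1 homozygote /
    heterozygote / parent-2 homozygote; the favorable-allele phase folds
    into the signed effect.
    """
    h = population.haplotypes[:, :, architecture.qtl_indices]
    dosage = h.sum(axis=1).astype(np.float64) - 1.0  # in {-1, 0, 1}
    values = dosage @ architecture.signed_effects()
    mean = float(values.mean()) if values.size else 0.0
    var = float(values.var(ddof=1)) if values.size > 1 else 0.0
    return GeneticValues(values, mean, var)


def marker_matrix(
    population: Population, architecture: TraitArchitecture
) -> np.ndarray:
    """Marker genotype codes, rows = individuals, entries in {-1, 0, +1}."""
    h = population.haplotypes[:, :, architecture.marker_indices]
    return (h.sum(axis=1).astype(np.int8) - 1).astype(np.int8)
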