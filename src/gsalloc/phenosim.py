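"""Plot phenotypes, entry means, and budget-constrained allocation.

Phenotypes are simulated on a plot basis: a single plot value is the true
genetic value plus a normal environmental deviation whose variance is set
so that single-plot heritability equals the target ``h2plot``,

    sigma_e^2 = sigma_a^2 / h2plot - sigma_a^2.

The entry mean of a line is the average of its ``r`` plot values, so the
entry-mean error variance is ``sigma_e^2 / r``.

Resources are expressed in field-plot equivalents.  A budget ``B`` buys
``n`` genotyped lines of which a fraction ``F`` is phenotyped with ``r``
replications, under the constraint ``B = n (C + r F)`` with ``C`` the
genotyping cost per line.  Line counts are rounded half-to-even.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .genome import GeneticValues

__all__ = [
    "PhenotypeConfig",
    "PhenotypeSet",
    "AllocationStrategy",
    "error_variance",
    "simulate_entry_means",
    "allocate",
    "realized_sigma_a2",
]


def error_variance(sigma_a2: float, h2plot: float) -> float:
    """Plot error variance achieving heritability ``h2plot`` on a plot basis."""
    if not 0 < h2plot <= 1:
        raise ConfigurationError("h2plot must be in (0, 1]")
    if sigma_a2 <= 0:
        raise ConfigurationError("sigma_a2 must be positive")
    return sigma_a2 * (1.0 / h2plot - 1.0)


@dataclass(frozen=True)
class PhenotypeConfig:
    """Phenotyping design: plot heritability, replications, variances."""

    h2plot: float
    r: int
    sigma_a2: float

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ConfigurationError("r must be >= 1")
        # validates h2plot / sigma_a2 as a side effect
        object.__setattr__(self, "_sigma_e2", error_variance(self.sigma_a2, self.h2plot))

    @property
    def sigma_e2(self) -> float:
        return self._sigma_e2


@dataclass(frozen=True)
class PhenotypeSet:
    """Entry means (averages of ``r`` plots) for phenotyped lines."""

    entry_means: np.ndarray  # (n_ph,) float
    r: int
    sigma_e2: float


def simulate_entry_means(
    values: GeneticValues | np.ndarray,
    r: int,
    sigma_e2: float,
    rng: np.random.Generator,
) -> PhenotypeSet:
    """Entry means: genetic value plus the mean of ``r`` plot deviations."""
    if r < 1:
        raise ConfigurationError("r must be >= 1")
    if sigma_e2 < 0:
        raise ConfigurationError("sigma_e2 must be >= 0")
    a = values.values if isinstance(values, GeneticValues) else np.asarray(values, float)
    noise = rng.normal(0.0, np.sqrt(sigma_e2), size=(a.size, r)).mean(axis=1)
    return PhenotypeSet(a + noise, r, sigma_e2)


@dataclass(frozen=True)
class AllocationStrategy:
    """One (B, C, F, r) budget cell resolved to line counts (n, n_ph)."""

    B: float
    C: float
    F: float
    r: int
    n: int
    n_ph: int


def _round_half_even(x: float) -> int:
    return int(round(x))


def allocate(B: float, C: float, F: float, r: int) -> AllocationStrategy:
    """Resolve a budget into genotyped and phenotyped line counts.

    ``n = round(B / (C + r F))`` and ``n_ph = round(F n)``, both rounded
    half-to-even; the realized cost may exceed ``B`` by less than one
    plot equivalent.
    """
    if B <= 0:
        raise ConfigurationError("B must be positive")
    if C < 0:
        raise ConfigurationError("C must be >= 0")
    if not 0 < F <= 1:
        raise ConfigurationError("F must be in (0, 1]")
    if r < 1:
        raise ConfigurationError("r must be >= 1")
    denom = C + r * F
    if denom <= 0:
        raise ConfigurationError("C + r*F must be positive")
    n = _round_half_even(B / denom)
    n_ph = _round_half_even(F * n)
    return AllocationStrategy(B, C, F, r, n, n_ph)


def realized_sigma_a2(values: GeneticValues | np.ndarray) -> float:
    """Sample variance (denominator n-1) of true genetic values.

    Used to calibrate plot noise so the intended plot heritability holds
    for the population actually simulated, independent of the
    linkage-induced covariance among QTL in any particular draw.
    """
    a = values.values if isinstance(values, GeneticValues) else np.asarray(values, float)
    if a.size < 2:
        raise InvalidInputError("need at least 2 individuals")
    return float(np.var(a, ddof=1))
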