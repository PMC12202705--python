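"""Detection power for clonal somatic mutations in impure tumor samples.

A clonal heterozygous mutation in a sample whose DNA is a fraction ``phi``
tumor-derived is expected on a fraction ``f = phi / 2`` of reads. With fixed
coverage ``C``, the number of variant-supporting reads is
``X ~ Binomial(C, f)`` and the probability of *missing* the mutation — seeing
fewer than ``m`` supporting reads — is the binomial lower tail
``P(X < m)``; for the canonical ``m = 1`` this is ``(1 - f)^C``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .errors import ParameterError

__all__ = [
    "PowerQuery",
    "PowerResult",
    "allele_fraction",
    "p_miss",
    "round_sig",
]

#: Zygosity factors: fraction of tumor-cell alleles carrying the variant.
ZYGOSITY = {"het": 0.5, "hom": 1.0}


def allele_fraction(phi: float, zygosity_factor: float = 0.5) -> float:
    """Expected variant allele fraction ``f = phi * zygosity_factor``.

    Parameters
    ----------
    phi
        Tumor-derived DNA fraction, in (0, 1].
    zygosity_factor
        Fraction of tumor alleles carrying the variant; 0.5 for a
        heterozygous clonal mutation (the default), 1.0 for homozygous.
    """
    if not 0.0 < phi <= 1.0:
        raise ParameterError(f"tumor fraction phi must be in (0, 1], got {phi}")
    if not 0.0 < zygosity_factor <= 1.0:
        raise ParameterError(
            f"zygosity_factor must be in (0, 1], got {zygosity_factor}"
        )
    return phi * zygosity_factor


@dataclass(frozen=True)
class PowerQuery:
    """Inputs for a miss-probability calculation.

    coverage: reads observed at the site (treated as fixed, not Poisson).
    tumor_fraction: tumor-derived DNA fraction phi in (0, 1].
    zygosity_factor: allele dosage in tumor cells (default heterozygous).
    min_supporting_reads: reads required to call the site detected; the
        single-read criterion is the canonical model, larger values are an
        extension for callers that demand multiple supporting reads.
    """

    coverage: int
    tumor_fraction: float
    zygosity_factor: float = 0.5
    min_supporting_reads: int = 1

    def __post_init__(self) -> None:
        if self.coverage < 0 or self.coverage != int(self.coverage):
            raise ParameterError(f"coverage must be a non-negative integer, got {self.coverage}")
        allele_fraction(self.tumor_fraction, self.zygosity_factor)  # validates both
        if self.min_supporting_reads < 1:
            raise ParameterError("min_supporting_reads must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    """Allele fraction and the miss/detect probabilities for one query."""

    allele_fraction: float
    p_miss: float
    p_detect: float

    @property
    def p_miss_percent(self) -> float:
        """Miss probability expressed as a percentage."""
        return 100.0 * self.p_miss


def p_miss(query: PowerQuery) -> PowerResult:
    """Probability of observing fewer than ``m`` variant-supporting reads.

    ``p_miss = P(X < m)`` with ``X ~ Binomial(C, f)`` and
    ``f = phi * zygosity_factor``. For ``m = 1`` this reduces to the closed
    form ``(1 - f)^C``.
    """
    f = allele_fraction(query.tumor_fraction, query.zygosity_factor)
    c, m = query.coverage, query.min_supporting_reads
    if m > c:
        warnings.warn(
            f"min_supporting_reads={m} exceeds coverage={c}; the mutation "
            "can never be detected (p_miss = 1)",
            stacklevel=2,
        )
        miss = 1.0
    elif m == 1:
        miss = (1.0 - f) ** c
    else:
        miss = float(stats.binom.cdf(m - 1, c, f))
    miss = min(max(miss, 0.0), 1.0)
    return PowerResult(allele_fraction=f, p_miss=miss, p_detect=1.0 - miss)


def round_sig(x: float, digits: int = 2) -> float:
    """Round ``x`` to ``digits`` significant figures (0 stays 0)."""
    if x == 0.0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (digits - 1))
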