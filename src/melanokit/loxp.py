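"""Classify loxP junction reads and estimate the recombined-cell fraction.

The engineered allele carries two loxP sites before Cre recombination, each
in a unique genomic context; recombination excises the intervening DNA and
leaves a single site fusing the outer flanks. Reads spanning the 34-bp loxP
core therefore fall into three junction classes:

- unrecombined 5' site: upstream flank A, downstream flank B (U5)
- unrecombined 3' site: upstream flank C, downstream flank D (U3)
- recombined site: upstream flank A, downstream flank D (R)

An unrecombined cell contributes both a U5 and a U3 junction while a
recombined cell contributes a single R junction, so the recombined-cell
fraction is estimated as ``rho = R / (R + (U5 + U3) / 2)`` — equivalently R
divided by R plus the average of the two unrecombined classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ParameterError
from .io import iter_reads

logger = logging.getLogger(__name__)

__all__ = [
    "LOXP_CORE",
    "LoxPConfig",
    "LoxPClassCounts",
    "PurityEstimate",
    "classify_reads",
    "estimate_purity",
]

#: Canonical 34-bp loxP recognition sequence (13-bp palindromic arms
#: flanking an 8-bp asymmetric spacer).
LOXP_CORE = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LoxPConfig:
    """Allele geometry and matching parameters for junction classification.

    The four flank sequences are the genomic contexts unique to the two
    unrecombined sites; they must be supplied per allele (``synthetic_data``
    produces matched configs for generated libraries). ``min_flank_bases``
    is the number of context bases required on each side of the core for an
    unambiguous call; ``max_flank_mismatches`` relaxes flank matching (the
    core itself is always matched exactly).
    """

    flank_5prime_up: str
    flank_5prime_down: str
    flank_3prime_up: str
    flank_3prime_down: str
    core: str = LOXP_CORE
    min_flank_bases: int = 3
    scan_both_strands: bool = True
    max_flank_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.core) != 34:
            raise ParameterError(f"loxP core must be 34 bases, got {len(self.core)}")
        k = self.min_flank_bases
        if k < 1:
            raise ParameterError("min_flank_bases must be >= 1")
        contexts = {
            "5'-upstream": self.flank_5prime_up[-k:],
            "5'-downstream": self.flank_5prime_down[:k],
            "3'-upstream": self.flank_3prime_up[-k:],
            "3'-downstream": self.flank_3prime_down[:k],
        }
        for name, ctx in contexts.items():
            if len(ctx) < k:
                raise ParameterError(f"{name} flank shorter than min_flank_bases={k}")
        vals = list(contexts.values())
        if len(set(vals)) != len(vals):
            raise ParameterError(
                f"flank contexts are not pairwise distinct within {k} bases of the core"
            )

    # Context fragments compared against read bases adjacent to the core.
    @property
    def up_a(self) -> str:
        return self.flank_5prime_up[-self.min_flank_bases :]

    @property
    def up_c(self) -> str:
        return self.flank_3prime_up[-self.min_flank_bases :]

    @property
    def down_b(self) -> str:
        return self.flank_5prime_down[: self.min_flank_bases]

    @property
    def down_d(self) -> str:
        return self.flank_3prime_down[: self.min_flank_bases]


@dataclass
class LoxPClassCounts:
    """Junction class counts; ``total_core_hits`` counts per-read class
    assignments, so the four classes always sum to it."""

    u5: int = 0
    u3: int = 0
    rec: int = 0
    ambiguous: int = 0

    @property
    def total_core_hits(self) -> int:
        return self.u5 + self.u3 + self.rec + self.ambiguous

    @property
    def n_informative(self) -> int:
        return self.u5 + self.u3 + self.rec

    def as_dict(self) -> dict[str, int]:
        return {
            "u5": self.u5,
            "u3": self.u3,
            "rec": self.rec,
            "ambiguous": self.ambiguous,
            "total_core_hits": self.total_core_hits,
        }


def _matches(observed: str, expected: str, max_mm: int) -> bool:
    if len(observed) != len(expected):
        return False
    mm = sum(a != b for a, b in zip(observed.upper(), expected.upper()))
    return mm <= max_mm


def _classify_hit(seq: str, pos: int, config: LoxPConfig) -> str:
    """Classify one core occurrence by its flanking context."""
    k = config.min_flank_bases
    up = seq[max(pos - k, 0) : pos]
    down = seq[pos + len(config.core) : pos + len(config.core) + k]
    if len(up) < k or len(down) < k:
        return "ambiguous"
    mm = config.max_flank_mismatches
    up_is_a = _matches(up, config.up_a, mm)
    up_is_c = _matches(up, config.up_c, mm)
    down_is_b = _matches(down, config.down_b, mm)
    down_is_d = _matches(down, config.down_d, mm)
    if up_is_a and not up_is_c and down_is_b and not down_is_d:
        return "u5"
    if up_is_c and not up_is_a and down_is_d and not down_is_b:
        return "u3"
    if up_is_a and not up_is_c and down_is_d and not down_is_b:
        return "rec"
    return "ambiguous"


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx == -1:
            return
        yield idx
        start = idx + 1


def classify_read(seq: str, config: LoxPConfig) -> set[str]:
    """Junction classes supported by one read (both strands if configured)."""
    classes: set[str] = set()
    strands = [seq.upper()]
    if config.scan_both_strands:
        strands.append(reverse_complement(seq.upper()))
    core = config.core.upper()
    for s in strands:
        for pos in _find_all(s, core):
            classes.add(_classify_hit(s, pos, config))
    return classes


def classify_reads(
    reads: str | Path | Iterable[tuple[str, str]], config: LoxPConfig
) -> LoxPClassCounts:
    """Scan a FASTA/FASTQ file or ``(id, sequence)`` stream for loxP junctions.

    The 34-bp core is matched exactly on both strands; each occurrence is
    classified by comparing ``min_flank_bases`` of context on each side to
    the configured flanks. A read contributes at most one count per class,
    so an amplicon containing the same junction twice is not double counted.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_reads(reads)
    counts = LoxPClassCounts()
    for read_id, seq in reads:
        try:
            classes = classify_read(seq, config)
        except Exception as exc:  # malformed record: skip, keep scanning
            logger.warning("skipping unreadable record %s: %s", read_id, exc)
            continue
        for cls in classes:
            setattr(counts, cls, getattr(counts, cls) + 1)
    return counts


@dataclass(frozen=True)
class PurityEstimate:
    """Recombined-cell fraction rho (interpreted as tumor-derived DNA
    fraction) with a percentile-bootstrap confidence interval."""

    rho: float
    ci_low: float
    ci_high: float
    n_informative: int
    counts: LoxPClassCounts = field(repr=False, default=None)


def purity_point_estimate(counts: LoxPClassCounts) -> float:
    """``rho = R / (R + (U5 + U3) / 2)`` — the 2:1 site-count correction."""
    denom = counts.rec + (counts.u5 + counts.u3) / 2.0
    return counts.rec / denom


def estimate_purity(
    counts: LoxPClassCounts,
    bootstrap_reps: int = 2000,
    conf_level: float = 0.95,
    seed: int | None = 0,
) -> PurityEstimate:
    """Estimate the recombined-cell fraction with a multinomial bootstrap CI.

    The informative reads (R, U5, U3) are resampled ``bootstrap_reps`` times
    from their observed multinomial proportions and the purity formula is
    re-applied; the CI is the percentile interval. Ambiguous reads carry no
    junction information and are excluded.
    """
    n = counts.n_informative
    if n < 1:
        raise ParameterError(
            "purity is undefined with zero informative (R + U5 + U3) reads"
        )
    rho = purity_point_estimate(counts)
    if bootstrap_reps < 1:
        return PurityEstimate(rho, rho, rho, n, counts)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, np.array([counts.rec, counts.u5, counts.u3]) / n, size=bootstrap_reps)
    denom = draws[:, 0] + (draws[:, 1] + draws[:, 2]) / 2.0
    boot = np.divide(draws[:, 0], denom, out=np.zeros(bootstrap_reps), where=denom > 0)
    alpha = 1.0 - conf_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return PurityEstimate(rho, float(lo), float(hi), n, counts)
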