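"""Seeded synthetic-data generators with ground-truth bookkeeping.

Each generator emulates the statistical structure one pipeline stage assumes,
and returns a truth record sufficient to recompute every downstream estimate,
so the generated dataset is its own oracle:

- :func:`simulate_incidence_cohort` — exponential (single-hit) waiting times
  with a detection lag and administrative right-censoring.
- :func:`simulate_loxp_library` — reads from an engineered locus carrying
  unrecombined and recombined loxP junctions at a known cell-fraction mix,
  honoring the 2:1 loxP site-count asymmetry between unrecombined and
  recombined cells.
- :func:`simulate_count_matrix` — negative-binomial UMI counts with variance
  ``mu + c^2 mu^2`` for biological coefficient of variation ``c``, with
  planted cell-type signatures of stated log2 fold change.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
dataset; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import io
from .errors import ParameterError
from .loxp import LOXP_CORE, LoxPConfig, reverse_complement

__all__ = [
    "CohortSpec",
    "LoxPLibrarySpec",
    "PlantedSignature",
    "CountsSpec",
    "simulate_incidence_cohort",
    "simulate_loxp_library",
    "simulate_count_matrix",
    "make_loxp_config",
    "write_cohort_dataset",
    "write_loxp_dataset",
    "write_counts_dataset",
]

LN2 = math.log(2.0)
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _truth_json(truth) -> str:
    """Serialize a truth dataclass to JSON (numpy arrays become lists)."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"cannot serialize {type(obj)}")

    return json.dumps(dataclasses.asdict(truth), default=default, indent=1)


# --------------------------------------------------------------------------
# Tumor-free survival cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Single-hit incidence cohort: tumors initiate at constant rate
    ``lambda = ln2 / half_time_weeks`` after a detection lag, and follow-up
    ends (administrative censoring) at ``followup_weeks``."""

    n_subjects: int
    half_time_weeks: float
    lag_weeks: float = 0.0
    followup_weeks: float = 60.0
    group: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be positive")
        if self.half_time_weeks <= 0:
            raise ParameterError("half_time_weeks must be positive")
        if self.lag_weeks < 0:
            raise ParameterError("lag_weeks must be non-negative")
        if self.followup_weeks < self.lag_weeks:
            raise ParameterError("followup_weeks must be >= lag_weeks")


@dataclass
class CohortTruth:
    """Latent (uncensored) event times and the generating parameters."""

    spec: CohortSpec
    latent_times: np.ndarray = field(repr=False)
    rate_per_week: float = 0.0


def simulate_incidence_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw tumor-free survival times ``lag + Exponential(ln2 / t_half)``.

    Events are observed if the latent time falls within follow-up, otherwise
    the subject is censored at ``followup_weeks``. Returns the survival table
    (``subject_id, group, time_weeks, event``) and the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    rate = LN2 / spec.half_time_weeks
    latent = spec.lag_weeks + rng.exponential(scale=1.0 / rate, size=spec.n_subjects)
    event = latent <= spec.followup_weeks
    observed = np.where(event, latent, spec.followup_weeks)
    table = pd.DataFrame(
        {
            "subject_id": [f"m{i:04d}" for i in range(spec.n_subjects)],
            "group": spec.group,
            "time_weeks": observed,
            "event": event.astype(int),
        }
    )
    return table, CohortTruth(spec=spec, latent_times=latent, rate_per_week=rate)


# --------------------------------------------------------------------------
# loxP junction read libraries


@dataclass(frozen=True)
class LoxPLibrarySpec:
    """Read library from a cell mix with true recombined fraction ``rho_true``.

    Each unrecombined cell contributes two junction templates (the 5' and 3'
    loxP sites in their distinct contexts); each recombined cell contributes
    one (the fused junction). Reads are centered on the 34-bp core, emitted
    on a random strand, with independent per-base substitution errors.
    """

    rho_true: float
    n_cells_sampled: int
    read_length: int = 60
    per_base_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_true <= 1.0:
            raise ParameterError("rho_true must be in [0, 1]")
        if self.n_cells_sampled < 1:
            raise ParameterError("n_cells_sampled must be positive")
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ParameterError("per_base_error must be in [0, 1]")


@dataclass
class LoxPTruth:
    """Per-read junction classes before sequencing error, plus the cell mix."""

    spec: LoxPLibrarySpec
    n_recombined_cells: int
    n_unrecombined_cells: int
    read_classes: list[str] = field(repr=False, default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            cls: sum(1 for c in self.read_classes if c == cls)
            for cls in ("u5", "u3", "rec")
        }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_loxp_config(
    seed: int = 0, flank_length: int = 20, min_flank_bases: int = 3
) -> LoxPConfig:
    """Generate an allele config with random, mutually distinct 20-mer flanks.

    The study allele's genomic context is locus-specific; for synthetic
    libraries random distinct flanks are drawn until the classifier's
    distinctness requirement at ``min_flank_bases`` is met.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        try:
            return LoxPConfig(
                flank_5prime_up=_random_seq(rng, flank_length),
                flank_5prime_down=_random_seq(rng, flank_length),
                flank_3prime_up=_random_seq(rng, flank_length),
                flank_3prime_down=_random_seq(rng, flank_length),
                min_flank_bases=min_flank_bases,
            )
        except ParameterError:
            continue
    raise ParameterError("could not draw distinct flank sequences")  # pragma: no cover


def _junction_template(config: LoxPConfig, cls: str) -> str:
    up = {"u5": config.flank_5prime_up, "u3": config.flank_3prime_up, "rec": config.flank_5prime_up}
    down = {"u5": config.flank_5prime_down, "u3": config.flank_3prime_down, "rec": config.flank_3prime_down}
    return up[cls] + config.core + down[cls]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with a uniformly random *different* base
        idx = np.where(hit)[0]
        for i in idx:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_loxp_library(
    spec: LoxPLibrarySpec, config: LoxPConfig | None = None
) -> tuple[list[tuple[str, str]], LoxPTruth, LoxPConfig]:
    """Emit junction-spanning reads for a known recombined-cell fraction.

    The number of recombined cells is Binomial(n_cells_sampled, rho_true);
    each unrecombined cell yields one U5 and one U3 read, each recombined
    cell one R read. Returns ``(reads, truth, config)`` where reads are
    ``(read_id, sequence)`` pairs and truth holds the pre-error class of
    every read.
    """
    if config is None:
        config = make_loxp_config(seed=spec.seed)
    min_len = len(config.core) + 2 * config.min_flank_bases
    if spec.read_length < min_len:
        raise ParameterError(
            f"read_length {spec.read_length} cannot span core + 2 x "
            f"{config.min_flank_bases} flank bases (need >= {min_len})"
        )
    flank_avail = min(
        len(config.flank_5prime_up),
        len(config.flank_5prime_down),
        len(config.flank_3prime_up),
        len(config.flank_3prime_down),
    )
    left = (spec.read_length - len(config.core)) // 2
    right = spec.read_length - len(config.core) - left
    if max(left, right) > flank_avail:
        raise ParameterError(
            f"read_length {spec.read_length} needs {max(left, right)} flank bases "
            f"but config flanks provide only {flank_avail}"
        )

    rng = np.random.default_rng(spec.seed)
    n_rec = int(rng.binomial(spec.n_cells_sampled, spec.rho_true))
    n_unrec = spec.n_cells_sampled - n_rec
    classes = ["u5"] * n_unrec + ["u3"] * n_unrec + ["rec"] * n_rec
    order = rng.permutation(len(classes))

    reads: list[tuple[str, str]] = []
    truth_classes: list[str] = []
    core_start = flank_avail  # template = up_flank + core + down_flank
    for i, j in enumerate(order):
        cls = classes[j]
        template = _junction_template(config, cls)
        start = core_start - left
        seq = template[start : start + spec.read_length]
        seq = _mutate(seq, spec.per_base_error, rng)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((f"read{i:06d}_{cls}", seq))
        truth_classes.append(cls)
    truth = LoxPTruth(
        spec=spec,
        n_recombined_cells=n_rec,
        n_unrecombined_cells=n_unrec,
        read_classes=truth_classes,
    )
    return reads, truth, config


# --------------------------------------------------------------------------
# Negative-binomial UMI count matrices


@dataclass(frozen=True)
class PlantedSignature:
    """A gene set over-expressed (log2 fold change) in one cell type."""

    cell_type: str
    genes: tuple[str, ...]
    log2_fold_change: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass(frozen=True)
class CountsSpec:
    """Negative-binomial UMI counts with variance ``mu + c^2 mu^2``.

    ``baseline_gene_means`` are relative expression levels (drawn lognormal
    sigma=1 when omitted); per-type profiles apply planted fold changes and
    are renormalized so every cell's expected depth is ``depth_per_cell``
    (the compositional effect of a sequencing experiment). ``biological_cv``
    is the extra-Poisson noise scale c, mapping to NB overdispersion
    ``theta = 1 / c^2``.
    """

    n_genes: int
    n_cells: int
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {"background": 0.8, "planted": 0.2}
    )
    baseline_gene_means: tuple[float, ...] | None = None
    planted_signatures: tuple[PlantedSignature, ...] = ()
    biological_cv: float = 0.55
    depth_per_cell: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_cells < 2:
            raise ParameterError("need at least 2 genes and 2 cells")
        if self.biological_cv <= 0:
            raise ParameterError("biological_cv must be positive")
        if self.depth_per_cell <= 0:
            raise ParameterError("depth_per_cell must be positive")
        props = np.array(list(self.type_proportions.values()), dtype=float)
        if (props < 0).any() or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
            raise ParameterError("type_proportions must be a simplex (sum to 1)")
        object.__setattr__(self, "planted_signatures", tuple(self.planted_signatures))
        if self.baseline_gene_means is not None:
            means = tuple(float(m) for m in self.baseline_gene_means)
            if len(means) != self.n_genes or any(m <= 0 for m in means):
                raise ParameterError(
                    "baseline_gene_means must be n_genes positive values"
                )
            object.__setattr__(self, "baseline_gene_means", means)

    @property
    def gene_names(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_genes)]

    @property
    def cell_names(self) -> list[str]:
        return [f"cell{i:05d}" for i in range(self.n_cells)]


@dataclass
class CountsTruth:
    """Per-cell type labels and the per-type expected mean of every gene."""

    spec: CountsSpec
    cell_types: list[str] = field(repr=False, default_factory=list)
    type_means: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    theta: float = 0.0


def simulate_count_matrix(
    spec: CountsSpec,
) -> tuple[sparse.csr_matrix, CountsTruth]:
    """Sample a genes x cells NB count matrix with planted signatures.

    For a cell of type t, gene g has mean ``mu_gt = depth * p_gt`` where the
    expression profile ``p_t`` is the (fold-change-adjusted, renormalized)
    baseline, and counts are NB with variance ``mu + mu^2 / theta``,
    ``theta = 1 / c^2``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names
    gene_index = {g: i for i, g in enumerate(genes)}

    if spec.baseline_gene_means is None:
        baseline = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    else:
        baseline = np.array(spec.baseline_gene_means, dtype=float)

    for sig in spec.planted_signatures:
        unknown_type = sig.cell_type not in spec.type_proportions
        unknown_genes = [g for g in sig.genes if g not in gene_index]
        if unknown_type or unknown_genes:
            raise ParameterError(
                f"planted signature references unknown cell type or genes: "
                f"{sig.cell_type if unknown_type else unknown_genes}"
            )

    type_names = list(spec.type_proportions)
    type_means: dict[str, np.ndarray] = {}
    for t in type_names:
        rel = baseline.copy()
        for sig in spec.planted_signatures:
            if sig.cell_type == t:
                idx = [gene_index[g] for g in sig.genes]
                rel[idx] *= 2.0 ** sig.log2_fold_change
        type_means[t] = spec.depth_per_cell * rel / rel.sum()

    props = np.array([spec.type_proportions[t] for t in type_names])
    labels = rng.choice(len(type_names), size=spec.n_cells, p=props)
    cell_types = [type_names[i] for i in labels]

    theta = 1.0 / spec.biological_cv**2
    mu = np.column_stack([type_means[t] for t in cell_types])
    counts = rng.negative_binomial(n=theta, p=theta / (theta + mu))
    x = sparse.csr_matrix(counts)
    truth = CountsTruth(spec=spec, cell_types=cell_types, type_means=type_means, theta=theta)
    return x, truth


# --------------------------------------------------------------------------
# Dataset writers (plain-text artifacts + JSON truth sidecars)


def write_cohort_dataset(spec: CohortSpec, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_incidence_cohort(spec)
    io.write_survival_csv(table, out_dir / "cohort.csv")
    (out_dir / "truth.json").write_text(_truth_json(truth))
    return out_dir


def write_loxp_dataset(
    spec: LoxPLibrarySpec, out_dir: str | Path, config: LoxPConfig | None = None
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads, truth, config = simulate_loxp_library(spec, config)
    io.write_fastq(reads, out_dir / "reads.fastq")
    (out_dir / "truth.json").write_text(_truth_json(truth))
    (out_dir / "allele.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))
    return out_dir


def write_counts_dataset(spec: CountsSpec, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x, truth = simulate_count_matrix(spec)
    io.write_mtx_bundle(x, spec.gene_names, spec.cell_names, out_dir)
    pd.DataFrame({"barcode": spec.cell_names, "cell_type": truth.cell_types}).to_csv(
        out_dir / "labels.tsv", sep="\t", index=False
    )
    if spec.planted_signatures:
        io.write_gmt(
            {s.cell_type + "_signature": list(s.genes) for s in spec.planted_signatures},
            out_dir / "signatures.gmt",
        )
    (out_dir / "truth.json").write_text(_truth_json(truth))
    return out_dir
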