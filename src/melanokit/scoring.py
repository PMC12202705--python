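"""Gene-signature membership scores from CV-parameterized Pearson residuals.

Pipeline: raw UMI counts are converted to analytic Pearson residuals under a
negative-binomial null whose overdispersion is set by a biological
coefficient of variation c (``theta = 1 / c^2``, so the NB variance
``mu + mu^2 / theta`` equals ``mu + c^2 mu^2``); residuals are clipped to
``+/- sqrt(n_cells)``, z-standardized per gene across cells, and a cell's
membership score for a gene signature is the unweighted mean of its z-scores
over the signature genes present in the matrix. Separately,
:func:`cluster_centroid_distances` computes pairwise Euclidean distances
between cluster centroids in a low-dimensional embedding (e.g. the top 10
PCs, or the top 30 integrated dimensions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import squareform, pdist

from .errors import ParameterError
from . import io

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NoiseModel",
    "ResidualMatrix",
    "pearson_residuals",
    "standardize_residuals",
    "membership_score",
    "score_signatures",
    "cluster_centroid_distances",
    "estimate_cv",
]


@dataclass
class CountMatrix:
    """A genes x cells UMI count matrix with identifiers.

    ``x`` may be dense or sparse; absent sparse entries mean zero counts.
    """

    genes: list[str]
    cells: list[str]
    x: sparse.spmatrix | np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = self.x.shape
        if shape != (len(self.genes), len(self.cells)):
            raise ParameterError(
                f"matrix shape {shape} does not match {len(self.genes)} genes x "
                f"{len(self.cells)} cells"
            )
        if self.dense().min() < 0:
            raise ParameterError("counts must be non-negative")

    def dense(self) -> np.ndarray:
        return self.x.toarray() if sparse.issparse(self.x) else np.asarray(self.x)

    @classmethod
    def from_mtx(cls, mtx: str | Path, features: str | Path, barcodes: str | Path) -> "CountMatrix":
        x, genes, cells = io.read_mtx_bundle(mtx, features, barcodes)
        return cls(genes=genes, cells=cells, x=x)


@dataclass(frozen=True)
class NoiseModel:
    """Biological-noise model: CV ``c`` maps to NB overdispersion
    ``theta = 1 / c^2``; residuals are clipped at ``clip_bound``
    (default ``sqrt(n_cells)``, set at fit time when None)."""

    cv: float
    clip_bound: float | None = None

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ParameterError("biological CV must be positive")
        if self.clip_bound is not None and self.clip_bound <= 0:
            raise ParameterError("clip_bound must be positive")

    @property
    def theta(self) -> float:
        return 1.0 / self.cv**2


@dataclass
class ResidualMatrix:
    """Clipped analytic Pearson residuals with the expected-mean matrix."""

    genes: list[str]
    cells: list[str]
    residuals: np.ndarray = field(repr=False)
    expected: np.ndarray = field(repr=False)
    model: NoiseModel = NoiseModel(cv=0.55)
    clip_bound: float = 0.0


def pearson_residuals(counts: CountMatrix, model: NoiseModel) -> ResidualMatrix:
    """Analytic Pearson residuals under the NB null with CV-set dispersion.

    The expected count is the product of marginals,
    ``mu_gc = (gene total * cell total) / grand total``, and the residual is
    ``(x - mu) / sqrt(mu + mu^2 / theta)`` clipped to ``+/- clip_bound``
    (default ``sqrt(n_cells)``). Genes with zero total counts are removed
    with a warning.
    """
    x = counts.dense().astype(float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ParameterError("need at least 2 genes and 2 cells")
    gene_tot = x.sum(axis=1)
    cell_tot = x.sum(axis=0)
    grand = x.sum()
    if grand <= 0:
        raise ParameterError("all-zero count matrix")
    keep = gene_tot > 0
    if not keep.all():
        dropped = [g for g, k in zip(counts.genes, keep) if not k]
        logger.warning("removing %d gene(s) with zero total counts", len(dropped))
        x = x[keep]
        gene_tot = gene_tot[keep]
    genes = [g for g, k in zip(counts.genes, keep) if k]

    mu = np.outer(gene_tot, cell_tot) / grand
    var = mu + mu**2 / model.theta
    resid = (x - mu) / np.sqrt(var)
    clip = model.clip_bound if model.clip_bound is not None else math.sqrt(x.shape[1])
    resid = np.clip(resid, -clip, clip)
    return ResidualMatrix(
        genes=genes,
        cells=list(counts.cells),
        residuals=resid,
        expected=mu,
        model=model,
        clip_bound=clip,
    )


def standardize_residuals(residuals: ResidualMatrix) -> pd.DataFrame:
    """Z-score each gene's residuals across cells (sample SD, ddof=1).

    Zero-variance genes are dropped with a warning. Returns a genes x cells
    DataFrame whose rows have mean 0 and SD 1.
    """
    r = residuals.residuals
    if r.shape[1] < 2:
        raise ParameterError("need at least 2 cells to standardize")
    mean = r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, ddof=1, keepdims=True)
    keep = (sd > 0).ravel()
    if not keep.any():
        raise ParameterError("every gene has zero residual variance")
    if not keep.all():
        logger.warning("dropping %d zero-variance gene(s)", int((~keep).sum()))
    z = (r[keep] - mean[keep]) / sd[keep]
    genes = [g for g, k in zip(residuals.genes, keep) if k]
    return pd.DataFrame(z, index=genes, columns=residuals.cells)


@dataclass
class MembershipScores:
    """Per-cell signature scores with gene-usage bookkeeping."""

    signature: str
    scores: pd.Series = field(repr=False)
    n_genes_used: int = 0
    genes_missing: tuple[str, ...] = ()


def membership_score(
    z: pd.DataFrame,
    signature_genes: Sequence[str],
    name: str = "signature",
    symbol_map: Mapping[str, str] | None = None,
) -> MembershipScores:
    """Per-cell mean z-score over the signature genes present in the matrix.

    Gene identifiers match case-insensitively; ``symbol_map`` optionally
    translates signature identifiers (e.g. human symbols) to the matrix's
    namespace first. Missing genes are reported, never imputed.
    """
    lookup = {g.lower(): g for g in z.index}
    used, missing = [], []
    for g in signature_genes:
        mapped = symbol_map.get(g, g) if symbol_map else g
        row = lookup.get(str(mapped).lower())
        (used if row is not None else missing).append(row if row is not None else g)
    if not used:
        raise ParameterError(
            f"signature {name!r} shares no genes with the matrix; missing: {missing}"
        )
    scores = z.loc[used].mean(axis=0)
    scores.name = name
    return MembershipScores(
        signature=name,
        scores=scores,
        n_genes_used=len(used),
        genes_missing=tuple(missing),
    )


def score_signatures(
    counts: CountMatrix,
    signatures: Mapping[str, Sequence[str]],
    model: NoiseModel,
    symbol_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """End-to-end scoring: residuals -> z-scores -> per-signature means.

    Returns a cells x signatures DataFrame of membership scores.
    """
    z = standardize_residuals(pearson_residuals(counts, model))
    cols = {
        name: membership_score(z, genes, name=name, symbol_map=symbol_map).scores
        for name, genes in signatures.items()
    }
    return pd.DataFrame(cols)


def cluster_centroid_distances(
    coords: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    n_dims: int | None = None,
) -> pd.DataFrame:
    """Pairwise Euclidean distances between cluster centroids.

    The centroid of a cluster is the per-cluster mean of the first
    ``n_dims`` embedding coordinates (all coordinates when None). Clusters
    with zero cells are excluded with a warning. The result is symmetric
    with a zero diagonal.
    """
    coords = pd.DataFrame(np.asarray(coords, dtype=float))
    labels = pd.Series(list(labels), index=coords.index, name="cluster")
    if len(labels) != len(coords):
        raise ParameterError("labels and coordinates differ in length")
    if n_dims is not None:
        if n_dims < 1 or n_dims > coords.shape[1]:
            raise ParameterError(
                f"n_dims must be in [1, {coords.shape[1]}], got {n_dims}"
            )
        coords = coords.iloc[:, :n_dims]
    centroids = coords.groupby(labels, observed=True).mean()
    if isinstance(labels.dtype, pd.CategoricalDtype):
        empty = set(labels.cat.categories) - set(centroids.index)
        if empty:
            logger.warning("excluding empty cluster(s): %s", sorted(empty))
    if len(centroids) < 2:
        raise ParameterError("need at least 2 non-empty clusters")
    dist = squareform(pdist(centroids.to_numpy()))
    return pd.DataFrame(dist, index=centroids.index, columns=centroids.index)


def estimate_cv(counts: CountMatrix) -> float:
    """Moment-based estimate of the biological CV from a count matrix.

    Fits the quadratic mean-variance relation ``var = mu + c^2 mu^2`` across
    genes by least squares on ``var - mu`` against ``mu^2``. A convenience
    for choosing ``c``; not part of the canonical scoring procedure.
    """
    x = counts.dense().astype(float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    keep = mean > 0
    if keep.sum() < 2:
        raise ParameterError("too few expressed genes to estimate a CV")
    m, v = mean[keep], var[keep]
    c2 = float(np.sum((v - m) * m**2) / np.sum(m**4))
    if c2 <= 0:
        raise ParameterError(
            "no extra-Poisson variance detected; the CV is not identifiable"
        )
    return math.sqrt(c2)
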