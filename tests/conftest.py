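import numpy as np
import pytest

from melanokit import scoring, synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """200-subject single-hit cohort with a 4-week lag (seed 1)."""
    spec = sd.CohortSpec(
        n_subjects=200, half_time_weeks=33.0, lag_weeks=4.0, followup_weeks=60.0, seed=1
    )
    table, truth = sd.simulate_incidence_cohort(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def loxp_library():
    """Error-free 200-cell loxP library at rho_true = 0.36 (seed 7)."""
    spec = sd.LoxPLibrarySpec(rho_true=0.36, n_cells_sampled=200, per_base_error=0.0, seed=7)
    reads, truth, config = sd.simulate_loxp_library(spec)
    return spec, reads, truth, config


@pytest.fixture(scope="session")
def null_counts():
    """Single-type NB count matrix (200 genes x 600 cells, c = 0.55)."""
    spec = sd.CountsSpec(
        n_genes=200, n_cells=600, type_proportions={"bg": 1.0}, biological_cv=0.55, seed=3
    )
    x, truth = sd.simulate_count_matrix(spec)
    cm = scoring.CountMatrix(genes=spec.gene_names, cells=spec.cell_names, x=x)
    return spec, cm, truth


@pytest.fixture(scope="session")
def planted_counts():
    """Counts with a 50-gene signature planted at log2FC = 1 in 20% of cells."""
    genes = [f"gene{i:04d}" for i in range(300)]
    sig = sd.PlantedSignature("planted", tuple(genes[:50]), 1.0)
    spec = sd.CountsSpec(
        n_genes=300,
        n_cells=1000,
        type_proportions={"background": 0.8, "planted": 0.2},
        planted_signatures=(sig,),
        biological_cv=0.55,
        seed=5,
    )
    x, truth = sd.simulate_count_matrix(spec)
    cm = scoring.CountMatrix(genes=spec.gene_names, cells=spec.cell_names, x=x)
    return spec, cm, truth, sig


def auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), independent of sklearn."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = positive.sum()
    n_neg = len(positive) - n_pos
    return (ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
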