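import numpy as np
import pandas as pd
import pytest

from edgestage.cohort_io import ExpressionMatrix, PhenotypeTable
from edgestage.edge_features import build_edge_matrix, fit_reference
from edgestage.synthetic_cohort import CohortDesign, generate_cohort


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """4 genes x 4 samples, raw scale, with a zero-heavy gene."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 0.0, 3.0, 0.0],
            "s2": [2.0, 0.0, 0.0, 7.0],
            "s3": [4.0, 1.0, 0.0, 0.0],
            "s4": [8.0, 0.0, 0.0, 1.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return ExpressionMatrix(values, log_transformed=False)


def small_design(seed: int = 11, **kw) -> CohortDesign:
    """A scaled-down cohort used by unit tests (fast to generate and rank)."""
    kw.setdefault("n_genes", 80)
    kw.setdefault("n_pairs", 40)
    kw.setdefault("samples_per_class", {s: 25 for s in ("normal", "I", "II", "III", "IV")})
    kw.setdefault("n_node_genes", 6)
    kw.setdefault("n_pcc_pairs", 4)
    kw.setdefault("n_cov_pairs", 4)
    kw.setdefault("n_residual_pairs", 4)
    return CohortDesign(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """Generated small cohort: (expr, pheno, universe, truth)."""
    return generate_cohort(small_design())


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    expr, pheno, universe, _ = small_cohort
    return fit_reference(expr, pheno, universe)


@pytest.fixture(scope="session")
def small_edge_matrices(small_cohort, small_reference):
    expr, pheno, _, _ = small_cohort
    return {
        t: build_edge_matrix(small_reference, expr, pheno, t)
        for t in ("delta_pcc", "delta_cov", "residual")
    }


@pytest.fixture(scope="session")
def small_feature_pools(small_cohort, small_edge_matrices):
    """Per-type feature matrices for ranking/integration tests."""
    expr, pheno, _, truth = small_cohort
    pools = {t: em.values for t, em in small_edge_matrices.items()}
    node_pool = list(truth.planted_node_genes) + [
        g for g in expr.gene_ids[6:20]
    ]  # planted node genes plus noise genes
    pools["node"] = expr.values.loc[node_pool].T
    return pools


FAST_FOREST = {"n_estimators": 60, "random_state": 42}
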