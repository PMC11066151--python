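import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from frontsig.io_formats import EARLY_RELAPSE, NO_RELAPSE
from frontsig.synthetic_data import SimulationConfig, simulate_study

settings.register_profile("suite", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("suite")


def make_labeled_matrix(n_pos, n_neg, n_genes, seed, effect=0.0,
                        signs=None, n_signal=0):
    """Gaussian genes x samples matrix with optional planted signal.

    The first ``n_signal`` genes get a between-group mean difference of
    ``effect`` with the given signs (+1 up in early relapse).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    x = rng.normal(8.0, 1.0, size=(n_genes, n_pos + n_neg))
    if n_signal:
        signs = np.asarray(signs if signs is not None else [1] * n_signal)
        for i in range(n_signal):
            x[i, :n_pos] += signs[i] * effect / 2.0
            x[i, n_pos:] -= signs[i] * effect / 2.0
    samples = [f"P{j:03d}" for j in range(n_pos + n_neg)]
    expr = pd.DataFrame(x, index=genes, columns=samples)
    pheno = pd.Series([EARLY_RELAPSE] * n_pos + [NO_RELAPSE] * n_neg,
                      index=samples, name="group")
    return expr, pheno


@pytest.fixture(scope="session")
def small_study():
    """A compact planted-signal paired cohort for pipeline tests."""
    config = SimulationConfig(
        n_genes=300, n_sets=6, genes_per_set=12,
        n_early=10, n_no=10, missing_if=2,
        planted_sets=("SET01", "SET02"), effect_size=1.5,
        seed=42,
    )
    bulk, front, phenotype, gene_sets = simulate_study(config)
    return {"config": config, "bulk": bulk, "front": front,
            "phenotype": phenotype, "gene_sets": gene_sets}


@pytest.fixture()
def tiny_expr():
    expr = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [0.5, 0.5, 0.5, 0.5]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    pheno = pd.Series([NO_RELAPSE, NO_RELAPSE, EARLY_RELAPSE, EARLY_RELAPSE],
                      index=expr.columns, name="group")
    return expr, pheno
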