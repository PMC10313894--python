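import numpy as np
import pandas as pd
import pytest

from cellregvar import simulate as sim
from cellregvar.feature_model import FeatureGrid, FeatureLayout, TrainConfig, \
    train_expression_model


@pytest.fixture(scope="session")
def small_layout():
    # 4 features x 6 bins = 24 slots
    return FeatureLayout(window_bp=600, bin_bp=200, n_features=4)


@pytest.fixture(scope="session")
def grid_fixture():
    """Grids + noiseless linear expression for 90 genes, 4 clusters."""
    grids, truth = sim.gen_feature_grids(90, 5, 8, rank=3, noise_sd=0.05,
                                         seed=11)
    rng = np.random.default_rng(7)
    W = rng.normal(size=(4, 40)) / np.sqrt(40)
    expr, _ = sim.gen_expression_from_grids(grids, W, noise_sd=0.0, seed=11)
    gene_table = sim.gen_gene_table(90, seed=11)
    return {"grids": grids, "weights": W, "expr": expr,
            "gene_table": gene_table, "truth": truth}


@pytest.fixture(scope="session")
def trained_models(grid_fixture):
    grids = grid_fixture["grids"]
    expr = grid_fixture["expr"]
    X = np.stack([grids[g].flatten() for g in expr.index])
    cfg = TrainConfig(l2_lambda=1.0)
    return [train_expression_model(X, expr[c].to_numpy(), cfg, seed=3 + j,
                                   cluster_id=c)
            for j, c in enumerate(expr.columns)]


@pytest.fixture(scope="session")
def genotypes_200():
    return sim.gen_genotypes(200, 30, ld_block=5, copy_prob=0.95, seed=5)
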