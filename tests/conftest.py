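import numpy as np
import pandas as pd
import pytest

from devstab import ExpressionMatrix, SimulationConfig


def make_matrix(values, sample_meta=None, scale="log10p1", genes=None):
    """Small ExpressionMatrix from a 2-D array; metadata defaults to embryos."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{j}" for j in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame(index=pd.Index(samples, name="sample"))
    meta["stage"] = "st1"
    meta["strain"] = "inbred"
    meta["sex"] = "F"
    meta["pair_id"] = ""
    meta["role"] = "embryo"
    if sample_meta:
        for col, vals in sample_meta.items():
            meta[col] = vals
    return ExpressionMatrix(df, meta, scale)


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=400, n_pairs_per_stage=8, seed=101)


@pytest.fixture
def null_config():
    """Twin noise equals technical noise: flat coupling, no gene heterogeneity."""
    return SimulationConfig(
        n_genes=800,
        n_pairs_per_stage=20,
        seed=7,
        stage_noise_sd=(0.05, 0.05, 0.05, 0.05),
        tech_noise_sd=0.05,
        mean_variance_coupling=(1.0, 0.0, 1.0),
        gene_scale_heterogeneity=0.0,
    )
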