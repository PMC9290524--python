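import numpy as np
import pandas as pd
import pytest

from foragenet import expression as ex
from foragenet import simulate


def make_expression(values: np.ndarray, genes=None, samples=None, scale="log2"):
    """Wrap a raw array as an ExpressionMatrix for fixture-free tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ex.ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        scale=scale,
    )


@pytest.fixture(scope="session")
def small_config():
    """A fast 3-module configuration used by several stages."""
    return simulate.SimulationConfig(
        n_samples=60,
        n_modules=3,
        genes_per_module=40,
        n_background_genes=100,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    factors = simulate.generate_factor_table(small_config)
    counts, truth = simulate.generate_expression(small_config, factors)
    logexpr = ex.log_transform(ex.filter_by_mean_tpm(ex.counts_to_tpm(counts)))
    return {"factors": factors, "counts": counts, "truth": truth, "logexpr": logexpr}


@pytest.fixture(scope="session")
def default_dataset():
    """The reference benchmark conditions (5 x 100 planted genes, 500
    background, 100 samples)."""
    config = simulate.SimulationConfig(seed=101)
    factors = simulate.generate_factor_table(config)
    counts, truth = simulate.generate_expression(config, factors)
    logexpr = ex.log_transform(ex.filter_by_mean_tpm(ex.counts_to_tpm(counts)))
    return {
        "config": config,
        "factors": factors,
        "counts": counts,
        "truth": truth,
        "logexpr": logexpr,
    }
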