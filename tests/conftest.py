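import numpy as np
import pytest

from icaqtl import SimulationConfig, simulate_dataset, standardize_genes
from icaqtl.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated cohort under the generator defaults (seed 7)."""
    cfg = SimulationConfig(seed=7)
    expr, geno, truth = simulate_dataset(cfg)
    return cfg, expr, geno, truth


@pytest.fixture(scope="session")
def standardized_default(default_dataset):
    _, expr, _, _ = default_dataset
    return standardize_genes(expr)


def make_expression(values, state="arcsinh", detection_p=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(g)],
        sample_ids=[f"s{j}" for j in range(n)],
        detection_p=detection_p,
        transform_state=state,
    )


@pytest.fixture
def expr_factory():
    return make_expression
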