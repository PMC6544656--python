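import numpy as np
import pandas as pd
import pytest

from revtranslate import coexpression as cx
from revtranslate import preprocess as pp
from revtranslate.synthetic import ExprSimConfig, simulate_expression


@pytest.fixture(scope="session")
def small_expression():
    """300-gene matrix with two planted 30-gene modules, one down in cases."""
    cfg = ExprSimConfig(
        n_genes=300, module_sizes=(30, 30), case_shift_per_module=(-1.5, 0.0), seed=11
    )
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_expression):
    expr, traits, truth = small_expression
    kept = pp.background_filter(expr, traits)
    norm = pp.drop_zero_variance(
        pp.baseline_transform(pp.quantile_normalize(expr.loc[kept]))
    )
    return norm, traits, truth


@pytest.fixture(scope="session")
def small_network(small_normalized):
    norm, traits, truth = small_normalized
    cor = cx.correlation_matrix(norm)
    adj = cx.adjacency(cor, cx.DEFAULT_BETA)
    tom = cx.topological_overlap(adj)
    detection = cx.detect_modules(tom, min_module_size=10, expr=norm)
    return norm, traits, truth, adj, detection


def random_correlation_like(rng: np.random.Generator, n_genes: int = 15) -> pd.DataFrame:
    """A valid correlation matrix from random expression profiles."""
    x = rng.standard_normal((n_genes, 10))
    cor = np.corrcoef(x)
    ids = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(cor, index=ids, columns=ids)
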