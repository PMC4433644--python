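import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from modmir.expression import ExpressionMatrix
from modmir.synthetic import SyntheticConfig, generate_expression, generate_ppi


@pytest.fixture
def toy_matrix():
    """Six samples in two groups; three features with known structure."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0],
            "s2": [2.0, 5.5, 2.0],
            "s3": [3.0, 4.5, 2.0],
            "s4": [4.0, 5.0, 2.0],
            "s5": [5.0, 5.5, 2.0],
            "s6": [6.0, 4.5, 2.0],
        },
        index=pd.Index(["A", "B", "C"], name="feature_id"),
    )
    groups = pd.Series(
        ["case", "case", "case", "control", "control", "control"],
        index=values.columns,
    )
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted benchmark shared by slower tests."""
    config = SyntheticConfig(
        n_genes=400,
        n_mirnas=40,
        n_planted_modules=3,
        intra_module_edge_prob=1.0,
        seed=11,
    )
    net, truth = generate_ppi(config)
    genes = generate_expression(config, truth, "gene")
    mirnas = generate_expression(config, truth, "mirna")
    return config, net, truth, genes, mirnas


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
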